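"""GWAS summary statistics: containers, delimited-text I/O, and allele harmonization.

A :class:`SumStats` wraps one trait's per-SNP association records (effect
sizes are per-allele; log-odds for case-control traits, SD units for
quantitative traits). :func:`harmonize` aligns an exposure and an outcome
GWAS to a common effect allele, the step every two-sample Mendelian
randomization analysis needs before ratio estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

QUANTITATIVE = "quantitative"
CASE_CONTROL = "case_control"

#: canonical column order for summary-statistics tables
COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

NOT_PALINDROMIC = "not_palindromic"
PALINDROMIC_RESOLVABLE = "palindromic_resolvable"
PALINDROMIC_AMBIGUOUS = "palindromic_ambiguous"

KEPT = "kept"
FLIPPED = "flipped"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_INCOMPATIBLE = "dropped_incompatible"

HARMONIZED_COLUMNS = [
    "snp_id", "beta_exp", "se_exp", "pval_exp", "eaf_exp",
    "beta_out", "se_out", "pval_out", "action",
]


class ConfigurationError(ValueError):
    """A run configuration (column map, gene id, preset …) is invalid."""


class InputError(ValueError):
    """Input data violate a precondition (empty table, missing SNP …)."""


@dataclass
class SumStats:
    """One trait's GWAS summary statistics.

    Parameters
    ----------
    trait_id:
        Identifier for the trait (protein, disease endpoint, lifestyle item).
    trait_type:
        ``"quantitative"`` (betas per SD) or ``"case_control"`` (log-odds).
    df:
        Records with columns :data:`COLUMNS`; ``snp_id`` unique.
    n_case, n_control:
        Case/control counts, required for case-control traits.
    """

    trait_id: str
    trait_type: str
    df: pd.DataFrame
    n_case: int | None = None
    n_control: int | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in (QUANTITATIVE, CASE_CONTROL):
            raise ConfigurationError(
                f"trait_type must be {QUANTITATIVE!r} or {CASE_CONTROL!r}, "
                f"got {self.trait_type!r}"
            )
        if self.trait_type == CASE_CONTROL and not (self.n_case and self.n_control):
            raise ConfigurationError(
                "case_control traits require n_case and n_control"
            )
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ConfigurationError(f"missing summary-stat columns: {missing}")
        if self.df["snp_id"].duplicated().any():
            dupes = self.df.loc[self.df["snp_id"].duplicated(), "snp_id"]
            raise InputError(
                f"duplicate snp_id within trait {self.trait_id!r}: "
                f"{sorted(set(dupes))[:5]}"
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def effective_n(self) -> float:
        """Sample size used on the z-score scale.

        For case-control traits this is the effective sample size
        ``4 / (1/n_case + 1/n_control)``; otherwise the median per-SNP n.
        """
        if self.trait_type == CASE_CONTROL:
            return 4.0 / (1.0 / self.n_case + 1.0 / self.n_control)
        return float(np.median(self.df["n"]))

    def sorted(self) -> "SumStats":
        """Records ordered by (chrom, pos)."""
        df = self.df.sort_values(["chrom", "pos"], kind="mergesort")
        return replace(self, df=df.reset_index(drop=True))

    def subset(self, snp_ids) -> "SumStats":
        keep = self.df[self.df["snp_id"].isin(list(snp_ids))]
        return replace(self, df=keep.reset_index(drop=True))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, columns=COLUMNS)


def validate_records(df: pd.DataFrame, trait_id: str = "?") -> pd.DataFrame:
    """Drop rows violating record invariants; log the dropped count.

    Invariants enforced: se > 0, pval in (0, 1], eaf in [0, 1] when present,
    effect_allele != other_allele, pos > 0. Rows where the supplied p-value
    disagrees with the normal approximation from |beta/se| by more than 10%
    (relative, on the z scale) are warned about but retained.
    """
    ok = (
        (df["se"] > 0)
        & (df["pval"] > 0)
        & (df["pval"] <= 1)
        & (df["pos"] > 0)
        & (df["effect_allele"].astype(str) != df["other_allele"].astype(str))
        & (df["eaf"].isna() | ((df["eaf"] >= 0) & (df["eaf"] <= 1)))
        & df["beta"].notna()
        & df["se"].notna()
    )
    n_bad = int((~ok).sum())
    if n_bad:
        log.info("trait %s: dropped %d invalid record(s)", trait_id, n_bad)
    out = df[ok].reset_index(drop=True)

    z_obs = np.abs(out["beta"] / out["se"])
    z_imp = stats.norm.isf(np.clip(out["pval"], 1e-300, 1.0) / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(z_imp - z_obs) / np.where(z_obs > 0, z_obs, np.nan)
    n_warn = int(np.nansum(rel > 0.10))
    if n_warn:
        log.warning(
            "trait %s: %d record(s) with p inconsistent with |beta/se| "
            "beyond 10%% on the z scale", trait_id, n_warn,
        )
    return out


def read_sumstats(
    path,
    column_map: dict | None = None,
    trait_type: str = QUANTITATIVE,
    trait_id: str | None = None,
    n_case: int | None = None,
    n_control: int | None = None,
    sep: str | None = None,
) -> SumStats:
    """Read a delimited summary-statistics table into a :class:`SumStats`.

    ``column_map`` maps canonical names (:data:`COLUMNS`) to the file's
    column names; canonical names present in the file need no entry.
    Rows failing record invariants are dropped (count logged).
    """
    column_map = dict(column_map or {})
    df = pd.read_csv(path, sep=sep, engine="python")
    if df.empty:
        raise InputError(f"{path}: empty summary-statistics table")
    rename = {}
    for canon in COLUMNS:
        src = column_map.get(canon, canon)
        if src not in df.columns:
            if canon in ("eaf", "n"):
                df[canon] = np.nan
                continue
            raise ConfigurationError(
                f"{path}: required column {canon!r} (file column {src!r}) not found"
            )
        rename[src] = canon
    df = df.rename(columns=rename)
    df = df[COLUMNS].copy()
    for col in ("pos",):
        df[col] = df[col].astype(int)
    for col in ("eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["chrom"] = df["chrom"].astype(str)
    df = validate_records(df, trait_id or str(path))
    if df.empty:
        raise InputError(f"{path}: no valid records after filtering")
    return SumStats(
        trait_id=trait_id or str(path),
        trait_type=trait_type,
        df=df,
        n_case=n_case,
        n_control=n_control,
    )


def is_palindromic(
    effect_allele: str,
    other_allele: str,
    eaf: float | None,
    ambiguity_band: float = 0.08,
) -> str:
    """Classify an allele pair's strand ambiguity.

    A/T and C/G pairs read the same on both strands; they are resolvable by
    allele frequency unless the effect-allele frequency is missing or within
    ``ambiguity_band`` of 0.5.
    """
    a, b = str(effect_allele).upper(), str(other_allele).upper()
    if not (a in _BASES and b in _BASES):
        return NOT_PALINDROMIC
    if _COMPLEMENT[a] != b:
        return NOT_PALINDROMIC
    if eaf is None or (isinstance(eaf, float) and np.isnan(eaf)):
        return PALINDROMIC_AMBIGUOUS
    if abs(float(eaf) - 0.5) < ambiguity_band:
        return PALINDROMIC_AMBIGUOUS
    return PALINDROMIC_RESOLVABLE


def _classify_pair(ea_x, oa_x, ea_y, oa_y):
    """How outcome alleles relate to exposure alleles.

    Returns one of ``same`` (identical orientation), ``swap`` (effect and
    other allele exchanged), or ``None`` (incompatible). Opposite-strand
    reports (complemented alleles) map onto same/swap.
    """
    if (ea_y, oa_y) == (ea_x, oa_x):
        return "same"
    if (ea_y, oa_y) == (oa_x, ea_x):
        return "swap"
    if all(a in _BASES for a in (ea_x, oa_x, ea_y, oa_y)):
        cx = (_COMPLEMENT[ea_x], _COMPLEMENT[oa_x])
        if (ea_y, oa_y) == cx:
            return "same"
        if (ea_y, oa_y) == (cx[1], cx[0]):
            return "swap"
    return None


def harmonize(
    exposure: SumStats,
    outcome: SumStats,
    drop_ambiguous_palindromic: bool = True,
    ambiguity_band: float = 0.08,
) -> pd.DataFrame:
    """Align outcome effects to the exposure's effect allele.

    SNPs are matched by ``snp_id``. Outcome records in the reverse
    orientation get their beta sign flipped (and frequency complemented);
    palindromic SNPs are aligned by allele frequency when both frequencies
    are available, and dropped when ambiguous and the flag is set. Indels,
    multi-allelic and otherwise incompatible pairs are dropped.

    Returns a table with columns :data:`HARMONIZED_COLUMNS`; dropped rows
    carry no estimates (NaN), only the action code.
    """
    if len(exposure) == 0 or len(outcome) == 0:
        raise InputError("harmonize: both traits must be nonempty")
    merged = exposure.df.merge(
        outcome.df, on="snp_id", how="inner", suffixes=("_exp", "_out")
    )
    if merged.empty:
        log.warning(
            "harmonize: no shared SNPs between %s and %s",
            exposure.trait_id, outcome.trait_id,
        )
        return pd.DataFrame(columns=HARMONIZED_COLUMNS)

    rows = []
    for rec in merged.itertuples(index=False):
        ea_x = str(rec.effect_allele_exp).upper()
        oa_x = str(rec.other_allele_exp).upper()
        ea_y = str(rec.effect_allele_out).upper()
        oa_y = str(rec.other_allele_out).upper()
        action = None
        if not all(a in _BASES for a in (ea_x, oa_x, ea_y, oa_y)):
            # indels / multi-base alleles: only biallelic SNVs are used
            action = DROPPED_INCOMPATIBLE
        else:
            pal = is_palindromic(ea_x, oa_x, rec.eaf_exp, ambiguity_band)
            rel = _classify_pair(ea_x, oa_x, ea_y, oa_y)
            if rel is None:
                action = DROPPED_INCOMPATIBLE
            elif pal == PALINDROMIC_AMBIGUOUS and drop_ambiguous_palindromic:
                action = DROPPED_PALINDROMIC
            elif pal != NOT_PALINDROMIC:
                # strand is unknowable from alleles; align minor/major by eaf
                eaf_y = rec.eaf_out
                if not (pd.isna(rec.eaf_exp) or pd.isna(eaf_y)):
                    same_side = (rec.eaf_exp < 0.5) == (eaf_y < 0.5)
                    action = KEPT if same_side else FLIPPED
                else:
                    action = KEPT if rel == "same" else FLIPPED
            else:
                action = KEPT if rel == "same" else FLIPPED

        if action in (KEPT, FLIPPED):
            sign = 1.0 if action == KEPT else -1.0
            rows.append((
                rec.snp_id, rec.beta_exp, rec.se_exp, rec.pval_exp, rec.eaf_exp,
                sign * rec.beta_out, rec.se_out, rec.pval_out, action,
            ))
        else:
            rows.append((
                rec.snp_id, np.nan, np.nan, np.nan, np.nan,
                np.nan, np.nan, np.nan, action,
            ))
    out = pd.DataFrame(rows, columns=HARMONIZED_COLUMNS)
    n_drop = int(out["action"].str.startswith("dropped").sum())
    if n_drop:
        log.info(
            "harmonize %s vs %s: dropped %d of %d shared SNP(s)",
            exposure.trait_id, outcome.trait_id, n_drop, len(out),
        )
    return out


def kept_pairs(harmonized: pd.DataFrame) -> pd.DataFrame:
    """Rows of a harmonization table that carry usable estimates."""
    return harmonized[harmonized["action"].isin([KEPT, FLIPPED])].reset_index(drop=True)
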