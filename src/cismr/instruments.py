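"""Instrument selection for a cis-pQTL (or lifestyle) exposure.

Selection composes four criteria: a cis window around the gene's
transcription start site, genome-wide significance, greedy LD clumping
(PLINK-style, smallest p first), and the weak-instrument F gate F > 10.
Two presets mirror the two instrument regimes of a proteome-wide screen:
``pqtl`` (P < 5e-8, r² < 0.1, 10,000 kb) and ``lifestyle``
(P < 1e-5, r² < 0.001, 10,000 kb).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .sumstats import ConfigurationError, InputError, SumStats

CIS_FAIL = "cis_fail"
PVAL_FAIL = "pval_fail"
CLUMPED_OUT = "clumped_out"
WEAK_INSTRUMENT = "weak_instrument"
SELECTED = "selected"


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene's location: identifier, chromosome, transcription start site (1-based bp)."""

    gene_id: str
    chrom: str
    tss: int

    def __post_init__(self):
        if self.tss <= 0:
            raise ConfigurationError(f"{self.gene_id}: tss must be positive")


def read_gene_annotations(path, sep: str | None = None) -> dict[str, GeneAnnotation]:
    """Read a 3-column (gene_id, chrom, tss) delimited annotation table."""
    df = pd.read_csv(path, sep=sep, engine="python")
    for col in ("gene_id", "chrom", "tss"):
        if col not in df.columns:
            raise ConfigurationError(f"{path}: missing annotation column {col!r}")
    genes = {}
    for rec in df.itertuples(index=False):
        g = GeneAnnotation(str(rec.gene_id), str(rec.chrom), int(rec.tss))
        if g.gene_id in genes:
            raise InputError(f"{path}: duplicate gene_id {g.gene_id!r}")
        genes[g.gene_id] = g
    return genes


@dataclass
class LDMatrix:
    """Pairwise correlation (r, signed) between the SNPs of one region."""

    snp_ids: list[str]
    r: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.snp_ids)
        if self.r.shape != (k, k):
            raise InputError(f"LD matrix shape {self.r.shape} != ({k}, {k})")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise InputError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise InputError("LD matrix diagonal is not 1")
        if np.linalg.eigvalsh(self.r).min() < -1e-8:
            raise InputError("LD matrix is not positive semidefinite")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def r2(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]] ** 2)

    def subset(self, snp_ids) -> "LDMatrix":
        idx = [self._index[s] for s in snp_ids]
        return LDMatrix(list(snp_ids), self.r[np.ix_(idx, idx)])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.r, columns=self.snp_ids).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t")
        return cls(list(df.columns), df.to_numpy(dtype=float))


@dataclass(frozen=True)
class InstrumentConfig:
    """Thresholds for the four selection criteria."""

    window_bp: int = 1_000_000
    p_max: float = 5e-8
    r2_max: float = 0.1
    clump_window_kb: int = 10_000
    f_min: float = 10.0

    def __post_init__(self):
        if not (0 < self.p_max < 1):
            raise ConfigurationError("p_max must lie in (0, 1)")
        if not (0 < self.r2_max < 1):
            raise ConfigurationError("r2_max must lie in (0, 1)")


PRESETS = {
    "pqtl": InstrumentConfig(),
    "lifestyle": InstrumentConfig(p_max=1e-5, r2_max=0.001),
}


@dataclass
class InstrumentSet:
    """Outcome of instrument selection for one exposure.

    ``selected`` holds the surviving records, ``f_stats`` their per-SNP F,
    and ``selection_log`` one reason code per input SNP.
    """

    exposure_id: str
    selected: pd.DataFrame
    f_stats: pd.Series
    selection_log: pd.DataFrame

    def __len__(self) -> int:
        return len(self.selected)


def cis_filter(sumstats: SumStats, gene: GeneAnnotation, window_bp: int = 1_000_000) -> SumStats:
    """Keep SNPs on the gene's chromosome within ±window_bp of its TSS (closed bounds)."""
    if window_bp <= 0:
        raise ConfigurationError("window_bp must be positive")
    df = sumstats.df
    keep = (df["chrom"].astype(str) == str(gene.chrom)) & (
        (df["pos"] - gene.tss).abs() <= window_bp
    )
    return replace(sumstats, df=df[keep].reset_index(drop=True))


def significance_filter(sumstats: SumStats, p_max: float = 5e-8) -> SumStats:
    """Keep SNPs with p strictly below p_max (boundary excluded, as printed)."""
    if not (0 < p_max < 1):
        raise ConfigurationError("p_max must lie in (0, 1)")
    df = sumstats.df
    return replace(sumstats, df=df[df["pval"] < p_max].reset_index(drop=True))


def ld_clump(
    candidates: SumStats,
    ld: LDMatrix,
    r2_max: float = 0.1,
    window_kb: int = 10_000,
) -> tuple[SumStats, pd.DataFrame]:
    """Greedy p-ordered LD clumping.

    Repeatedly keep the remaining SNP with the smallest p (ties broken by
    snp_id), then discard remaining SNPs within ``window_kb`` of it whose
    squared correlation with it is >= ``r2_max``. Returns the kept records
    and a (snp_id, reason) log over all candidates.
    """
    df = candidates.df
    missing = [s for s in df["snp_id"] if s not in ld._index]
    if missing:
        raise InputError(f"candidate SNP(s) absent from LD matrix: {missing[:5]}")
    order = df.sort_values(["pval", "snp_id"], kind="mergesort")
    alive = dict(zip(order["snp_id"], order["pos"]))
    kept, reasons = [], {}
    for snp, pos in list(alive.items()):
        if snp not in alive:
            continue
        kept.append(snp)
        reasons[snp] = SELECTED
        del alive[snp]
        for other, opos in list(alive.items()):
            if abs(opos - pos) <= window_kb * 1000 and ld.r2(snp, other) >= r2_max:
                reasons[other] = CLUMPED_OUT
                del alive[other]
    log = pd.DataFrame(
        {"snp_id": list(reasons), "reason": [reasons[s] for s in reasons]}
    )
    kept_df = df[df["snp_id"].isin(kept)].reset_index(drop=True)
    return replace(candidates, df=kept_df), log


def f_statistic(beta, se):
    """Per-SNP instrument-strength F: the squared z-score (beta/se)²."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise InputError("f_statistic: se must be positive")
    return (beta / se) ** 2


def select_instruments(
    sumstats: SumStats,
    gene: GeneAnnotation | None,
    ld: LDMatrix,
    cfg: InstrumentConfig = PRESETS["pqtl"],
) -> InstrumentSet:
    """Apply the four criteria in order: cis window, significance, clump, F gate.

    ``gene=None`` skips the cis restriction (lifestyle exposures, reverse
    mode). The selection log covers every input SNP exactly once with the
    first criterion it failed.
    """
    reasons = {}
    stage = sumstats
    if gene is not None:
        cis = cis_filter(stage, gene, cfg.window_bp)
        for s in stage.df["snp_id"]:
            if s not in set(cis.df["snp_id"]):
                reasons[s] = CIS_FAIL
        stage = cis
    sig = significance_filter(stage, cfg.p_max)
    sig_ids = set(sig.df["snp_id"])
    for s in stage.df["snp_id"]:
        if s not in sig_ids:
            reasons[s] = PVAL_FAIL
    if len(sig) == 0:
        empty = sig.df.iloc[0:0]
        return InstrumentSet(
            exposure_id=sumstats.trait_id,
            selected=empty,
            f_stats=pd.Series(dtype=float),
            selection_log=_as_log(sumstats, reasons),
        )
    clumped, clump_log = ld_clump(sig, ld, cfg.r2_max, cfg.clump_window_kb)
    for rec in clump_log.itertuples(index=False):
        if rec.reason == CLUMPED_OUT:
            reasons[rec.snp_id] = CLUMPED_OUT
    f = f_statistic(clumped.df["beta"], clumped.df["se"])
    strong = f > cfg.f_min
    for s, ok in zip(clumped.df["snp_id"], strong):
        reasons[s] = SELECTED if ok else WEAK_INSTRUMENT
    selected = clumped.df[np.asarray(strong)].reset_index(drop=True)
    f_stats = pd.Series(np.asarray(f)[np.asarray(strong)], index=selected["snp_id"])
    return InstrumentSet(
        exposure_id=sumstats.trait_id,
        selected=selected,
        f_stats=f_stats,
        selection_log=_as_log(sumstats, reasons),
    )


def _as_log(sumstats: SumStats, reasons: dict) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": sumstats.df["snp_id"],
            "reason": [reasons[s] for s in sumstats.df["snp_id"]],
        }
    )
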