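"""End-to-end orchestration of the causal screen.

Stage order mirrors the study design: proteome-wide forward MR with FDR
prioritization, Bayesian colocalization follow-up of the FDR survivors,
reverse MR (disease as exposure) to exclude reverse causation, and
lifestyle-factor MR on the validated proteins. Every stage is a plain
function over in-memory objects; :func:`run_all` wires them together and
:func:`write_report` persists delimited tables plus a run manifest. A fixed
seed reproduces every table byte-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coloc import (
    DEFAULT_P1, DEFAULT_P2, DEFAULT_P12,
    coloc_abf, coloc_decision, coloc_from_harmonized,
)
from .instruments import (
    PRESETS, GeneAnnotation, InstrumentConfig,
    f_statistic, ld_clump, significance_filter, select_instruments,
)
from .mr import fdr_table, mr_per_exposure
from .sumstats import (
    CASE_CONTROL, QUANTITATIVE, InputError, SumStats, harmonize, kept_pairs,
)
from .synth import SyntheticStudy, simulate_mr_study

log = logging.getLogger(__name__)

MR_TABLE_COLUMNS = [
    "exposure", "outcome", "method", "n_snps", "beta", "se", "or", "ci_low",
    "ci_high", "pval", "pval_fdr", "significant", "q", "q_df", "q_pval",
    "egger_intercept", "egger_intercept_pval", "min_f",
]

COLOC_TABLE_COLUMNS = [
    "exposure", "outcome", "n_snps", "pph0", "pph1", "pph2", "pph3", "pph4",
    "decision", "reason",
]


@dataclass
class RunConfig:
    """Thresholds and options for one pipeline run."""

    preset: str = "pqtl"
    fdr_threshold: float = 0.05
    pph4_min: float = 0.75
    sum34_min: float = 0.8
    coloc_p1: float = DEFAULT_P1
    coloc_p2: float = DEFAULT_P2
    coloc_p12: float = DEFAULT_P12
    drop_ambiguous_palindromic: bool = True
    reverse_family: str = "passed"  # MR family for reverse FDR: the list passed in
    seed: int = 0

    def __post_init__(self):
        for name in ("fdr_threshold", "pph4_min", "sum34_min"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise InputError(f"RunConfig: {name} must lie in (0, 1)")

    @property
    def instrument_cfg(self) -> InstrumentConfig:
        return PRESETS[self.preset]


@dataclass
class StudyReport:
    forward: pd.DataFrame
    coloc: pd.DataFrame | None = None
    reverse: pd.DataFrame | None = None
    lifestyle: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def _gene_lookup(genes: pd.DataFrame) -> dict[str, GeneAnnotation]:
    return {
        str(r.gene_id): GeneAnnotation(str(r.gene_id), str(r.chrom), int(r.tss))
        for r in genes.itertuples(index=False)
    }


def _result_row(res, min_f=np.nan) -> dict:
    row = res.to_dict()
    row["min_f"] = min_f
    return row


def run_forward_mr(study: SyntheticStudy, cfg: RunConfig = RunConfig()):
    """Per-protein instrument selection, harmonization and MR, then BH-FDR.

    The FDR family is exactly the set of exposures that yielded at least one
    harmonized instrument; the rest are returned in the skip log.
    Returns (mr_table, skip_log).
    """
    genes = _gene_lookup(study.genes)
    icfg = cfg.instrument_cfg
    rows, skipped = [], []
    for prot in sorted(study.exposures):
        expo = study.exposures[prot]
        gene = genes.get(prot)
        if gene is None:
            raise InputError(f"run_forward_mr: no gene annotation for {prot}")
        instr = select_instruments(expo, gene, study.ld_regions[prot], icfg)
        if len(instr) == 0:
            counts = instr.selection_log["reason"].value_counts().to_dict()
            skipped.append({"exposure": prot, "reason": "no_instruments", **counts})
            continue
        sel = SumStats(prot, QUANTITATIVE, instr.selected)
        harm = kept_pairs(harmonize(
            sel, study.outcome,
            drop_ambiguous_palindromic=cfg.drop_ambiguous_palindromic,
        ))
        if harm.empty:
            skipped.append({"exposure": prot, "reason": "no_harmonized_snps"})
            continue
        res = mr_per_exposure(
            prot, study.outcome.trait_id,
            harm["beta_exp"], harm["se_exp"], harm["beta_out"], harm["se_out"],
        )
        rows.append(_result_row(res, min_f=float(instr.f_stats.min())))
    if not rows:
        raise InputError(
            f"run_forward_mr: no exposure yielded instruments "
            f"({len(skipped)} skipped)"
        )
    table = fdr_table(pd.DataFrame(rows), cfg.fdr_threshold)
    table = table[MR_TABLE_COLUMNS]
    return table, pd.DataFrame(skipped)


def fdr_survivors(mr_table: pd.DataFrame) -> list[str]:
    return list(mr_table.loc[mr_table["significant"], "exposure"])


def run_coloc_followup(
    study: SyntheticStudy, survivors: list[str], cfg: RunConfig = RunConfig()
) -> pd.DataFrame:
    """Colocalize each FDR survivor's cis region against the outcome signal."""
    rows = []
    for prot in survivors:
        if prot not in study.ld_regions or prot not in study.exposures:
            log.warning("coloc: no regional data for %s, skipped", prot)
            continue
        region_ids = study.ld_regions[prot].snp_ids
        expo = study.exposures[prot].subset(region_ids)
        out = study.outcome.subset(region_ids)
        if len(expo) == 0 or len(out) == 0:
            log.warning("coloc: empty region overlap for %s, skipped", prot)
            continue
        harm = harmonize(
            expo, out, drop_ambiguous_palindromic=cfg.drop_ambiguous_palindromic
        )
        ci = coloc_from_harmonized(
            harm,
            trait1_type=QUANTITATIVE,
            trait2_type=study.outcome.trait_type,
            p1=cfg.coloc_p1, p2=cfg.coloc_p2, p12=cfg.coloc_p12,
        )
        res = coloc_decision(coloc_abf(ci), cfg.pph4_min, cfg.sum34_min)
        rows.append({
            "exposure": prot, "outcome": study.outcome.trait_id,
            "n_snps": res.n_snps,
            "pph0": res.pph0, "pph1": res.pph1, "pph2": res.pph2,
            "pph3": res.pph3, "pph4": res.pph4,
            "decision": res.decision, "reason": res.reason,
        })
    return pd.DataFrame(rows, columns=COLOC_TABLE_COLUMNS)


def run_reverse_mr(
    study: SyntheticStudy, proteins: list[str], cfg: RunConfig = RunConfig()
) -> pd.DataFrame:
    """Disease-as-exposure MR against each protein, BH-FDR across proteins.

    Outcome instruments are selected genome-wide (no cis window) with the
    forward significance/clumping thresholds; cross-region LD is zero.
    """
    icfg = cfg.instrument_cfg
    sig = significance_filter(study.outcome, icfg.p_max)
    if len(sig) == 0:
        log.warning("reverse MR: outcome has no genome-wide-significant SNPs")
        return pd.DataFrame(
            [{"exposure": study.outcome.trait_id, "outcome": p, "method": "na",
              "n_snps": 0} for p in proteins]
        )
    ld = study.ld_for(list(sig.df["snp_id"]))
    clumped, _ = ld_clump(sig, ld, icfg.r2_max, icfg.clump_window_kb)
    f = f_statistic(clumped.df["beta"], clumped.df["se"])
    instr_df = clumped.df[np.asarray(f) > icfg.f_min].reset_index(drop=True)
    if instr_df.empty:
        log.warning("reverse MR: all outcome instruments weak (F <= %s)", icfg.f_min)
        return pd.DataFrame(
            [{"exposure": study.outcome.trait_id, "outcome": p, "method": "na",
              "n_snps": 0} for p in proteins]
        )
    out_as_exp = SumStats(
        study.outcome.trait_id, study.outcome.trait_type, instr_df,
        n_case=study.outcome.n_case, n_control=study.outcome.n_control,
    )
    rows = []
    for prot in proteins:
        harm = kept_pairs(harmonize(
            out_as_exp, study.exposures[prot],
            drop_ambiguous_palindromic=cfg.drop_ambiguous_palindromic,
        ))
        if harm.empty:
            rows.append({"exposure": study.outcome.trait_id, "outcome": prot,
                         "method": "na", "n_snps": 0})
            continue
        res = mr_per_exposure(
            study.outcome.trait_id, prot,
            harm["beta_exp"], harm["se_exp"], harm["beta_out"], harm["se_out"],
        )
        rows.append(_result_row(res))
    table = pd.DataFrame(rows)
    ok = table["method"] != "na" if "method" in table else []
    if len(table) and table.loc[ok].shape[0]:
        adj = fdr_table(table.loc[ok].copy(), cfg.fdr_threshold)
        table.loc[ok, "pval_fdr"] = adj["pval_fdr"].to_numpy()
        table.loc[ok, "significant"] = adj["significant"].to_numpy()
    return table


def run_lifestyle_mr(study: SyntheticStudy, cfg: RunConfig | None = None) -> pd.DataFrame:
    """MR of each lifestyle exposure on each protein.

    Uses the ``lifestyle`` instrument preset (P < 1e-5, r² < 0.001,
    10,000 kb). Headline inference is at nominal p; a BH-FDR column over
    all pairs is attached for reference but does not gate the flag.
    """
    cfg = cfg or RunConfig(preset="lifestyle")
    icfg = PRESETS["lifestyle"]
    rows = []
    for name in sorted(study.lifestyle):
        ls = study.lifestyle[name]
        instr = select_instruments(ls, None, study.ld_regions[f"LS_{name}"], icfg)
        if len(instr) == 0:
            log.warning("lifestyle MR: %s has no instruments", name)
            continue
        sel = SumStats(name, QUANTITATIVE, instr.selected)
        for prot in sorted(study.exposures):
            harm = kept_pairs(harmonize(
                sel, study.exposures[prot],
                drop_ambiguous_palindromic=cfg.drop_ambiguous_palindromic,
            ))
            if harm.empty:
                continue
            res = mr_per_exposure(
                name, prot,
                harm["beta_exp"], harm["se_exp"], harm["beta_out"], harm["se_out"],
            )
            rows.append(_result_row(res))
    table = pd.DataFrame(rows)
    if len(table):
        table = fdr_table(table, cfg.fdr_threshold)
        table = table.rename(columns={"significant": "significant_fdr"})
        table["significant_nominal"] = table["pval"] < 0.05
    return table


def write_report(
    outdir,
    report: StudyReport,
    cfg: RunConfig,
) -> None:
    """Write delimited result tables and a YAML run manifest.

    Re-running with the same seed and inputs reproduces every file
    byte-identically (no timestamps are recorded).
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"write_report: cannot create {outdir}: {exc}") from exc
    counts = {}
    for name, table in [
        ("forward_mr", report.forward), ("coloc", report.coloc),
        ("reverse_mr", report.reverse), ("lifestyle_mr", report.lifestyle),
    ]:
        if table is None:
            counts[name] = "not_run"
            continue
        table.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        counts[name] = int(len(table))
    manifest = {
        "cismr_version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "table_rows": counts,
    }
    manifest.update(report.manifest)
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def run_all(
    study: SyntheticStudy,
    cfg: RunConfig = RunConfig(),
    outdir=None,
) -> StudyReport:
    """Forward MR -> FDR -> coloc follow-up -> reverse MR -> lifestyle MR.

    Colocalization and reverse MR only ever see the FDR survivors; reverse
    MR's FDR family defaults to the coloc-validated proteins. Lifestyle MR
    runs when the study carries lifestyle traits.
    """
    forward, skipped = run_forward_mr(study, cfg)
    survivors = fdr_survivors(forward)
    coloc_table = run_coloc_followup(study, survivors, cfg)
    validated = (
        list(coloc_table.loc[coloc_table["decision"] == "colocalized", "exposure"])
        if len(coloc_table) else []
    )
    reverse_table = run_reverse_mr(study, validated, cfg) if validated else pd.DataFrame()
    lifestyle_table = run_lifestyle_mr(study, cfg) if study.lifestyle else None
    report = StudyReport(
        forward=forward,
        coloc=coloc_table,
        reverse=reverse_table if validated else None,
        lifestyle=lifestyle_table,
        manifest={
            "n_exposures_tested": int(len(forward)),
            "n_exposures_skipped": int(len(skipped)),
            "n_fdr_significant": int(len(survivors)),
            "n_colocalized": int(len(validated)),
        },
    )
    if outdir is not None:
        write_report(outdir, report, cfg)
    return report
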