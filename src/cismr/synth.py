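"""Synthetic GWAS summary statistics with known causal truth.

Summary statistics are drawn directly from the sampling distribution of
GWAS z-scores: for a region with LD correlation matrix R and joint
(per-standardized-genotype) causal effects b, the marginal z-vector is

    z ~ MVN( sqrt(n) * R b,  R )

with beta = z/sqrt(n) and se = 1/sqrt(n) on the standardized scale. For
case-control traits n is the effective sample size 4/(1/n_case + 1/n_control)
and betas are read on the log-odds scale. No individual-level genotypes are
simulated; this is sufficient (and exact, under the usual large-sample
approximation) for every downstream stage.

Defaults emulate the study conditions of a proteome-wide plasma-protein
screen against a binary disease endpoint: an exposure GWAS of 35,559
individuals, a disease GWAS of 11,755 cases / 441,978 controls, cis regions
with 1-2 independent genome-wide-significant instruments, and AR(1)
regional LD.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so each component's stream is
reproducible regardless of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .instruments import LDMatrix
from .sumstats import CASE_CONTROL, COLUMNS, QUANTITATIVE, InputError, SumStats

# non-palindromic allele pairs used for generated SNPs
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]

SHARED = "shared"
DISTINCT = "distinct"
NULL = "null"
EXPOSURE_ONLY = "exposure_only"


def effective_n(n_case: int, n_control: int) -> float:
    """Effective sample size of a case-control GWAS, 4/(1/n_case + 1/n_control)."""
    return 4.0 / (1.0 / n_case + 1.0 / n_control)


def ar1_ld(n_snps: int, rho: float, snp_ids: list[str] | None = None) -> LDMatrix:
    """AR(1) LD: r[i, j] = rho^|i-j|; symmetric and positive definite for rho in [0, 1)."""
    if not (0 <= rho < 1):
        raise InputError("ar1_ld: rho must lie in [0, 1)")
    idx = np.arange(n_snps)
    r = rho ** np.abs(np.subtract.outer(idx, idx)).astype(float)
    if snp_ids is None:
        snp_ids = [f"snp{i:04d}" for i in range(n_snps)]
    return LDMatrix(snp_ids, r)


@lru_cache(maxsize=8)
def _ar1_chol(n_snps: int, rho: float) -> np.ndarray:
    """Closed-form lower Cholesky factor of the AR(1) correlation matrix."""
    L = np.zeros((n_snps, n_snps))
    i, j = np.tril_indices(n_snps)
    scale = np.where(j == 0, 1.0, np.sqrt(1.0 - rho**2))
    L[i, j] = rho ** (i - j).astype(float) * scale
    return L


@dataclass
class Scenario:
    """Generative truth for one two-trait region.

    ``causal1``/``causal2`` are lists of (snp_index, joint effect) pairs per
    trait; when None they are filled from the ``sharing`` preset: ``shared``
    (one causal SNP common to both traits), ``distinct`` (one causal SNP
    each, far apart), ``null`` (no association), ``exposure_only``. Joint
    effects are per SD of standardized genotype; ``effect1 = 0.1`` puts
    ~1% of trait variance on the causal SNP. ``theta``, when set, makes the
    shared preset's trait-2 effect mediated: effect2 = theta * effect1.
    """

    n_snps: int = 200
    ld_rho: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    sharing: str = SHARED
    causal1: list[tuple[int, float]] | None = None
    causal2: list[tuple[int, float]] | None = None
    effect1: float = 0.1
    effect2: float = 0.1
    theta: float | None = None
    pleiotropy_sd: float = 0.0
    n1: int = 35_559
    trait2_type: str = CASE_CONTROL
    n2: int | None = None
    n_case: int = 11_755
    n_control: int = 441_978
    trait1_id: str = "protein"
    trait2_id: str = "disease"
    chrom: str = "1"
    tss: int = 1_500_000
    spacing_bp: int = 2_000
    seed: int = 0

    def __post_init__(self):
        if self.theta is not None and not np.isfinite(self.theta):
            raise InputError("Scenario: theta must be finite")
        if self.causal1 is None or self.causal2 is None:
            c1, c2 = self._preset_causals()
            self.causal1 = self.causal1 if self.causal1 is not None else c1
            self.causal2 = self.causal2 if self.causal2 is not None else c2
        for cfg in (self.causal1, self.causal2):
            for idx, _ in cfg:
                if not (0 <= idx < self.n_snps):
                    raise InputError(f"Scenario: causal index {idx} out of range")

    def _preset_causals(self):
        n = self.n_snps
        e2 = self.theta * self.effect1 if self.theta is not None else self.effect2
        if self.sharing == SHARED:
            return [(n // 2, self.effect1)], [(n // 2, e2)]
        if self.sharing == DISTINCT:
            return [(n // 4, self.effect1)], [(3 * n // 4, self.effect2)]
        if self.sharing == NULL:
            return [], []
        if self.sharing == EXPOSURE_ONLY:
            return [(n // 2, self.effect1)], []
        raise InputError(f"Scenario: unknown sharing preset {self.sharing!r}")


@dataclass
class RegionTruth:
    """Realized generative state behind one simulated region pair."""

    ld: LDMatrix
    causal1: list[tuple[int, float]]
    causal2: list[tuple[int, float]]
    marginal1: np.ndarray
    marginal2: np.ndarray
    scenario: Scenario


def _joint_vector(causal, n_snps):
    b = np.zeros(n_snps)
    for idx, eff in causal:
        b[idx] += eff
    return b


def _trait_df(snp_ids, chrom, positions, alleles, eaf, z, n_scale, n_col):
    beta = z / np.sqrt(n_scale)
    se = np.full_like(beta, 1.0 / np.sqrt(n_scale))
    pval = np.minimum(1.0, 2.0 * stats.norm.sf(np.abs(z)))
    # p-values exactly consistent with |beta/se| by construction
    return pd.DataFrame({
        "snp_id": snp_ids,
        "chrom": chrom,
        "pos": positions,
        "effect_allele": [a for a, _ in alleles],
        "other_allele": [b for _, b in alleles],
        "eaf": eaf,
        "beta": beta,
        "se": se,
        "pval": pval,
        "n": n_col,
    })[COLUMNS]


def simulate_region(
    scenario: Scenario, rng: np.random.Generator | None = None
) -> tuple[SumStats, SumStats, RegionTruth]:
    """Draw one region pair of summary statistics under the scenario.

    Identical scenario (and default rng) gives bit-identical output.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    n = scenario.n_snps
    snp_ids = [f"{scenario.trait1_id}_snp{i:04d}" for i in range(n)]
    ld = ar1_ld(n, scenario.ld_rho, snp_ids)
    chol = _ar1_chol(n, scenario.ld_rho)

    b1 = _joint_vector(scenario.causal1, n)
    b2 = _joint_vector(scenario.causal2, n)
    if scenario.pleiotropy_sd > 0:
        for idx, _ in scenario.causal1:
            b2[idx] += rng.normal(0.0, scenario.pleiotropy_sd)
    m1 = ld.r @ b1
    m2 = ld.r @ b2

    n1 = scenario.n1
    if scenario.trait2_type == CASE_CONTROL:
        n2 = effective_n(scenario.n_case, scenario.n_control)
        n2_col = scenario.n_case + scenario.n_control
    else:
        n2 = scenario.n2 or scenario.n1
        n2_col = n2
    z1 = np.sqrt(n1) * m1 + chol @ rng.standard_normal(n)
    z2 = np.sqrt(n2) * m2 + chol @ rng.standard_normal(n)

    positions = scenario.tss - (n // 2) * scenario.spacing_bp + np.arange(n) * scenario.spacing_bp
    alleles = [_ALLELE_PAIRS[k] for k in rng.integers(0, len(_ALLELE_PAIRS), n)]
    eaf = rng.uniform(*scenario.maf_range, n)

    df1 = _trait_df(snp_ids, scenario.chrom, positions, alleles, eaf, z1, n1, n1)
    df2 = _trait_df(snp_ids, scenario.chrom, positions, alleles, eaf, z2, n2, n2_col)
    t1 = SumStats(scenario.trait1_id, QUANTITATIVE, df1)
    t2 = SumStats(
        scenario.trait2_id,
        scenario.trait2_type,
        df2,
        n_case=scenario.n_case if scenario.trait2_type == CASE_CONTROL else None,
        n_control=scenario.n_control if scenario.trait2_type == CASE_CONTROL else None,
    )
    truth = RegionTruth(ld, list(scenario.causal1), list(scenario.causal2), m1, m2, scenario)
    return t1, t2, truth


# ---------------------------------------------------------------------------
# instrument-level fast path (no LD, independent instruments)

def draw_instrument_stats(
    rng: np.random.Generator,
    k: int,
    theta: float,
    n_exp: int,
    n_out_eff: float,
    effect_range: tuple[float, float] = (0.08, 0.25),
    pleiotropy_sd: float = 0.0,
):
    """Draw observed (beta_exp, se_exp, beta_out, se_out) for k independent instruments.

    Marginal distribution identical to the region generator at the causal
    SNPs; used for high-replicate calibration and recovery studies.
    Returns (bx, sx, by, sy, bx_true).
    """
    mag = rng.uniform(*effect_range, k)
    bx_true = mag * rng.choice([-1.0, 1.0], k)
    sx = np.full(k, 1.0 / np.sqrt(n_exp))
    sy = np.full(k, 1.0 / np.sqrt(n_out_eff))
    by_true = theta * bx_true
    if pleiotropy_sd > 0:
        by_true = by_true + rng.normal(0.0, pleiotropy_sd, k)
    bx = bx_true + rng.normal(0.0, 1.0, k) * sx
    by = by_true + rng.normal(0.0, 1.0, k) * sy
    return bx, sx, by, sy, bx_true


def replicate_mr_estimates(
    n_reps: int,
    theta: float,
    k: int = 2,
    n_exp: int = 35_559,
    n_out_eff: float | None = None,
    n_case: int = 11_755,
    n_control: int = 441_978,
    effect_range: tuple[float, float] = (0.08, 0.25),
    pleiotropy_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo replicates of the per-exposure MR estimate under known theta.

    Each replicate draws k independent instruments and runs the headline
    estimator (Wald ratio for k = 1, fixed-effect IVW otherwise). Returns a
    frame with beta, se, pval and 95% CI per replicate.
    """
    if n_out_eff is None:
        n_out_eff = effective_n(n_case, n_control)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    z_crit = stats.norm.ppf(0.975)
    rows = np.empty((n_reps, 3))
    for i in range(n_reps):
        bx, sx, by, sy, _ = draw_instrument_stats(
            rng, k, theta, n_exp, n_out_eff, effect_range, pleiotropy_sd
        )
        ratios = by / bx
        if k == 1:
            beta = ratios[0]
            se = np.sqrt(sy[0] ** 2 + beta**2 * sx[0] ** 2) / np.abs(bx[0])
        else:
            w0 = bx**2 / sy**2
            beta0 = np.sum(w0 * ratios) / np.sum(w0)
            ratio_ses = np.sqrt(sy**2 + beta0**2 * sx**2) / np.abs(bx)
            w = ratio_ses**-2.0
            beta = np.sum(w * ratios) / np.sum(w)
            se = np.sum(w) ** -0.5
        rows[i] = beta, se, np.abs(beta / se)
    out = pd.DataFrame(rows, columns=["beta", "se", "absz"])
    out["pval"] = np.minimum(1.0, 2.0 * stats.norm.sf(out["absz"]))
    out["ci_low"] = out["beta"] - z_crit * out["se"]
    out["ci_high"] = out["beta"] + z_crit * out["se"]
    return out.drop(columns="absz")


# ---------------------------------------------------------------------------
# whole-study generator

@dataclass
class SyntheticStudy:
    """A complete synthetic two-sample MR study with known truth.

    ``exposures`` maps protein id -> cis-region GWAS (plus records at the
    disease and lifestyle loci so reverse and lifestyle MR are possible);
    ``outcome`` is the disease GWAS over all region SNPs and its own
    genome-wide loci; ``ld_regions`` holds one LD matrix per region key.
    """

    exposures: dict[str, SumStats]
    outcome: SumStats
    genes: pd.DataFrame
    ld_regions: dict[str, LDMatrix]
    truth: pd.DataFrame
    lifestyle: dict[str, SumStats] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def ld_for(self, snp_ids: list[str]) -> LDMatrix:
        """Block LD over arbitrary SNPs: within-region values, zero across regions."""
        index = {}
        for key, ld in self.ld_regions.items():
            for s in ld.snp_ids:
                index[s] = (key, ld)
        k = len(snp_ids)
        r = np.eye(k)
        for i, a in enumerate(snp_ids):
            for j in range(i + 1, k):
                b = snp_ids[j]
                ka, kb = index.get(a), index.get(b)
                if ka is None or kb is None:
                    raise InputError(f"ld_for: unknown SNP {a if ka is None else b}")
                if ka[0] == kb[0]:
                    r[i, j] = r[j, i] = ka[1].r[
                        ka[1]._index[a], kb[1]._index[b]
                    ]
        return LDMatrix(list(snp_ids), r)

    def to_dir(self, path) -> None:
        path = Path(path)
        (path / "exposures").mkdir(parents=True, exist_ok=True)
        (path / "ld").mkdir(exist_ok=True)
        for name, ss in self.exposures.items():
            ss.to_tsv(path / "exposures" / f"{name}.tsv")
        self.outcome.to_tsv(path / "outcome.tsv")
        self.genes.to_csv(path / "genes.tsv", sep="\t", index=False)
        for key, ld in self.ld_regions.items():
            ld.to_tsv(path / "ld" / f"{key}.tsv")
        self.truth.to_csv(path / "truth.tsv", sep="\t", index=False)
        if self.lifestyle:
            (path / "lifestyle").mkdir(exist_ok=True)
            for name, ss in self.lifestyle.items():
                ss.to_tsv(path / "lifestyle" / f"{name}.tsv")
        with open(path / "config.yaml", "w") as fh:
            yaml.safe_dump(self.config, fh, sort_keys=True)

    @classmethod
    def from_dir(cls, path) -> "SyntheticStudy":
        path = Path(path)
        with open(path / "config.yaml") as fh:
            config = yaml.safe_load(fh)
        n_case = config.get("n_case", 11_755)
        n_control = config.get("n_control", 441_978)
        exposures = {}
        for f in sorted((path / "exposures").glob("*.tsv")):
            df = pd.read_csv(f, sep="\t")
            exposures[f.stem] = SumStats(f.stem, QUANTITATIVE, df)
        odf = pd.read_csv(path / "outcome.tsv", sep="\t")
        outcome = SumStats("outcome", CASE_CONTROL, odf, n_case=n_case, n_control=n_control)
        genes = pd.read_csv(path / "genes.tsv", sep="\t")
        genes["chrom"] = genes["chrom"].astype(str)
        ld_regions = {
            f.stem: LDMatrix.from_tsv(f) for f in sorted((path / "ld").glob("*.tsv"))
        }
        truth = pd.read_csv(path / "truth.tsv", sep="\t")
        lifestyle = {}
        if (path / "lifestyle").is_dir():
            for f in sorted((path / "lifestyle").glob("*.tsv")):
                df = pd.read_csv(f, sep="\t")
                lifestyle[f.stem] = SumStats(f.stem, QUANTITATIVE, df)
        return cls(exposures, outcome, genes, ld_regions, truth, lifestyle, config)


def simulate_mr_study(
    n_exposures: int = 20,
    frac_causal: float = 0.2,
    theta: float = 0.5,
    instruments_per_exposure: int = 2,
    n_exp: int = 35_559,
    n_case: int = 11_755,
    n_control: int = 441_978,
    pleiotropy_sd: float = 0.0,
    seed: int = 0,
    n_snps_region: int = 200,
    ld_rho: float = 0.35,
    maf_range: tuple[float, float] = (0.05, 0.5),
    effect_range: tuple[float, float] = (0.05, 0.12),
    n_disease_loci: int = 5,
    disease_effect_range: tuple[float, float] = (0.10, 0.25),
    reverse_theta: float = 0.0,
    lifestyle_specs: dict | None = None,
    flip_fraction: float = 0.0,
) -> SyntheticStudy:
    """Simulate a proteome-style screen: many protein exposures, one disease outcome.

    A fraction ``frac_causal`` of exposures carries a true causal effect
    ``theta`` (log-odds of disease per SD of protein); the rest affect the
    outcome only through ``pleiotropy_sd`` direct effects. Each exposure
    gets a cis region with ``instruments_per_exposure`` (1 or 2) independent
    genome-wide-significant causal SNPs, joint effects drawn from
    ``effect_range`` (0.25-1.4% of protein variance) with random sign. The
    default regional LD (adjacent-SNP r = 0.35, geometric decay) is chosen
    so that r² < 0.1 clumping recovers exactly the configured instruments:
    SNPs one step out are clumped away (r² = 0.12) and SNPs two steps out
    carry too little of the signal to reach genome-wide significance, so
    selection reproduces the 1-2 independent instruments per protein that
    the emulated pQTL resource reports. The
    outcome additionally carries ``n_disease_loci`` independent genome-wide
    loci of its own, whose effects on each protein are
    ``reverse_theta`` x locus effect (zero by default: no reverse
    causation). ``lifestyle_specs`` maps a lifestyle trait name to
    ``{"protein_effects": {protein_id: beta}, "n": 300000, "k": 8,
    "z_range": (4.8, 7.0)}`` to generate sub-genome-wide instruments for
    lifestyle -> protein MR. ``flip_fraction`` swaps the reported allele
    orientation of that share of outcome records (a harmonization stressor;
    information-preserving).
    """
    if not (0 <= frac_causal <= 1):
        raise InputError("frac_causal must lie in [0, 1]")
    if instruments_per_exposure not in (1, 2):
        raise InputError("instruments_per_exposure must be 1 or 2")
    ss = np.random.SeedSequence(seed)
    master = np.random.default_rng(ss.spawn(1)[0])
    n_causal = int(round(frac_causal * n_exposures))
    causal_ids = set(master.choice(n_exposures, size=n_causal, replace=False).tolist())

    exposures: dict[str, SumStats] = {}
    outcome_parts: list[pd.DataFrame] = []
    ld_regions: dict[str, LDMatrix] = {}
    gene_rows, truth_rows = [], []
    n2_eff = effective_n(n_case, n_control)

    region_seeds = ss.spawn(n_exposures + 3)
    k = instruments_per_exposure
    n = n_snps_region
    instrument_idx = [n // 2] if k == 1 else [n // 3, 2 * n // 3]

    for i in range(n_exposures):
        rng = np.random.default_rng(region_seeds[i])
        prot = f"PROT_{i + 1:03d}"
        is_causal = i in causal_ids
        theta_i = theta if is_causal else 0.0
        mag = rng.uniform(*effect_range, k)
        b1 = list(zip(instrument_idx, mag * rng.choice([-1.0, 1.0], k)))
        b2 = [(idx, theta_i * eff) for idx, eff in b1]
        scen = Scenario(
            n_snps=n, ld_rho=ld_rho, maf_range=maf_range,
            causal1=b1, causal2=b2, pleiotropy_sd=pleiotropy_sd,
            n1=n_exp, n_case=n_case, n_control=n_control,
            trait1_id=prot, trait2_id="AD",
            chrom=str(i + 1), seed=0,
        )
        t1, t2, truth = simulate_region(scen, rng=rng)
        exposures[prot] = t1
        outcome_parts.append(t2.df)
        ld_regions[prot] = truth.ld
        gene_rows.append({"gene_id": prot, "chrom": scen.chrom, "tss": scen.tss})
        truth_rows.append({
            "exposure_id": prot,
            "causal": is_causal,
            "theta": theta_i,
            "n_instruments": k,
            "instrument_snps": ";".join(t1.df["snp_id"].iloc[list(instrument_idx)]),
        })

    # disease's own genome-wide loci (independent single SNPs)
    rng_dis = np.random.default_rng(region_seeds[n_exposures])
    dis_ids = [f"DIS_snp{j:02d}" for j in range(n_disease_loci)]
    if n_disease_loci:
        b_dis = rng_dis.uniform(*disease_effect_range, n_disease_loci)
        alleles = [_ALLELE_PAIRS[j] for j in rng_dis.integers(0, len(_ALLELE_PAIRS), n_disease_loci)]
        eaf = rng_dis.uniform(*maf_range, n_disease_loci)
        z_dis = np.sqrt(n2_eff) * b_dis + rng_dis.standard_normal(n_disease_loci)
        dis_df = _trait_df(
            dis_ids, [f"D{j + 1}" for j in range(n_disease_loci)],
            np.full(n_disease_loci, 1_000_000), alleles, eaf, z_dis,
            n2_eff, n_case + n_control,
        )
        outcome_parts.append(dis_df)
        ld_regions["DIS"] = LDMatrix(dis_ids, np.eye(n_disease_loci))
        # each protein's association at the disease loci (reverse path)
        for prot, ssx in exposures.items():
            zp = np.sqrt(n_exp) * reverse_theta * b_dis + rng_dis.standard_normal(n_disease_loci)
            pdf = _trait_df(
                dis_ids, [f"D{j + 1}" for j in range(n_disease_loci)],
                np.full(n_disease_loci, 1_000_000), alleles, eaf, zp, n_exp, n_exp,
            )
            ssx.df = pd.concat([ssx.df, pdf], ignore_index=True)

    # lifestyle exposures with sub-genome-wide instruments
    lifestyle: dict[str, SumStats] = {}
    rng_ls = np.random.default_rng(region_seeds[n_exposures + 1])
    for name, spec in (lifestyle_specs or {}).items():
        n_ls = int(spec.get("n", 300_000))
        k_ls = int(spec.get("k", 8))
        z_lo, z_hi = spec.get("z_range", (4.8, 7.0))
        se_ls = 1.0 / np.sqrt(n_ls)
        b_true = rng_ls.uniform(z_lo, z_hi, k_ls) * se_ls * rng_ls.choice([-1.0, 1.0], k_ls)
        ids = [f"{name}_snp{j:02d}" for j in range(k_ls)]
        alleles = [_ALLELE_PAIRS[j] for j in rng_ls.integers(0, len(_ALLELE_PAIRS), k_ls)]
        eaf = rng_ls.uniform(*maf_range, k_ls)
        z_obs = np.sqrt(n_ls) * b_true + rng_ls.standard_normal(k_ls)
        ls_df = _trait_df(
            ids, f"L_{name}", 1_000_000 + np.arange(k_ls) * 200_000,
            alleles, eaf, z_obs, n_ls, n_ls,
        )
        lifestyle[name] = SumStats(name, QUANTITATIVE, ls_df)
        ld_regions[f"LS_{name}"] = LDMatrix(ids, np.eye(k_ls))
        effects = spec.get("protein_effects", {})
        for prot, ssx in exposures.items():
            beta_lp = float(effects.get(prot, 0.0))
            zp = np.sqrt(n_exp) * beta_lp * b_true + rng_ls.standard_normal(k_ls)
            pdf = _trait_df(
                ids, f"L_{name}", 1_000_000 + np.arange(k_ls) * 200_000,
                alleles, eaf, zp, n_exp, n_exp,
            )
            ssx.df = pd.concat([ssx.df, pdf], ignore_index=True)

    outcome_df = pd.concat(outcome_parts, ignore_index=True)
    if flip_fraction > 0:
        rng_flip = np.random.default_rng(region_seeds[n_exposures + 2])
        mask = rng_flip.random(len(outcome_df)) < flip_fraction
        ea = outcome_df.loc[mask, "effect_allele"].copy()
        outcome_df.loc[mask, "effect_allele"] = outcome_df.loc[mask, "other_allele"]
        outcome_df.loc[mask, "other_allele"] = ea
        outcome_df.loc[mask, "beta"] = -outcome_df.loc[mask, "beta"]
        outcome_df.loc[mask, "eaf"] = 1.0 - outcome_df.loc[mask, "eaf"]
    outcome = SumStats("AD", CASE_CONTROL, outcome_df, n_case=n_case, n_control=n_control)

    config = {
        "n_exposures": n_exposures, "frac_causal": frac_causal, "theta": theta,
        "instruments_per_exposure": instruments_per_exposure,
        "n_exp": n_exp, "n_case": n_case, "n_control": n_control,
        "pleiotropy_sd": pleiotropy_sd, "seed": seed,
        "n_snps_region": n_snps_region, "ld_rho": ld_rho,
        "maf_range": list(maf_range), "effect_range": list(effect_range),
        "n_disease_loci": n_disease_loci, "reverse_theta": reverse_theta,
        "flip_fraction": flip_fraction,
    }
    return SyntheticStudy(
        exposures=exposures,
        outcome=outcome,
        genes=pd.DataFrame(gene_rows),
        ld_regions=ld_regions,
        truth=pd.DataFrame(truth_rows),
        lifestyle=lifestyle,
        config=config,
    )
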