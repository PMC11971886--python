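"""Bayesian colocalization of two traits' association signals in a region.

Per-SNP evidence is the Wakefield approximate Bayes factor computed from the
effect estimate, its standard error and a prior effect-size SD. The region
posterior is over five hypotheses: H0 neither trait associated, H1/H2 only
trait 1 / only trait 2, H3 both associated through distinct causal variants,
H4 both associated through one shared causal variant. Decision rule:
colocalized when PPH4 > 0.75 or PPH3 + PPH4 > 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .sumstats import CASE_CONTROL, QUANTITATIVE, InputError

#: default prior effect-size SD (sqrt W) by trait type: SD units for
#: quantitative traits, log-odds for case-control traits
DEFAULT_PRIOR_SD = {QUANTITATIVE: 0.2, CASE_CONTROL: 0.15}

#: default per-SNP prior probabilities of association with trait 1 only,
#: trait 2 only, and both
DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5

COLOCALIZED = "colocalized"
NOT_COLOCALIZED = "not_colocalized"


def wakefield_log_abf(beta, se, prior_sd: float):
    """Log approximate Bayes factor for one association estimate.

    With V = se², W = prior_sd², z = beta/se and shrinkage r = W/(V+W):

        log ABF = 0.5 * [log(1 - r) + r z²]

    Positive values favour a real effect over the null.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise InputError("wakefield_log_abf: se must be positive")
    if prior_sd <= 0:
        raise InputError("wakefield_log_abf: prior_sd must be positive")
    v = se**2
    w = prior_sd**2
    r = w / (v + w)
    z = beta / se
    return 0.5 * (np.log1p(-r) + r * z**2)


@dataclass
class ColocInput:
    """Aligned per-SNP estimates for two traits over one region.

    Both traits must cover the identical ordered SNP list (harmonize first).
    """

    snp_ids: list[str]
    beta1: np.ndarray
    se1: np.ndarray
    beta2: np.ndarray
    se2: np.ndarray
    trait1_type: str = QUANTITATIVE
    trait2_type: str = CASE_CONTROL
    prior_sd1: float | None = None
    prior_sd2: float | None = None
    p1: float = DEFAULT_P1
    p2: float = DEFAULT_P2
    p12: float = DEFAULT_P12

    def __post_init__(self):
        for name in ("beta1", "se1", "beta2", "se2"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        k = len(self.snp_ids)
        for name in ("beta1", "se1", "beta2", "se2"):
            if getattr(self, name).shape != (k,):
                raise InputError(f"ColocInput: {name} misaligned with SNP list")
        if np.any(self.se1 <= 0) or np.any(self.se2 <= 0):
            raise InputError("ColocInput: all standard errors must be positive")
        if min(self.p1, self.p2, self.p12) <= 0 or self.p1 + self.p2 + self.p12 >= 1:
            raise InputError("ColocInput: need p1, p2, p12 > 0 and p1+p2+p12 < 1")
        if self.prior_sd1 is None:
            self.prior_sd1 = DEFAULT_PRIOR_SD[self.trait1_type]
        if self.prior_sd2 is None:
            self.prior_sd2 = DEFAULT_PRIOR_SD[self.trait2_type]


@dataclass
class ColocResult:
    pph0: float
    pph1: float
    pph2: float
    pph3: float
    pph4: float
    n_snps: int
    log_masses: dict = field(default_factory=dict)
    decision: str | None = None
    reason: str | None = None

    def posteriors(self) -> np.ndarray:
        return np.array([self.pph0, self.pph1, self.pph2, self.pph3, self.pph4])


def _log1mexp(x: float) -> float:
    """log(1 - exp(x)) for x <= 0, -inf at x = 0."""
    if x >= 0:
        return -np.inf
    if x > -0.693:
        return float(np.log(-np.expm1(x)))
    return float(np.log1p(-np.exp(x)))


def coloc_abf(inp: ColocInput) -> ColocResult:
    """Five-hypothesis posterior from per-SNP approximate Bayes factors.

    With per-SNP log BFs L1_j, L2_j, the unnormalized hypothesis masses are

        H0: 1
        H1: p1  * sum_j exp(L1_j)
        H2: p2  * sum_j exp(L2_j)
        H3: p1 p2 * [ (sum_j exp L1_j)(sum_j exp L2_j) - sum_j exp(L1_j+L2_j) ]
        H4: p12 * sum_j exp(L1_j + L2_j)

    computed in log space (log-sum-exp) so regions with very strong signals
    do not overflow. In a single-SNP region the H3 cross term vanishes
    exactly, so pph3 = 0.
    """
    if len(inp.snp_ids) == 0:
        raise InputError("coloc_abf: at least one SNP required")
    l1 = wakefield_log_abf(inp.beta1, inp.se1, inp.prior_sd1)
    l2 = wakefield_log_abf(inp.beta2, inp.se2, inp.prior_sd2)
    lse1 = float(logsumexp(l1))
    lse2 = float(logsumexp(l2))
    lse12 = float(logsumexp(l1 + l2))
    # single-SNP region: the H3 cross term vanishes identically
    log_cross = (
        -np.inf if len(inp.snp_ids) == 1
        else _log1mexp(min(0.0, lse12 - lse1 - lse2))
    )
    log_h = np.array([
        0.0,
        np.log(inp.p1) + lse1,
        np.log(inp.p2) + lse2,
        np.log(inp.p1) + np.log(inp.p2) + lse1 + lse2 + log_cross,
        np.log(inp.p12) + lse12,
    ])
    post = np.exp(log_h - logsumexp(log_h))
    post /= post.sum()
    return ColocResult(
        pph0=float(post[0]),
        pph1=float(post[1]),
        pph2=float(post[2]),
        pph3=float(post[3]),
        pph4=float(post[4]),
        n_snps=len(inp.snp_ids),
        log_masses={f"h{i}": float(v) for i, v in enumerate(log_h)},
    )


def coloc_decision(
    result: ColocResult,
    pph4_min: float = 0.75,
    sum34_min: float = 0.8,
) -> ColocResult:
    """Apply the decision rule; returns the result with decision and reason set.

    Colocalized when PPH4 > pph4_min, or when PPH3 + PPH4 > sum34_min
    (the combined clause also fires when LD cannot separate two signals).
    """
    if result.pph4 > pph4_min:
        result.decision = COLOCALIZED
        result.reason = f"pph4={result.pph4:.3f} > {pph4_min}"
    elif result.pph3 + result.pph4 > sum34_min:
        result.decision = COLOCALIZED
        result.reason = (
            f"pph3+pph4={result.pph3 + result.pph4:.3f} > {sum34_min}"
        )
    else:
        result.decision = NOT_COLOCALIZED
        result.reason = (
            f"pph4={result.pph4:.3f} <= {pph4_min} and "
            f"pph3+pph4={result.pph3 + result.pph4:.3f} <= {sum34_min}"
        )
    return result


def coloc_from_harmonized(
    harmonized: pd.DataFrame,
    trait1_type: str = QUANTITATIVE,
    trait2_type: str = CASE_CONTROL,
    **kwargs,
) -> ColocInput:
    """Build a ColocInput from the kept rows of a harmonization table."""
    from .sumstats import kept_pairs

    kept = kept_pairs(harmonized)
    if kept.empty:
        raise InputError("coloc_from_harmonized: no usable harmonized SNPs")
    return ColocInput(
        snp_ids=list(kept["snp_id"]),
        beta1=kept["beta_exp"].to_numpy(),
        se1=kept["se_exp"].to_numpy(),
        beta2=kept["beta_out"].to_numpy(),
        se2=kept["se_out"].to_numpy(),
        trait1_type=trait1_type,
        trait2_type=trait2_type,
        **kwargs,
    )
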