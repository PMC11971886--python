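"""Two-sample Mendelian randomization estimators and supporting statistics.

Implements the Wald ratio (single instrument), fixed-effect inverse-variance
weighting (IVW), MR-Egger regression (directional-pleiotropy sensitivity),
Cochran's Q heterogeneity, conversion of log-odds effects to odds ratios per
SD of exposure, the inverse OR/CI -> p consistency check, and
Benjamini-Hochberg FDR adjustment.

Conventions: fixed-effect IVW (with 1-2 instruments per exposure a
random-effects variance is not estimable); delta-method SE for the Wald
ratio including the exposure-uncertainty term; normal (not t) reference
distributions throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .sumstats import InputError

WALD_RATIO = "wald_ratio"
IVW = "ivw"
EGGER = "egger"


def _norm_p(z) -> float:
    """Two-sided normal p-value, floored at 1e-300 so it stays in (0, 1]."""
    return float(min(1.0, max(2.0 * stats.norm.sf(abs(float(z))), 1e-300)))


def ratio_se(beta_exp, se_exp, beta_out, se_out):
    """Delta-method SE of the ratio beta_out/beta_exp, exposure term included.

    se² = (se_out² + ratio²·se_exp²) / beta_exp². The second (exposure
    uncertainty) term matters whenever the exposure GWAS is not much larger
    than the outcome GWAS and the causal effect is sizable; dropping it
    (the common first-order shortcut se_out/|beta_exp|) gives anti-
    conservative confidence intervals exactly in that regime.
    """
    beta_exp = np.asarray(beta_exp, dtype=float)
    ratio = np.asarray(beta_out, dtype=float) / beta_exp
    return np.sqrt(
        (np.asarray(se_out, dtype=float) ** 2 + ratio**2 * np.asarray(se_exp, dtype=float) ** 2)
        / beta_exp**2
    )


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float):
    """Single-instrument causal estimate: outcome effect over exposure effect.

    SE by the delta method with the exposure-uncertainty term
    (:func:`ratio_se`). Returns (beta, se, pval).
    """
    if beta_exp == 0:
        raise InputError("wald_ratio: beta_exp must be nonzero")
    beta = beta_out / beta_exp
    se = float(ratio_se(beta_exp, se_exp, beta_out, se_out))
    return beta, se, _norm_p(beta / se)


def ivw(betas, ses):
    """Fixed-effect inverse-variance-weighted mean of per-SNP ratio estimates.

    beta = sum(w_j b_j) / sum(w_j) with w_j = se_j^-2; se = sum(w_j)^-1/2.
    Returns (beta, se, pval). With one SNP this equals its Wald ratio.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.size == 0:
        raise InputError("ivw: at least one ratio estimate required")
    if np.any(ses <= 0):
        raise InputError("ivw: all standard errors must be positive")
    w = ses**-2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    return beta, se, _norm_p(beta / se)


@dataclass
class EggerResult:
    """MR-Egger slope and intercept; NaN and ``defined=False`` when n < 3."""

    n_snps: int
    slope: float = np.nan
    slope_se: float = np.nan
    slope_pval: float = np.nan
    intercept: float = np.nan
    intercept_se: float = np.nan
    intercept_pval: float = np.nan
    defined: bool = False


def mr_egger(beta_exp, beta_out, se_out) -> EggerResult:
    """Weighted regression of outcome on exposure effects with a free intercept.

    Instruments are first oriented so every exposure effect is positive
    (flipping the outcome effect with it); weights are se_out^-2. The
    intercept estimates the average directional pleiotropy. Coefficient
    covariance is (X'WX)^-1 without residual-variance rescaling; p-values
    use the normal reference. Undefined (flagged, not raised) for n < 3.
    """
    bx = np.asarray(beta_exp, dtype=float)
    by = np.asarray(beta_out, dtype=float)
    sy = np.asarray(se_out, dtype=float)
    n = bx.size
    if n < 3:
        return EggerResult(n_snps=int(n))
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = sy**-2
    X = np.column_stack([np.ones(n), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    cov = np.linalg.inv(xtwx)
    coef = cov @ xtwy
    intercept, slope = coef
    i_se, s_se = np.sqrt(np.diag(cov))
    return EggerResult(
        n_snps=int(n),
        slope=float(slope),
        slope_se=float(s_se),
        slope_pval=_norm_p(slope / s_se),
        intercept=float(intercept),
        intercept_se=float(i_se),
        intercept_pval=_norm_p(intercept / i_se),
        defined=True,
    )


def cochran_q(betas, ses):
    """Cochran's Q heterogeneity of per-SNP ratios about the IVW mean.

    Q = sum w_j (b_j - b_ivw)^2, df = n - 1, chi-square upper-tail p.
    Returns (nan, 0, nan) when n < 2 (flagged, not raised).
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    n = betas.size
    if n < 2:
        return np.nan, 0, np.nan
    b_ivw, _, _ = ivw(betas, ses)
    w = ses**-2
    q = float(np.sum(w * (betas - b_ivw) ** 2))
    df = int(n - 1)
    return q, df, float(stats.chi2.sf(q, df))


def effect_to_or(beta: float, se: float, level: float = 0.95):
    """Convert a log-odds effect to OR with a Wald CI and percent risk change.

    pct_change = 100*(OR - 1): positive values are a risk increase per SD
    of exposure, negative magnitudes a risk reduction.
    Returns (or_, ci_low, ci_high, pval, pct_change).
    """
    if se <= 0:
        raise InputError("effect_to_or: se must be positive")
    z_crit = stats.norm.ppf(0.5 + level / 2.0)
    or_ = float(np.exp(beta))
    ci_low = float(np.exp(beta - z_crit * se))
    ci_high = float(np.exp(beta + z_crit * se))
    return or_, ci_low, ci_high, _norm_p(beta / se), 100.0 * (or_ - 1.0)


def or_ci_to_p(or_: float, ci_low: float, ci_high: float, level: float = 0.95):
    """Recover (z, p) from a printed OR and its confidence interval.

    se = (ln ci_high - ln ci_low) / (2 z_level); z = ln(OR)/se. Used to
    cross-check published result rows for internal consistency.
    """
    if not (0 < ci_low < or_ < ci_high):
        raise InputError("or_ci_to_p: require 0 < ci_low < or < ci_high")
    z_crit = stats.norm.ppf(0.5 + level / 2.0)
    se = (np.log(ci_high) - np.log(ci_low)) / (2.0 * z_crit)
    z = float(np.log(or_) / se)
    return z, _norm_p(z)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1, rank-monotone)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise InputError("bh_fdr: p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fdr_table(results: pd.DataFrame, threshold: float = 0.05) -> pd.DataFrame:
    """Attach BH-adjusted p-values and a significance flag to an MR table."""
    out = results.copy()
    out["pval_fdr"] = bh_fdr(out["pval"].to_numpy()) if len(out) else []
    out["significant"] = out["pval_fdr"] < threshold if len(out) else []
    return out


@dataclass
class MRResult:
    """Per-exposure causal estimate on the log-odds (or SD) scale."""

    exposure_id: str
    outcome_id: str
    method: str
    n_snps: int
    beta: float
    se: float
    pval: float
    or_: float
    ci_low: float
    ci_high: float
    q_stat: float = np.nan
    q_df: int = 0
    q_pval: float = np.nan
    egger_intercept: float = np.nan
    egger_intercept_se: float = np.nan
    egger_intercept_pval: float = np.nan

    def to_dict(self) -> dict:
        return {
            "exposure": self.exposure_id,
            "outcome": self.outcome_id,
            "method": self.method,
            "n_snps": self.n_snps,
            "beta": self.beta,
            "se": self.se,
            "pval": self.pval,
            "or": self.or_,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "q": self.q_stat,
            "q_df": self.q_df,
            "q_pval": self.q_pval,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_pval": self.egger_intercept_pval,
        }


def mr_per_exposure(
    exposure_id: str,
    outcome_id: str,
    beta_exp,
    se_exp,
    beta_out,
    se_out,
) -> MRResult:
    """Headline MR estimate for one exposure from harmonized instruments.

    One instrument -> Wald ratio; two or more -> fixed-effect IVW with
    Cochran's Q attached; three or more additionally attach the MR-Egger
    intercept as a pleiotropy sensitivity (the headline stays IVW).
    """
    bx = np.asarray(beta_exp, dtype=float)
    sx = np.asarray(se_exp, dtype=float)
    by = np.asarray(beta_out, dtype=float)
    sy = np.asarray(se_out, dtype=float)
    n = bx.size
    if n == 0:
        raise InputError(f"{exposure_id}: no harmonized instruments")
    ratios = by / bx
    if n == 1:
        method = WALD_RATIO
        beta, se, pval = wald_ratio(bx[0], sx[0], by[0], sy[0])
        q, q_df, q_p = np.nan, 0, np.nan
    else:
        # two-pass IVW: per-SNP ratio variances use a pooled first-pass
        # estimate rather than each SNP's own noisy ratio, which would
        # correlate weights with ratios and attenuate the weighted mean
        method = IVW
        beta0, _, _ = ivw(ratios, sy / np.abs(bx))
        ratio_ses = np.sqrt(sy**2 + beta0**2 * sx**2) / np.abs(bx)
        beta, se, pval = ivw(ratios, ratio_ses)
        q, q_df, q_p = cochran_q(ratios, ratio_ses)
    or_, lo, hi, _, _ = effect_to_or(beta, se)
    res = MRResult(
        exposure_id=exposure_id,
        outcome_id=outcome_id,
        method=method,
        n_snps=int(n),
        beta=beta,
        se=se,
        pval=pval,
        or_=or_,
        ci_low=lo,
        ci_high=hi,
        q_stat=q,
        q_df=q_df,
        q_pval=q_p,
    )
    if n >= 3:
        egger = mr_egger(bx, by, sy)
        res.egger_intercept = egger.intercept
        res.egger_intercept_se = egger.intercept_se
        res.egger_intercept_pval = egger.intercept_pval
    return res
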