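import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cismr.mr import (
    EGGER, IVW, WALD_RATIO,
    bh_fdr, cochran_q, effect_to_or, ivw, mr_egger, mr_per_exposure,
    or_ci_to_p, ratio_se, wald_ratio,
)
from cismr.sumstats import InputError
from cismr.synth import replicate_mr_estimates


class TestWaldRatio:
    def test_direct_ratio(self):
        beta, se, p = wald_ratio(0.1, 0.02, 0.05, 0.01)
        assert beta == pytest.approx(0.5)
        # delta-method SE including the exposure-uncertainty term
        assert se == pytest.approx(np.sqrt(0.01**2 + 0.25 * 0.02**2) / 0.1)

    def test_sign_propagation(self):
        beta, se, _ = wald_ratio(-0.1, 0.02, 0.05, 0.01)
        assert beta == pytest.approx(-0.5)
        assert se == pytest.approx(np.sqrt(0.01**2 + 0.25 * 0.02**2) / 0.1)

    def test_unit_exposure_passes_outcome_through(self):
        beta, se, _ = wald_ratio(1.0, 0.01, 0.3, 0.2)
        assert beta == pytest.approx(0.3)
        assert se == pytest.approx(0.2, rel=1e-3)  # exposure term negligible

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(InputError):
            wald_ratio(0.0, 0.02, 0.05, 0.01)


class TestIvw:
    def test_single_snp_equals_wald_ratio(self):
        bx, sx, by, sy = 0.12, 0.015, 0.05, 0.02
        w_beta, w_se, w_p = wald_ratio(bx, sx, by, sy)
        i_beta, i_se, i_p = ivw([by / bx], [ratio_se(bx, sx, by, sy)])
        assert (i_beta, i_se, i_p) == (w_beta, w_se, w_p)

    def test_hand_computed_weighted_mean(self):
        beta, se, _ = ivw([0.5, 0.7], [0.1, 0.2])
        # weights 100 and 25
        assert beta == pytest.approx(0.54)
        assert se == pytest.approx(125**-0.5)

    def test_equal_ses_give_arithmetic_mean(self, rng):
        b = rng.normal(size=6)
        beta, _, _ = ivw(b, np.full(6, 0.3))
        assert beta == pytest.approx(b.mean())

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            ivw([], [])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.floats(-2, 2, allow_nan=False), st.floats(0.01, 1.0)),
        min_size=1, max_size=10,
    ))
    def test_convexity_of_weighted_mean(self, pairs):
        betas = [b for b, _ in pairs]
        beta, _, _ = ivw(betas, [s for _, s in pairs])
        assert min(betas) - 1e-12 <= beta <= max(betas) + 1e-12


class TestEgger:
    def test_exact_line_through_origin(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        res = mr_egger(bx, 0.5 * bx, np.full(4, 0.05))
        assert res.slope == pytest.approx(0.5)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_pleiotropy_recovered(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        res = mr_egger(bx, 0.1 + 0.5 * bx, np.full(5, 0.05))
        assert res.intercept == pytest.approx(0.1)
        assert res.slope == pytest.approx(0.5)

    def test_matches_normal_equations_oracle(self, rng):
        bx = rng.uniform(0.05, 0.3, 5) * rng.choice([-1, 1], 5)
        by = 0.05 + 0.4 * bx + rng.normal(0, 0.02, 5)
        sy = rng.uniform(0.01, 0.05, 5)
        res = mr_egger(bx, by, sy)
        # oracle: orient, then solve the 2x2 weighted normal equations
        sign = np.sign(bx)
        x, y, w = bx * sign, by * sign, sy**-2
        s0, s1, s2 = w.sum(), (w * x).sum(), (w * x**2).sum()
        det = s0 * s2 - s1**2
        intercept = (s2 * (w * y).sum() - s1 * (w * x * y).sum()) / det
        slope = (s0 * (w * x * y).sum() - s1 * (w * y).sum()) / det
        assert res.intercept == pytest.approx(intercept, abs=1e-10)
        assert res.slope == pytest.approx(slope, abs=1e-10)
        assert res.intercept_se == pytest.approx(np.sqrt(s2 / det), abs=1e-10)
        assert res.slope_se == pytest.approx(np.sqrt(s0 / det), abs=1e-10)
        # independent cross-check: statsmodels WLS coefficients
        import statsmodels.api as sm
        fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
        assert res.intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert res.slope == pytest.approx(fit.params[1], abs=1e-10)

    def test_undefined_below_three_snps(self):
        res = mr_egger([0.1, 0.2], [0.05, 0.1], [0.02, 0.02])
        assert not res.defined
        assert np.isnan(res.slope)


class TestCochranQ:
    def test_no_dispersion(self):
        q, df, p = cochran_q([0.4, 0.4, 0.4], [0.1, 0.2, 0.3])
        assert q == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_value(self):
        q, df, p = cochran_q([0.5, 0.7], [0.1, 0.2])
        # 100*(0.5-0.54)^2 + 25*(0.7-0.54)^2
        assert q == pytest.approx(0.8)
        assert df == 1
        assert p == pytest.approx(stats.chi2.sf(0.8, 1))

    def test_duplication_doubles_df(self, rng):
        b = rng.normal(0.3, 0.1, 4)
        s = rng.uniform(0.05, 0.2, 4)
        _, df1, _ = cochran_q(b, s)
        _, df2, _ = cochran_q(np.tile(b, 2), np.tile(s, 2))
        assert (df1, df2) == (3, 7)

    def test_flagged_below_two(self):
        q, df, p = cochran_q([0.5], [0.1])
        assert np.isnan(q) and df == 0


class TestEffectToOr:
    def test_null_effect(self):
        or_, lo, hi, p, pct = effect_to_or(0.0, 0.1)
        assert or_ == 1.0 and pct == 0.0
        assert lo * hi == pytest.approx(1.0)  # symmetric about 1 on log scale

    def test_published_row_reproduced(self):
        # OR 1.62 with 95% CI 1.31-2.01 (per SD of exposure)
        or_, lo, hi, p, pct = effect_to_or(np.log(1.62), 0.1092)
        assert or_ == pytest.approx(1.62)
        assert lo == pytest.approx(1.31, abs=0.005)
        assert hi == pytest.approx(2.01, abs=0.005)

    def test_risk_reduction_percent(self):
        *_, pct = effect_to_or(np.log(0.66), 0.07)
        assert pct == pytest.approx(-34.0)


class TestOrCiToP:
    def test_published_row(self):
        z, p = or_ci_to_p(1.62, 1.31, 2.01)
        assert z == pytest.approx(4.42, abs=0.01)
        assert p == pytest.approx(1.0e-5, rel=0.01)

    def test_null_or(self):
        z, p = or_ci_to_p(1.0 + 1e-15, 0.8, 1.25)
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_strong_row_recomputed(self):
        z, p = or_ci_to_p(2.26, 1.82, 2.82)
        assert z == pytest.approx(7.30, abs=0.01)
        assert p == pytest.approx(2.9e-13, rel=0.05)

    def test_ordering_enforced(self):
        with pytest.raises(InputError):
            or_ci_to_p(1.2, 1.3, 2.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(-1.5, 1.5, allow_nan=False), st.floats(0.02, 0.5))
    def test_inverse_of_effect_to_or(self, beta, se):
        or_, lo, hi, p1, _ = effect_to_or(beta, se)
        z, p2 = or_ci_to_p(or_, lo, hi)
        assert abs(z) == pytest.approx(abs(beta) / se, abs=1e-10)
        assert p2 == pytest.approx(p1, abs=1e-10)


class TestBhFdr:
    def test_hand_applied_step_up(self):
        adj = bh_fdr([0.001, 0.01, 0.02, 0.05])
        np.testing.assert_allclose(adj, [0.004, 0.02, 0.02 * 4 / 3, 0.05], rtol=1e-12)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_all_equal(self):
        np.testing.assert_allclose(bh_fdr([0.03] * 5), [0.03] * 5)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-10, 1.0), min_size=1, max_size=30))
    def test_adjusted_at_least_raw_and_rank_monotone(self, pvals):
        adj = bh_fdr(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestMrPerExposure:
    def test_single_snp_uses_wald_ratio(self):
        res = mr_per_exposure("x", "y", [0.1], [0.02], [0.05], [0.01])
        assert res.method == WALD_RATIO
        assert res.n_snps == 1
        assert np.isnan(res.q_stat) and np.isnan(res.egger_intercept)
        assert res.or_ == pytest.approx(np.exp(res.beta))

    def test_two_snps_ivw_without_egger(self):
        res = mr_per_exposure(
            "x", "y", [0.1, 0.2], [0.02, 0.02], [0.05, 0.1], [0.01, 0.01]
        )
        assert res.method == IVW
        assert res.q_df == 1
        assert np.isnan(res.egger_intercept)

    def test_three_snps_attach_egger(self):
        res = mr_per_exposure(
            "x", "y", [0.1, 0.2, 0.3], [0.02] * 3, [0.05, 0.1, 0.16], [0.01] * 3
        )
        assert res.method == IVW
        assert np.isfinite(res.egger_intercept)

    def test_zero_snps_rejected(self):
        with pytest.raises(InputError):
            mr_per_exposure("x", "y", [], [], [], [])

    def test_five_snp_recovery(self):
        """IVW on 5-instrument exposures recovers theta = 0.3 within 3 MC SE."""
        df = replicate_mr_estimates(500, theta=0.3, k=5, seed=101)
        mc_se = df["beta"].std() / np.sqrt(len(df))
        assert df["beta"].mean() == pytest.approx(0.3, abs=3 * mc_se)
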