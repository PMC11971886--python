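import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cismr.instruments import (
    CLUMPED_OUT, PVAL_FAIL, PRESETS, SELECTED, WEAK_INSTRUMENT,
    GeneAnnotation, InstrumentConfig, LDMatrix,
    cis_filter, f_statistic, ld_clump, select_instruments, significance_filter,
)
from cismr.sumstats import InputError
from cismr.synth import ar1_ld, simulate_mr_study

from conftest import make_sumstats

GENE = GeneAnnotation("GENE1", "1", 2_000_000)


class TestCisFilter:
    @pytest.mark.parametrize(
        "pos, chrom, kept",
        [
            (3_000_000, "1", True),   # exactly window_bp away: closed boundary
            (3_000_001, "1", False),  # one bp outside
            (1_000_000, "1", True),
            (999_999, "1", False),
            (2_000_000, "2", False),  # chromosome mismatch
        ],
    )
    def test_window_boundaries(self, pos, chrom, kept):
        ss = make_sumstats([{"pos": pos, "chrom": chrom}])
        got = cis_filter(ss, GENE, window_bp=1_000_000)
        assert (len(got) == 1) == kept


class TestSignificanceFilter:
    def test_strict_inequality(self):
        ss = make_sumstats([
            {"snp_id": "below", "pval": 4.9e-8},
            {"snp_id": "at", "pval": 5e-8},
            {"snp_id": "above", "pval": 1e-6},
        ])
        got = significance_filter(ss, 5e-8)
        assert list(got.df["snp_id"]) == ["below"]

    def test_empty_input(self):
        ss = make_sumstats([{"pval": 0.5}])
        got = significance_filter(significance_filter(ss, 1e-3), 1e-3)
        assert len(got) == 0


def _ld(snp_ids, r):
    return LDMatrix(snp_ids, np.asarray(r))


class TestLdClump:
    def test_dominated_partner_removed(self):
        ss = make_sumstats([
            {"snp_id": "a", "pval": 1e-10},
            {"snp_id": "b", "pval": 1e-9},
        ])
        ld = _ld(["a", "b"], [[1, np.sqrt(0.5)], [np.sqrt(0.5), 1]])
        kept, log = ld_clump(ss, ld, r2_max=0.1)
        assert list(kept.df["snp_id"]) == ["a"]
        assert dict(zip(log["snp_id"], log["reason"]))["b"] == CLUMPED_OUT

    def test_below_threshold_both_kept(self):
        ss = make_sumstats([
            {"snp_id": "a", "pval": 1e-10},
            {"snp_id": "b", "pval": 1e-9},
        ])
        ld = _ld(["a", "b"], [[1, np.sqrt(0.05)], [np.sqrt(0.05), 1]])
        kept, _ = ld_clump(ss, ld, r2_max=0.1)
        assert sorted(kept.df["snp_id"]) == ["a", "b"]

    def test_missing_candidate_named(self):
        ss = make_sumstats([{"snp_id": "a"}, {"snp_id": "ghost"}])
        ld = _ld(["a"], [[1.0]])
        with pytest.raises(InputError, match="ghost"):
            ld_clump(ss, ld)

    @staticmethod
    def _greedy_oracle(pvals, snp_ids, positions, r, r2_max, window_bp):
        """Independent re-trace of p-ordered greedy clumping."""
        order = sorted(range(len(pvals)), key=lambda i: (pvals[i], snp_ids[i]))
        alive = set(order)
        kept = []
        for i in order:
            if i not in alive:
                continue
            kept.append(snp_ids[i])
            alive.discard(i)
            for j in list(alive):
                if (abs(positions[j] - positions[i]) <= window_bp
                        and r[i, j] ** 2 >= r2_max):
                    alive.discard(j)
        return kept

    def test_ar1_region_matches_oracle(self, rng):
        n = 10
        pvals = rng.permutation(np.geomspace(1e-12, 1e-9, n))
        ss = make_sumstats([
            {"snp_id": f"s{i}", "pos": 1000 + 500 * i, "pval": pvals[i]}
            for i in range(n)
        ])
        ld = ar1_ld(n, 0.9, [f"s{i}" for i in range(n)])
        kept, _ = ld_clump(ss, ld, r2_max=0.1, window_kb=10_000)
        oracle = self._greedy_oracle(
            pvals, [f"s{i}" for i in range(n)],
            ss.df["pos"].to_numpy(), ld.r, 0.1, 10_000_000,
        )
        assert sorted(kept.df["snp_id"]) == sorted(oracle)
        # all kept pairs genuinely independent
        sub = ld.subset(list(kept.df["snp_id"]))
        off = sub.r[~np.eye(len(sub.snp_ids), dtype=bool)]
        assert np.all(off**2 < 0.1)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.permutations(list(range(8))))
    def test_row_order_invariance(self, perm):
        pvals = np.geomspace(1e-12, 1e-9, 8)
        ids = [f"s{i}" for i in range(8)]
        ld = ar1_ld(8, 0.8, ids)
        base = make_sumstats([
            {"snp_id": ids[i], "pos": 1000 + 500 * i, "pval": pvals[i]}
            for i in range(8)
        ])
        shuffled = make_sumstats([
            {"snp_id": ids[i], "pos": 1000 + 500 * i, "pval": pvals[i]}
            for i in perm
        ])
        k1, _ = ld_clump(base, ld, r2_max=0.2)
        k2, _ = ld_clump(shuffled, ld, r2_max=0.2)
        assert sorted(k1.df["snp_id"]) == sorted(k2.df["snp_id"])

    def test_weakening_r2_is_monotone(self, rng):
        n = 12
        ids = [f"s{i}" for i in range(n)]
        ld = ar1_ld(n, 0.9, ids)
        ss = make_sumstats([
            {"snp_id": ids[i], "pos": 1000 + 300 * i,
             "pval": float(rng.uniform(1e-12, 1e-8))}
            for i in range(n)
        ])
        sizes = [len(ld_clump(ss, ld, r2_max=r2)[0]) for r2 in (0.05, 0.1, 0.3, 0.8)]
        assert sizes == sorted(sizes)


class TestFStatistic:
    def test_values(self):
        assert f_statistic(0.1, 0.02) == pytest.approx(25.0)
        assert f_statistic(0.02, 0.02) == pytest.approx(1.0)
        # just under the weak-instrument gate
        assert f_statistic(0.0632, 0.02) == pytest.approx(9.9856)
        assert f_statistic(0.0632, 0.02) < 10

    def test_nonpositive_se_rejected(self):
        with pytest.raises(InputError):
            f_statistic(0.1, 0.0)


class TestSelectInstruments:
    def test_synthetic_region_one_strong_snp(self):
        study = simulate_mr_study(
            n_exposures=1, frac_causal=1.0, theta=0.3,
            instruments_per_exposure=1, n_snps_region=60, seed=1,
            n_disease_loci=0,
        )
        prot = "PROT_001"
        gene = GeneAnnotation(prot, "1", 1_500_000)
        instr = select_instruments(
            study.exposures[prot], gene, study.ld_regions[prot], PRESETS["pqtl"]
        )
        assert len(instr) == 1
        assert (instr.f_stats > 10).all()

    def test_all_nonsignificant_logged(self):
        ss = make_sumstats([
            {"snp_id": "a", "pos": 2_000_000, "pval": 1e-3},
            {"snp_id": "b", "pos": 2_001_000, "pval": 1e-4},
        ])
        ld = _ld(["a", "b"], np.eye(2))
        instr = select_instruments(ss, GENE, ld)
        assert len(instr) == 0
        assert set(instr.selection_log["reason"]) == {PVAL_FAIL}

    def test_lifestyle_preset_admits_sub_genomewide_snp(self):
        ss = make_sumstats([{"snp_id": "a", "pos": 2_000_000, "pval": 5e-6,
                             "beta": 0.1, "se": 0.021}])
        ld = _ld(["a"], [[1.0]])
        assert len(select_instruments(ss, GENE, ld, PRESETS["lifestyle"])) == 1
        assert len(select_instruments(ss, GENE, ld, PRESETS["pqtl"])) == 0

    def test_weak_instrument_gated(self):
        # significant p but F = 9 < 10: z from p must disagree, so pval is
        # set to match |beta/se| = 3 is impossible at 5e-8; use F just under
        ss = make_sumstats([{"snp_id": "a", "pos": 2_000_000, "pval": 4e-8,
                             "beta": 0.0632, "se": 0.02}])
        ld = _ld(["a"], [[1.0]])
        instr = select_instruments(ss, GENE, ld)
        assert len(instr) == 0
        assert list(instr.selection_log["reason"]) == [WEAK_INSTRUMENT]

    def test_log_covers_every_snp_and_criteria_hold(self):
        study = simulate_mr_study(
            n_exposures=2, frac_causal=0.5, theta=0.5,
            n_snps_region=80, seed=4, n_disease_loci=3,
        )
        prot = "PROT_002"
        gene = GeneAnnotation(prot, "2", 1_500_000)
        cfg = PRESETS["pqtl"]
        instr = select_instruments(
            study.exposures[prot], gene, study.ld_regions[prot], cfg
        )
        log = instr.selection_log
        assert sorted(log["snp_id"]) == sorted(study.exposures[prot].df["snp_id"])
        assert not log["snp_id"].duplicated().any()
        # re-check the four criteria against the raw inputs
        raw = study.exposures[prot].df.set_index("snp_id")
        for snp in instr.selected["snp_id"]:
            row = raw.loc[snp]
            assert row["chrom"] == gene.chrom
            assert abs(row["pos"] - gene.tss) <= cfg.window_bp
            assert row["pval"] < cfg.p_max
            assert (row["beta"] / row["se"]) ** 2 > cfg.f_min
        ids = list(instr.selected["snp_id"])
        sub = study.ld_regions[prot].subset(ids)
        off = sub.r[~np.eye(len(ids), dtype=bool)]
        assert np.all(off**2 < cfg.r2_max)


def test_presets_match_study_thresholds():
    pqtl, life = PRESETS["pqtl"], PRESETS["lifestyle"]
    assert (pqtl.p_max, pqtl.r2_max, pqtl.clump_window_kb) == (5e-8, 0.1, 10_000)
    assert (life.p_max, life.r2_max, life.clump_window_kb) == (1e-5, 0.001, 10_000)
    assert pqtl.window_bp == 1_000_000 and pqtl.f_min == 10
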