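"""Tests for size factors, dispersion, the NB Wald test and DEG calling."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from conftest import nb_counts, two_group_meta
from nptrap import differential_expression as de
from nptrap.errors import EstimationError, ValidationError


def make_cm(counts, meta=None, **kwargs):
    if meta is None:
        meta = two_group_meta(counts.shape[1] // 2)
    return de.CountMatrix(counts, meta, **kwargs)


class TestSizeFactors:
    def test_doubled_column(self):
        counts = pd.DataFrame({"s0": [10, 100, 40], "s1": [20, 200, 80]},
                              index=["a", "b", "c"])
        sf = de.size_factors_median_of_ratios(counts)
        assert sf["s0"] == pytest.approx(1 / np.sqrt(2))
        assert sf["s1"] == pytest.approx(np.sqrt(2))

    def test_identical_columns(self):
        counts = pd.DataFrame({"s0": [10, 100], "s1": [10, 100], "s2": [10, 100]})
        assert de.size_factors_median_of_ratios(counts).tolist() == pytest.approx([1, 1, 1])

    def test_single_sample(self):
        counts = pd.DataFrame({"s0": [5, 10]})
        assert de.size_factors_median_of_ratios(counts)["s0"] == 1.0

    def test_sparse_fallback_warns(self):
        counts = pd.DataFrame({"s0": [10, 0, 7], "s1": [0, 10, 0]})
        with pytest.warns(UserWarning, match="positive-subset"):
            sf = de.size_factors_median_of_ratios(counts)
        assert (sf > 0).all()


class TestCrossNormalization:
    def test_unit_factors_are_identity(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(50, (20, 6)),
                              columns=two_group_meta().index)
        cm = make_cm(counts, read_class="tc")
        out = de.apply_cross_normalization(cm, pd.Series(1.0, index=counts.columns))
        assert out.counts.equals(counts)
        assert (out.size_factors == 1.0).all()

    def test_missing_factor_rejected(self):
        counts = pd.DataFrame(np.ones((3, 6), dtype=int),
                              columns=two_group_meta().index)
        cm = make_cm(counts, read_class="tc")
        with pytest.raises(ValidationError):
            de.apply_cross_normalization(cm, pd.Series({"s0": 1.0}))

    @staticmethod
    def labeled_fraction_sim(seed=60, n_genes=500):
        """Totals constant across conditions; labeled fraction doubles."""
        rng = np.random.default_rng(seed)
        meta = two_group_meta()
        total_mean = np.full((n_genes, 6), 800.0)
        total = nb_counts(rng, total_mean, 0.02)
        f = np.where(meta["condition"] == "stress", 0.5, 0.25)
        tc = rng.binomial(total, f[None, :])
        idx = [f"g{i}" for i in range(n_genes)]
        return (pd.DataFrame(total, index=idx, columns=meta.index),
                pd.DataFrame(tc, index=idx, columns=meta.index), meta)

    def test_total_factors_detect_labeled_fraction_change(self):
        total, tc, meta = self.labeled_fraction_sim()
        factors = de.size_factors_median_of_ratios(total)
        res_total = de.nb_wald_test(de.CountMatrix(total, meta), factors=factors)
        cm_tc = de.apply_cross_normalization(de.CountMatrix(tc, meta, read_class="tc"),
                                             factors)
        res_tc = de.nb_wald_test(cm_tc)
        assert abs(res_total["log2_fc"].median()) < 0.1
        assert res_tc["log2_fc"].median() == pytest.approx(1.0, abs=0.1)

    def test_anti_pattern_is_biased(self):
        total, tc, meta = self.labeled_fraction_sim()
        bad_factors = de.size_factors_median_of_ratios(tc)  # the anti-pattern
        res_bad = de.nb_wald_test(de.CountMatrix(tc, meta), factors=bad_factors)
        assert abs(res_bad["log2_fc"].median()) < 0.3  # signal normalized away

    def test_common_scaling_invariance(self):
        total, tc, meta = self.labeled_fraction_sim()
        factors = de.size_factors_median_of_ratios(total)
        res1 = de.nb_wald_test(de.CountMatrix(tc, meta), factors=factors)
        factors3 = de.size_factors_median_of_ratios(total * 3)
        res3 = de.nb_wald_test(de.CountMatrix(tc * 3, meta), factors=factors3)
        assert np.allclose(res1["log2_fc"], res3["log2_fc"], atol=0.02)


class TestDispersion:
    def test_poisson_counts(self):
        rng = np.random.default_rng(61)
        counts = pd.DataFrame(rng.poisson(500, (2000, 6)),
                              columns=two_group_meta().index)
        disp = de.estimate_dispersion(make_cm(counts))
        assert np.median(disp) < 0.01

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(62)
        counts = pd.DataFrame(nb_counts(rng, 500.0, 0.05, (2000, 6)),
                              columns=two_group_meta().index)
        disp = de.estimate_dispersion(make_cm(counts))
        assert 0.035 <= np.median(disp) <= 0.065

    def test_constant_counts_floor(self):
        counts = pd.DataFrame(np.full((5, 6), 100), columns=two_group_meta().index)
        disp = de.estimate_dispersion(make_cm(counts))
        assert (disp <= 1e-6).all()

    def test_single_replicate_fallback_warns(self):
        meta = two_group_meta(1)
        counts = pd.DataFrame([[10, 12]], columns=meta.index)
        with pytest.warns(UserWarning, match="global dispersion"):
            de.estimate_dispersion(de.CountMatrix(counts, meta))


class TestWaldTest:
    def test_null_calibration(self):
        rng = np.random.default_rng(63)
        mean = rng.lognormal(np.log(300), 0.7, 2000)
        counts = pd.DataFrame(nb_counts(rng, mean[:, None], 0.05, (2000, 6)),
                              index=[f"g{i}" for i in range(2000)],
                              columns=two_group_meta().index)
        res = de.nb_wald_test(make_cm(counts))
        frac = (res["p_value"] < 0.05).mean()
        assert 0.035 <= frac <= 0.065
        # p-value uniformity under the null (exchangeability)
        assert stats.kstest(res["p_value"], "uniform").pvalue > 0.01

    def test_planted_effect_recovery(self):
        rng = np.random.default_rng(64)
        n, n_planted = 2000, 200
        mu = np.full((n, 6), 500.0)
        mu[:n_planted, 3:] *= 4.0  # log2FC = 2 in 10% of genes
        counts = pd.DataFrame(nb_counts(rng, mu, 0.05),
                              index=[f"g{i}" for i in range(n)],
                              columns=two_group_meta().index)
        res = de.nb_wald_test(make_cm(counts))
        lfc = res["log2_fc"].to_numpy()[:n_planted]
        se_theory = np.sqrt(2 * (1 / 500 + 0.05) / 3) / np.log(2)
        coverage = np.abs(lfc - 2.0) < 0.3
        expected_cov = 2 * stats.norm.cdf(0.3 / se_theory) - 1
        # matches the CLT prediction for 3v3 at this dispersion (~74%)
        assert coverage.mean() == pytest.approx(expected_cov, abs=0.08)
        sig = res["p_adj"] < 0.05
        assert sig[:n_planted].mean() >= 0.9                       # power
        assert sig[n_planted:].sum() / max(sig.sum(), 1) <= 0.10    # FDR

    def test_identical_groups_gene(self):
        meta = two_group_meta()
        counts = pd.DataFrame(np.tile([[100], [50]], 6), columns=meta.index,
                              index=["a", "b"])
        res = de.nb_wald_test(de.CountMatrix(counts, meta))
        assert res.loc["a", "log2_fc"] == pytest.approx(0.0, abs=1e-6)
        assert res.loc["a", "p_value"] == pytest.approx(1.0, abs=1e-6)

    def test_one_condition_rejected(self):
        meta = two_group_meta()
        meta["condition"] = "control"
        counts = pd.DataFrame(np.ones((2, 6), dtype=int), columns=meta.index)
        with pytest.raises(EstimationError):
            de.nb_wald_test(de.CountMatrix(counts, meta))

    def test_zero_condition_flagged(self):
        rng = np.random.default_rng(65)
        meta = two_group_meta()
        counts = pd.DataFrame(rng.poisson(100, (10, 6)), columns=meta.index,
                              index=[f"g{i}" for i in range(10)])
        counts.iloc[0, 3:] = 0
        res = de.nb_wald_test(de.CountMatrix(counts, meta))
        assert res.iloc[0]["status"] == "zero_ridge"
        assert np.isfinite(res.iloc[0]["log2_fc"])

    def test_lrt_close_to_wald(self):
        rng = np.random.default_rng(66)
        counts = pd.DataFrame(nb_counts(rng, 300.0, 0.05, (200, 6)),
                              columns=two_group_meta().index)
        cm = make_cm(counts)
        p_wald = de.nb_wald_test(cm)["p_value"]
        p_lrt = de.nb_wald_test(cm, use_lrt=True)["p_value"]
        assert stats.spearmanr(p_wald, p_lrt).statistic > 0.95


class TestGridSearchOracle:
    def test_wald_matches_independent_ml_fit(self):
        """Refined 2-D grid search over (intercept, lfc) as an independent MLE."""
        rng = np.random.default_rng(67)
        meta = two_group_meta()
        mu = np.full((20, 6), 200.0)
        mu[:10, 3:] *= 3.0
        counts = pd.DataFrame(nb_counts(rng, mu, 0.05),
                              index=[f"g{i}" for i in range(20)], columns=meta.index)
        cm = make_cm(counts)
        factors = de.size_factors_median_of_ratios(counts)
        disp = de.estimate_dispersion(cm, factors)
        res = de.nb_wald_test(cm, factors=factors, dispersions=disp)

        X = np.column_stack([np.ones(6), np.array([0, 0, 0, 1, 1, 1.0])])
        log_sf = np.log(factors.to_numpy())
        for g, gene in enumerate(counts.index):
            y = counts.loc[gene].to_numpy()
            alpha = disp[gene]

            def nll(beta):
                m = np.exp(log_sf + X @ beta)
                return -de.nb_loglik(y, m, alpha)

            # iterative grid refinement, independent of IRLS
            center = np.array([np.log(y.mean() + 0.5), 0.0])
            half = np.array([3.0, 3.0])
            for _ in range(12):
                b0 = np.linspace(center[0] - half[0], center[0] + half[0], 21)
                b1 = np.linspace(center[1] - half[1], center[1] + half[1], 21)
                vals = np.array([[nll(np.array([a, b])) for b in b1] for a in b0])
                i, j = np.unravel_index(np.argmin(vals), vals.shape)
                center = np.array([b0[i], b1[j]])
                half = half / 4
            lfc_oracle = center[1] / np.log(2)
            assert res.loc[gene, "log2_fc"] == pytest.approx(lfc_oracle, abs=2e-3)
            # SE via numerical Hessian at the oracle optimum
            eps = 1e-4
            h = np.zeros((2, 2))
            for a in range(2):
                for b in range(2):
                    pp = center.copy(); pp[a] += eps; pp[b] += eps
                    pm = center.copy(); pm[a] += eps; pm[b] -= eps
                    mp = center.copy(); mp[a] -= eps; mp[b] += eps
                    mm = center.copy(); mm[a] -= eps; mm[b] -= eps
                    h[a, b] = (nll(pp) - nll(pm) - nll(mp) + nll(mm)) / (4 * eps**2)
            se_oracle = np.sqrt(np.linalg.inv(h)[1, 1]) / np.log(2)
            wald_oracle = lfc_oracle / se_oracle
            # observed-information SE differs from expected-information SE only
            # through curvature noise; 3 significant figures on the statistic
            assert res.loc[gene, "wald_stat"] == pytest.approx(wald_oracle, rel=5e-2)


class TestBH:
    def test_hand_computed_example(self):
        out = de.bh_adjust([0.01, 0.04, 0.03])
        assert out == pytest.approx([0.03, 0.04, 0.04])

    def test_all_ones(self):
        assert de.bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_single_value(self):
        assert de.bh_adjust([0.2]) == pytest.approx([0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            de.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_monotone_and_order_preserving(self, ps):
        adj = de.bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(ps, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_fdr_control_in_simulation(self):
        rng = np.random.default_rng(68)
        fdrs = []
        for _ in range(40):
            p = np.concatenate([rng.uniform(0, 1, 900),
                                rng.beta(0.05, 10, 100)])  # 10% true effects
            rej = de.bh_adjust(p) < 0.05
            fdrs.append(rej[:900].sum() / max(rej.sum(), 1))
        assert np.mean(fdrs) <= 0.05 + 0.02


class TestDEGCalling:
    @pytest.mark.parametrize("p_adj,lfc,expected", [
        (0.01, 2.0, "up"),
        (0.01, 1.0, "neither"),   # below the |1.5| threshold
        (0.2, 3.0, "neither"),
        (0.01, -2.0, "down"),
    ])
    def test_thresholds(self, p_adj, lfc, expected):
        res = pd.DataFrame({"p_adj": [p_adj], "log2_fc": [lfc]}, index=["g"])
        up, down = de.call_degs(res, alpha=0.05, lfc_threshold=1.5)
        got = "up" if "g" in up else "down" if "g" in down else "neither"
        assert got == expected


class TestCPM:
    def test_simple_value(self):
        counts = pd.DataFrame({"s": [100]})
        lib = pd.Series({"s": 1e6})
        assert de.cpm(counts, lib).iloc[0, 0] == pytest.approx(100.0)

    def test_columns_sum_to_million(self):
        rng = np.random.default_rng(69)
        counts = pd.DataFrame(rng.poisson(50, (30, 4)))
        out = de.cpm(counts)
        assert out.sum(axis=0).to_numpy() == pytest.approx([1e6] * 4)

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"s": [0]})
        with pytest.raises(ValidationError):
            de.cpm(counts)

    def test_replicate_log_cpm_correlation(self):
        rng = np.random.default_rng(70)
        mean = rng.lognormal(np.log(1000), 1.6, 2000)
        counts = pd.DataFrame(nb_counts(rng, mean[:, None], 0.05, (2000, 2)))
        keep = counts.mean(axis=1) >= 100
        log_cpm = np.log2(de.cpm(counts[keep]) + 1)
        assert np.corrcoef(log_cpm[0], log_cpm[1])[0, 1] > 0.95
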