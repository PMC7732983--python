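"""NB testing machinery: size factors, BH, DE, LRT, z-tests, QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from isomirseq.quantify import CountMatrix
from isomirseq.simulate import CountSimConfig, PlantedEffect, simulate_counts
from isomirseq.stats import (bh_adjust, classify_shape, de_test,
                             global_category_test, lrt_trend, qc_summary,
                             size_factors, ztest_proportions)


class TestBH:
    @given(st.integers(0, 2**31 - 1))
    def test_equals_textbook_step_up_oracle(self, seed):
        """Our BH equals statsmodels' independent implementation."""
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 200))
        _, oracle, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_adjust(p), oracle, rtol=1e-12)

    def test_nan_excluded_from_family(self):
        p = np.array([0.01, np.nan, 0.04])
        adj = bh_adjust(p)
        assert np.isnan(adj[1])
        # family size is 2, not 3
        assert adj[0] == pytest.approx(0.02)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        raw = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        assert np.allclose(size_factors(raw), 1.0)

    def test_doubled_sample_detected(self):
        raw = pd.DataFrame({"a": [10, 20, 5], "b": [20, 40, 10]})
        f = size_factors(raw)
        assert f["b"] / f["a"] == pytest.approx(2.0)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_median_of_ratios(self, seed):
        # odd feature count: ratio-scale and log-scale medians coincide
        rng = np.random.default_rng(seed)
        raw = pd.DataFrame(rng.integers(1, 2000, size=(31, 5)),
                           columns=list("abcde"))
        f = size_factors(raw)
        # independent direct computation
        geo = np.exp(np.log(raw.to_numpy(float)).mean(axis=1))
        ratios = raw.to_numpy(float) / geo[:, None]
        brute = np.median(ratios, axis=0)
        brute = brute / np.exp(np.mean(np.log(brute)))
        assert np.allclose(f, brute, rtol=1e-12)

    def test_matches_pydeseq2_median_of_ratios(self):
        """Cross-check against DESeq2's reference implementation."""
        from pydeseq2.preprocessing import deseq2_norm

        rng = np.random.default_rng(0)
        raw = pd.DataFrame(rng.integers(1, 2000, size=(50, 6)),
                           columns=[f"s{i}" for i in range(6)])
        _, sf = deseq2_norm(raw.T)
        ours = size_factors(raw)
        # pydeseq2 does not mean-center log factors; compare up to scale
        ratio = ours.to_numpy() / np.asarray(sf)
        assert np.allclose(ratio, ratio[0], rtol=1e-9)


def _null_matrix(seed=42, n=2000):
    cm, _ = simulate_counts(CountSimConfig(n_features=n, rng_seed=seed))
    return cm


class TestDETest:
    def test_type_one_calibration_under_null(self):
        """Raw p < 0.05 fraction within [0.03, 0.07] on the null simulation."""
        de = de_test(_null_matrix(), "SEN", "SEN+M")
        frac = (de.p < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_power_on_planted_fourfold_effects(self):
        """>= 90% of planted 4-fold features called; <= 5% false calls."""
        effects = [PlantedEffect(f"feat_{i:05d}", "linear-up", (1.0, 4.0))
                   for i in range(50)]
        cfg = CountSimConfig(n_features=2000,
                             baseline_log_mean=np.log(500.0),
                             baseline_log_sd=0.0, dispersion=0.05,
                             effects=effects, rng_seed=7)
        cm, _ = simulate_counts(cfg)
        de = de_test(cm, "SEN", "SEN+M")
        assert de.iloc[:50]["called"].mean() >= 0.90
        assert de.iloc[50:]["called"].mean() <= 0.05

    def test_identical_counts_give_null_result(self):
        raw = pd.DataFrame(
            {f"s{i}": [100, 7, 3000] for i in range(6)},
            index=["f1", "f2", "f3"])
        cond = {f"s{i}": ("SEN" if i < 3 else "SEN+M") for i in range(6)}
        de = de_test(CountMatrix(raw, cond))
        assert np.allclose(de.log2fc, 0.0)
        assert (de.p > 0.9).all()

    def test_all_zero_feature_excluded_from_family(self):
        rng = np.random.default_rng(3)
        raw = pd.DataFrame(rng.integers(10, 100, size=(10, 6)),
                           columns=[f"s{i}" for i in range(6)])
        raw.iloc[0] = 0
        cond = {f"s{i}": ("SEN" if i < 3 else "SEN+M") for i in range(6)}
        de = de_test(CountMatrix(raw, cond))
        assert np.isnan(de.iloc[0].p) and not de.iloc[0].called

    def test_called_iff_thresholds_met(self):
        de = de_test(_null_matrix(seed=5, n=300), "SEN", "SEN+M")
        expect = (de.fdr < 0.05) & (de.log2fc.abs() >= np.log2(1.5))
        assert (de.called == expect.fillna(False)).all()


class TestLRT:
    def test_calibration_under_null(self):
        tr = lrt_trend(_null_matrix())
        frac = (tr.p < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_equal_condition_means_give_small_stat(self):
        raw = pd.DataFrame({f"s{i}": [500] * 5 for i in range(9)})
        cond = {f"s{i}": c for i, c in enumerate(
            ["Young"] * 3 + ["SEN"] * 3 + ["SEN+M"] * 3)}
        tr = lrt_trend(CountMatrix(raw, cond))
        assert (tr.lrt_stat < 1e-6).all()
        assert (tr.p > 0.999).all()

    def test_strong_u_pattern_recovered(self):
        effects = [PlantedEffect(f"feat_{i:05d}", "U", (0.25, 16.0))
                   for i in range(20)]
        cfg = CountSimConfig(n_features=500,
                             baseline_log_mean=np.log(500.0),
                             baseline_log_sd=0.0, dispersion=0.05,
                             effects=effects, rng_seed=3)
        cm, _ = simulate_counts(cfg)
        tr = lrt_trend(cm)
        assert (tr.iloc[:20].fdr < 0.05).all()
        assert (tr.iloc[:20]["shape"] == "U").all()


class TestClassifyShape:
    @pytest.mark.parametrize("means,expected", [
        ((10, 100, 1000), "linear-up"),
        ((1000, 100, 10), "linear-down"),
        ((10, 100, 12), "inverted-U"),
        ((100, 10, 90), "U"),
        ((100, 100, 100), "flat"),
    ])
    def test_shapes(self, means, expected):
        assert classify_shape(means, fdr=0.001) == expected

    def test_flat_when_not_significant(self):
        assert classify_shape((10, 100, 1000), fdr=0.2) == "flat"

    @given(st.integers(0, 2**31 - 1))
    def test_invariant_to_monotone_rescaling(self, seed):
        rng = np.random.default_rng(seed)
        means = tuple(rng.uniform(1, 1000, 3))
        scale = rng.uniform(0.01, 100)
        assert classify_shape(means, 0.01) == \
            classify_shape(tuple(m * scale for m in means), 0.01)


class TestZTest:
    def test_identical_proportions_p_one(self):
        assert ztest_proportions(50, 100, 50, 100) == pytest.approx(1.0)

    def test_large_difference_significant(self):
        assert ztest_proportions(4429, 10000, 5505, 10000) < 0.001

    def test_degenerate_tables(self):
        assert ztest_proportions(0, 100, 0, 200) == 1.0
        assert ztest_proportions(100, 100, 200, 200) == 1.0

    @pytest.mark.parametrize("x1,n1,x2,n2", [
        (1000, 10000, 1030, 10000), (3000, 10000, 3100, 10000),
        (500, 5000, 540, 5000), (2000, 20000, 2080, 20000)])
    def test_agrees_with_fisher_exact_within_ten_percent(self, x1, n1, x2, n2):
        z_p = ztest_proportions(x1, n1, x2, n2)
        _, f_p = sps.fisher_exact([[x1, n1 - x1], [x2, n2 - x2]])
        assert abs(z_p - f_p) / f_p < 0.10


class TestGlobalCategoryTest:
    def test_identical_distributions_p_one(self):
        assert global_category_test([100, 50, 25], [200, 100, 50]) == \
            pytest.approx(1.0)

    def test_wildly_different_distributions(self):
        assert global_category_test([900, 100], [100, 900]) < 1e-6

    def test_chi2_matches_permutation_on_small_table(self):
        a, b = [40, 25, 15], [30, 30, 20]
        p_chi = global_category_test(a, b)
        p_perm = global_category_test(a, b, method="permutation",
                                      n_perm=20000, seed=0)
        assert abs(p_chi - p_perm) < 3 * np.sqrt(p_chi * (1 - p_chi) / 20000) \
            + 0.01


class TestQC:
    def test_duplicated_sample_correlates_perfectly(self):
        rng = np.random.default_rng(0)
        col = rng.uniform(0, 1000, 50)
        rpm = pd.DataFrame({"a": col, "b": col, "c": rng.uniform(0, 1000, 50)})
        qc = qc_summary(rpm)
        assert qc.pearson.loc["a", "b"] == pytest.approx(1.0)
        assert np.allclose(np.diag(qc.pearson), 1.0)
        assert np.allclose(qc.pearson, qc.pearson.T)

    def test_variance_fractions_shape(self):
        rng = np.random.default_rng(1)
        rpm = pd.DataFrame(rng.uniform(0, 1000, size=(100, 6)),
                           columns=list("abcdef"))
        qc = qc_summary(rpm)
        vf = qc.variance_fractions
        assert vf.sum() <= 1.0 + 1e-9
        assert all(vf[i] >= vf[i + 1] for i in range(len(vf) - 1))

    def test_two_samples_single_pc_explains_everything(self):
        rng = np.random.default_rng(2)
        rpm = pd.DataFrame(rng.uniform(0, 1000, size=(50, 2)),
                           columns=["a", "b"])
        qc = qc_summary(rpm)
        assert qc.variance_fractions[0] == pytest.approx(1.0)
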