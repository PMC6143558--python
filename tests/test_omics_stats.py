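"""Transforms, imputation, multiple testing, and differential screens."""

import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evoprofiler.omics_stats import (
    DifferentialThresholds,
    adjust_pvalues,
    differential_features,
    geometric_fold_change,
    glog_transform,
    impute_missing,
    permutation_pvalue,
    rsd,
)


class TestGlog:
    def test_lambda_zero_is_plain_log(self):
        assert glog_transform(5.0, lam=0.0) == pytest.approx(math.log(5.0))

    def test_zero_value_lambda_four(self):
        assert glog_transform(0.0, lam=4.0) == pytest.approx(0.0)

    def test_closed_form_case(self):
        # log((3 + sqrt(9 + 16)) / 2) = log(4)
        assert glog_transform(3.0, lam=16.0) == pytest.approx(math.log(4.0))

    def test_domain_error(self):
        with pytest.raises(ValueError):
            glog_transform(0.0, lam=0.0)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1e4), min_size=2, max_size=10, unique=True),
           st.floats(0.01, 100.0))
    def test_strictly_increasing(self, values, lam):
        from hypothesis import assume
        values = sorted(values)
        assume(min(np.diff(values)) > 1e-6)  # ulp-spaced inputs round flat
        out = glog_transform(np.array(values), lam=lam)
        assert np.all(np.diff(out) > 0)


class TestImpute:
    def test_no_missing_is_identity(self):
        mat = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["a", "b"], columns=["s1", "s2"])
        out, mask = impute_missing(mat, {"a": 1.0, "b": 1.0})
        pd.testing.assert_frame_equal(out, mat)
        assert not mask.to_numpy().any()

    def test_half_lloq_fill(self):
        mat = pd.DataFrame([[np.nan, 2.0]], index=["a"], columns=["s1", "s2"])
        out, mask = impute_missing(mat, {"a": 0.8})
        assert out.loc["a", "s1"] == pytest.approx(0.4)
        assert mask.loc["a", "s1"] and not mask.loc["a", "s2"]

    def test_biomass_normalization(self):
        mat = pd.DataFrame([[np.nan]], index=["a"], columns=["s1"])
        out, _ = impute_missing(mat, {"a": 0.8}, biomass_factor={"s1": 2.0})
        assert out.loc["a", "s1"] == pytest.approx(0.2)

    def test_missing_without_lloq_raises(self):
        mat = pd.DataFrame([[np.nan]], index=["a"], columns=["s1"])
        with pytest.raises(ValueError):
            impute_missing(mat, {})


class TestRsd:
    def test_constant_vector_zero(self):
        assert rsd([4.0, 4.0, 4.0]) == 0.0

    def test_two_point_case(self):
        assert rsd([1.0, 3.0]) == pytest.approx(100 * math.sqrt(2) / 2)

    def test_fifty_percent_filter_drops_variable_component(self):
        assert rsd([1.0, 3.0]) >= 50.0  # the QC rule would drop this one

    def test_zero_mean_raises(self):
        with pytest.raises(ValueError):
            rsd([-1.0, 1.0])


class TestAdjustments:
    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=20))
    def test_agrees_with_brute_force_definitions(self, pvals):
        p = np.asarray(pvals)
        m = len(p)
        bonf = np.minimum(p * m, 1.0)
        assert adjust_pvalues(p, "bonferroni") == pytest.approx(bonf)
        # BH step-up from the definition
        order = np.argsort(p)
        bh_sorted = p[order] * m / np.arange(1, m + 1)
        bh_sorted = np.minimum.accumulate(bh_sorted[::-1])[::-1]
        bh = np.empty(m)
        bh[order] = np.minimum(bh_sorted, 1.0)
        assert adjust_pvalues(p, "bh") == pytest.approx(bh)

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(size=15)
        for method in ("bonferroni", "bh"):
            assert np.all(adjust_pvalues(p, method) >= p - 1e-15)


class TestPermutation:
    def test_exact_on_tiny_groups_matches_enumeration(self):
        a = [1.0, 2.0, 3.0]
        b = [10.0, 11.0, 12.0]
        # only the identity split and its mirror are as extreme: p = 2/20
        assert permutation_pvalue(a, b) == pytest.approx(2 / 20)

    def test_null_calibration(self):
        # type-I error at alpha=0.05 within 3 binomial sds over 2000 sims
        rng = np.random.default_rng(99)
        alpha, n_sims = 0.05, 2000
        rejections = 0
        for i in range(n_sims):
            x = rng.normal(size=20)
            p = permutation_pvalue(x[:10], x[10:], n_permutations=199, seed=i)
            rejections += p <= alpha
        rate = rejections / n_sims
        sd = math.sqrt(alpha * (1 - alpha) / n_sims)
        assert abs(rate - alpha) <= 3 * sd

    def test_seed_required_for_monte_carlo(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        with pytest.raises(ValueError):
            permutation_pvalue(x[:15], x[15:], n_permutations=100, seed=None)


class TestGeometricFoldChange:
    def test_sign_of_magnitude_change(self):
        assert geometric_fold_change([1, 1, 1], [10, 10, 10]) == pytest.approx(1.0, abs=1e-6)
        assert geometric_fold_change([10, 10, 10], [1, 1, 1]) == pytest.approx(-1.0, abs=1e-6)

    def test_uses_absolute_values(self):
        assert geometric_fold_change([-2, -2], [2, 2]) == pytest.approx(0.0, abs=1e-6)


class TestDifferentialFeatures:
    def _mat(self, rows, samples):
        return pd.DataFrame(rows, index=[f"c{i}" for i in range(len(rows))],
                            columns=samples)

    def test_identical_groups_not_significant(self):
        samples = [f"s{i}" for i in range(6)]
        mat = self._mat([[5.0] * 6, [2.0] * 6], samples)
        for datatype in ("metabolite", "transcript", "flux"):
            res = differential_features(mat, samples[:3], samples[3:], datatype)
            assert not res["significant"].any()

    @pytest.mark.parametrize("datatype", ["metabolite", "transcript"])
    def test_large_separation_significant(self, rng, datatype):
        samples = [f"s{i}" for i in range(6)]
        rows = [list(1.0 + rng.normal(0, 0.01, 3)) + list(8.0 + rng.normal(0, 0.01, 3))
                for _ in range(5)]
        mat = self._mat(rows, samples)
        res = differential_features(mat, samples[:3], samples[3:], datatype)
        # closed-form t on such data gives p << 0.01/m and |log2 FC| = 3
        assert res["significant"].all()
        assert np.all(np.abs(res["fc_stat"]) > 1.0)

    def test_flux_magnitude_gate(self):
        # gfc below 0.001 fails the magnitude gate even at tiny p
        samples = [f"s{i}" for i in range(12)]
        a = 1.0 + np.arange(6) * 1e-6
        b = a * 10 ** 0.0005  # gfc = 0.0005
        mat = self._mat([list(a) + list(b)], samples)
        res = differential_features(mat, samples[:6], samples[6:], "flux")
        assert res.loc[0, "p"] < 0.01
        assert abs(res.loc[0, "fc_stat"]) < 0.001
        assert not res.loc[0, "significant"]

    def test_flux_excluded_subsystem_filter(self):
        samples = [f"s{i}" for i in range(12)]
        a = list(1.0 + np.arange(6) * 1e-6)
        b = list(np.array(a) * 100)
        mat = self._mat([a + b, a + b], samples)
        res = differential_features(
            mat, samples[:6], samples[6:], "flux",
            subsystems={"c0": "Exchange", "c1": "Citric Acid Cycle"})
        assert not res.loc[0, "significant"]   # excluded subsystem
        assert res.loc[1, "significant"]

    def test_mutation_frequency_passthrough(self):
        samples = ["s0", "s1"]
        mat = self._mat([[0.05, 0.05], [0.6, 0.7]], samples)
        res = differential_features(mat, ["s0"], ["s0", "s1"], "mutation")
        assert list(res["significant"]) == [False, True]

    def test_literal_fold_change_band(self):
        # the literal printed band selects the UNCHANGED components
        samples = [f"s{i}" for i in range(6)]
        mat = self._mat([[1.0, 1.001, 0.999, 1.2, 1.201, 1.199]], samples)
        th = DifferentialThresholds(literal_fc_band=True)
        res = differential_features(mat, samples[:3], samples[3:], "metabolite",
                                    thresholds=th)
        assert res.loc[0, "significant"]  # tiny FC now *passes* the literal band

    def test_unknown_datatype_rejected(self):
        mat = self._mat([[1, 2, 3, 4]], ["a", "b", "c", "d"])
        with pytest.raises(ValueError):
            differential_features(mat, ["a", "b"], ["c", "d"], "proteome")

    def test_zero_variance_unequal_means_is_significant(self):
        samples = [f"s{i}" for i in range(6)]
        mat = self._mat([[1.0] * 3 + [8.0] * 3], samples)
        res = differential_features(mat, samples[:3], samples[3:], "transcript")
        assert res.loc[0, "p"] <= 1e-300
        assert res.loc[0, "significant"]
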