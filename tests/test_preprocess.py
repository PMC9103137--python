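"""Cleaning, clamping/filtering, exact two-means discretization, and the
preprocessing verification probe."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mgrselect.preprocess import (
    PreprocessConfig,
    bcw_config,
    clamp_and_filter,
    clean_matrix,
    discretize_two_means,
    golub_config,
    log10_transform,
    preliminary_filter,
    run_preprocess,
    two_means_split,
    verify_preprocessing,
)


class TestCleanMatrix:
    def test_mb_diagnosis_maps_to_binary(self):
        df = pd.DataFrame({"diagnosis": ["M", "B", "M"],
                           "f1": [1.0, 2.0, 3.0], "f2": [0.5, 0.1, 0.9]})
        res = clean_matrix(df, "diagnosis")
        assert res.labels.tolist() == [1, 0, 1]
        assert res.values.shape == (3, 2)

    def test_numeric_table_passes_through(self):
        df = pd.DataFrame({"y": [0, 1, 0], "a": [1, 2, 3], "b": [4, 5, 6]})
        res = clean_matrix(df, "y")
        np.testing.assert_array_equal(res.values, [[1, 4], [2, 5], [3, 6]])
        assert res.labels.tolist() == [0, 1, 0]

    def test_three_statuses_rejected(self):
        df = pd.DataFrame({"y": ["a", "b", "c"], "f": [1, 2, 3]})
        with pytest.raises(ValueError, match="2 statuses"):
            clean_matrix(df, "y")

    def test_unparseable_cell_named(self):
        df = pd.DataFrame({"y": [0, 1], "f": ["1.5", "oops"]})
        with pytest.raises(ValueError, match="f"):
            clean_matrix(df, "y")

    def test_missing_rows_dropped_and_counted(self):
        df = pd.DataFrame({"y": [0, 1, 1], "a": [1.0, np.nan, 3.0],
                           "b": [1.0, 2.0, 3.0]})
        res = clean_matrix(df, "y")
        assert res.dropped_rows == 1
        assert res.values.shape == (2, 2)


class TestClampAndFilter:
    CFG = PreprocessConfig(floor_value=100, ceiling_value=16000,
                           ratio_threshold=5, range_threshold=500)

    def test_wide_range_gene_retained_and_clamped(self):
        vals = np.array([[-10.0], [20000.0]])
        out, names = clamp_and_filter(vals, ("g",), self.CFG)
        np.testing.assert_array_equal(out, [[100.0], [16000.0]])
        assert names == ("g",)

    def test_low_ratio_gene_excluded(self):
        # post-clamp range [100, 400]: ratio 4 <= 5
        vals = np.array([[100.0, 100.0], [400.0, 16000.0]])
        out, names = clamp_and_filter(vals, ("lo", "hi"), self.CFG)
        assert names == ("hi",)

    def test_low_range_gene_excluded(self):
        # range 400 <= 500 even though ratio 1.4 is fine... ratio 1.4 <= 5 too;
        # use values where only the range rule bites
        vals = np.array([[1000.0, 100.0], [1400.0, 16000.0]])
        out, names = clamp_and_filter(vals, ("narrow", "wide"), self.CFG)
        assert names == ("wide",)

    def test_all_removed_is_an_error(self):
        vals = np.array([[100.0], [105.0]])
        with pytest.raises(ValueError, match="every variable"):
            clamp_and_filter(vals, ("g",), self.CFG)

    def test_relaxing_thresholds_is_monotone(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(100, 16000, size=(20, 50))
        strict = PreprocessConfig(ratio_threshold=10, range_threshold=2000)
        loose = PreprocessConfig(ratio_threshold=5, range_threshold=500)
        _, kept_strict = clamp_and_filter(vals, tuple(map(str, range(50))), strict)
        _, kept_loose = clamp_and_filter(vals, tuple(map(str, range(50))), loose)
        assert set(kept_strict) <= set(kept_loose)


class TestLog10:
    def test_arithmetic(self):
        out = log10_transform(np.array([[100.0, 16000.0]]))
        assert out[0, 0] == pytest.approx(2.0)
        assert out[0, 1] == pytest.approx(4.2041, abs=1e-4)

    def test_roundtrip(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(100, 16000, size=(5, 5))
        np.testing.assert_allclose(10 ** log10_transform(vals), vals,
                                   rtol=0, atol=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log10_transform(np.array([[0.0, 1.0]]))


class TestTwoMeans:
    def test_well_separated_clusters(self):
        codes, const = two_means_split(
            np.array([0.9, 1.0, 1.1, 4.8, 5.0, 5.2]))
        assert codes.tolist() == [0, 0, 0, 1, 1, 1]
        assert not const

    def test_constant_slice_all_zero(self):
        codes, const = two_means_split(np.full(5, 2.0))
        assert codes.tolist() == [0] * 5 and const

    def test_lower_mean_cluster_gets_code_zero(self):
        codes, _ = two_means_split(np.array([10.0, 0.0, 10.0]))
        assert codes.tolist() == [1, 0, 1]

    def test_matches_exhaustive_bipartition(self):
        """The sorted-threshold search attains the global 2-cluster SSE
        optimum, checked against enumeration of all bipartitions."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.normal(size=8)
            codes, _ = two_means_split(x)

            def sse(mask):
                out = 0.0
                for grp in (x[mask], x[~mask]):
                    if len(grp):
                        out += ((grp - grp.mean()) ** 2).sum()
                return out

            best = min(sse(np.array(m)) for m in
                       itertools.product([True, False], repeat=8)
                       if any(m) and not all(m))
            assert sse(codes == 0) == pytest.approx(best, abs=1e-9)

    def test_agrees_with_kmeans_on_separated_data(self):
        from sklearn.cluster import KMeans
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 0.3, 15), rng.normal(5, 0.3, 15)])
        codes, _ = two_means_split(x)
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(
            x.reshape(-1, 1))
        km_codes = km.labels_
        if km.cluster_centers_[0, 0] > km.cluster_centers_[1, 0]:
            km_codes = 1 - km_codes
        np.testing.assert_array_equal(codes, km_codes)

    def test_axis_orientation(self):
        vals = np.array([[0.0, 10.0], [0.1, 11.0], [5.0, 0.0]])
        per_var = discretize_two_means(vals, "per-variable")
        per_sample = discretize_two_means(vals, "per-sample")
        assert per_var[:, 0].tolist() == [0, 0, 1]
        assert per_sample[0].tolist() == [0, 1]


class TestPreliminaryFilter:
    def test_none_keeps_everything(self):
        keep = preliminary_filter(np.ones((4, 3)), [0, 0, 1, 1], "none", 0.05)
        assert keep.all()

    def test_planted_mean_shift_retained(self):
        rng = np.random.default_rng(5)
        labels = np.repeat([0, 1], 100)
        noise = rng.normal(size=(200, 5))
        signal = rng.normal(3 * labels, 1).reshape(-1, 1)
        vals = np.hstack([signal, noise])
        keep = preliminary_filter(vals, labels, "t-test", 0.05)
        assert keep[0]

    def test_noise_retention_near_alpha(self):
        rng = np.random.default_rng(6)
        labels = np.repeat([0, 1], 50)
        vals = rng.normal(size=(100, 400))
        keep = preliminary_filter(vals, labels, "t-test", 0.05)
        assert 0.01 <= keep.mean() <= 0.12

    def test_fold_change(self):
        labels = np.array([0, 0, 1, 1])
        vals = np.array([[1.0, 1.0], [1.0, 1.0], [4.0, 1.1], [4.0, 0.9]])
        keep = preliminary_filter(vals, labels, "fold-change", 2.0)
        assert keep.tolist() == [True, False]

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            preliminary_filter(np.ones((4, 2)), [0, 0, 1, 1], "anova", 0.05)


class TestRecipes:
    def _expression_table(self, seed=0, n=24, p=40):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(50, 20000, size=(n, p))
        df = pd.DataFrame(vals, columns=[f"g{i}" for i in range(p)])
        df["status"] = np.tile(["ALL", "AML"], n // 2)
        return df

    def test_golub_recipe_is_deterministic(self):
        df = self._expression_table()
        m1 = run_preprocess(df, "status", golub_config())
        m2 = run_preprocess(df, "status", golub_config())
        np.testing.assert_array_equal(m1.values, m2.values)
        assert m1.variable_names == m2.variable_names
        assert m1.labels.tolist() == m2.labels.tolist()
        assert set(np.unique(m1.values)) <= {0, 1}

    def test_bcw_recipe_discretizes_per_variable(self):
        df = pd.DataFrame({
            "diagnosis": ["M", "M", "B", "B"],
            "f1": [10.0, 11.0, 1.0, 1.2],
            "f2": [0.1, 0.2, 5.0, 5.1],
        })
        m = run_preprocess(df, "diagnosis", bcw_config())
        assert m.values[:, 0].tolist() == [1, 1, 0, 0]
        assert m.labels.tolist() == [1, 1, 0, 0]


class TestVerifyPreprocessing:
    def _planted_table(self, seed=0, n=120, p=40, permute=False):
        """Continuous table whose discretized first column determines the label."""
        rng = np.random.default_rng(seed)
        z = rng.integers(0, 2, size=(n, p))
        x = z * 3.0 + rng.normal(0, 0.4, size=(n, p))
        y = np.where(rng.random(n) < 0.92, z[:, 0], rng.integers(0, 2, n))
        if permute:
            y = rng.permutation(y)
        df = pd.DataFrame(x, columns=[f"v{i}" for i in range(p)])
        df["y"] = y
        return df

    def test_planted_signal_judged_reasonable(self):
        report = verify_preprocessing(
            self._planted_table(), "y", bcw_config(),
            n_probe=20, seed=0, folds=3, bda_B=60)
        assert report.reasonable
        assert report.accuracy > report.baseline + report.margin

    def test_permuted_labels_judged_unreasonable(self):
        report = verify_preprocessing(
            self._planted_table(permute=True), "y", bcw_config(),
            n_probe=20, seed=0, folds=3, bda_B=60)
        assert not report.reasonable

    def test_probe_larger_than_p_uses_all_with_warning(self):
        report = verify_preprocessing(
            self._planted_table(p=12), "y", bcw_config(),
            n_probe=100, seed=0, folds=3, bda_B=60)
        assert report.n_probe_used == 12
        assert report.warning is not None
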