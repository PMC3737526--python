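"""Preprocessing, gene selection, clustering/classification accuracy and
similarity statistics."""

import numpy as np
import pytest
from scipy import stats

import ipcc
from ipcc import errors
from ipcc.core import CorrelationFeatures, ExpressionMatrix
from ipcc.evaluate import gene_f_statistics


def em(values):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return ExpressionMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(n)],
        sample_ids=[f"s{j}" for j in range(m)],
    )


class TestPreprocess:
    def test_constant_gene_filtered_out(self):
        X = em([[500, 500, 500], [200, 900, 3000]])
        out = ipcc.preprocess_floor_ceil_filter_log(X, min_ratio=1.5, min_diff=10)
        assert out.gene_ids == ["g1"]

    def test_values_in_range_only_logged(self):
        X = em([[200.0, 2000.0], [150.0, 9000.0]])
        out = ipcc.preprocess_floor_ceil_filter_log(X, min_ratio=2, min_diff=100)
        assert np.allclose(out.values, np.log10(X.values))

    def test_hand_application_of_the_three_steps(self):
        # gene g0 spans (50, 20000): clamped to (100, 16000), ratio 160,
        # diff 15900 -> kept and logged; g1 barely varies -> filtered; g2 kept
        X = em([[50, 800, 20000], [300, 310, 305], [120, 900, 4000]])
        out = ipcc.preprocess_floor_ceil_filter_log(X)
        assert out.gene_ids == ["g0", "g2"]
        assert np.allclose(out.values[0], np.log10([100, 800, 16000]))

    def test_all_filtered_raises(self):
        X = em([[400, 401, 402]])
        with pytest.raises(errors.AllGenesFiltered):
            ipcc.preprocess_floor_ceil_filter_log(X)

    def test_bad_bounds(self):
        with pytest.raises(ValueError):
            ipcc.preprocess_floor_ceil_filter_log(em([[1.0, 2.0]]), floor=10, ceil=5)


class TestFTestSelect:
    labels6 = {f"s{j}": ("A" if j < 3 else "B") for j in range(6)}

    def test_hand_anova_value(self):
        f = gene_f_statistics(np.array([[1.0, 2, 3, 4, 5, 6]]),
                              np.array(["A"] * 3 + ["B"] * 3, dtype=object))
        assert f[0] == pytest.approx(13.5)

    def test_degenerate_conventions(self):
        values = np.array([
            [5.0, 5, 5, 5, 5, 5],     # constant -> F = 0
            [0.0, 0, 0, 1, 1, 1],     # perfect separator -> F = inf
            [1.0, 2, 3, 4, 5, 6],
        ])
        y = np.array(["A"] * 3 + ["B"] * 3, dtype=object)
        f = gene_f_statistics(values, y)
        assert f[0] == 0.0 and np.isinf(f[1])
        X = em(values)
        sel = ipcc.f_test_select(X, self.labels6, top_k=3)
        assert sel.gene_ids == ["g1", "g2", "g0"]  # inf first, constant last

    def test_matches_scipy_oneway_anova(self, rng):
        values = rng.normal(size=(25, 12))
        y = np.array(["A"] * 4 + ["B"] * 4 + ["C"] * 4, dtype=object)
        ours = gene_f_statistics(values, y)
        ref = np.array([
            stats.f_oneway(row[:4], row[4:8], row[8:]).statistic for row in values
        ])
        assert np.allclose(ours, ref, atol=1e-10)

    def test_top_k_all_is_stable_descending(self, rng):
        values = rng.normal(size=(10, 6))
        values[4] = values[2]  # duplicated gene: stable tie-break by input order
        X = em(values)
        sel = ipcc.f_test_select(X, self.labels6, top_k=10)
        f = gene_f_statistics(values, np.array(["A"] * 3 + ["B"] * 3, dtype=object))
        assert sorted(sel.gene_ids, key=lambda g: int(g[1:])) == X.gene_ids
        assert list(f[[int(g[1:]) for g in sel.gene_ids]]) == sorted(f, reverse=True)
        assert sel.gene_ids.index("g2") < sel.gene_ids.index("g4")

    def test_small_class_rejected(self):
        labels = {f"s{j}": ("A" if j == 0 else "B") for j in range(6)}
        with pytest.raises(errors.DegenerateClass):
            ipcc.f_test_select(em(np.ones((3, 6)) + np.arange(6)), labels, top_k=1)


class TestKMeansAndMatching:
    def test_separated_clouds_always_recovered(self, rng):
        x = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(5, 0.1, (10, 2))])
        truth = ["a"] * 10 + ["b"] * 10
        for part in ipcc.kmeans_runs(x, k=2, n_runs=10, seed=0):
            assert ipcc.match_accuracy(part, truth) == 1.0

    def test_runs_reproducible_given_seed(self, rng):
        x = rng.normal(size=(30, 4))
        a = ipcc.kmeans_runs(x, k=3, n_runs=5, seed=7)
        b = ipcc.kmeans_runs(x, k=3, n_runs=5, seed=7)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa, pb)

    def test_k_larger_than_m(self, rng):
        with pytest.raises(errors.KLargerThanM):
            ipcc.kmeans_runs(rng.normal(size=(3, 2)), k=4, n_runs=1, seed=0)

    @pytest.mark.parametrize(
        "pred, truth, expected",
        [
            ([1, 1, 0, 0], ["x", "x", "y", "y"], 1.0),          # renaming only
            ([1, 1, 1, 2, 3, 3], list("AABBCC"), 5 / 6),         # exhaustive best map
            ([0, 0, 0, 0, 0, 0], list("AABBCC"), 1 / 3),         # single cluster
        ],
    )
    def test_match_accuracy_values(self, pred, truth, expected):
        assert ipcc.match_accuracy(pred, truth) == pytest.approx(expected)

    def test_match_accuracy_invariances(self, rng):
        truth = rng.integers(0, 3, 40)
        pred = rng.integers(0, 3, 40)
        base = ipcc.match_accuracy(pred, truth)
        renamed = np.array([{0: 7, 1: 5, 2: 9}[p] for p in pred])
        assert ipcc.match_accuracy(renamed, truth) == base
        order = rng.permutation(40)
        assert ipcc.match_accuracy(pred[order], truth[order]) == base

    def test_length_mismatch(self):
        with pytest.raises(errors.SampleMismatch):
            ipcc.match_accuracy([0, 1], [0, 1, 2])

    def test_order_one_features_cluster_low_noise_simulation(self):
        d = ipcc.simulate_class_data(ipcc.SimulationSpec(noise_fold=10, sigma=0.1, seed=21))
        C1 = ipcc.sample_correlation_matrix(d.expression)
        acc = ipcc.clustering_accuracies(
            C1, d.labels, C1.sample_ids, k=3, n_runs=50, seed=0
        )
        assert acc.mean() > 0.9


class TestLoocvGaussianNB:
    def test_separable_constant_classes(self):
        x = np.array([[0.0, 0], [0, 0.1], [5, 5], [5, 5.1]])
        assert ipcc.loocv_gaussian_nb(x, ["a", "a", "b", "b"]) == 1.0

    def test_chance_level_on_permuted_null(self):
        X = ipcc.simulate_null_data("normal", m=120, n=40, seed=13)
        y = np.random.default_rng(13).permutation(["a", "b", "c"] * 40)
        acc = ipcc.loocv_gaussian_nb(X, y)
        p = 1 / 3
        assert abs(acc - p) <= 3 * np.sqrt(p * (1 - p) / 120)

    def test_global_positive_scaling_invariance(self, rng):
        x = rng.normal(size=(24, 5))
        y = ["a", "b", "c"] * 8
        assert ipcc.loocv_gaussian_nb(x, y) == ipcc.loocv_gaussian_nb(2.5 * x, y)

    def test_degenerate_class(self):
        with pytest.raises(errors.DegenerateClass):
            ipcc.loocv_gaussian_nb(np.eye(3), ["a", "a", "b"])


class TestIntraInterSimilarity:
    def cf(self, values):
        values = np.asarray(values, dtype=float)
        return CorrelationFeatures(
            values=values, order=1,
            sample_ids=[f"s{i + 1}" for i in range(values.shape[0])],
        )

    def test_ideal_block_matrix(self):
        v = np.array([[1, 1, -1, -1], [1, 1, -1, -1], [-1, -1, 1, 1], [-1, -1, 1, 1]], float)
        labels = {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}
        intra, inter, diff = ipcc.intra_inter_similarity(self.cf(v), labels)
        assert (intra, inter, diff) == (1.0, -1.0, 2.0)

    def test_uniform_matrix_has_zero_difference(self):
        v = np.full((4, 4), 0.4) + 0.6 * np.eye(4)
        labels = {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}
        intra, inter, diff = ipcc.intra_inter_similarity(self.cf(v), labels)
        assert intra == pytest.approx(0.4) and inter == pytest.approx(0.4)
        assert diff == pytest.approx(0.0)

    def test_toy3_hand_average(self):
        labels = {"s1": "c1", "s2": "c2", "s3": "c2", "s4": "c3"}
        intra, inter, diff = ipcc.intra_inter_similarity(ipcc.toy_fixture(3), labels)
        assert intra == pytest.approx(1.0)
        assert inter == pytest.approx(-0.4)
        assert diff == pytest.approx(1.4)

    def test_single_class_rejected(self):
        labels = {"s1": "A", "s2": "A", "s3": "A"}
        with pytest.raises(errors.SingleClass):
            ipcc.intra_inter_similarity(ipcc.toy_fixture(2), labels)


class TestAccuracyTTest:
    def test_identical_lists(self):
        t, p = ipcc.accuracy_ttest([0.7, 0.8, 0.9], [0.7, 0.8, 0.9])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_separated_lists(self, rng):
        a = rng.normal(0.0, 1e-4, 20)
        b = 1.0 + rng.normal(0.0, 1e-4, 20)
        _, p = ipcc.accuracy_ttest(a, b)
        assert p < 1e-6

    def test_zero_variance_conventions(self):
        assert ipcc.accuracy_ttest([0.5, 0.5], [0.5, 0.5]) == (0.0, 1.0)
        t, p = ipcc.accuracy_ttest([0.0, 0.0], [1.0, 1.0])
        assert np.isinf(t) and p == 0.0

    def test_insufficient_replicates(self):
        with pytest.raises(errors.InsufficientReplicates):
            ipcc.accuracy_ttest([0.5], [0.5, 0.6])
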