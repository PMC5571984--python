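"""Class-association tests, template correlations, scale/shift fits, UPGMA."""

import numpy as np
import pytest
from scipy import stats

from tdfe.association import (
    ClassLabels,
    categorical_regression_test,
    groupwise_timepoint_test,
    scale_shift_fit,
    template_correlations,
    upgma_pair,
)
from tdfe.selection import MIN_P


def labels(classes):
    return ClassLabels([f"s{i}" for i in range(len(classes))], classes)


class TestCategoricalRegression:
    def test_perfect_fit_reports_minimal_p(self):
        res = categorical_regression_test([1, 1, 0, 0],
                                          labels(["A", "A", "B", "B"]))
        assert res.p == MIN_P
        assert res.r_squared == pytest.approx(1.0)

    def test_equal_class_means_gives_p_one(self):
        res = categorical_regression_test([1, -1, 1, -1],
                                          labels(["A", "A", "B", "B"]))
        assert res.f_stat == 0.0
        assert res.p == 1.0

    def test_matches_one_way_anova(self, rng):
        v = rng.normal(size=12)
        cls = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        res = categorical_regression_test(v, labels(cls))
        f, p = stats.f_oneway(v[:4], v[4:8], v[8:])
        assert res.f_stat == pytest.approx(f)
        assert res.p == pytest.approx(p)

    def test_null_p_uniform(self):
        """4 classes x 10 samples, i.i.d. normal response: P ~ U(0,1)."""
        rng = np.random.default_rng(99)
        cls = [c for c in "ABCD" for _ in range(10)]
        ps = [
            categorical_regression_test(rng.normal(size=40), labels(cls)).p
            for _ in range(2000)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_invariances(self, rng):
        v = rng.normal(size=9)
        cls = ["A", "A", "A", "B", "B", "B", "C", "C", "C"]
        base = categorical_regression_test(v, labels(cls))
        renamed = categorical_regression_test(
            v, labels([{"A": "x", "B": "y", "C": "z"}[c] for c in cls])
        )
        affine = categorical_regression_test(3.0 * v - 7.0, labels(cls))
        assert renamed.p == pytest.approx(base.p)
        assert affine.p == pytest.approx(base.p)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            categorical_regression_test([1, 2, 3], labels(["A", "A", "A"]))
        with pytest.raises(ValueError, match="more samples"):
            categorical_regression_test([1, 2], labels(["A", "B"]))


class TestTemplateCorrelations:
    def test_self_correlation_is_one(self):
        t = np.array([1.0, 2.0, 3.0, 5.0])
        out = template_correlations(t, t[None, :])
        assert out["r"][0] == pytest.approx(1.0)
        assert out["p"][0] == MIN_P

    def test_orthogonal_profile_p_one(self):
        t = np.array([1.0, -1.0, 1.0, -1.0])
        prof = np.array([[1.0, 1.0, -1.0, -1.0]])
        out = template_correlations(t, prof)
        assert out["r"][0] == pytest.approx(0.0, abs=1e-12)
        assert out["p"][0] == pytest.approx(1.0)

    def test_worked_example(self):
        out = template_correlations([1, 2, 3, 4, 5],
                                    np.array([[1, 2, 3, 4, 6.0]]))
        assert out["r"][0] == pytest.approx(12 / np.sqrt(148), abs=1e-4)

    def test_zero_variance_profile_flagged(self):
        out = template_correlations([1.0, 2.0, 3.0],
                                    np.array([[5.0, 5.0, 5.0], [1, 2, 3.0]]))
        assert bool(out["excluded"][0]) and not bool(out["excluded"][1])
        assert np.isnan(out["r"][0])

    def test_null_p_uniform(self):
        rng = np.random.default_rng(4)
        t = rng.normal(size=30)
        profiles = rng.normal(size=(2000, 30))
        out = template_correlations(t, profiles)
        assert stats.kstest(out["p"], "uniform").pvalue > 0.01


class TestScaleShift:
    def test_identity_profile(self):
        t = np.array([1.0, 2.0, 3.0])
        fit = scale_shift_fit(t, t[None, :])
        assert fit.slope[0] == pytest.approx(1.0)
        assert fit.intercept[0] == pytest.approx(0.0, abs=1e-12)

    def test_affine_profile(self):
        t = np.array([1.0, 3.0, 5.0, 7.0])
        prof = (t - 3.0) / 2.0
        fit = scale_shift_fit(t, prof[None, :])
        assert fit.slope[0] == pytest.approx(2.0)
        assert fit.intercept[0] == pytest.approx(3.0)
        np.testing.assert_allclose(fit.fitted[0], t)

    def test_constant_profile_flagged(self):
        t = np.array([1.0, 2.0, 3.0])
        fit = scale_shift_fit(t, np.array([[4.0, 4.0, 4.0]]))
        assert fit.degenerate[0]
        assert fit.slope[0] == 0.0
        assert fit.intercept[0] == pytest.approx(2.0)


class TestGroupwise:
    def test_two_group_t_example(self):
        # 3 features, one time point, two groups
        fitted = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0]])
        out = groupwise_timepoint_test(fitted, groups=["A", "B"],
                                       times=[1, 1])
        assert out["statistic"][0] == pytest.approx(-np.sqrt(1.5), abs=1e-4)
        assert out["p"][0] == pytest.approx(0.2879, abs=1e-4)

    def test_identical_groups_p_one(self):
        fitted = np.array([[1.0, 1.0], [2.0, 2.0]])
        out = groupwise_timepoint_test(fitted, ["A", "B"], [1, 1])
        assert out["p"][0] == pytest.approx(1.0)

    def test_three_identical_groups_p_one(self):
        fitted = np.tile(np.array([[1.0], [2.0]]), (1, 3))
        out = groupwise_timepoint_test(fitted, ["A", "B", "C"], [1, 1, 1])
        assert out["test"][0] == "F"
        assert out["p"][0] == pytest.approx(1.0)

    def test_degenerate_group_named(self):
        fitted = np.array([[1.0, 2.0]])
        with pytest.raises(ValueError, match="time point"):
            groupwise_timepoint_test(fitted, ["A", "B"], [1, 1])


def brute_force_upgma(dist):
    """Exhaustive UPGMA merge heights: at each step merge the two clusters
    with the smallest mean inter-leaf distance (the unweighted average)."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    heights = []
    next_id = n
    while len(clusters) > 1:
        keys = sorted(clusters)
        h, a, b = min(
            (
                np.mean([dist[x, y] for x in clusters[a] for y in clusters[b]]),
                a,
                b,
            )
            for i, a in enumerate(keys)
            for b in keys[i + 1:]
        )
        heights.append(h)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return heights


class TestUPGMA:
    def test_duplicate_vector_merges_first(self, rng):
        v = rng.normal(size=10)
        res = upgma_pair({"a": v, "b": v.copy(), "c": rng.normal(size=10)})
        assert ("a", "b") in res.pairs
        assert res.merge_tree[0, 2] == pytest.approx(-1.0)

    def test_sign_flip_gives_distance_minus_one(self, rng):
        v = rng.normal(size=8)
        res = upgma_pair({"v": v, "neg": -v, "w": rng.normal(size=8)})
        assert res.distance[0, 1] == pytest.approx(-1.0)
        assert ("v", "neg") in res.pairs

    def test_invariant_under_sign_flips(self, rng):
        vecs = {f"v{i}": rng.normal(size=12) for i in range(5)}
        base = upgma_pair(vecs)
        flipped = upgma_pair(
            {k: (-v if i % 2 else v) for i, (k, v) in enumerate(vecs.items())}
        )
        np.testing.assert_allclose(base.distance, flipped.distance,
                                   atol=1e-12)
        assert base.pairs == flipped.pairs

    def test_matches_brute_force_on_four_vectors(self, rng):
        vecs = {f"v{i}": rng.normal(size=15) for i in range(4)}
        res = upgma_pair(vecs)
        oracle = brute_force_upgma(res.distance)
        # same merge heights in the same order
        np.testing.assert_allclose(res.merge_tree[:, 2], oracle, atol=1e-12)

    def test_zero_variance_vector_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            upgma_pair({"a": np.ones(5), "b": np.arange(5.0)})
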