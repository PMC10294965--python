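"""Probability pooling, distribution fits, distances, and inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from primood.confidence import (
    ProbabilityCluster, cauchy_mle, cauchy_summary, gaussian_summary,
    group_difference_test, pc1_scores, pool_motion_probabilities,
    spearman_with_impairment, wasserstein_1d,
)


def _frame(rows):
    return pd.DataFrame(rows, columns=["subject_id", "version_id",
                                       "predicted_label", "winning_probability"])


class TestPooling:
    def test_motion_based_filter(self):
        df = _frame([("s", "v", "reach", 0.9), ("s", "v", "idle", 0.99),
                     ("s", "v", "transport", 0.7)])
        cl = pool_motion_probabilities(df, "s")
        np.testing.assert_array_equal(cl.values, [0.9, 0.7])

    def test_all_idle_gives_empty_cluster(self):
        df = _frame([("s", "v", "idle", 0.99), ("s", "v", "stabilization", 0.8)])
        assert pool_motion_probabilities(df, "s").is_empty

    def test_pools_across_versions(self):
        rows = [("s", f"v{k}", "reach", 0.5 + 0.01 * k) for k in range(3)]
        cl = pool_motion_probabilities(_frame(rows), "s")
        assert cl.values.size == 3
        assert cl.version_ids == ["v0", "v1", "v2"]


class TestGaussianSummary:
    def test_two_values(self):
        m, sd = gaussian_summary(ProbabilityCluster("s", np.array([0.6, 0.8]), []))
        assert m == pytest.approx(0.7)
        assert sd == pytest.approx(np.sqrt(0.02), rel=1e-12)

    def test_constant_cluster(self):
        _, sd = gaussian_summary(ProbabilityCluster("s", np.full(5, 0.5), []))
        assert sd == 0.0

    def test_permutation_invariant(self):
        v = np.array([0.3, 0.9, 0.5, 0.7])
        a = gaussian_summary(ProbabilityCluster("s", v, []))
        b = gaussian_summary(ProbabilityCluster("s", v[::-1], []))
        assert a == b


class TestCauchyFit:
    def test_symmetric_three_points_returns_median(self):
        loc, scale = cauchy_summary(ProbabilityCluster("s", np.array([0.3, 0.5, 0.7]), []))
        assert loc == pytest.approx(0.5, abs=1e-8)
        assert scale > 0

    def test_recovers_location_from_truncated_draws(self):
        rng = np.random.default_rng(42)
        draws = stats.cauchy.rvs(loc=0.8, scale=0.05, size=20000, random_state=rng)
        draws = draws[(draws > 0) & (draws <= 1)][:5000]
        loc, scale, conv = cauchy_mle(draws)
        assert conv
        assert loc == pytest.approx(0.8, abs=0.01)
        assert scale == pytest.approx(0.05, abs=0.01)

    def test_matches_scipy_mle(self):
        """Independent route: scipy's generic MLE on the same sample."""
        rng = np.random.default_rng(7)
        x = stats.cauchy.rvs(loc=0.6, scale=0.1, size=400, random_state=rng)
        loc, scale, _ = cauchy_mle(x)
        s_loc, s_scale = stats.cauchy.fit(x)
        assert loc == pytest.approx(s_loc, abs=1e-4)
        assert scale == pytest.approx(s_scale, abs=1e-4)

    def test_affine_equivariance(self):
        rng = np.random.default_rng(3)
        x = stats.cauchy.rvs(loc=0.5, scale=0.08, size=300, random_state=rng)
        loc0, scale0, _ = cauchy_mle(x)
        loc1, scale1, _ = cauchy_mle(x + 0.2)
        assert loc1 == pytest.approx(loc0 + 0.2, abs=1e-6)
        assert scale1 == pytest.approx(scale0, abs=1e-6)


class TestPC1:
    def test_anticorrelated_features_explain_everything(self):
        loc = np.array([0.9, 0.8, 0.7, 0.6])
        res = pc1_scores(loc, 1.0 - loc)
        assert res.explained_ratio == pytest.approx(1.0)

    def test_sign_convention_higher_score_lower_confidence(self):
        loc = np.array([0.9, 0.8, 0.7, 0.6])        # decreasing confidence
        res = pc1_scores(loc, np.full(4, 0.1))      # constant spread dropped
        assert res.dropped_feature == "spread"
        assert all(a < b for a, b in zip(res.scores, res.scores[1:]))

    def test_duplicate_subjects_identical_scores(self):
        loc = np.array([0.9, 0.9, 0.7, 0.5])
        spr = np.array([0.1, 0.1, 0.2, 0.3])
        res = pc1_scores(loc, spr)
        assert res.scores[0] == pytest.approx(res.scores[1])


class TestWasserstein:
    def test_identical_clusters_zero(self):
        v = np.array([0.2, 0.5, 0.9])
        assert wasserstein_1d(v, v) == 0.0

    def test_two_point_closed_form(self):
        assert wasserstein_1d([0.2, 0.4], [0.4, 0.6]) == pytest.approx(0.2)

    def test_translation_property(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0.3, 0.9, 50)
        d = 0.07
        assert wasserstein_1d(v - d, v) == pytest.approx(d, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wasserstein_1d([], [0.5])


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman_with_impairment([0.1, 0.2, 0.3, 0.4, 0.5],
                                          [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)

    def test_reversed(self):
        rho, _ = spearman_with_impairment([0.5, 0.4, 0.3, 0.2, 0.1],
                                          [10, 20, 30, 40, 50])
        assert rho == pytest.approx(-1.0)

    def test_constant_flagged(self):
        with pytest.raises(ValueError):
            spearman_with_impairment([0.5] * 5, [1, 2, 3, 4, 5])


class TestGroupDifference:
    def test_identical_groups(self):
        v = [0.5, 0.6, 0.7]
        obs, p = group_difference_test(v, v, n_perm=199, seed=0)
        assert obs == 0.0
        assert p == 1.0

    def test_separated_groups_small_p_with_floor(self):
        a = [0.9 + 0.01 * i for i in range(6)]
        b = [0.1 + 0.01 * i for i in range(6)]
        obs, p = group_difference_test(a, b, n_perm=999, seed=1)
        assert obs == pytest.approx(0.8, abs=0.02)
        # only the original labeling (and its mirror) reproduces |obs|
        assert 1 / 1000 <= p <= 0.02

    def test_scale_invariance_of_p(self):
        a = [0.8, 0.85, 0.9, 0.95]
        b = [0.5, 0.55, 0.6, 0.65]
        _, p1 = group_difference_test(a, b, n_perm=499, seed=5)
        _, p2 = group_difference_test([2 * x for x in a], [2 * x for x in b],
                                      n_perm=499, seed=5)
        assert p1 == p2
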