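"""Silhouette, fuzzy silhouette, ARI and matched classification accuracy."""

import itertools

import numpy as np
import pytest

from clusterpower.cluster import UNASSIGNED, FuzzyPartition, HardPartition
from clusterpower.evaluate import (
    UndefinedMetricError,
    adjusted_rand,
    chance_level,
    classification_accuracy,
    fuzzy_silhouette,
    silhouette,
)


def brute_silhouette(Y, labels):
    """Literal evaluation of the mean-pairwise silhouette formula."""
    Y, labels = np.asarray(Y, float), np.asarray(labels)
    vals = []
    for i in range(len(Y)):
        own = [j for j in range(len(Y)) if labels[j] == labels[i] and j != i]
        if not own:
            vals.append(0.0)
            continue
        a = np.mean([np.linalg.norm(Y[i] - Y[j]) for j in own])
        b = min(
            np.mean([np.linalg.norm(Y[i] - Y[j]) for j in range(len(Y)) if labels[j] == c])
            for c in set(labels) if c != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def brute_ari(truth, pred):
    """Pair-counting definition of the adjusted Rand index."""
    n = len(truth)
    same_t = lambda i, j: truth[i] == truth[j]
    same_p = lambda i, j: pred[i] == pred[j]
    pairs = list(itertools.combinations(range(n), 2))
    a = sum(1 for i, j in pairs if same_t(i, j) and same_p(i, j))
    rows = np.unique(truth, return_counts=True)[1]
    cols = np.unique(pred, return_counts=True)[1]
    sum_rows = sum(c * (c - 1) / 2 for c in rows)
    sum_cols = sum(c * (c - 1) / 2 for c in cols)
    total = len(pairs)
    expected = sum_rows * sum_cols / total
    max_index = (sum_rows + sum_cols) / 2
    return (a - expected) / (max_index - expected)


class TestSilhouette:
    def test_duplicated_point_clusters_score_one(self):
        Y = np.array([[0, 0], [0, 0], [9, 9], [9, 9]])
        assert silhouette(Y, [0, 0, 1, 1]).score == 1.0

    def test_four_point_instance_matches_hand_formula(self):
        # cluster A = {(0,0),(0,1)}, B = {(10,0),(10,1)}: a=1, b=(10+sqrt(101))/2
        Y = np.array([[0, 0], [0, 1], [10, 0], [10, 1]])
        res = silhouette(Y, [0, 0, 1, 1])
        b = (10 + np.sqrt(101)) / 2
        assert res.score == pytest.approx((b - 1) / b, rel=1e-9)
        assert res.score == pytest.approx(0.9001, abs=2e-4)
        assert res.n_used == 4

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(5):
            Y = rng.standard_normal((25, 2))
            labels = rng.integers(0, 3, 25)
            if np.unique(labels).size < 2:
                continue
            assert silhouette(Y, labels).score == pytest.approx(
                brute_silhouette(Y, labels), rel=1e-9
            )

    def test_unassigned_excluded(self, rng):
        Y = np.vstack([rng.standard_normal((10, 2)), [[50.0, 50.0]]])
        labels = np.array([0] * 5 + [1] * 5 + [UNASSIGNED])
        res = silhouette(Y, HardPartition(labels=labels))
        assert res.n_used == 10

    def test_single_cluster_undefined(self):
        with pytest.raises(UndefinedMetricError):
            silhouette(np.zeros((5, 2)), [0] * 5)

    def test_rigid_motion_and_relabel_invariance(self, rng):
        Y = rng.standard_normal((30, 2))
        labels = rng.integers(0, 3, 30)
        base = silhouette(Y, labels).score
        R = np.array([[0, -1], [1, 0]])
        assert silhouette(Y @ R + 5.0, labels).score == pytest.approx(base, rel=1e-9)
        assert silhouette(Y, 2 - labels).score == pytest.approx(base, rel=1e-9)

    def test_bounds(self, rng):
        for _ in range(10):
            Y = rng.standard_normal((20, 2))
            labels = rng.integers(0, 4, 20)
            if np.unique(labels).size < 2:
                continue
            assert -1.0 <= silhouette(Y, labels).score <= 1.0


class TestFuzzySilhouette:
    def _random_crisp(self, rng, n=20, k=3):
        labels = rng.integers(0, k, n)
        U = np.zeros((n, k))
        U[np.arange(n), labels] = 1.0
        return rng.standard_normal((n, 2)), FuzzyPartition(U=U)

    def test_crisp_membership_equals_plain(self, rng):
        for _ in range(5):
            Y, fp = self._random_crisp(rng)
            if np.unique(fp.hard_labels).size < 2:
                continue
            assert fuzzy_silhouette(Y, fp, alpha=1.0).score == pytest.approx(
                silhouette(Y, fp.hard_labels).score, rel=1e-12
            )

    def test_alpha_zero_equals_plain(self, rng):
        Y = rng.standard_normal((30, 2))
        U = rng.dirichlet(np.ones(3), size=30)
        fp = FuzzyPartition(U=U)
        assert fuzzy_silhouette(Y, fp, alpha=0.0).score == pytest.approx(
            silhouette(Y, fp.hard_labels).score, rel=1e-12
        )

    def test_three_point_weighting_by_hand(self):
        # memberships (0.9,0.1), (0.6,0.4), (0.5,0.5): weights 0.8, 0.2, 0
        from sklearn.metrics import silhouette_samples

        Y = np.array([[0.0, 0.0], [4.0, 0.0], [2.0, 1.0]])
        fp = FuzzyPartition(U=np.array([[0.9, 0.1], [0.4, 0.6], [0.5, 0.5]]))
        sv = silhouette_samples(Y, fp.hard_labels)
        expected = (0.8 * sv[0] + 0.2 * sv[1]) / 1.0
        assert fuzzy_silhouette(Y, fp, alpha=1.0).score == pytest.approx(
            expected, rel=1e-9
        )

    def test_all_tied_memberships_undefined(self):
        # every observation maximally ambiguous -> no usable weight
        Y = np.array([[0.0, 0], [1, 0], [2, 0], [3, 0]])
        U = np.array([[0.5, 0.5]] * 4)
        with pytest.raises(UndefinedMetricError):
            fuzzy_silhouette(Y, FuzzyPartition(U=U), alpha=1.0)


class TestAdjustedRand:
    def test_identical_and_permuted_labelings(self):
        truth = [0, 0, 1, 1, 2, 2]
        assert adjusted_rand(truth, truth) == 1.0
        assert adjusted_rand(truth, [2, 2, 0, 0, 1, 1]) == 1.0

    def test_matches_pair_counting_formula(self):
        truth = [0, 0, 1, 1, 2, 2]
        pred = [0, 0, 1, 2, 2, 2]
        assert adjusted_rand(truth, pred) == pytest.approx(
            brute_ari(truth, pred), rel=1e-12
        )

    def test_matches_bruteforce_on_random_labelings(self, rng):
        for _ in range(5):
            truth = rng.integers(0, 3, 12)
            pred = rng.integers(0, 4, 12)
            assert adjusted_rand(truth, pred) == pytest.approx(
                brute_ari(truth, pred), rel=1e-9
            )

    def test_random_labelings_mean_near_zero(self):
        rng = np.random.default_rng(123)
        vals = []
        for _ in range(1000):
            truth = rng.integers(0, 3, 200)
            pred = rng.integers(0, 3, 200)
            vals.append(adjusted_rand(truth, pred))
        assert abs(np.mean(vals)) < 0.02

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rand([0, 1], [0, 1, 2])


class TestClassificationAccuracy:
    def test_exact_and_swapped_predictions(self):
        truth = [0, 0, 1, 1]
        assert classification_accuracy(truth, [0, 0, 1, 1])[0] == 1.0
        assert classification_accuracy(truth, [1, 1, 0, 0])[0] == 1.0

    def test_unassigned_count_as_errors(self):
        truth = np.repeat([0, 1], 50)
        pred = truth.copy()
        pred[:7] = UNASSIGNED
        acc, chance = classification_accuracy(truth, pred)
        assert acc == pytest.approx(0.93)
        assert chance == pytest.approx(0.50)

    def test_chance_is_largest_cluster_share(self):
        truth = [0] * 9 + [1]
        assert chance_level(truth) == pytest.approx(0.9)

    def test_all_in_largest_cluster_predictor_hits_chance(self, rng):
        truth = rng.integers(0, 3, 60)
        biggest = np.bincount(truth).argmax()
        pred = np.full(60, biggest)
        acc, chance = classification_accuracy(truth, pred)
        assert acc == pytest.approx(chance)

    def test_surplus_clusters_absorb_errors(self):
        # more predicted clusters than true ones: extra ones count as wrong
        truth = [0, 0, 0, 1, 1, 1]
        pred = [0, 0, 2, 1, 1, 3]
        acc, _ = classification_accuracy(truth, pred)
        assert acc == pytest.approx(4 / 6)
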