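"""Cluster-validity and accuracy metrics.

Silhouette follows the standard mean-pairwise-distance definition: for each
assigned observation, a = mean distance to the other members of its own
cluster, b = the smallest mean distance to any other cluster, and
s = (b - a) / max(a, b).  The score is the mean of s over assigned
observations; unassigned observations (e.g. HDBSCAN noise) are excluded.
Scores of 0.5 and 0.7 are the conventional thresholds for evidence and
strong evidence of clustering.

The fuzzy silhouette weights each observation's crisp silhouette value by
(mu_p - mu_q)^alpha, the gap between its largest and second-largest cluster
memberships, so confidently assigned observations dominate.  At alpha = 0
it reduces exactly to the plain silhouette.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from .cluster import UNASSIGNED, FuzzyPartition, HardPartition

__all__ = [
    "UndefinedMetricError",
    "SilhouetteResult",
    "silhouette",
    "fuzzy_silhouette",
    "adjusted_rand",
    "classification_accuracy",
    "chance_level",
]


class UndefinedMetricError(ValueError):
    """Metric undefined on this input (e.g. fewer than 2 populated clusters)."""


@dataclass(frozen=True)
class SilhouetteResult:
    score: float
    n_used: int


def _as_labels(partition) -> np.ndarray:
    if isinstance(partition, HardPartition):
        return partition.labels
    return np.asarray(partition, dtype=int)


def silhouette(Y: np.ndarray, partition) -> SilhouetteResult:
    """Mean silhouette over assigned observations (Euclidean distances)."""
    Y = np.asarray(Y, dtype=float)
    labels = _as_labels(partition)
    mask = labels != UNASSIGNED
    labs = labels[mask]
    uniq = np.unique(labs)
    if uniq.size < 2:
        raise UndefinedMetricError("silhouette needs >= 2 populated clusters")
    if uniq.size >= labs.size:
        raise UndefinedMetricError("silhouette needs more observations than clusters")
    s = silhouette_samples(Y[mask], labs, metric="euclidean")
    return SilhouetteResult(score=float(s.mean()), n_used=int(mask.sum()))


def fuzzy_silhouette(
    Y: np.ndarray, membership: FuzzyPartition, alpha: float = 1.0
) -> SilhouetteResult:
    """Membership-gap-weighted silhouette for fuzzy partitions.

    Crisp silhouette values are computed from the argmax (hard) labels; the
    weight of observation j is ``(mu_p - mu_q)**alpha`` where mu_p, mu_q
    are its two largest memberships.  Exactly tied memberships give weight
    0 for alpha > 0 (the observation is maximally ambiguous); alpha = 0
    gives every observation weight 1, recovering the plain silhouette.
    """
    if alpha < 0:
        raise UndefinedMetricError("alpha must be >= 0")
    Y = np.asarray(Y, dtype=float)
    U = membership.U
    hard = membership.hard_labels
    uniq = np.unique(hard)
    if uniq.size < 2:
        raise UndefinedMetricError("fuzzy silhouette needs >= 2 populated clusters")
    s = silhouette_samples(Y, hard, metric="euclidean")
    top2 = -np.partition(-U, 1, axis=1)[:, :2]
    gap = top2[:, 0] - top2[:, 1]
    w = gap**alpha  # 0**0 == 1: alpha=0 weights everything equally
    total = w.sum()
    if total <= 0:
        raise UndefinedMetricError("all fuzzy-silhouette weights are zero")
    return SilhouetteResult(score=float((w * s).sum() / total), n_used=len(s))


def adjusted_rand(truth, pred) -> float:
    """Adjusted Rand index between ground truth and a predicted partition.

    1 = identical partitions (up to relabelling), 0 = chance-level overlap,
    negative = worse than chance.  Unassigned predictions are excluded from
    the contingency table, mirroring the silhouette exclusion rule.
    """
    truth = np.asarray(_as_labels(truth))
    pred = np.asarray(_as_labels(pred))
    if truth.shape != pred.shape:
        raise ValueError("truth and prediction must have equal length")
    mask = pred != UNASSIGNED
    if mask.sum() == 0:
        return 0.0
    return float(adjusted_rand_score(truth[mask], pred[mask]))


def chance_level(truth) -> float:
    """Chance classification accuracy: share of the largest true cluster."""
    truth = np.asarray(_as_labels(truth))
    _, counts = np.unique(truth, return_counts=True)
    return float(counts.max() / truth.size)


def classification_accuracy(truth, pred) -> tuple[float, float]:
    """Best-matching classification accuracy and its chance level.

    Predicted cluster ids are matched one-to-one to true ids by optimal
    bipartite assignment (maximising the number of agreeing observations);
    unassigned observations count as errors.  Returns ``(accuracy, chance)``
    where chance is the largest true cluster's share of the sample.
    """
    truth = np.asarray(_as_labels(truth))
    pred = np.asarray(_as_labels(pred))
    if truth.shape != pred.shape:
        raise ValueError("truth and prediction must have equal length")
    n = truth.size
    mask = pred != UNASSIGNED
    correct = 0
    if mask.any():
        t, p = truth[mask], pred[mask]
        t_ids, t_inv = np.unique(t, return_inverse=True)
        p_ids, p_inv = np.unique(p, return_inverse=True)
        table = np.zeros((t_ids.size, p_ids.size), dtype=int)
        np.add.at(table, (t_inv, p_inv), 1)
        rows, cols = linear_sum_assignment(table, maximize=True)
        correct = int(table[rows, cols].sum())
    return correct / n, chance_level(truth)
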