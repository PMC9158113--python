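"""Population designs for clustered multivariate-normal data.

A population is described by k subgroups in standardised feature space
(every feature has unit standard deviation), so subgroup separation can be
expressed on the familiar Cohen's d scale.  The multivariate separation
between two subgroup centroids is the Euclidean quadrature of per-feature
effect sizes,

    Delta = sqrt(sum_i delta_i**2),

which serves as the effect-size metric for cluster analysis throughout
this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InvalidDesignError",
    "EffectDesign",
    "CentroidLayout",
    "PopulationSpec",
    "delta_from_feature_effects",
    "make_mean_arrays",
    "make_equidistant_centroids",
    "population_from_centroids",
]


class InvalidDesignError(ValueError):
    """Raised when a population design violates its invariants."""


@dataclass(frozen=True)
class EffectDesign:
    """Per-feature standardised mean differences (Cohen's d) between clusters.

    Parameters
    ----------
    per_feature_d
        One non-negative effect size per feature; zeros mark features on
        which the clusters do not differ.
    """

    per_feature_d: tuple[float, ...]

    def __init__(self, per_feature_d) -> None:
        d = tuple(float(v) for v in per_feature_d)
        if len(d) == 0:
            raise InvalidDesignError("effect design needs at least one feature")
        if any(v < 0 for v in d):
            raise InvalidDesignError("per-feature effect sizes must be >= 0")
        object.__setattr__(self, "per_feature_d", d)

    @property
    def n_features(self) -> int:
        return len(self.per_feature_d)


def delta_from_feature_effects(effects: EffectDesign) -> float:
    """Multivariate centroid separation Delta from per-feature effect sizes.

    Delta = sqrt(sum delta_i^2); it is 0 iff every per-feature effect is 0,
    scales linearly with the effect sizes, and is invariant to feature order.
    """
    if not isinstance(effects, EffectDesign):
        effects = EffectDesign(effects)
    d = np.asarray(effects.per_feature_d, dtype=float)
    return float(np.sqrt(np.sum(d * d)))


def make_mean_arrays(
    k: int,
    n_features: int,
    d: float,
    n_diff_features: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Construct per-cluster mean arrays from a single within-feature Cohen's d.

    For ``k=2`` each differing feature gets means ``-d/2`` and ``+d/2``, the
    assignment of sign to cluster shuffled independently per feature.  For
    ``k=3`` the middle cluster is the zero vector and the two outer clusters
    receive ``+d`` / ``-d`` per differing feature (sign order shuffled per
    feature).  Features beyond the first ``n_diff_features`` have mean 0 in
    every cluster.
    """
    if k not in (2, 3):
        raise InvalidDesignError(
            "make_mean_arrays supports k=2 or k=3; for other k use "
            "make_equidistant_centroids and population_from_centroids"
        )
    if not 1 <= n_diff_features <= n_features:
        raise InvalidDesignError("need 1 <= n_diff_features <= n_features")
    if d < 0:
        raise InvalidDesignError("Cohen's d must be >= 0")

    means = [np.zeros(n_features) for _ in range(k)]
    if k == 2:
        lo, hi = -d / 2.0, d / 2.0
        receivers = (0, 1)
    else:
        # cluster 1 is the zero-mean "middle" cluster
        lo, hi = -d, d
        receivers = (0, 2)
    for j in range(n_diff_features):
        a, b = receivers if rng.random() < 0.5 else receivers[::-1]
        means[a][j] = lo
        means[b][j] = hi
    return means


@dataclass(frozen=True)
class CentroidLayout:
    """k cluster centroids in 2-D with nearest-neighbour separation ``delta``."""

    k: int
    delta: float
    centroids: np.ndarray  # (k, 2)

    def min_pairwise_distance(self) -> float:
        if self.k < 2:
            raise InvalidDesignError("pairwise distance undefined for k < 2")
        c = self.centroids
        dists = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
        iu = np.triu_indices(self.k, 1)
        return float(dists[iu].min())


def make_equidistant_centroids(k: int, delta: float) -> CentroidLayout:
    """Place k equidistant centroids in 2-D, centred on the origin.

    k=1: the origin.  k=2: two points ``delta`` apart on the x-axis.
    k=3: equilateral triangle of side ``delta``.  k=4: a square of side
    ``delta`` — four mutually equidistant points do not exist in the plane,
    so the *nearest-neighbour* separation (the quantity that limits cluster
    detection) is what equals ``delta``; the two diagonals are
    ``delta * sqrt(2)``.
    """
    if delta < 0:
        raise InvalidDesignError("delta must be >= 0")
    if k == 1:
        pts = np.zeros((1, 2))
    elif k == 2:
        pts = np.array([[-delta / 2.0, 0.0], [delta / 2.0, 0.0]])
    elif k == 3:
        # circumradius of an equilateral triangle of side delta
        r = delta / np.sqrt(3.0)
        ang = np.deg2rad([90.0, 210.0, 330.0])
        pts = r * np.column_stack([np.cos(ang), np.sin(ang)])
    elif k == 4:
        h = delta / 2.0
        pts = np.array([[-h, -h], [-h, h], [h, -h], [h, h]])
    else:
        raise InvalidDesignError("equidistant layouts supported for k = 1..4")
    pts = pts - pts.mean(axis=0)
    return CentroidLayout(k=k, delta=float(delta), centroids=pts)


@dataclass(frozen=True)
class PopulationSpec:
    """Generative description of a clustered population.

    Each of the ``k`` subgroups is a multivariate normal distribution in
    standardised space: every covariance matrix is a correlation matrix
    (unit diagonal), so all per-feature standard deviations are 1.
    """

    n_features: int
    k: int
    weights: tuple[float, ...]
    means: tuple[np.ndarray, ...]
    covariances: tuple[np.ndarray, ...]
    layout: CentroidLayout | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.k < 1:
            raise InvalidDesignError("k must be >= 1")
        if len(self.weights) != self.k:
            raise InvalidDesignError("need one weight per subgroup")
        if any(w <= 0 for w in self.weights):
            raise InvalidDesignError("weights must be positive")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise InvalidDesignError("weights must sum to 1")
        if len(self.means) != self.k or len(self.covariances) != self.k:
            raise InvalidDesignError("need one mean array and covariance per subgroup")
        p = self.n_features
        for m in self.means:
            if m.shape != (p,):
                raise InvalidDesignError("mean array length must equal n_features")
        for c in self.covariances:
            if c.shape != (p, p):
                raise InvalidDesignError("covariance must be n_features x n_features")
            if not np.allclose(c, c.T, atol=1e-8):
                raise InvalidDesignError("covariance must be symmetric")
            if not np.allclose(np.diag(c), 1.0, atol=1e-8):
                raise InvalidDesignError("covariance must have unit diagonal")
            if np.linalg.eigvalsh(c).min() < -1e-8:
                raise InvalidDesignError("covariance must be positive semi-definite")


def population_from_centroids(
    layout: CentroidLayout,
    weights=None,
    covariances=None,
) -> PopulationSpec:
    """Build a 2-feature PopulationSpec whose subgroup means are the layout's
    centroids.  Default weights are equal; default covariances are identity
    (uncorrelated unit-variance features)."""
    k = layout.k
    if weights is None:
        weights = tuple(1.0 / k for _ in range(k))
    else:
        weights = tuple(float(w) for w in weights)
    if covariances is None:
        covariances = tuple(np.eye(2) for _ in range(k))
    else:
        covariances = tuple(np.asarray(c, dtype=float) for c in covariances)
    means = tuple(np.asarray(c, dtype=float) for c in layout.centroids)
    return PopulationSpec(
        n_features=2, k=k, weights=weights, means=means,
        covariances=covariances, layout=layout,
    )
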