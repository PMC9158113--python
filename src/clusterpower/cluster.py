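"""Uniform adapters around hard and fuzzy clustering algorithms.

Hard partitioners (k-means, agglomerative, HDBSCAN) return a
:class:`HardPartition`; fuzzy ones (c-means, Gaussian mixture posteriors)
return a row-stochastic membership matrix in a :class:`FuzzyPartition`.
HDBSCAN may leave low-density observations unassigned, marked with the
``UNASSIGNED`` sentinel; every other algorithm assigns all observations.
All stochastic algorithms are seeded through a numpy Generator, so the same
seed and data give identical partitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import HDBSCAN as _SKHDBSCAN
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.mixture import GaussianMixture

__all__ = [
    "UNASSIGNED",
    "ClusterFitError",
    "HardPartition",
    "FuzzyPartition",
    "MixtureFit",
    "run_kmeans",
    "run_agglomerative",
    "run_hdbscan",
    "run_cmeans",
    "run_gmm",
]

#: Sentinel label for observations no cluster claimed (HDBSCAN noise).
UNASSIGNED = -1


class ClusterFitError(RuntimeError):
    """A clustering/mixture fit failed or was requested on invalid input."""


@dataclass(frozen=True)
class HardPartition:
    labels: np.ndarray
    n_clusters_found: int = field(init=False)

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        found = np.unique(labels[labels != UNASSIGNED]).size
        object.__setattr__(self, "n_clusters_found", int(found))

    @property
    def assigned(self) -> np.ndarray:
        return self.labels != UNASSIGNED


@dataclass(frozen=True)
class FuzzyPartition:
    """Membership weights over clusters; rows sum to 1."""

    U: np.ndarray

    def __post_init__(self):
        U = np.asarray(self.U, dtype=float)
        if U.ndim != 2:
            raise ClusterFitError("membership matrix must be 2-D")
        if not np.allclose(U.sum(axis=1), 1.0, atol=1e-9):
            raise ClusterFitError("membership rows must sum to 1")
        object.__setattr__(self, "U", U)

    @property
    def hard_labels(self) -> np.ndarray:
        return np.argmax(self.U, axis=1)

    def to_hard(self) -> HardPartition:
        return HardPartition(labels=self.hard_labels)


@dataclass(frozen=True)
class MixtureFit:
    membership: FuzzyPartition
    bic: float


def _seed_from(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31 - 1))


def run_kmeans(Y: np.ndarray, k: int, rng: np.random.Generator) -> HardPartition:
    """Lloyd k-means with 10 random restarts, best inertia kept."""
    Y = np.asarray(Y, dtype=float)
    if k < 1 or Y.shape[0] < k:
        raise ClusterFitError(f"k-means needs N >= k >= 1, got N={Y.shape[0]}, k={k}")
    km = KMeans(n_clusters=k, n_init=10, random_state=_seed_from(rng))
    return HardPartition(labels=km.fit_predict(Y))


def run_agglomerative(
    Y: np.ndarray, k: int, flavour: str = "ward_euclidean"
) -> HardPartition:
    """Agglomerative clustering cut at k clusters.

    ``ward_euclidean`` minimises merged-group variance on Euclidean
    distances; ``average_cosine`` uses average linkage on cosine distances
    (undefined for zero vectors).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.shape[0] < k:
        raise ClusterFitError("agglomerative needs N >= k")
    if flavour == "ward_euclidean":
        model = AgglomerativeClustering(n_clusters=k, linkage="ward")
    elif flavour == "average_cosine":
        if np.any(np.linalg.norm(Y, axis=1) == 0):
            raise ClusterFitError("cosine distance undefined for zero vectors")
        model = AgglomerativeClustering(n_clusters=k, linkage="average", metric="cosine")
    else:
        raise ClusterFitError(f"unknown agglomerative flavour {flavour!r}")
    return HardPartition(labels=model.fit_predict(Y))


def run_hdbscan(Y: np.ndarray, min_cluster_size: int = 5) -> HardPartition:
    """HDBSCAN; reports its own cluster count, noise points stay UNASSIGNED."""
    Y = np.asarray(Y, dtype=float)
    model = _SKHDBSCAN(min_cluster_size=min_cluster_size, copy=True)
    return HardPartition(labels=model.fit_predict(Y))


def _fcm(
    Y: np.ndarray,
    k: int,
    m: float,
    rng: np.random.Generator,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> np.ndarray:
    """Fuzzy c-means membership matrix (Bezdek's alternating optimisation).

    Memberships are initialised uniformly at random and renormalised; each
    iteration recomputes centroids as membership^m-weighted means and
    memberships from inverse relative distances; stops when the largest
    membership change is below ``tol``.  Observations coincident with a
    centroid get membership 1 for it.
    """
    n = Y.shape[0]
    U = rng.random((n, k))
    U /= U.sum(axis=1, keepdims=True)
    exponent = 2.0 / (m - 1.0)
    for _ in range(max_iter):
        Um = U**m
        centroids = (Um.T @ Y) / Um.sum(axis=0)[:, None]
        d = np.linalg.norm(Y[:, None, :] - centroids[None, :, :], axis=-1)
        U_new = np.empty_like(U)
        zero = d <= 1e-12
        hit = zero.any(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d ** (-exponent)
            U_new = inv / inv.sum(axis=1, keepdims=True)
        if hit.any():
            U_new[hit] = zero[hit] / zero[hit].sum(axis=1, keepdims=True)
        shift = np.abs(U_new - U).max()
        U = U_new
        if shift < tol:
            break
    return U


def run_cmeans(
    Y: np.ndarray, k: int, rng: np.random.Generator, m: float = 2.0
) -> FuzzyPartition:
    """Fuzzy c-means with fuzzifier ``m`` (default 2, the conventional choice)."""
    Y = np.asarray(Y, dtype=float)
    if m <= 1:
        raise ClusterFitError("fuzzifier m must be > 1")
    if k < 2 or Y.shape[0] < k:
        raise ClusterFitError("c-means needs N >= k >= 2")
    return FuzzyPartition(U=_fcm(Y, k, m, rng))


def run_gmm(Y: np.ndarray, k: int, rng: np.random.Generator) -> MixtureFit:
    """Gaussian mixture EM fit with full per-component covariances.

    Posterior responsibilities form the fuzzy membership matrix; the BIC of
    the fitted mixture is returned for model selection.  A singular or
    non-converging fit raises :class:`ClusterFitError` so callers can
    exclude that k from model selection.
    """
    Y = np.asarray(Y, dtype=float)
    if k < 1:
        raise ClusterFitError("mixture needs k >= 1")
    if Y.shape[0] <= k:
        raise ClusterFitError("mixture needs N > k for full covariances")
    gm = GaussianMixture(
        n_components=k, covariance_type="full", reg_covar=1e-6,
        n_init=1, random_state=_seed_from(rng),
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(Y)
        U = gm.predict_proba(Y)
        bic = float(gm.bic(Y))
    except (ValueError, np.linalg.LinAlgError) as exc:  # singular fit
        raise ClusterFitError(f"mixture fit failed for k={k}: {exc}") from exc
    if not np.all(np.isfinite(U)):
        raise ClusterFitError(f"mixture fit produced non-finite posteriors at k={k}")
    return MixtureFit(membership=FuzzyPartition(U=U), bic=bic)
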