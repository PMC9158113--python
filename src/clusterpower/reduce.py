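"""Dimensionality reduction to 2-D and measurement of centroid separation.

Three strategies are supported: ``none`` (pass-through), metric
multi-dimensional scaling (MDS) on Euclidean distances, and UMAP with the
library's default neighbourhood parameters.  Non-linear embeddings do not
preserve the population separation Delta: MDS tends to exaggerate centroid
distances slightly, while UMAP shrinks them at small separations and
inflates them at large ones, so reduced-space separations are interpreted
as trends rather than calibrated effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.manifold import MDS

from .simulate import LabelledDataset

__all__ = ["ReducedDataset", "reduce_dataset", "observed_centroid_separation"]

METHODS = ("none", "mds", "umap")


class UndefinedSeparationError(ValueError):
    """Raised when centroid separation is requested for < 2 clusters."""


@dataclass(frozen=True)
class ReducedDataset:
    Y: np.ndarray
    method: str
    source: LabelledDataset


def _seed_from(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31 - 1))


def reduce_dataset(
    data: LabelledDataset,
    method: str = "none",
    rng: np.random.Generator | None = None,
    n_init: int = 2,
) -> ReducedDataset:
    """Project a dataset to 2-D (or pass it through unchanged).

    ``mds`` runs metric MDS (SMACOF) on Euclidean distances between
    standardised features; ``umap`` runs UMAP with default neighbourhood
    parameters.  Both are seeded from ``rng`` for reproducibility.
    """
    if method not in METHODS:
        raise ValueError(f"unknown reduction method {method!r}")
    if method == "none":
        return ReducedDataset(Y=data.X, method="none", source=data)
    if data.n_observations < 3:
        raise ValueError("mds/umap need at least 3 observations")
    if rng is None:
        rng = np.random.default_rng()
    seed = _seed_from(rng)
    if method == "mds":
        model = MDS(
            n_components=2, metric_mds=True, metric="euclidean", init="random",
            n_init=n_init, random_state=seed, normalized_stress=False,
        )
        Y = model.fit_transform(data.X)
    else:
        import umap  # deferred: numba compilation makes this import slow

        model = umap.UMAP(n_components=2, random_state=seed)
        Y = model.fit_transform(data.X)
    return ReducedDataset(Y=np.asarray(Y, dtype=float), method=method, source=data)


def observed_centroid_separation(Y: np.ndarray, labels: np.ndarray) -> float:
    """Minimum pairwise Euclidean distance between cluster mean positions.

    For two clusters this is the centroid distance; for three it equals the
    middle-to-outer distance of an equidistant design (the smallest
    between-cluster distance); for general k it is the minimum over all
    centroid pairs — the separation that limits detectability.
    """
    Y = np.asarray(Y, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise UndefinedSeparationError("separation needs >= 2 clusters")
    centroids = np.vstack([Y[labels == u].mean(axis=0) for u in uniq])
    d = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=-1)
    iu = np.triu_indices(uniq.size, 1)
    return float(d[iu].min())
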