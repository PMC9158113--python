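"""Covariance generation and dataset sampling.

Subgroups are sampled from multivariate normal distributions in
standardised space.  Covariance structure is expressed as correlation
matrices of one of four kinds:

``none``
    identity (uncorrelated features);
``random``
    off-diagonals drawn uniformly from [-0.3, 0.3];
``factor``
    features partitioned into contiguous, near-equal blocks ("factors");
    within-block correlations have magnitude uniform in [0.4, 0.9] with a
    random sign per block, between-block correlations are uniform in
    [-0.3, 0.3];
``mixed``
    a different kind per cluster.

Randomly filled correlation matrices are generally indefinite; they are
repaired to the nearest-in-spirit valid correlation matrix by clipping
negative eigenvalues at zero, reconstructing, and rescaling to unit
diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import InvalidDesignError, PopulationSpec

__all__ = [
    "CovarianceModel",
    "LabelledDataset",
    "make_covariance",
    "subgroup_sizes",
    "simulate_dataset",
    "write_dataset",
    "read_dataset",
]

_KINDS = ("none", "random", "factor", "mixed")


@dataclass(frozen=True)
class CovarianceModel:
    kind: str = "none"
    n_factors: int | None = None
    per_cluster_kinds: tuple | None = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise InvalidDesignError(f"unknown covariance kind {self.kind!r}")
        if self.kind == "factor" and not self.n_factors:
            raise InvalidDesignError("kind='factor' requires n_factors")
        if self.kind == "mixed" and not self.per_cluster_kinds:
            raise InvalidDesignError("kind='mixed' requires per_cluster_kinds")


@dataclass(frozen=True)
class LabelledDataset:
    """Observations-by-features matrix with ground-truth subgroup labels."""

    X: np.ndarray
    labels: np.ndarray
    spec: PopulationSpec | None = None

    @property
    def n_observations(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def _nearest_correlation(c: np.ndarray) -> np.ndarray:
    """PSD repair by eigenvalue clipping, then rescale to unit diagonal."""
    c = (c + c.T) / 2.0
    w, v = np.linalg.eigh(c)
    if w.min() >= 0:
        return c
    w = np.clip(w, 0.0, None)
    c = (v * w) @ v.T
    d = np.sqrt(np.clip(np.diag(c), 1e-12, None))
    c = c / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return (c + c.T) / 2.0


def _random_corr(p: int, rng: np.random.Generator) -> np.ndarray:
    c = rng.uniform(-0.3, 0.3, size=(p, p))
    c = np.triu(c, 1)
    c = c + c.T
    np.fill_diagonal(c, 1.0)
    return _nearest_correlation(c)


def _factor_corr(p: int, n_factors: int, rng: np.random.Generator) -> np.ndarray:
    if n_factors > p:
        raise InvalidDesignError("n_factors cannot exceed n_features")
    # contiguous, near-equal blocks
    bounds = np.linspace(0, p, n_factors + 1).round().astype(int)
    c = rng.uniform(-0.3, 0.3, size=(p, p))
    for b in range(n_factors):
        lo, hi = bounds[b], bounds[b + 1]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        block = sign * rng.uniform(0.4, 0.9, size=(hi - lo, hi - lo))
        c[lo:hi, lo:hi] = block
    c = np.triu(c, 1)
    c = c + c.T
    np.fill_diagonal(c, 1.0)
    return _nearest_correlation(c)


def make_covariance(
    model: CovarianceModel, n_features: int, rng: np.random.Generator
):
    """Generate correlation matrix/matrices for the given covariance model.

    Returns a single ``(p, p)`` matrix, or a list of per-cluster matrices
    when ``model.kind == 'mixed'``.
    """
    p = n_features
    if p < 1:
        raise InvalidDesignError("n_features must be >= 1")
    if model.kind == "none":
        return np.eye(p)
    if model.kind == "random":
        return _random_corr(p, rng)
    if model.kind == "factor":
        return _factor_corr(p, model.n_factors, rng)
    out = []
    for sub in model.per_cluster_kinds:
        sub_model = sub if isinstance(sub, CovarianceModel) else CovarianceModel(**sub)
        if sub_model.kind == "mixed":
            raise InvalidDesignError("mixed covariance cannot nest")
        out.append(make_covariance(sub_model, p, rng))
    return out


def subgroup_sizes(weights, N: int) -> np.ndarray:
    """Deterministic subgroup sizes: round(w_i * N), remainder going to the
    largest fractional parts first, so sizes always sum to N."""
    w = np.asarray(weights, dtype=float)
    exact = w * N
    sizes = np.floor(exact).astype(int)
    frac = exact - sizes
    short = N - sizes.sum()
    # hand out the remainder largest-fraction first (ties: lower index first)
    order = np.argsort(-frac, kind="stable")
    sizes[order[:short]] += 1
    if (sizes == 0).any():
        raise InvalidDesignError(
            f"subgroup sizes {sizes.tolist()} contain an empty subgroup at N={N}"
        )
    return sizes


def simulate_dataset(
    spec: PopulationSpec, N: int, rng: np.random.Generator
) -> LabelledDataset:
    """Draw a labelled sample of N observations from a population spec.

    Subgroup sizes are deterministic (see :func:`subgroup_sizes`); within
    each subgroup observations are i.i.d. multivariate normal with the
    subgroup's mean array and correlation matrix.  Labels are returned in
    generation order (block per subgroup).
    """
    if N < spec.k:
        raise InvalidDesignError("N must be at least the number of subgroups")
    sizes = subgroup_sizes(spec.weights, N)
    blocks, labels = [], []
    for i, n_i in enumerate(sizes):
        x = rng.multivariate_normal(
            spec.means[i], spec.covariances[i], size=int(n_i),
            method="cholesky" if _is_pd(spec.covariances[i]) else "eigh",
        )
        blocks.append(x)
        labels.append(np.full(int(n_i), i, dtype=int))
    return LabelledDataset(
        X=np.vstack(blocks), labels=np.concatenate(labels), spec=spec
    )


def _is_pd(c: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(c)
        return True
    except np.linalg.LinAlgError:
        return False


def write_dataset(data: LabelledDataset, path) -> None:
    """Write observations x features as CSV; final column = ground-truth label."""
    df = pd.DataFrame(
        data.X, columns=[f"feature_{j}" for j in range(data.n_features)]
    )
    df["label"] = data.labels
    df.to_csv(path, index=False)


def read_dataset(path) -> LabelledDataset:
    """Read a CSV written by :func:`write_dataset` (label column optional)."""
    df = pd.read_csv(path)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty dataset")
    if "label" in df.columns:
        labels = df.pop("label").to_numpy(dtype=int)
    else:
        labels = np.zeros(len(df), dtype=int)
    X = df.to_numpy(dtype=float)
    return LabelledDataset(X=X, labels=labels)
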