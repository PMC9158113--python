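"""Monte-Carlo estimation of statistical power for cluster detection.

Power is the probability that a pipeline declares a truly subgrouped
dataset "clustered".  The decision mimics a blinded analyst: algorithms
that need a prespecified k are run over a candidate grid (2..5 by default),
each solution is scored with the appropriate silhouette (plain for hard
partitions, fuzzy with alpha = 1 for membership matrices), and the dataset
counts as clustered when the *best* score reaches the threshold (0.5 by
default; 0.7 marks strong evidence).  HDBSCAN chooses its own cluster
count, so it is fit once and declared clustered only when it finds at
least two clusters whose silhouette reaches the threshold.

Cluster-number accuracy is the probability that the score-maximising k
equals the true k; classification accuracy is measured at the selected k
via optimal label matching.  Every cell of a power table derives its
iteration seeds deterministically from one master seed, so cells are
independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cluster import (
    ClusterFitError,
    FuzzyPartition,
    HardPartition,
    run_agglomerative,
    run_cmeans,
    run_gmm,
    run_hdbscan,
    run_kmeans,
)
from .design import (
    PopulationSpec,
    make_equidistant_centroids,
    population_from_centroids,
)
from .evaluate import (
    UndefinedMetricError,
    classification_accuracy,
    fuzzy_silhouette,
    silhouette,
)
from .simulate import simulate_dataset

__all__ = [
    "ALGORITHMS",
    "DecisionRule",
    "ClusteringOutcome",
    "PowerCell",
    "PowerTable",
    "detect_clustering",
    "estimate_power",
    "power_table",
    "compare_methods",
]

ALGORITHMS = ("kmeans", "ward", "cosine", "hdbscan", "cmeans", "gmm")
_GRID_ALGORITHMS = ("kmeans", "ward", "cosine", "cmeans", "gmm")
_FUZZY_ALGORITHMS = ("cmeans", "gmm")


@dataclass(frozen=True)
class DecisionRule:
    """Thresholds and candidate-k grid for the clustered-or-not decision."""

    silhouette_threshold: float = 0.5
    strong_threshold: float = 0.7
    k_grid: tuple[int, ...] = (2, 3, 4, 5)
    fuzzy_alpha: float = 1.0
    cmeans_fuzzifier: float = 2.0
    hdbscan_min_cluster_size: int = 5

    def __post_init__(self):
        if not 0 < self.silhouette_threshold < 1:
            raise ValueError("silhouette_threshold must be in (0, 1)")
        if not 0 < self.strong_threshold < 1:
            raise ValueError("strong_threshold must be in (0, 1)")
        if len(self.k_grid) == 0:
            raise ValueError("k_grid must be nonempty")
        object.__setattr__(self, "k_grid", tuple(sorted(int(k) for k in self.k_grid)))

    @staticmethod
    def comparison() -> "DecisionRule":
        """The wider grid (k = 2..7) used in the three-method comparison."""
        return DecisionRule(k_grid=tuple(range(2, 8)))


@dataclass(frozen=True)
class ClusteringOutcome:
    """Result of one clustered-or-not evaluation of a dataset."""

    algorithm: str
    best_k: int
    best_silhouette: float
    is_clustered: bool
    strong_evidence: bool
    partition: HardPartition | None
    membership: FuzzyPartition | None = None
    ari: float | None = None
    accuracy: float | None = None
    chance: float | None = None
    bic_best_k: int | None = None
    silhouette_by_k: dict = field(default_factory=dict)


def _fit_and_score(Y, algorithm, k, rule, rng):
    """One (algorithm, k) fit; returns (score, hard partition, membership, bic)."""
    if algorithm == "kmeans":
        part = run_kmeans(Y, k, rng)
        return silhouette(Y, part).score, part, None, None
    if algorithm == "ward":
        part = run_agglomerative(Y, k, "ward_euclidean")
        return silhouette(Y, part).score, part, None, None
    if algorithm == "cosine":
        part = run_agglomerative(Y, k, "average_cosine")
        return silhouette(Y, part).score, part, None, None
    if algorithm == "cmeans":
        fuzzy = run_cmeans(Y, k, rng, m=rule.cmeans_fuzzifier)
        return (
            fuzzy_silhouette(Y, fuzzy, alpha=rule.fuzzy_alpha).score,
            fuzzy.to_hard(), fuzzy, None,
        )
    if algorithm == "gmm":
        fit = run_gmm(Y, k, rng)
        fuzzy = fit.membership
        return (
            fuzzy_silhouette(Y, fuzzy, alpha=rule.fuzzy_alpha).score,
            fuzzy.to_hard(), fuzzy, fit.bic,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


def detect_clustering(
    Y: np.ndarray,
    algorithm: str,
    rule: DecisionRule,
    rng: np.random.Generator,
    truth: np.ndarray | None = None,
) -> ClusteringOutcome:
    """Run one pipeline on a data matrix and decide clustered-or-not.

    Grid algorithms are fit at every k in ``rule.k_grid``; the k with the
    highest (fuzzy) silhouette wins, ties going to the smallest k.  HDBSCAN
    is fit once with its own cluster count.  Degenerate fits (undefined
    silhouette, failed mixture) are excluded from selection; if no k yields
    a valid score the outcome is "not clustered".
    """
    Y = np.asarray(Y, dtype=float)
    best_k, best_score, best_part, best_memb = 0, -math.inf, None, None
    bics: dict[int, float] = {}
    scores: dict[int, float] = {}

    if algorithm == "hdbscan":
        part = run_hdbscan(Y, min_cluster_size=rule.hdbscan_min_cluster_size)
        best_k, best_part = part.n_clusters_found, part
        if part.n_clusters_found >= 2:
            try:
                best_score = silhouette(Y, part).score
                scores[best_k] = best_score
            except UndefinedMetricError:
                best_score = -math.inf
    elif algorithm in _GRID_ALGORITHMS:
        for k in rule.k_grid:
            try:
                score, part, memb, bic = _fit_and_score(Y, algorithm, k, rule, rng)
            except (ClusterFitError, UndefinedMetricError):
                continue
            scores[k] = score
            if bic is not None:
                bics[k] = bic
            if score > best_score:
                best_k, best_score, best_part, best_memb = k, score, part, memb
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")

    found = math.isfinite(best_score)
    is_clustered = found and best_score >= rule.silhouette_threshold
    strong = found and best_score >= rule.strong_threshold
    outcome = ClusteringOutcome(
        algorithm=algorithm,
        best_k=best_k,
        best_silhouette=best_score if found else math.nan,
        is_clustered=is_clustered,
        strong_evidence=strong,
        partition=best_part,
        membership=best_memb,
        bic_best_k=min(bics, key=bics.get) if bics else None,
        silhouette_by_k=scores,
    )
    if truth is not None and best_part is not None:
        acc, chance = classification_accuracy(truth, best_part)
        from .evaluate import adjusted_rand

        outcome = replace(
            outcome, accuracy=acc, chance=chance,
            ari=adjusted_rand(truth, best_part),
        )
    return outcome


@dataclass(frozen=True)
class PowerCell:
    """Monte-Carlo summary for one (algorithm, design, N) cell."""

    algorithm: str
    k_true: int
    weights: tuple[float, ...]
    delta: float
    N: int
    n_iterations: int
    seed: int
    power: float
    k_accuracy: float
    mean_accuracy: float
    mean_silhouette: float
    bic_k_accuracy: float | None = None


def _iteration_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def equidistant_population(
    k_true: int, delta: float, weights=None, covariances=None
) -> PopulationSpec:
    """2-feature population with k_true equidistant subgroups at separation delta."""
    layout = make_equidistant_centroids(k_true, delta)
    return population_from_centroids(layout, weights=weights, covariances=covariances)


def estimate_power(
    spec: PopulationSpec,
    N: int,
    algorithm: str,
    rule: DecisionRule,
    n_iterations: int,
    seed: int,
) -> PowerCell:
    """Estimate power, k-accuracy and classification accuracy for one cell.

    Each iteration simulates a fresh dataset from ``spec`` (iteration seeds
    derived deterministically from ``seed``), applies the detection rule,
    and records whether clustering was declared, whether the selected k
    equals the true k, and the optimal-matching accuracy at the selected k.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    detected, k_correct, accs, sils = [], [], [], []
    for child in _iteration_seeds(seed, n_iterations):
        rng = np.random.default_rng(child)
        data = simulate_dataset(spec, N, rng)
        out = detect_clustering(data.X, algorithm, rule, rng, truth=data.labels)
        detected.append(out.is_clustered)
        k_correct.append(out.best_k == spec.k)
        if out.accuracy is not None:
            accs.append(out.accuracy)
        if math.isfinite(out.best_silhouette):
            sils.append(out.best_silhouette)
    delta = spec.layout.delta if spec.layout is not None else math.nan
    return PowerCell(
        algorithm=algorithm, k_true=spec.k, weights=spec.weights,
        delta=delta, N=N, n_iterations=n_iterations, seed=seed,
        power=float(np.mean(detected)),
        k_accuracy=float(np.mean(k_correct)),
        mean_accuracy=float(np.mean(accs)) if accs else math.nan,
        mean_silhouette=float(np.mean(sils)) if sils else math.nan,
    )


@dataclass(frozen=True)
class PowerTable:
    """Collection of power cells over a (delta x N) grid."""

    cells: tuple[PowerCell, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "algorithm": c.algorithm, "k_true": c.k_true,
                "weights": "/".join(f"{w:g}" for w in c.weights),
                "delta": c.delta, "N": c.N,
                "power": c.power, "k_accuracy": c.k_accuracy,
                "mean_accuracy": c.mean_accuracy,
                "mean_silhouette": c.mean_silhouette,
                "bic_k_accuracy": c.bic_k_accuracy,
                "n_iterations": c.n_iterations, "seed": c.seed,
            }
            for c in self.cells
        ]
        return pd.DataFrame(rows)

    def wide_percentages(self, value: str = "power") -> pd.DataFrame:
        """Rows = N, columns = delta, integer percentages."""
        df = self.to_frame()
        wide = df.pivot_table(index=["algorithm", "k_true", "weights", "N"],
                              columns="delta", values=value)
        return (wide * 100).round().astype("Int64")


def power_table(
    algorithm: str,
    k_true: int,
    weights,
    deltas,
    Ns,
    rule: DecisionRule,
    n_iterations: int,
    seed: int,
    covariances=None,
    progress=None,
) -> PowerTable:
    """Estimate power over a (delta x N) grid with one master seed.

    Cell seeds are spawned deterministically from the master seed in grid
    order, so any cell can be recomputed in isolation.
    """
    deltas, Ns = list(deltas), list(Ns)
    cell_seeds = np.random.SeedSequence(seed).spawn(len(deltas) * len(Ns))
    cells = []
    i = 0
    for delta in deltas:
        spec = equidistant_population(k_true, delta, weights, covariances)
        for N in Ns:
            cell_seed = int(cell_seeds[i].generate_state(1)[0] % (2**31 - 1))
            cell = estimate_power(spec, N, algorithm, rule, n_iterations, cell_seed)
            cells.append(cell)
            if progress is not None:
                progress(cell)
            i += 1
    return PowerTable(cells=tuple(cells))


def compare_methods(
    k_true: int,
    deltas,
    N: int,
    n_iterations: int,
    seed: int,
    rule: DecisionRule | None = None,
) -> pd.DataFrame:
    """Matched comparison of k-means, c-means and Gaussian mixtures.

    In every iteration one dataset is simulated and handed to all three
    methods (k grid 2..7 by default), so differences in power reflect the
    methods, not sampling noise.  K-means is scored with the plain
    silhouette; c-means and mixture posteriors with the fuzzy silhouette
    (alpha = 1).  For mixtures the BIC-minimising k is recorded alongside
    the silhouette-maximising one.

    Returns a long-format frame with one row per (delta, method).
    """
    rule = rule or DecisionRule.comparison()
    methods = ("kmeans", "cmeans", "gmm")
    deltas = list(deltas)
    cell_seeds = np.random.SeedSequence(seed).spawn(len(deltas))
    rows = []
    for delta, cell_seed in zip(deltas, cell_seeds):
        spec = equidistant_population(k_true, delta)
        stats = {m: {"det": [], "k_ok": [], "sil": [], "acc": []} for m in methods}
        bic_ok = []
        for child in cell_seed.spawn(n_iterations):
            rng = np.random.default_rng(child)
            data = simulate_dataset(spec, N, rng)
            for m in methods:
                out = detect_clustering(data.X, m, rule, rng, truth=data.labels)
                stats[m]["det"].append(out.is_clustered)
                stats[m]["k_ok"].append(out.best_k == k_true)
                if math.isfinite(out.best_silhouette):
                    stats[m]["sil"].append(out.best_silhouette)
                if out.accuracy is not None:
                    stats[m]["acc"].append(out.accuracy)
                if m == "gmm" and out.bic_best_k is not None:
                    bic_ok.append(out.bic_best_k == k_true)
        for m in methods:
            s = stats[m]
            rows.append({
                "method": m, "k_true": k_true, "delta": delta, "N": N,
                "power": float(np.mean(s["det"])),
                "k_accuracy": float(np.mean(s["k_ok"])),
                "mean_silhouette": float(np.mean(s["sil"])) if s["sil"] else math.nan,
                "mean_accuracy": float(np.mean(s["acc"])) if s["acc"] else math.nan,
                "bic_k_accuracy": float(np.mean(bic_ok)) if m == "gmm" and bic_ok else math.nan,
                "n_iterations": n_iterations,
            })
    return pd.DataFrame(rows)
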