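# Methods

## Generative model

A population is k multivariate normal subgroups in standardised space:
every feature has SD 1, so each subgroup covariance is a correlation
matrix and differences between subgroup means are on the Cohen's d scale.
Subgroup separation is summarised by the nearest-neighbour centroid
distance Δ; for per-feature effect sizes δᵢ it equals the quadrature
Δ = √(Σδᵢ²), and `design.delta_from_feature_effects` evaluates exactly
that (homogeneous of degree 1, permutation-invariant, zero iff all δᵢ are
zero).

Two ways of placing centroids are provided.

* **Per-feature construction** (`design.make_mean_arrays`): for two
  subgroups, each differing feature contributes means −d/2 and +d/2, the
  sign assignment shuffled independently per feature from the caller's
  seeded generator; for three subgroups the middle one is the zero vector
  and the outer two receive ±d. Non-differing features are 0 everywhere.
  This mirrors high-dimensional designs where separation accumulates
  across many features.
* **Equidistant 2-D layouts** (`design.make_equidistant_centroids`):
  k = 1 the origin; k = 2 two points Δ apart; k = 3 an equilateral
  triangle of side Δ; k = 4 a square of side Δ. Four mutually equidistant
  points do not exist in the plane, so for k = 4 "equidistant" means the
  nearest-neighbour separation — the distance that limits detection — is
  Δ, while the diagonals are Δ√2. All layouts are centred on the origin so
  the population grand mean is zero.

## Covariance structures

`simulate.make_covariance` produces correlation matrices of four kinds:
identity ("none"); "random", off-diagonals uniform in [−0.3, 0.3];
"factor", features split into contiguous near-equal blocks whose
within-block correlations have magnitude uniform in [0.4, 0.9] with one
random sign per block (keeping blocks internally coherent) and
between-block entries uniform in [−0.3, 0.3]; and "mixed", one kind per
cluster. Randomly filled matrices are usually indefinite; they are
repaired by clipping negative eigenvalues at zero, reconstructing, and
rescaling to unit diagonal. The repair is deterministic and
structure-preserving in practice (a 20 000-observation sample from a
repaired 3-factor matrix reproduces it entrywise to < 0.05, which the test
suite checks), but it does shrink extreme entries slightly, so block
correlations should be read as approximate targets.

Subgroup sizes at sample size N are deterministic — round(wᵢ·N) with the
remainder assigned largest-fractional-part first — rather than
multinomially drawn. Fixed sizes match the fixed-percentage framing of the
study designs (e.g. a 10%/90% split of N = 10 is always 1 + 9) and remove
one source of Monte-Carlo variance. A weight small enough to round to zero
observations is an error, not a silent empty group.

## Pipelines

**Reduction.** `reduce.reduce_dataset` supports pass-through, metric MDS
(SMACOF on Euclidean distances between standardised features, random
initialisation, seeded) and UMAP (library defaults, 2 components, seeded).
Separation in an embedding is measured by
`reduce.observed_centroid_separation`: the minimum pairwise Euclidean
distance between per-cluster mean positions, which for the 3-cluster
equidistant design equals the middle-to-outer distance and generalises
conservatively to any k. Non-linear embeddings are not calibrated: MDS
tends to exaggerate separation slightly, and UMAP shrinks it below Δ ≈ 3
while inflating it for well-separated groups. These are asserted only as
majority-vote trends in the tests, never as point values — UMAP outcomes
vary materially across seeds and library versions.

**Clustering.** `cluster` wraps k-means (10 restarts, best inertia),
agglomerative clustering (Ward/Euclidean or average/cosine), HDBSCAN
(scikit-learn's implementation; default `min_cluster_size = 5`; noise
points carry the `UNASSIGNED` sentinel), Gaussian mixtures (full
per-component covariances, k-means initialisation, reg_covar = 1e−6; a
singular fit raises and is excluded from model selection), and fuzzy
c-means. C-means is implemented in-package as Bezdek's alternating
optimisation — membership-weighted centroids and inverse-relative-distance
membership updates with fuzzifier m = 2 (the conventional default,
exposed in `DecisionRule`), tolerance 1e−6 on the membership matrix, at
most 300 sweeps, random membership initialisation from the caller's
generator. A convergence test verifies the returned matrix is a fixed
point of a literal elementwise evaluation of the update formula.

**Evaluation.** The silhouette is the standard mean-pairwise-distance
version: a = mean distance to co-members, b = smallest mean distance to
another cluster, s = (b − a)/max(a, b), averaged over assigned
observations (HDBSCAN noise excluded). The descriptive phrase "distance to
its assigned centroid" that sometimes accompanies the silhouette would
suggest the simplified centroid-based variant; we deliberately use the
mean-pairwise definition, both because it is the canonical one and because
the centroid-based variant is empirically untenable here — it scores
forced splits of a single Gaussian above 0.5, producing a ~100%
false-positive rate where the genuine procedure produces ~0%. The fuzzy
silhouette weights each observation's crisp silhouette (computed from
argmax labels) by (μₚ − μ_q)^α; at α = 0 it equals the plain silhouette
exactly, and exactly tied memberships get weight 0 (deterministic
tie-break). The ARI is computed from the standard contingency-table
formula with unassigned predictions excluded (mirroring the silhouette
rule), while classification accuracy counts them as errors, matches
predicted to true clusters by optimal bipartite assignment, and reports
chance as the largest true subgroup's share.

## Decision rule and power

`power.detect_clustering` mimics a blinded analyst: fit every k in the
candidate grid (2–5 by default, 2–7 in the three-method comparison), score
each solution with the appropriate silhouette, select the
silhouette-maximising k (ties to the smallest k), and declare clustering
when that best score reaches 0.5. HDBSCAN is fit once; fewer than two
found clusters means "not clustered". Degenerate fits are dropped from
selection. The decision deliberately uses the best-k silhouette rather
than the true-k silhouette: the analyst does not know the true k, and this
makes detection and k-selection two readings of one procedure. The
alternative (score at the true k) lowers power by several points in
unequal tiny-sample designs and was considered and documented, not mixed
in.

`power.estimate_power` runs 100 iterations per cell by default (the
resolution used throughout: binomial SE ≤ 5 points). Iteration seeds are
spawned deterministically from the cell seed, and grid cells spawn their
seeds from one master seed in grid order, so any cell is independently
reproducible bit-for-bit. Power = fraction declared clustered; k-accuracy
= fraction with best k equal to the true k; classification accuracy is
recorded at the selected k (surplus clusters absorb errors under optimal
matching). `power.compare_methods` hands each simulated dataset to
k-means, c-means and Gaussian mixtures in the same iteration, so method
contrasts are paired; for mixtures it additionally records whether the
BIC-minimising k matches the truth.

## Problem sizes and runtime

Power grids in the tests and the acceptance script use the study-scale
conditions: 2-feature equidistant populations, N between 10 and 160 (120
for the comparison experiment), Δ between 1 and 10, 100 iterations per
cell. High-dimensional trend checks use 15-feature populations at N =
300–500; large-sample calibration checks (separation recovery, covariance
convergence) use N = 20 000. The full suite runs in under two minutes on
one CPU; the acceptance script in about one.

## Known limitations

* Subgroups are Gaussian with unit SDs; no heteroscedasticity, skew,
  outliers or missing data. Real biomedical data will generally yield
  lower power than these idealised conditions.
* HDBSCAN results depend materially on the density parameterisation and
  on implementation details of cluster extraction; with
  `min_cluster_size = 5`, power at Δ ≈ 3 is non-monotone in N (overlapping
  clusters merge as density grows). Treat HDBSCAN cells as approximate and
  tune `min_cluster_size` to the application.
* Posterior-based fuzzy silhouettes (mixtures) are sharper than c-means
  membership-based ones, so mixture detection power sits between k-means
  and c-means at moderate separation (Δ ≈ 3) instead of matching c-means.
* UMAP separations are trend-level only; they are not comparable across
  umap-learn versions.
* The fuzzy silhouette inflates scores relative to the plain silhouette
  on average (that is its purpose), so the 0.5/0.7 thresholds are not
  directly transferable between discrete and fuzzy pipelines; the
  false-positive calibration at k = 1 is the guard rail, and it holds at
  ~0% for all three methods at N = 120.
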