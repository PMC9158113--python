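# clusterpower

Simulation-based statistical power analysis for cluster detection.

Cluster algorithms (k-means, agglomerative clustering, HDBSCAN, fuzzy
c-means, Gaussian mixture modelling) are increasingly used in biomedical
research to find subgroups in multivariate data, yet unlike a t-test there
is no textbook formula for their statistical power — the probability of
correctly declaring that subgroups exist. `clusterpower` answers the
question by Monte Carlo: it simulates populations of multivariate normal
subgroups with controlled separation, runs complete analysis pipelines
(optional dimensionality reduction, clustering over a candidate-k grid,
silhouette-based decision), and tabulates power, cluster-number accuracy
and classification accuracy over grids of sample size N and separation Δ.
It is aimed at researchers planning a clustering study (e.g. for a
preregistration) who need to know what effect size and sample size their
pipeline requires.

## The model

Each of k subgroups is a multivariate normal distribution in standardised
space (every feature has SD 1), so the separation between two subgroup
centroids is a multivariate effect size

```
Δ = sqrt( Σᵢ δᵢ² )
```

where δᵢ is the per-feature Cohen's d. A study expecting small effects
(d = 0.3) on 20 of 100 features, medium (0.5) on 12 and large (0.8) on 4
therefore expects Δ = √(20·0.09 + 12·0.25 + 4·0.64) ≈ 2.7.

A dataset counts as **clustered** when the silhouette score of the best
solution reaches 0.5 (0.7 = strong evidence). Algorithms that need a
prespecified k are run over a grid (2–5 by default) and the
silhouette-maximising k is selected; HDBSCAN reports its own cluster
count. Fuzzy partitions (c-means memberships, mixture posteriors) are
scored with the fuzzy silhouette, which weights each observation's crisp
silhouette value by (μₚ − μ_q)^α, the gap between its two largest cluster
memberships (α = 1 by default). **Power** is the fraction of simulated
datasets declared clustered; **k-accuracy** the fraction in which the
selected k equals the true k; **classification accuracy** the fraction of
observations recovered under optimal cluster-to-truth matching (chance =
the largest subgroup's share).

## Worked example

```python
import numpy as np
from clusterpower import (
    DecisionRule, EffectDesign, delta_from_feature_effects,
    equidistant_population, estimate_power,
)

# expected separation for the planned measurement battery
d = [0.3] * 20 + [0.5] * 12 + [0.8] * 4 + [0.0] * 64
print(round(delta_from_feature_effects(EffectDesign(d)), 1))   # 2.7

# power of k-means to detect two equal subgroups at Delta = 4, N = 10
spec = equidistant_population(k_true=2, delta=4.0)
cell = estimate_power(spec, N=10, algorithm="kmeans",
                      rule=DecisionRule(), n_iterations=100, seed=1)
print(cell.power, cell.k_accuracy)                             # 0.85 0.84
```

The first number says a 100-feature battery with those per-feature effects
yields centroid separation Δ = 2.7 — below the Δ ≈ 4 that discrete
clustering needs, so the example study should plan for dimensionality
reduction (MDS raises measured separation) or a fuzzy method. The second
pair says that at Δ = 4 even N = 10 gives ~85% power, and the
silhouette-maximising k equals the true k in ~84% of draws.

There is also a CLI for the same machinery:

```
clusterpower simulate --config run.yaml --out data/
clusterpower power    --config run.yaml --out results/
clusterpower detect   --data mydata.csv --algorithm cmeans
```

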