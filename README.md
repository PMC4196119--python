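# progpath

Progression-path modeling for static tumor cohorts.

A tumor cohort profiled once per patient — expression plus gene-level copy
number, with survival follow-up — is a cross-section of an ongoing
process: every patient sits somewhere along a branching progression
trajectory.  `progpath` reconstructs that trajectory without longitudinal
data, for computational biologists working with cohort-scale molecular
snapshots.  The pipeline has four stages:

1. **Feature selection against censored survival** (`progpath.margin`).
   Regression on survival time y is decomposed into binary splits at
   every midpoint between consecutive distinct times.  For sample *n* at
   endpoint *s*, the expected hypothesis margin is

   ρ̄ₙ(s|w) = wᵀ( Σⱼ Q(j|n,w)|xₙ−xⱼ| − Σⱼ P(j|n,w)|xₙ−xⱼ| ) ≜ wᵀzₙ(s),

   with Q, P kernel-estimated probabilities of xⱼ being the nearest
   neighbor of xₙ on the opposite / same side of the split in the
   w-weighted block metric.  Weights solve
   min Σₙ,ₖ max(0, 1 − wᵀzₙ(k)) s.t. w ≥ 0, ‖w‖₁ ≤ λ,
   iterated with margin re-estimation to a fixed point; features with
   wⱼ > 10⁻³ are selected.
2. **Self-tuning spectral consensus clustering** (`progpath.spectral`).
   Mutual-KNN graph (K = 30), locally scaled similarities
   Sᵢⱼ = exp(−‖xᵢ−xⱼ‖²/σᵢσⱼ), normalized Laplacian D^{−1/2}SD^{−1/2},
   cluster number by Givens-rotation alignability of the top
   eigenvectors, K-means on the row-normalized spectral embedding, and
   stability via subsampled consensus matrices and similarity-form
   silhouette widths.
3. **Principal curve by EM** (`progpath.curve`).  A discretized,
   possibly branching curve (tree of nodes) fitted as a constrained
   Gaussian mixture, L = Σₙ log Σₘ pₘ N(xₙ|μₘ, σ²I), with σ fixed and
   chosen at the elbow of the (curve length, fitting error) sweep by
   two-line regression.
4. **Progression tree and mapping** (`progpath.tree`).  Clusters are
   placed on the curve backbone; root-to-leaf paths order samples by
   arc-length pseudotime; covariates map on by Spearman rank
   correlation, gene trajectories by CV-selected polynomials, survival
   by Kaplan-Meier.

Real cohorts of this kind are controlled-access, so `progpath.synth`
generates branching-manifold cohorts with survival outcomes for
validation and examples (see `docs/methods.md` for the study designs).

## Worked example

```python
import numpy as np
import scipy.stats
from progpath import (
    simulate_branching_data, init_topology, sweep_sigma, elbow_select,
    build_tree, extract_path, project_samples,
)
from progpath.curve import default_sigma_grid

matrix, truth = simulate_branching_data(
    n_samples=600, j_rel=20, j_irrel=0, noise_sd=0.1,
    clusters_trunk=2, clusters_arm=3, seed=5,
)
X = matrix.values
centroids = np.array([X[truth.cluster == c].mean(0) for c in np.unique(truth.cluster)])
topo, nodes = init_topology(X, "centroids", centroids=centroids, n_nodes=100)
sweep, models = sweep_sigma(X, topo, nodes, default_sigma_grid(X), max_iter=200)
sigma = elbow_select(sweep)
model = models[int(np.argmin(np.abs(sweep.sigmas - sigma)))]
roots = np.argsort(truth.latent)[:20]          # least-progressed samples
model.root = int(np.argmin(((model.mu - X[roots].mean(0)) ** 2).sum(1)))
tree = build_tree(truth.cluster, model, X, root_samples=roots)
print(f"sigma* = {sigma:.3f}")
print("leaves:", tree.leaves())
proj = project_samples(X, model)
for leaf in tree.leaves():
    path = extract_path(tree, leaf)
    r = scipy.stats.spearmanr(proj["arc_length"][path.sample_index],
                              truth.latent[path.sample_index]).statistic
    print(f"path to cluster {leaf}: n = {path.sample_index.size}, "
          f"pseudotime vs truth Spearman r = {r:.3f}")
```

Output:

```
sigma* = 0.222
leaves: [4, 7]
path to cluster 4: n = 467, pseudotime vs truth Spearman r = 0.996
path to cluster 7: n = 393, pseudotime vs truth Spearman r = 0.996
```

The elbow picks the noise scale σ* ≈ 0.22; the cluster-level tree has two
leaves (one per arm of the planted bifurcation) with one branch point, and
on both root-to-leaf paths the recovered arc-length pseudotime orders
samples almost exactly as the true latent progression coordinate.

A command-line interface mirrors the library
(`progpath simulate | scale | stack | filter | select | cluster | curve |
tree | km`); each subcommand reads and writes plain TSV/JSON.

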