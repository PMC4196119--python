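# Methods

`progpath` models tumor progression from a *static* cohort: one molecular
snapshot per patient, no longitudinal sampling.  The premise is that a
cross-section of many tumors at different stages traces out the progression
process itself — a low-dimensional, possibly branching manifold in marker
space — and that survival outcomes, cluster structure and a fitted
principal curve can jointly recover it.  This note records the models, the
parameter choices that matter, and the limits of what the synthetic
validation shows.

## Preprocessing

Expression and copy-number matrices are stacked per sample into one
feature vector.  Each feature is robustly scaled: an affine map sends its
2% quantile to 0 and its 98% quantile to 1 (quantiles by linear
interpolation of order statistics, the "type 7" convention), and values
beyond the anchors are clipped to [0, 1].  Clipping is the minimal
reading of outlier removal; a constant feature has no scale and maps to
zeros with a warning.  Samples censored before `min_years` (default 10)
of follow-up are removed before feature selection: an early-censored
patient contributes almost nothing to any survival endpoint, whereas a
death is informative at any time.  A stricter variant
(`drop_all_short=True`) also removes early deaths; the default keeps
them.  Missing clinical covariates are pairwise-dropped downstream, never
imputed.

## Feature selection on survival endpoints

Regression of censored survival times on tens of thousands of features is
decomposed into binary classification problems: for every midpoint s_k
between consecutive *distinct* observed times, the cohort splits into
"shorter than s_k" versus "longer than s_k".  For sample n at endpoint
s_k, the hypothesis margin is

    rho_n(s_k | w) = w' ( |x_n - NN_opp| - |x_n - NN_same| ),

the feature-weighted block (L1) distance to the nearest neighbor on the
opposite side minus that to the nearest neighbor on the same side.
Because nearest neighbors depend on the learned metric, they are treated
as hidden variables: the margin is replaced by its expectation z_n(k)
under kernel-estimated neighbor probabilities

    Q(j | n, w)  ∝  exp( -d_w(x_n, x_j) / (d̄_n · kappa) ),

normalized per split side, where d̄_n is sample n's mean weighted
distance to the cohort.  Normalizing by d̄_n makes the kernel
*scale-free*: multiplying w by a constant leaves Q and P unchanged, so
the sharpness of the soft nearest-neighbor averaging cannot drift with
the weight budget — without this, larger budgets sharpen the soft-min
and systematically bias held-out margins.  `kernel_width` (kappa,
default 2) is therefore in units of the mean distance: 2 is a broad,
stable averaging; values near 0 recover the hard hypothesis margin.

Weights are fitted by minimizing the total hinge loss
`sum_{n,k} max(0, 1 - w' z_n(k))` over the simplex-like set
{w >= 0, ||w||_1 <= lambda}, alternated with margin re-estimation until
the weight vector moves less than `tol` (1e-4, infinity norm; at most
`max_iter` = 50 rounds).  The inner solve is projected subgradient
descent with normalized directions, step `0.05 · lambda / sqrt(t)`, and
Euclidean projection onto the constraint set (positive-part then simplex
projection), restarted from the uniform feasible point at every
fixed-point round so that the weight update is a deterministic map of
the current metric alone (empirically a contraction: successive weight
changes shrink geometrically).  The returned solution is the tail
average of the iterates.
This matters: the hinge minimum is a broad plateau and its vertices are
sparse and arbitrary — an exact LP solver returns one of many
near-minimizers that concentrates weight on a few of a group of similarly
informative features and can park budget on chance-correlated noise
features.  The tail-averaged small-step path instead lands on the spread
interior near-minimizer (at a hinge value within a fraction of a percent
of the vertex optimum), which is the solution of scientific interest when
the goal is to *enumerate* the relevant features.  Features with
converged weight above tau = 1e-3 are selected.

The budget lambda (default 14 for cohorts on the scale of the synthetic
suite) can be tuned by k-fold cross-validation: the criterion is the
held-out endpoint misclassification rate (an expected margin <= 0 counts
as an error) — the generalization error the feature subspace is meant to
minimize — and the smallest lambda within one standard error of the best
score is chosen (the usual parsimony rule).  Error rate rather than
held-out hinge because the hinge scales with ||w|| and therefore cannot
compare budgets; the parsimony rule because on structureless data all
budgets tie within noise and the sparsest model should win.

## Self-tuning spectral clustering with consensus

Samples are connected in a mutual K-nearest-neighbor graph (Euclidean
distance, K = 30, ties broken by index); sigma_i is the distance from
sample i to its K-th neighbor, and edge similarities are locally scaled,
S_ij = exp(-||x_i - x_j||^2 / (sigma_i sigma_j)).  Zero local scales
(duplicates beyond K) borrow the smallest positive scale.  The spectrum
of L = D^{-1/2} S D^{-1/2} (eigenvalues in [-1, 1]; the multiplicity of 1
counts connected components) carries the cluster structure.

The number of clusters is estimated by eigenvector alignability: for each
candidate C, the top-C eigenvectors are rotated by gradient descent over
all C(C-1)/2 Givens angles (200 iterations, rate 0.05, analytic gradient,
one restart at a smaller rate if the cost fails to improve) to minimize
J = sum_i sum_c Z_ic^2 / max_c|Z_ic|^2; quality(C) = 1 - (J/N - 1)/C, and
the argmax wins with ties to the larger C.  A row of the eigenvector
matrix that is numerically zero — which happens when C is below the
number of connected components — means the embedding cannot see that
sample, and is charged cost 2 (an aligned row costs 1) so such C never
wins.  Labels come from K-means (best of 10 seeded k-means++ restarts by
within-cluster SSE) on the row-normalized top-C eigenvector matrix.

Stability is quantified two ways.  Consensus: the pipeline is re-run at
fixed C on subsamples (default 1,000 runs of 80% drawn without
replacement) and consensus_ij is the fraction of co-sampled runs in which
i and j co-cluster (never-co-sampled pairs are missing, excluded from
summaries).  The full-data clustering remains authoritative for labels;
the consensus matrix is a diagnostic (an average-linkage cut of the
consensus dissimilarity is available via ``labels_from="consensus"``).  Silhouette: in similarity form,
width_i = mean similarity to own cluster (excluding self) minus the
highest mean similarity to any other cluster; a cluster is stable iff its
mean width is positive; a singleton's width is 0 by convention.

## Principal curve by EM at fixed noise scale

The curve is discretized as M nodes (default 100) joined into a tree —
either a path along the first principal component or the minimum spanning
tree over supplied cluster centroids with each MST edge subdivided
proportionally to its length (this is how branches enter; the topology is
fixed during EM).  Data are modeled as a mixture: node mu_m is chosen
with probability p_m and observed with isotropic noise N(0, sigma^2 I).
EM maximizes the likelihood over {mu, p} with sigma *fixed by the user*,
because jointly estimating sigma is ill-posed (sigma -> 0 interpolates
every data point).  All mixture computations use log-sum-exp; EM stops at
relative log-likelihood gain below 1e-6 (at most 500 iterations); a node
with vanishing total responsibility is frozen for that iteration with a
warning.  After each M-step the interior nodes of every maximal degree-2
chain are re-placed at equal arc-length spacing along the current
polyline, realizing the equally-spaced-segment discretization (branch
points and leaves stay put).  With reparameterization disabled the
procedure is *exactly* isotropic fixed-variance Gaussian-mixture EM,
which is how it is verified.  The initialization is deterministic;
``n_restarts`` adds jittered restarts keeping the best log-likelihood.

sigma is chosen by an elbow criterion: sweeping a descending log-spaced
grid (default 12 values spanning [0.02, 0.3] x the RMS distance to the
data mean — sigma is a per-coordinate noise scale, and above roughly
0.4 x RMS the optimal curve collapses onto the data mean, a degenerate
record that would distort the elbow), warm-starting each fit from the
previous one unless that fit collapsed (a point-curve cannot be
re-expanded by EM, so the sweep then restarts from the initial nodes),
and recording curve
length (sum of segment lengths) against fitting error (sum of squared
distances to the *continuously projected* closest point on any segment —
the stricter reading of distance-to-curve).  Shorter sigma gives longer
curves and smaller error; the working point is the record whose length is
nearest the intersection of the two least-squares lines fitted to the two
arms of the (length, error) curve, with the breakpoint chosen by total
SSE over all interior splits.  Collinear records have no elbow; the
shortest-length (most conservative) record is returned with a warning.

Sample projections are orthogonal projections onto the nearest segment
(ties to the lower edge index); the pseudotime coordinate is the arc
length from a designated root node (the node nearest the mean of the
baseline samples, e.g. normal tissue, else node 0).

## Progression tree and covariate mapping

Clusters below `min_cluster_size` (default 5, generalizing the omission
of tiny unstable clusters) are dropped.  Each curve node is claimed by
the cluster holding the plurality of samples projecting nearest to it;
unclaimed nodes inherit from the nearest claimed node along the curve;
a cluster claiming disconnected curve regions keeps only its largest
region (by sample count, with a warning).  Contracting runs of
equally-claimed nodes yields the cluster-level tree; edge lengths are
Euclidean centroid distances; the root is the cluster holding the
baseline samples.  A path is the cluster sequence from the root to a
leaf; its samples are ordered by the arc-length coordinate.

Covariates are mapped onto paths by Spearman rank correlation (average
ranks for ties; missing values pairwise-dropped; zero variance reported
as missing).  Two-sided P values use the t approximation
t = r sqrt((n-2)/(1-r^2)) for n > 10 and the exact permutation
distribution for n <= 10, where the t approximation is unreliable.
Per-sample copy-number burden is the sum of absolute alteration
magnitudes.  Gene trajectories along a path are least-squares polynomials
of the min-max-normalized expression, with the degree (grid 1..8) chosen
by tenfold cross-validated MSE, ties to the lower degree.  Per-cluster
survival uses the Kaplan-Meier product-limit estimator (via lifelines),
reported at event times with at-risk counts.  The PCA view is ordinary
mean-centered PCA with its explained-variance fraction.

## Synthetic study design

Real progression cohorts with joint expression, copy-number and long
follow-up are controlled-access, so validation runs on generators that
emulate their structure.  The branching generator draws a latent
progression coordinate uniformly in arc length over a trunk that
bifurcates into two arms (lengths 1 and 1 in latent units).  Each of the
`j_rel` relevant features is a stage-wise activation: a sigmoid ramp of
width 0.25 in latent units (wide enough that successive activations
overlap and the manifold never stalls), switching on or off (random
sign) at its own unique change point.  The features form three
transcriptional programs: half belong to a shared trunk program with
change points spread along the trunk, and a quarter each to
arm-specific programs whose activations rise from exactly zero at the
bifurcation along their own arm and stay off in the other lineage —
the way branch-defining programs behave, and what makes the lineages
diverge promptly in feature space.  Unique change points matter: a
shared change point would make an exactly redundant feature pair that
any sparsity-inducing selector may legitimately prune, which would say
nothing about the method.  Relevant features carry N(0, 0.1^2) noise;
irrelevant features are i.i.d. standard normal.  Planted clusters are
equal arc-length bins (2 trunk + 2 per arm by default).  Survival is
time = link(t_max - t) + N(0, 0.5^2) with the monotone nonlinear default
link(u) = 1 + 20 u^1.5 (years), so progressed tumors die sooner;
censoring is independent: a fraction `censor_rate` (default 0.2) of
samples is censored uniformly before its event time.

The default validation problem sizes — a 600-sample bifurcation suite for
geometry, an ~180-sample cohort (about 150 after the censoring filter)
with 20 relevant / 980 irrelevant features for selection, 400-sample
blob sets for clustering — run the full pipeline in minutes on one CPU
and are stated in the test and acceptance code.

What the generators do *not* emulate: real marginal expression
distributions, gene-gene correlation beyond the shared manifold,
batch structure, informative censoring, or subtype-specific noise.
Passing the synthetic suite shows the algorithms recover the structure
they assume; it does not certify performance on any real cohort.

## Known limitations

- The curve topology is fixed by the centroid MST (or PC1) before EM;
  topology errors in that initialization are not corrected, and dead-end
  side branches appear only if the centroid MST contains them.
- The rotation-based cluster-number criterion saturates on exactly
  disconnected similarity graphs (any C at or above the component count
  can align perfectly); the zero-row penalty resolves C below the
  component count, and ties above it fall to the larger C by design.
- The feature selector's fixed point is contractive only for moderate
  kernel widths; very small kappa (hard nearest neighbors) can
  oscillate, which is reported via `converged=False`.
- Spearman P values for 10 < n < 30 rely on the t approximation, which
  is mildly anticonservative in the extreme tails.
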