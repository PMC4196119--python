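"""Self-tuning spectral clustering with consensus resampling.

Samples are connected in a mutual K-nearest-neighbor graph; similarities
use local scaling, S_ij = exp(-||x_i - x_j||^2 / (sigma_i sigma_j)) with
sigma_i the distance from i to its K-th nearest neighbor, so dense and
sparse regions are weighted comparably.  Clusters live in the top
eigenvectors of the normalized Laplacian L = D^{-1/2} S D^{-1/2}; the
number of clusters is estimated by how well those eigenvectors can be
rotated onto the canonical axes (one nonzero entry per row), and K-means
on the row-normalized eigenvector matrix assigns labels.  Stability is
assessed by subsampled consensus clustering and a similarity-based
silhouette width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse.linalg
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import pairwise_distances
from sklearn.utils.validation import validate_data

_DENSE_EIG_LIMIT = 2000


@dataclass
class SimilarityGraph:
    """Mutual-KNN adjacency with per-sample local scales."""

    adjacency: np.ndarray  # bool, symmetric, zero diagonal
    scales: np.ndarray  # sigma_i = distance to K-th nearest neighbor


def mutual_knn(X: np.ndarray, k: int = 30) -> SimilarityGraph:
    """Mutual K-nearest-neighbor graph under Euclidean distance.

    An edge (i, j) exists iff j is among the K nearest neighbors of i AND
    vice versa.  Ties in distance are broken by sample index.  The local
    scale sigma_i is the distance from i to its K-th nearest neighbor.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} samples (got {n}); reduce k")
    D = pairwise_distances(X)
    np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    scales = D[np.arange(n), order[:, -1]].copy()
    in_knn = np.zeros((n, n), dtype=bool)
    np.put_along_axis(in_knn, order, True, axis=1)
    adjacency = in_knn & in_knn.T
    np.fill_diagonal(adjacency, False)
    return SimilarityGraph(adjacency, scales)


def local_scaled_similarity(graph: SimilarityGraph, X: np.ndarray) -> np.ndarray:
    """Locally scaled similarity exp(-||x_i-x_j||^2/(sigma_i sigma_j)) on graph edges.

    Zero local scales (duplicate points beyond K) are replaced by the
    smallest positive scale, with a warning.
    """
    X = np.asarray(X, dtype=float)
    scales = graph.scales.copy()
    if np.any(scales <= 0):
        positive = scales[scales > 0]
        if positive.size == 0:
            raise ValueError("all local scales are zero (all points coincide)")
        warnings.warn(
            f"{int((scales <= 0).sum())} zero local scale(s) replaced by the "
            "smallest positive scale",
            UserWarning,
        )
        scales[scales <= 0] = positive.min()
    D2 = pairwise_distances(X, squared=True)
    S = np.exp(-D2 / np.outer(scales, scales))
    S = np.where(graph.adjacency, S, 0.0)
    return (S + S.T) / 2.0


def normalized_laplacian(S: np.ndarray) -> np.ndarray:
    """Symmetrically normalized similarity L = D^{-1/2} S D^{-1/2}.

    Eigenvalues lie in [-1, 1]; the multiplicity of eigenvalue 1 equals
    the number of connected components.  Isolated vertices (zero degree)
    are an error — the caller decides whether to drop them.
    """
    S = np.asarray(S, dtype=float)
    deg = S.sum(axis=1)
    isolated = np.nonzero(deg <= 0)[0]
    if isolated.size:
        raise ValueError(f"isolated vertices (zero similarity degree): {isolated.tolist()}")
    dinv = 1.0 / np.sqrt(deg)
    return S * np.outer(dinv, dinv)


@dataclass
class SpectralEmbedding:
    """Top eigenpairs of the normalized Laplacian with row-normalized rows."""

    eigenvalues: np.ndarray  # descending
    U: np.ndarray  # (N, C) eigenvectors
    Y: np.ndarray  # U with rows scaled to unit norm
    zero_rows: np.ndarray  # bool flags: rows of U that were (numerically) zero


def _top_eigenpairs(L: np.ndarray, c: int) -> tuple[np.ndarray, np.ndarray]:
    n = L.shape[0]
    if n <= _DENSE_EIG_LIMIT:
        vals, vecs = scipy.linalg.eigh(L)
        return vals[::-1][:c], vecs[:, ::-1][:, :c]
    vals, vecs = scipy.sparse.linalg.eigsh(L, k=c, which="LA")
    idx = np.argsort(vals)[::-1]
    return vals[idx], vecs[:, idx]


def spectral_embed(L: np.ndarray, c: int) -> SpectralEmbedding:
    """Top-``c`` eigenvectors of L (descending eigenvalue), rows normalized to unit norm."""
    if c < 1:
        raise ValueError("c must be >= 1")
    vals, U = _top_eigenpairs(np.asarray(L, dtype=float), c)
    norms = np.linalg.norm(U, axis=1)
    zero = norms < 1e-12
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero row(s) in spectral embedding", UserWarning)
    Y = U / np.where(zero, 1.0, norms)[:, None]
    Y[zero] = 0.0
    return SpectralEmbedding(vals, U, Y, zero)


# ---------------------------------------------------------------------------
# cluster-number estimation by eigenvector rotation


def _givens_rotation(c: int, i: int, j: int, theta: float, derivative: bool = False) -> np.ndarray:
    G = np.zeros((c, c)) if derivative else np.eye(c)
    cs, sn = np.cos(theta), np.sin(theta)
    if derivative:
        G[i, i], G[j, j] = -sn, -sn
        G[i, j], G[j, i] = cs, -cs
    else:
        G[i, i], G[j, j] = cs, cs
        G[i, j], G[j, i] = sn, -sn
    return G


def _rotation_cost_grad(U: np.ndarray, theta: np.ndarray, pairs: list[tuple[int, int]]):
    """Alignment cost J = sum_nc Z_nc^2 / m_n^2 (m_n = max_c |Z_nc|) and its gradient."""
    c = U.shape[1]
    Gs = [_givens_rotation(c, i, j, t) for (i, j), t in zip(pairs, theta)]
    # prefix[k] = G_0 ... G_{k-1}, suffix[k] = G_k ... G_{K-1}
    K = len(pairs)
    prefix = [np.eye(c)]
    for G in Gs:
        prefix.append(prefix[-1] @ G)
    suffix = [np.eye(c)]
    for G in reversed(Gs):
        suffix.append(G @ suffix[-1])
    suffix = suffix[::-1]
    Z = U @ prefix[-1]
    mi = np.argmax(np.abs(Z), axis=1)
    m = np.abs(Z[np.arange(Z.shape[0]), mi])
    # rows that are (numerically) zero — e.g. eigenvectors of a disconnected
    # graph taken at C below the component count — mean the embedding cannot
    # see those samples at this C: each is charged cost 2 (an aligned row
    # costs 1) so such C never wins, and contributes no gradient.
    zero_rows = m < 1e-10 * max(m.max(), 1.0)
    if zero_rows.any():
        Z = Z[~zero_rows]
        mi = mi[~zero_rows]
        m = m[~zero_rows]
    n_zero = int(zero_rows.sum())
    m = np.maximum(m, 1e-12)
    cost = float(np.sum(Z**2 / m[:, None] ** 2)) + 2.0 * n_zero
    grad = np.empty(K)
    rows = np.arange(Z.shape[0])
    for kk in range(K):
        i, j = pairs[kk]
        A = _givens_rotation(c, i, j, theta[kk], derivative=True)
        V = U @ (prefix[kk] @ A @ suffix[kk + 1])
        if n_zero:
            V = V[~zero_rows]
        dm = np.sign(Z[rows, mi]) * V[rows, mi]
        grad[kk] = float(
            np.sum(2.0 * Z * V / m[:, None] ** 2)
            - np.sum(2.0 * (Z**2).sum(axis=1) / m**3 * dm)
        )
    return cost, grad


def _align_cost(U: np.ndarray, n_iter: int = 200, lr: float = 0.05) -> float:
    """Minimize the rotation cost over Givens angles by gradient descent."""
    c = U.shape[1]
    if c < 2:
        return float(U.shape[0])
    pairs = [(i, j) for i in range(c) for j in range(i + 1, c)]
    theta = np.zeros(len(pairs))
    best = np.inf
    for attempt, rate in enumerate((lr, lr / 5.0)):
        theta = np.zeros(len(pairs))
        cost = np.inf
        for _ in range(n_iter):
            cost, grad = _rotation_cost_grad(U, theta, pairs)
            best = min(best, cost)
            theta = theta - rate * grad
        cost, _ = _rotation_cost_grad(U, theta, pairs)
        best = min(best, cost)
        init_cost, _ = _rotation_cost_grad(U, np.zeros(len(pairs)), pairs)
        if best <= init_cost + 1e-9:
            break
        if attempt == 1:
            warnings.warn("rotation descent did not improve; using best found", UserWarning)
    return best


def estimate_cluster_number(
    L: np.ndarray, c_min: int = 2, c_max: int = 10
) -> tuple[int, dict[int, float]]:
    """Estimate the number of clusters from eigenvector alignability.

    For each candidate C, the top-C eigenvectors are rotated (by gradient
    descent over Givens angles) to be as axis-aligned as possible; the
    alignment quality ``1 - (J/N - 1)/C`` is 1 for a perfectly block-
    structured similarity.  Returns the argmax (ties to the larger C) and
    the per-candidate quality scores.
    """
    L = np.asarray(L, dtype=float)
    n = L.shape[0]
    if c_max < c_min:
        raise ValueError("c_max must be >= c_min")
    if c_max > n // 2:
        raise ValueError("c_max must be <= n_samples / 2")
    _, U_max = _top_eigenpairs(L, c_max)
    quality: dict[int, float] = {}
    for c in range(c_min, c_max + 1):
        cost = _align_cost(U_max[:, :c])
        quality[c] = 1.0 - (cost / n - 1.0) / c
    best = max(quality, key=lambda c: (quality[c], c))
    return best, quality


# ---------------------------------------------------------------------------
# K-means, consensus, silhouette


def kmeans_cluster(Y: np.ndarray, c: int, seed=None, restarts: int = 10) -> np.ndarray:
    """Best-of-``restarts`` seeded k-means++ on the embedding rows."""
    km = KMeans(n_clusters=c, n_init=restarts, random_state=seed)
    return km.fit_predict(Y)


def _spectral_labels(
    X: np.ndarray, c: int, knn_k: int, seed=None, restarts: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Full spectral pipeline at fixed C; isolated vertices are dropped.

    Returns (labels, kept_mask); labels are -1 for dropped samples.
    """
    X = np.asarray(X, dtype=float)
    keep = np.ones(X.shape[0], dtype=bool)
    while True:
        graph = mutual_knn(X[keep], k=min(knn_k, keep.sum() - 1))
        S = local_scaled_similarity(graph, X[keep])
        deg = S.sum(axis=1)
        if np.all(deg > 0):
            break
        idx = np.nonzero(keep)[0][deg <= 0]
        keep[idx] = False
        if keep.sum() <= c:
            raise ValueError("too many isolated samples to cluster")
    L = normalized_laplacian(S)
    emb = spectral_embed(L, c)
    labels = np.full(X.shape[0], -1, dtype=int)
    labels[keep] = kmeans_cluster(emb.Y, c, seed=seed, restarts=restarts)
    return labels, keep


def consensus_cluster(
    X: np.ndarray,
    c: int,
    runs: int = 1000,
    frac: float = 0.8,
    seed=None,
    knn_k: int = 30,
    kmeans_restarts: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Subsampled consensus matrix plus authoritative full-data labels.

    Each run draws ``floor(frac * N)`` samples without replacement, runs
    the full spectral pipeline at fixed C, and records co-membership.
    consensus_ij = (#runs i,j co-sampled and co-clustered) /
    (#runs i,j co-sampled); pairs never co-sampled are NaN.  The final
    labels come from one full-data clustering — the consensus matrix is a
    stability diagnostic, not the label source.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    m = int(np.floor(frac * n))
    if m < c:
        raise ValueError("subsample size below the number of clusters")
    rng = np.random.default_rng(seed)
    both = np.zeros((n, n))
    co = np.zeros((n, n))
    for _ in range(runs):
        idx = rng.choice(n, size=m, replace=False)
        run_seed = int(rng.integers(0, 2**31 - 1))
        labels, kept = _spectral_labels(
            X[idx], c, knn_k=knn_k, seed=run_seed, restarts=kmeans_restarts
        )
        used = idx[kept]
        lab = labels[kept]
        both[np.ix_(used, used)] += 1.0
        same = lab[:, None] == lab[None, :]
        co[np.ix_(used, used)] += same
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(both > 0, co / np.maximum(both, 1), np.nan)
    final_seed = int(rng.integers(0, 2**31 - 1)) if seed is not None else None
    final_labels, _ = _spectral_labels(
        X, c, knn_k=knn_k, seed=final_seed, restarts=kmeans_restarts
    )
    return consensus, final_labels


def silhouette_similarity(
    S: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, dict[int, float], dict[int, bool]]:
    """Similarity-based silhouette widths and per-cluster stability flags.

    width_i = mean similarity of i to its own cluster (excluding itself)
    minus the highest mean similarity of i to any other cluster.  A
    cluster is stable iff its mean width is positive.  A singleton
    cluster's sample has width 0.
    """
    S = np.asarray(S, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    n = S.shape[0]
    widths = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        own_others = own.copy()
        own_others[i] = False
        if not own_others.any():
            widths[i] = 0.0  # singleton cluster
            continue
        a = S[i, own_others].mean()
        b = max(S[i, labels == c].mean() for c in uniq if c != labels[i])
        widths[i] = a - b
    means = {int(c): float(widths[labels == c].mean()) for c in uniq}
    stable = {c: m > 0 for c, m in means.items()}
    return widths, means, stable


def _cut_consensus(consensus: np.ndarray, c: int) -> np.ndarray:
    """Average-linkage cut of the consensus dissimilarity at c clusters.

    Pairs never co-sampled (NaN) are treated as maximally dissimilar.
    """
    import scipy.cluster.hierarchy
    import scipy.spatial.distance

    d = 1.0 - np.where(np.isnan(consensus), 0.0, consensus)
    np.fill_diagonal(d, 0.0)
    link = scipy.cluster.hierarchy.linkage(
        scipy.spatial.distance.squareform(d, checks=False), method="average"
    )
    return scipy.cluster.hierarchy.fcluster(link, c, criterion="maxclust") - 1


# ---------------------------------------------------------------------------
# estimator


class SpectralConsensusClustering(ClusterMixin, BaseEstimator):
    """Self-tuning spectral clustering with consensus-resampling diagnostics.

    Builds a mutual-KNN graph with locally scaled similarities, estimates
    the number of clusters from eigenvector alignability (unless fixed),
    labels samples by K-means on the row-normalized spectral embedding,
    and quantifies stability via a subsampled consensus matrix and
    similarity-based silhouette widths.

    Parameters
    ----------
    n_clusters : int or None
        Fixed number of clusters, or None to estimate in [c_min, c_max].
    knn_k : int, default=30
        Neighborhood size for the mutual-KNN graph and local scales.
    c_min, c_max : search range for the cluster-number estimate.
    consensus_runs : int, default=1000
        Number of subsampled runs (0 disables the consensus matrix).
    subsample : float, default=0.8
        Fraction of samples drawn (without replacement) per run.
    labels_from : {"spectral", "consensus"}, default "spectral"
        "spectral" takes the full-data spectral clustering as the final
        labels (the consensus matrix stays a diagnostic); "consensus"
        instead cuts an average-linkage dendrogram of the consensus
        dissimilarity 1 - consensus at C clusters.
    kmeans_restarts : int, default=10
    random_state : int, optional

    Attributes
    ----------
    labels_ : ndarray — final full-data cluster labels (0-based).
    n_clusters_ : int — the number of clusters used.
    quality_scores_ : dict — alignment quality per candidate C (if estimated).
    consensus_ : ndarray or None — co-clustering frequencies (NaN = never co-sampled).
    silhouette_ : ndarray — per-sample similarity silhouette widths.
    cluster_stable_ : dict — per-cluster stability flag (mean width > 0).
    """

    def __init__(
        self,
        n_clusters=None,
        knn_k: int = 30,
        c_min: int = 2,
        c_max: int = 10,
        consensus_runs: int = 1000,
        subsample: float = 0.8,
        labels_from: str = "spectral",
        kmeans_restarts: int = 10,
        random_state=None,
    ):
        self.n_clusters = n_clusters
        self.knn_k = knn_k
        self.c_min = c_min
        self.c_max = c_max
        self.consensus_runs = consensus_runs
        self.subsample = subsample
        self.labels_from = labels_from
        self.kmeans_restarts = kmeans_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        X = validate_data(self, X)
        n = X.shape[0]
        # samples isolated in the mutual-KNN graph carry no spectral
        # information; they are dropped (labels_ = -1) with a warning
        keep = np.ones(n, dtype=bool)
        while True:
            graph = mutual_knn(X[keep], k=min(self.knn_k, int(keep.sum()) - 1))
            S = local_scaled_similarity(graph, X[keep])
            deg = S.sum(axis=1)
            if np.all(deg > 0):
                break
            idx = np.nonzero(keep)[0][deg <= 0]
            keep[idx] = False
        if not keep.all():
            warnings.warn(
                f"{int((~keep).sum())} isolated sample(s) excluded from clustering",
                UserWarning,
            )
        self.kept_mask_ = keep
        self.similarity_ = S
        L = normalized_laplacian(S)
        if self.n_clusters is None:
            c, self.quality_scores_ = estimate_cluster_number(L, self.c_min, self.c_max)
        else:
            c = int(self.n_clusters)
        self.n_clusters_ = c
        self.embedding_ = spectral_embed(L, c)
        rng = np.random.default_rng(self.random_state)
        km_seed = int(rng.integers(0, 2**31 - 1))
        if self.consensus_runs > 0:
            self.consensus_, self.labels_ = consensus_cluster(
                X,
                c,
                runs=self.consensus_runs,
                frac=self.subsample,
                seed=int(rng.integers(0, 2**31 - 1)),
                knn_k=self.knn_k,
                kmeans_restarts=self.kmeans_restarts,
            )
            if self.labels_from == "consensus":
                self.labels_ = _cut_consensus(self.consensus_, c)
            elif self.labels_from != "spectral":
                raise ValueError("labels_from must be 'spectral' or 'consensus'")
        else:
            self.consensus_ = None
            self.labels_ = np.full(n, -1, dtype=int)
            self.labels_[keep] = kmeans_cluster(
                self.embedding_.Y, c, seed=km_seed, restarts=self.kmeans_restarts
            )
        self.silhouette_ = np.full(n, np.nan)
        kept_labels = self.labels_[keep]
        self.silhouette_[keep], self.cluster_silhouette_, self.cluster_stable_ = (
            silhouette_similarity(S, kept_labels)
        )
        return self
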