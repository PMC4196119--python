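"""Progression-tree construction and covariate mapping.

The clustering (genetically homogeneous groups) and the principal curve
(global trend) are combined into a cluster-level progression tree: the
curve acts as a backbone, each curve node is claimed by the cluster whose
samples project nearest to it, runs of identically-claimed nodes are
contracted, and surviving adjacencies become tree edges whose lengths are
centroid distances.  Root-to-leaf paths order samples by their arc-length
projection coordinate (pseudotime); clinical covariates are mapped onto
paths by Spearman rank correlation, individual gene trajectories by
cross-validated polynomial fits, and per-cluster survival by the
Kaplan-Meier product-limit estimator.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats
from lifelines import KaplanMeierFitter
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold

from .curve import PrincipalCurveModel, project_samples

logger = logging.getLogger(__name__)


@dataclass
class ProgressionTree:
    """Cluster-level tree on the principal-curve backbone.

    ``graph`` nodes are cluster labels with attributes ``size`` and
    ``centroid``; edge attribute ``length`` is the Euclidean distance
    between cluster centroids.  ``sample_cluster`` is -1 for samples whose
    cluster was dropped as too small.
    """

    graph: nx.Graph
    root: int
    sample_cluster: np.ndarray
    sample_arc: np.ndarray
    node_cluster: np.ndarray  # curve node -> cluster label
    dropped_clusters: list[int] = field(default_factory=list)

    def leaves(self) -> list[int]:
        return [v for v in self.graph if self.graph.degree(v) == 1 and v != self.root]

    def to_json(self, path=None) -> str:
        obj = {
            "root": int(self.root),
            "nodes": [
                {
                    "id": int(v),
                    "size": int(self.graph.nodes[v]["size"]),
                    "centroid": np.asarray(self.graph.nodes[v]["centroid"]).tolist(),
                }
                for v in self.graph
            ],
            "edges": [
                {"source": int(u), "target": int(v), "length": float(d["length"])}
                for u, v, d in self.graph.edges(data=True)
            ],
        }
        text = json.dumps(obj)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_graphml(self, path) -> None:
        g = nx.Graph()
        for v, d in self.graph.nodes(data=True):
            g.add_node(
                int(v),
                size=int(d["size"]),
                centroid=",".join(f"{c:g}" for c in np.asarray(d["centroid"])),
            )
        for u, v, d in self.graph.edges(data=True):
            g.add_edge(int(u), int(v), length=float(d["length"]))
        nx.write_graphml(g, path)


def build_tree(
    labels: np.ndarray,
    model: PrincipalCurveModel,
    X: np.ndarray,
    min_cluster_size: int = 5,
    root_samples=None,
) -> ProgressionTree:
    """Merge cluster labels and the fitted curve into a progression tree.

    Clusters smaller than ``min_cluster_size`` are dropped.  Every curve
    node is claimed by the cluster holding the plurality of samples whose
    projection lands nearest that node (empty nodes inherit from the
    nearest claimed node along the curve).  Runs of equally-claimed nodes
    are contracted; if a cluster claims disconnected curve regions, only
    its largest region (by sample count) keeps the placement.  Edge length
    is the Euclidean distance between cluster centroids; the root is the
    cluster holding the plurality of the baseline samples (else the
    cluster claiming the curve's root node).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels).copy()
    uniq, counts = np.unique(labels[labels >= 0], return_counts=True)
    dropped = [int(c) for c, n in zip(uniq, counts) if n < min_cluster_size]
    if dropped:
        logger.info("dropping clusters below min size %d: %s", min_cluster_size, dropped)
        labels[np.isin(labels, dropped)] = -1
    retained = np.unique(labels[labels >= 0])
    if retained.size < 1:
        raise ValueError("no cluster survives the minimum-size filter")

    proj = project_samples(X, model)
    # nearest curve node to each sample's projected point
    node_of_sample = np.array(
        [
            int(np.argmin(((model.mu - pt) ** 2).sum(axis=1)))
            for pt in proj["point"]
        ]
    )
    M = model.topology.n_nodes
    g_nodes = model.topology.graph()
    node_cluster = np.full(M, -1, dtype=int)
    for m in range(M):
        here = labels[(node_of_sample == m) & (labels >= 0)]
        if here.size:
            vals, cnts = np.unique(here, return_counts=True)
            node_cluster[m] = int(vals[np.argmax(cnts)])
    # propagate to unclaimed nodes from nearest claimed node along the curve
    claimed = np.nonzero(node_cluster >= 0)[0]
    if claimed.size == 0:
        raise ValueError("no curve node received any sample projection")
    if claimed.size < M:
        frontier = list(claimed)
        seen = set(frontier)
        while frontier:  # multi-source BFS from the claimed nodes
            nxt = []
            for u in frontier:
                for v in g_nodes.neighbors(u):
                    if v not in seen:
                        seen.add(v)
                        node_cluster[v] = node_cluster[u]
                        nxt.append(v)
            frontier = nxt

    # enforce one connected curve region per cluster
    for c in np.unique(node_cluster):
        sub = g_nodes.subgraph(np.nonzero(node_cluster == c)[0])
        regions = list(nx.connected_components(sub))
        if len(regions) <= 1:
            continue
        warnings.warn(
            f"cluster {c} claims {len(regions)} disconnected curve regions; "
            "keeping the largest by sample count",
            UserWarning,
        )
        weights = [
            sum(int(((node_of_sample == m) & (labels == c)).sum()) for m in reg)
            for reg in regions
        ]
        keep = regions[int(np.argmax(weights))]
        for reg in regions:
            if reg is keep:
                continue
            for m in reg:
                node_cluster[m] = -2  # to be refilled from neighbors
        # refill from adjacent claimed nodes
        while np.any(node_cluster == -2):
            for m in np.nonzero(node_cluster == -2)[0]:
                nb = [v for v in g_nodes.neighbors(m) if node_cluster[v] >= 0]
                if nb:
                    node_cluster[m] = node_cluster[nb[0]]

    # contract equal-cluster runs: cluster graph from inter-cluster node edges
    tree = nx.Graph()
    for c in np.unique(node_cluster):
        members = labels == c
        if not members.any():
            continue
        tree.add_node(int(c), size=int(members.sum()), centroid=X[members].mean(axis=0))
    for a, b in model.topology.edges:
        ca, cb = int(node_cluster[a]), int(node_cluster[b])
        if ca != cb and ca in tree and cb in tree:
            la = np.linalg.norm(
                np.asarray(tree.nodes[ca]["centroid"]) - np.asarray(tree.nodes[cb]["centroid"])
            )
            tree.add_edge(ca, cb, length=float(la))

    if root_samples is not None:
        base = labels[np.asarray(root_samples, dtype=int)]
        base = base[base >= 0]
        vals, cnts = np.unique(base, return_counts=True)
        root = int(vals[np.argmax(cnts)])
    else:
        root = int(node_cluster[model.root])
        if root not in tree:
            root = int(next(iter(tree.nodes)))
    return ProgressionTree(tree, root, labels, proj["arc_length"], node_cluster, dropped)


@dataclass
class PathCoordinate:
    """Samples on one root-to-leaf path, ordered by arc length from the root."""

    leaf: int
    clusters: list[int]
    sample_index: np.ndarray
    arc_length: np.ndarray


def extract_path(tree: ProgressionTree, leaf: int) -> PathCoordinate:
    """All samples whose cluster lies on the root -> ``leaf`` path, ordered
    by their arc-length projection coordinate."""
    if leaf not in tree.graph:
        raise ValueError(f"unknown leaf {leaf}")
    clusters = nx.shortest_path(tree.graph, tree.root, leaf)
    mask = np.isin(tree.sample_cluster, clusters)
    idx = np.nonzero(mask)[0]
    order = np.argsort(tree.sample_arc[idx], kind="stable")
    idx = idx[order]
    return PathCoordinate(int(leaf), [int(c) for c in clusters], idx, tree.sample_arc[idx])


# ---------------------------------------------------------------------------
# covariate mapping


def spearman_path(
    coords: np.ndarray, covariate: np.ndarray, exact_max_n: int = 10
) -> tuple[float, float, int]:
    """Spearman rank correlation of a covariate with path position.

    Uses average ranks for ties.  The two-sided P comes from the
    t approximation t = r sqrt((n-2)/(1-r^2)) for n > ``exact_max_n`` and
    from the exact permutation distribution otherwise.  Missing covariate
    values are pairwise-dropped; zero variance makes r undefined (NaN).

    Returns (r, P, n_used).
    """
    coords = np.asarray(coords, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    ok = np.isfinite(coords) & np.isfinite(covariate)
    x, y = coords[ok], covariate[ok]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired non-missing values")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return float("nan"), float("nan"), n
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    if n > exact_max_n:
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r**2))
            p = float(2.0 * scipy.stats.t.sf(abs(t), df=n - 2))
    else:
        # exact permutation test on the rank cross-product
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        obs = abs(rx_c @ ry_c)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            stat = abs(rx_c[list(perm)] @ ry_c)
            if stat >= obs - 1e-9:
                count += 1
            total += 1
        p = count / total
    return r, p, n


def map_covariates(
    tree: ProgressionTree, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Spearman (r, P, n) of every covariate along every root-to-leaf path."""
    rows = []
    for leaf in tree.leaves():
        path = extract_path(tree, leaf)
        for name in covariates.columns:
            vals = covariates[name].to_numpy(float)[path.sample_index]
            r, p, n = spearman_path(path.arc_length, vals)
            rows.append({"path": leaf, "covariate": name, "r": r, "P": p, "n": n})
    return pd.DataFrame(rows)


@dataclass
class TrajectoryFit:
    """Cross-validated polynomial trend of one gene along one path."""

    degree: int
    coefficients: np.ndarray  # highest power first (numpy.polyfit order)
    cv_mse: dict[int, float]
    normalized: np.ndarray  # expression min-max scaled to [0, 1]

    def predict(self, coords: np.ndarray) -> np.ndarray:
        return np.polyval(self.coefficients, np.asarray(coords, float))


def fit_gene_trajectory(
    values: np.ndarray,
    coords: np.ndarray,
    degree_grid=range(1, 9),
    folds: int = 10,
    seed=None,
) -> TrajectoryFit:
    """Polynomial trend of a gene along a path, degree chosen by k-fold CV.

    Expression is min-max normalized to [0, 1] over the path samples
    (a constant gene maps to all zeros and gets a flat degree-1 fit); the
    degree minimizing CV mean squared error wins, ties to the lower
    degree, and the winning degree is refitted on all samples.
    """
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if np.unique(coords).size < 2:
        raise ValueError("degenerate design: all path coordinates equal")
    if values.size < folds:
        raise ValueError(f"need at least {folds} samples on the path")
    span = values.max() - values.min()
    norm = (values - values.min()) / span if span > 0 else np.zeros_like(values)
    if span == 0:
        return TrajectoryFit(1, np.polyfit(coords, norm, 1), {}, norm)
    degree_grid = sorted(int(d) for d in degree_grid)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    cv_mse: dict[int, float] = {}
    for d in degree_grid:
        errs = []
        for tr, va in kf.split(coords):
            if np.unique(coords[tr]).size <= d:
                errs.append(np.inf)
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", np.exceptions.RankWarning)
                c = np.polyfit(coords[tr], norm[tr], d)
            errs.append(float(np.mean((np.polyval(c, coords[va]) - norm[va]) ** 2)))
        cv_mse[d] = float(np.mean(errs))
    best = min(degree_grid, key=lambda d: (cv_mse[d], d))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", np.exceptions.RankWarning)
        coef = np.polyfit(coords, norm, best)
    return TrajectoryFit(best, coef, cv_mse, norm)


# ---------------------------------------------------------------------------
# survival and visualization


@dataclass
class KMEstimate:
    """Kaplan-Meier product-limit survival estimate (steps at event times)."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t) (right-continuous)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(times: np.ndarray, events: np.ndarray) -> KMEstimate:
    """Kaplan-Meier estimator: S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if np.any(times < 0):
        raise ValueError("survival times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    has_event = table["observed"] > 0
    ev_times = table.index[has_event].to_numpy(float)
    at_risk = table.loc[has_event, "at_risk"].to_numpy(float)
    sf = kmf.survival_function_
    surv = np.array([float(sf.loc[t].iloc[0]) for t in ev_times])
    return KMEstimate(ev_times, surv, at_risk)


def km_by_group(times, events, groups) -> dict:
    """One Kaplan-Meier estimate per group label (e.g. per cluster)."""
    groups = np.asarray(groups)
    return {
        g: km_curve(np.asarray(times)[groups == g], np.asarray(events)[groups == g])
        for g in np.unique(groups)
    }


def pca_view(X: np.ndarray, d: int = 3) -> tuple[np.ndarray, float]:
    """Mean-centered PCA projection onto ``d`` components and the fraction
    of total variance they explain."""
    X = np.asarray(X, dtype=float)
    d = int(d)
    if d > min(X.shape):
        raise ValueError("d must be <= min(n_samples, n_features)")
    pca = PCA(n_components=d).fit(X)
    return pca.transform(X), float(pca.explained_variance_ratio_.sum())
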