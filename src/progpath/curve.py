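"""Principal-curve fitting by EM under isotropic fixed-variance Gaussian noise.

A (possibly branching) curve is discretized into M nodes joined by a tree
of segments.  Data are modeled as draws from a mixture: a point mu_s on
the curve is chosen with probability p(s) and observed with isotropic
Gaussian noise N(0, sigma^2 I).  The log-likelihood

    L = sum_n log sum_m p_m N(x_n | mu_m, sigma^2 I)

is maximized over node positions and mixing weights by EM with sigma held
fixed by the user: estimating sigma by maximum likelihood is ill-posed
(sigma -> 0 sends the likelihood to infinity as the curve interpolates
every point).  Instead sigma is swept over a grid; smaller sigma yields a
longer, more complex curve and a smaller fitting error, and the working
point is chosen at the elbow of the (curve length, fitting error) curve
via a two-line regression.  After each M-step the nodes of every branch
are re-placed at equal arc-length spacing, which realizes the
equally-spaced-segment discretization of the curve.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted, validate_data


@dataclass
class CurveTopology:
    """Tree of curve nodes: M nodes, undirected acyclic connected edges."""

    n_nodes: int
    edges: list[tuple[int, int]]

    def __post_init__(self) -> None:
        g = self.graph()
        if g.number_of_nodes() != self.n_nodes or not nx.is_tree(g):
            raise ValueError("topology must be a connected acyclic tree over all nodes")

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g

    def chains(self) -> list[list[int]]:
        """Maximal paths whose interior nodes have degree 2 (the branches)."""
        g = self.graph()
        anchors = [v for v in g if g.degree(v) != 2]
        if not anchors:  # cycle-free, so this means a pure path of degree-2? only M<=2
            anchors = [0]
        seen_edges = set()
        chains = []
        for a in anchors:
            for nb in g.neighbors(a):
                if (a, nb) in seen_edges:
                    continue
                chain = [a, nb]
                seen_edges.add((a, nb))
                seen_edges.add((nb, a))
                while g.degree(chain[-1]) == 2:
                    nxt = [v for v in g.neighbors(chain[-1]) if v != chain[-2]][0]
                    seen_edges.add((chain[-1], nxt))
                    seen_edges.add((nxt, chain[-1]))
                    chain.append(nxt)
                chains.append(chain)
        return chains


@dataclass
class PrincipalCurveModel:
    """Fitted discretized principal curve (tree of nodes with mixing weights)."""

    mu: np.ndarray  # (M, J) node positions
    p: np.ndarray  # (M,) mixing weights, sum to 1
    sigma: float
    topology: CurveTopology
    root: int = 0
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False

    def to_json(self, path=None) -> str:
        obj = {
            "nodes": self.mu.tolist(),
            "edges": [list(e) for e in self.topology.edges],
            "p": self.p.tolist(),
            "sigma": self.sigma,
            "root": self.root,
            "loglik_trace": self.loglik_trace,
        }
        text = json.dumps(obj)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "PrincipalCurveModel":
        obj = json.loads(text)
        mu = np.asarray(obj["nodes"], dtype=float)
        topo = CurveTopology(mu.shape[0], [tuple(e) for e in obj["edges"]])
        return cls(
            mu,
            np.asarray(obj["p"], dtype=float),
            float(obj["sigma"]),
            topo,
            int(obj["root"]),
            list(obj["loglik_trace"]),
        )


# ---------------------------------------------------------------------------
# initialization


def init_topology(
    X: np.ndarray,
    backbone: str = "pc1",
    centroids: np.ndarray | None = None,
    n_nodes: int = 100,
) -> tuple[CurveTopology, np.ndarray]:
    """Initial curve topology and node positions.

    ``backbone="pc1"`` places nodes evenly along the first principal
    component segment spanning the data (a path topology).
    ``backbone="centroids"`` builds the Euclidean minimum spanning tree
    over supplied centroids and subdivides each MST edge into equal
    segments, allocating roughly ``n_nodes`` nodes proportionally to edge
    length — branch points in the centroid set become degree-3+ nodes.
    """
    X = np.asarray(X, dtype=float)
    if backbone == "pc1":
        if n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        mean = X.mean(axis=0)
        pc1 = PCA(n_components=1).fit(X).components_[0]
        proj = (X - mean) @ pc1
        ts = np.linspace(proj.min(), proj.max(), n_nodes)
        nodes = mean + ts[:, None] * pc1
        edges = [(i, i + 1) for i in range(n_nodes - 1)]
        return CurveTopology(n_nodes, edges), nodes
    if backbone != "centroids":
        raise ValueError("backbone must be 'pc1' or 'centroids'")
    if centroids is None or np.asarray(centroids).shape[0] < 2:
        raise ValueError("need at least 2 centroids for the MST backbone")
    C = np.asarray(centroids, dtype=float)
    ncen = C.shape[0]
    D = np.linalg.norm(C[:, None] - C[None, :], axis=2)
    g = nx.Graph()
    for i in range(ncen):
        for j in range(i + 1, ncen):
            g.add_edge(i, j, weight=D[i, j])
    mst = nx.minimum_spanning_tree(g)
    mst_edges = list(mst.edges())
    lengths = np.array([D[a, b] for a, b in mst_edges])
    budget = max(n_nodes - ncen, 0)  # interior nodes to distribute
    interior = np.floor(budget * lengths / lengths.sum()).astype(int) if lengths.sum() > 0 else np.zeros(len(mst_edges), dtype=int)
    nodes = [C[i] for i in range(ncen)]
    edges: list[tuple[int, int]] = []
    for (a, b), n_int in zip(mst_edges, interior):
        prev = a
        for s in range(1, n_int + 1):
            t = s / (n_int + 1)
            nodes.append(C[a] + t * (C[b] - C[a]))
            cur = len(nodes) - 1
            edges.append((prev, cur))
            prev = cur
        edges.append((prev, b))
    return CurveTopology(len(nodes), edges), np.asarray(nodes)


# ---------------------------------------------------------------------------
# EM


def _log_resp(X: np.ndarray, mu: np.ndarray, p: np.ndarray, sigma: float):
    """Log responsibilities and per-sample log-likelihood contributions."""
    J = X.shape[1]
    d2 = ((X[:, None, :] - mu[None, :, :]) ** 2).sum(axis=2)
    with np.errstate(divide="ignore"):
        logw = np.log(np.maximum(p, 1e-300))[None, :] - d2 / (2.0 * sigma**2)
    logw = logw - J / 2.0 * np.log(2.0 * np.pi * sigma**2)
    norm = logsumexp(logw, axis=1)
    return logw - norm[:, None], norm


def log_likelihood(X: np.ndarray, model: PrincipalCurveModel) -> float:
    """Mixture log-likelihood with the full Gaussian normalizing constant."""
    _, norm = _log_resp(np.asarray(X, float), model.mu, model.p, model.sigma)
    return float(norm.sum())


def _reparameterize(mu: np.ndarray, topology: CurveTopology) -> np.ndarray:
    """Re-place interior chain nodes at equal arc-length spacing.

    Branch points and leaves stay put; along every maximal degree-2 chain
    the interior nodes are slid along the current polyline so consecutive
    nodes are equally spaced in arc length.
    """
    out = mu.copy()
    for chain in topology.chains():
        pts = mu[chain]
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        total = seg.sum()
        if total <= 0 or len(chain) < 3:
            continue
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        targets = np.linspace(0.0, total, len(chain))
        for idx, t in zip(chain[1:-1], targets[1:-1]):
            k = np.searchsorted(cum, t, side="right") - 1
            k = min(k, len(seg) - 1)
            frac = (t - cum[k]) / seg[k] if seg[k] > 0 else 0.0
            out[idx] = pts[k] + frac * (pts[k + 1] - pts[k])
    return out


def em_fit(
    X: np.ndarray,
    topology: CurveTopology,
    node_init: np.ndarray,
    sigma: float,
    p_init: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    reparameterize: bool = True,
    root: int = 0,
) -> PrincipalCurveModel:
    """EM for node positions and mixing weights at fixed noise scale sigma.

    E-step: responsibilities r_nm ∝ p_m exp(-||x_n - mu_m||^2 / 2 sigma^2)
    (log-sum-exp normalized).  M-step: mu_m = responsibility-weighted data
    mean, p_m = mean responsibility; then (optionally) equal-arc-length
    reparameterization of each branch.  With reparameterization disabled
    this is exactly isotropic fixed-variance Gaussian-mixture EM, and the
    log-likelihood is non-decreasing.  Convergence: relative log-likelihood
    gain below ``tol``.
    """
    X = np.asarray(X, dtype=float)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    M = topology.n_nodes
    mu = np.asarray(node_init, dtype=float).copy()
    if mu.shape[0] != M:
        raise ValueError("node_init must have one row per topology node")
    p = np.full(M, 1.0 / M) if p_init is None else np.asarray(p_init, float).copy()
    trace: list[float] = []
    converged = False
    frozen_warned = False
    it = 0
    for it in range(1, max_iter + 1):
        logr, norm = _log_resp(X, mu, p, sigma)
        trace.append(float(norm.sum()))
        r = np.exp(logr)
        tot = r.sum(axis=0)
        dead = tot < 1e-12
        if dead.any() and not frozen_warned:
            warnings.warn(
                f"{int(dead.sum())} node(s) with vanishing responsibility frozen in place",
                UserWarning,
            )
            frozen_warned = True
        safe_tot = np.where(dead, 1.0, tot)
        mu_new = (r.T @ X) / safe_tot[:, None]
        mu_new[dead] = mu[dead]
        mu = mu_new
        p = tot / tot.sum()
        if reparameterize:
            mu = _reparameterize(mu, topology)
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol * (abs(trace[-2]) + 1.0):
            converged = True
            break
    model = PrincipalCurveModel(mu, p, float(sigma), topology, root, trace, it, converged)
    model.loglik_trace.append(log_likelihood(X, model))
    return model


# ---------------------------------------------------------------------------
# geometry


def curve_length(model: PrincipalCurveModel) -> float:
    """Total polyline length: sum of node-to-node segment lengths."""
    return float(
        sum(np.linalg.norm(model.mu[a] - model.mu[b]) for a, b in model.topology.edges)
    )


def _segment_projections(X: np.ndarray, model: PrincipalCurveModel):
    """Per-sample nearest point over all segments (continuous projection).

    Returns (squared distances, edge index, within-segment parameter t in
    [0, 1] measured from the edge's first node).  Ties go to the lower
    edge index.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    best_d2 = np.full(n, np.inf)
    best_edge = np.zeros(n, dtype=int)
    best_t = np.zeros(n)
    if not model.topology.edges:  # degenerate single-node curve
        d2 = ((X - model.mu[0]) ** 2).sum(axis=1)
        return d2, best_edge, best_t
    for e, (a, b) in enumerate(model.topology.edges):
        pa, pb = model.mu[a], model.mu[b]
        d = pb - pa
        dd = float(d @ d)
        t = np.clip((X - pa) @ d / dd, 0.0, 1.0) if dd > 0 else np.zeros(n)
        diff = X - (pa + t[:, None] * d)
        d2 = (diff**2).sum(axis=1)
        better = d2 < best_d2 - 1e-15
        best_d2[better] = d2[better]
        best_edge[better] = e
        best_t[better] = t[better]
    return best_d2, best_edge, best_t


def fitting_error(X: np.ndarray, model: PrincipalCurveModel) -> float:
    """Sum of squared distances from samples to their closest points on the curve."""
    d2, _, _ = _segment_projections(X, model)
    return float(d2.sum())


def _node_arc_lengths(model: PrincipalCurveModel) -> tuple[np.ndarray, dict]:
    """Arc length of every node from the root, plus each node's parent."""
    g = model.topology.graph()
    arc = np.zeros(model.topology.n_nodes)
    parent = {model.root: None}
    for u, v in nx.bfs_edges(g, model.root):
        arc[v] = arc[u] + np.linalg.norm(model.mu[v] - model.mu[u])
        parent[v] = u
    return arc, parent


def project_samples(X: np.ndarray, model: PrincipalCurveModel):
    """Orthogonal projection of each sample onto the curve.

    Returns a dict of arrays: ``point`` (closest point on the curve),
    ``edge`` (owning segment index), ``arc_length`` (distance from the
    root node along the tree), and ``distance`` (Euclidean residual).
    """
    X = np.asarray(X, dtype=float)
    d2, edge, t = _segment_projections(X, model)
    arc, parent = _node_arc_lengths(model)
    edges = model.topology.edges
    coords = np.empty(X.shape[0])
    points = np.empty_like(X)
    for i in range(X.shape[0]):
        a, b = edges[edge[i]]
        # orient the segment away from the root
        if parent.get(b) == a:
            lo, hi, tt = a, b, t[i]
        elif parent.get(a) == b:
            lo, hi, tt = b, a, 1.0 - t[i]
        else:  # disconnected edge should not occur in a tree
            lo, hi, tt = a, b, t[i]
        seg_len = np.linalg.norm(model.mu[hi] - model.mu[lo])
        coords[i] = arc[lo] + tt * seg_len
        pa, pb = model.mu[edges[edge[i]][0]], model.mu[edges[edge[i]][1]]
        points[i] = pa + t[i] * (pb - pa)
    return {
        "point": points,
        "edge": edge,
        "arc_length": coords,
        "distance": np.sqrt(d2),
    }


# ---------------------------------------------------------------------------
# sigma sweep and elbow selection


@dataclass
class ElbowSweep:
    """Per-sigma (curve length, fitting error) records plus the elbow choice."""

    sigmas: np.ndarray
    lengths: np.ndarray
    errors: np.ndarray
    selected_sigma: float | None = None
    breakpoint_length: float | None = None
    line_params: tuple | None = None


def default_sigma_grid(X: np.ndarray, n: int = 12) -> np.ndarray:
    """Log-spaced sigma grid spanning [0.02, 0.3] x RMS distance to the data mean.

    sigma is a per-coordinate noise scale, necessarily well below the
    overall data spread: above roughly 0.4 x RMS the optimal curve
    collapses onto the data mean and the fit is degenerate, so the grid
    stays below that regime.
    """
    X = np.asarray(X, dtype=float)
    rms = float(np.sqrt(((X - X.mean(axis=0)) ** 2).sum(axis=1).mean()))
    return np.geomspace(0.3 * rms, 0.02 * rms, n)


def sweep_sigma(
    X: np.ndarray,
    topology: CurveTopology,
    node_init: np.ndarray,
    sigma_grid: np.ndarray,
    root: int = 0,
    **em_kwargs,
) -> tuple[ElbowSweep, list[PrincipalCurveModel]]:
    """Fit the curve for each sigma (descending), warm-starting each fit
    from the previous one, and record (sigma, curve length, fitting error).

    At large sigma the optimal curve collapses onto the data mean; a
    collapsed fit is a useless warm start (EM cannot re-expand a
    degenerate curve into the right branches), so the next sigma then
    restarts from the original node initialization instead.
    """
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    if np.any(np.diff(sigma_grid) > 0):
        raise ValueError("sigma grid must be sorted descending")
    node_init = np.asarray(node_init, dtype=float)
    init_length = float(
        sum(np.linalg.norm(node_init[a] - node_init[b]) for a, b in topology.edges)
    )
    mu, p = node_init, None
    records, models = [], []
    for s in sigma_grid:
        try:
            model = em_fit(X, topology, mu, s, p_init=p, root=root, **em_kwargs)
        except Exception as exc:  # keep sweeping past a single bad fit
            warnings.warn(f"EM failed at sigma={s:g}: {exc}", UserWarning)
            continue
        records.append((s, curve_length(model), fitting_error(X, model)))
        models.append(model)
        if curve_length(model) > 0.05 * init_length:
            mu, p = model.mu, model.p
        else:  # collapsed curve: do not propagate it as a warm start
            mu, p = node_init, None
    if not records:
        raise ValueError("no sigma in the grid produced a fit")
    sig, lng, err = map(np.asarray, zip(*records))
    return ElbowSweep(sig, lng, err), models


def elbow_select(sweep: ElbowSweep) -> float:
    """Two-line elbow selection of sigma on the (length, error) curve.

    Records are sorted by curve length; every interior breakpoint splits
    them into two arms, each fitted by least squares.  The breakpoint
    minimizing the total SSE defines two lines whose intersection length
    L* picks sigma as the record with length nearest L*.  Collinear
    records have no elbow: the smallest-length record is returned with a
    warning.
    """
    order = np.argsort(sweep.lengths)
    x, y, sig = sweep.lengths[order], sweep.errors[order], sweep.sigmas[order]
    # collapse records with (numerically) identical curve length — large-sigma
    # fits all degenerate to the same near-zero-length curve and would
    # otherwise weight the two-line fit toward that single model
    span = max(x.max() - x.min(), 1e-12)
    keep = np.concatenate([[True], np.diff(x) > 1e-6 * span])
    x, y, sig = x[keep], y[keep], sig[keep]
    n = x.size
    if n < 4:
        raise ValueError("elbow selection needs at least 4 distinct sweep records")
    best = None
    for split in range(2, n - 1):  # each arm gets >= 2 points
        (m1, b1), res1 = _ols_line(x[:split], y[:split])
        (m2, b2), res2 = _ols_line(x[split:], y[split:])
        sse = res1 + res2
        if best is None or sse < best[0] - 1e-15:
            best = (sse, m1, b1, m2, b2)
    sse, m1, b1, m2, b2 = best
    total_var = float(((y - y.mean()) ** 2).sum())
    if abs(m1 - m2) < 1e-12 or sse > 0.999 * max(total_var, 1e-300):
        warnings.warn("no elbow detected (records nearly collinear)", UserWarning)
        idx = int(np.argmin(x))
        sweep.selected_sigma = float(sig[idx])
        sweep.breakpoint_length = float(x[idx])
        return sweep.selected_sigma
    l_star = (b2 - b1) / (m1 - m2)
    idx = int(np.argmin(np.abs(x - l_star)))
    sweep.selected_sigma = float(sig[idx])
    sweep.breakpoint_length = float(l_star)
    sweep.line_params = (m1, b1, m2, b2)
    return sweep.selected_sigma


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[tuple[float, float], float]:
    A = np.vstack([x, np.ones_like(x)]).T
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    res = float(((A @ coef - y) ** 2).sum())
    return (float(coef[0]), float(coef[1])), res


# ---------------------------------------------------------------------------
# estimator


class PrincipalCurve(TransformerMixin, BaseEstimator):
    """Discretized principal curve fitted by EM at fixed noise scale.

    The curve is a tree of ``n_nodes`` nodes initialized either along the
    first principal component ("pc1") or by subdividing the minimum
    spanning tree of supplied centroids ("centroids", which permits
    branches).  Node positions and mixing weights are fitted by EM; the
    noise scale sigma is either given or chosen by the two-line elbow on
    the (curve length, fitting error) sweep.

    Parameters
    ----------
    backbone : {"pc1", "centroids"}, default "pc1"
    centroids : array-like, optional — required for the MST backbone.
    n_nodes : int, default 100
    sigma : float or "auto", default "auto"
        Fixed noise scale, or elbow-selected from ``sigma_grid``.
    sigma_grid : array-like, optional — descending; default log-spaced
        12 values spanning [0.05, 2] x the RMS distance to the data mean.
    reparameterize : bool, default True
        Equal-arc-length node re-spacing after each M-step.
    root_samples : array-like of int, optional
        Sample indices of the baseline group; the root is the node nearest
        their mean.  Defaults to node 0.
    n_restarts : int, default 0
        Extra EM runs from jittered node initializations; the fit with
        the highest final log-likelihood wins.  0 keeps the single
        deterministic initialization.
    random_state : int, optional — seeds the restart jitter.
    tol, max_iter : EM convergence control.

    Attributes
    ----------
    model_ : PrincipalCurveModel — fitted nodes, weights, sigma, topology.
    sweep_ : ElbowSweep or None — sigma-sweep records when sigma="auto".
    sigma_ : float — the noise scale used.
    """

    def __init__(
        self,
        backbone: str = "pc1",
        centroids=None,
        n_nodes: int = 100,
        sigma="auto",
        sigma_grid=None,
        reparameterize: bool = True,
        root_samples=None,
        n_restarts: int = 0,
        random_state=None,
        tol: float = 1e-6,
        max_iter: int = 500,
    ):
        self.backbone = backbone
        self.centroids = centroids
        self.n_nodes = n_nodes
        self.sigma = sigma
        self.sigma_grid = sigma_grid
        self.reparameterize = reparameterize
        self.root_samples = root_samples
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = validate_data(self, X)
        topo, nodes = init_topology(
            X, backbone=self.backbone, centroids=self.centroids, n_nodes=self.n_nodes
        )
        root = 0
        if self.root_samples is not None:
            base = X[np.asarray(self.root_samples, dtype=int)].mean(axis=0)
            root = int(np.argmin(((nodes - base) ** 2).sum(axis=1)))
        em_kwargs = dict(
            tol=self.tol, max_iter=self.max_iter, reparameterize=self.reparameterize
        )
        if self.sigma == "auto":
            grid = (
                np.asarray(self.sigma_grid, dtype=float)
                if self.sigma_grid is not None
                else default_sigma_grid(X)
            )
            self.sweep_, models = sweep_sigma(X, topo, nodes, grid, root=root, **em_kwargs)
            sigma = elbow_select(self.sweep_)
            self.model_ = models[int(np.argmin(np.abs(self.sweep_.sigmas - sigma)))]
        else:
            self.sweep_ = None
            self.model_ = em_fit(X, topo, nodes, float(self.sigma), root=root, **em_kwargs)
        if self.n_restarts > 0:
            rng = np.random.default_rng(self.random_state)
            jitter_scale = 0.1 * float(np.std(X))
            for _ in range(int(self.n_restarts)):
                init = nodes + rng.normal(0.0, jitter_scale, size=nodes.shape)
                cand = em_fit(X, topo, init, self.model_.sigma, root=root, **em_kwargs)
                if cand.loglik_trace[-1] > self.model_.loglik_trace[-1]:
                    self.model_ = cand
        self.sigma_ = self.model_.sigma
        self.nodes_ = self.model_.mu
        self.mixing_ = self.model_.p
        self.loglik_trace_ = self.model_.loglik_trace
        return self

    def transform(self, X):
        """Arc-length coordinate (from the root) of each sample's projection."""
        check_is_fitted(self, "model_")
        X = validate_data(self, X, reset=False)
        return project_samples(X, self.model_)["arc_length"][:, None]

    def project(self, X):
        check_is_fitted(self, "model_")
        return project_samples(np.asarray(X, float), self.model_)
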