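"""Seeded generators for branching-manifold cohorts.

Real progression cohorts are controlled-access; these generators emit
data with the same statistical structure the pipeline assumes — a
low-dimensional branching manifold (trunk plus a bifurcation into two
arms) embedded in a high-dimensional feature space, many irrelevant
features, Gaussian measurement noise, cluster structure along the
manifold, survival times monotonically (and nonlinearly) tied to the
progression coordinate, and independent right censoring — so every stage
is testable without any download.  Everything is bit-reproducible from
(parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ClinicalTable, SampleMatrix


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated cohort."""

    latent: np.ndarray  # arc-length progression coordinate from the root
    branch: np.ndarray  # 0 = trunk, 1/2 = arms
    cluster: np.ndarray  # planted cluster label (equal arc-length bins)
    relevant: np.ndarray  # indices of informative features, ordered so that
    # matrix[:, relevant] reproduces the manifold coordinates
    backbone_nodes: np.ndarray  # true-manifold polyline vertices, in the
    # relevant subspace with columns ordered as in `relevant`
    backbone_edges: list
    noise_sd: float
    seed: int


def simulate_branching_data(
    n_samples: int = 600,
    j_rel: int = 20,
    j_irrel: int = 980,
    trunk_length: float = 1.0,
    arm_length: float = 1.0,
    noise_sd: float = 0.1,
    ramp_width: float = 0.25,
    amplitude: float = 1.0,
    clusters_trunk: int = 2,
    clusters_arm: int = 2,
    seed: int = 20140826,
) -> tuple[SampleMatrix, SyntheticTruth]:
    """Simulate a cohort on a trunk-plus-bifurcation manifold.

    The latent coordinate t is uniform in arc length over a tree with a
    trunk that splits into two arms.  Each relevant feature is a
    stage-wise activation: a sigmoid ramp of width ``ramp_width`` (in
    latent arc units, wide enough that successive activations overlap and
    the manifold never stalls) switching on (or off — random sign) at its own
    change point, the change points spread evenly along the two
    root-to-leaf paths and alternately assigned to arm 1 or arm 2 (a
    feature is frozen at its bifurcation value on the arm it does not
    follow).  Every relevant feature therefore varies by ``amplitude``
    somewhere along the tree and carries complementary positional
    information, the way trajectory-associated genes switch at different
    progression stages.  Relevant features get N(0, noise_sd^2) noise;
    irrelevant features are i.i.d. standard normal.  Planted clusters are
    equal arc-length bins (``clusters_trunk`` on the trunk,
    ``clusters_arm`` per arm).
    """
    if n_samples < 50:
        raise ValueError("n_samples must be >= 50")
    if j_rel < 2:
        raise ValueError("j_rel must be >= 2")
    if trunk_length <= 0 or arm_length <= 0:
        raise ValueError("branch lengths must be positive")
    rng = np.random.default_rng(seed)

    path_len = trunk_length + arm_length
    # Three transcriptional programs, one unique change point per feature
    # (a shared change point would make an exactly redundant pair that
    # sparse selection could legitimately prune): half the features form
    # the shared trunk program with change points spread along the trunk,
    # and a quarter each form arm-specific programs whose change points
    # span their arm — lineage markers switching soon after the
    # bifurcation make the arms diverge promptly, as branch-defining
    # programs do.
    n_trunk = j_rel // 2
    n_arm1 = (j_rel - n_trunk + 1) // 2
    n_arm2 = j_rel - n_trunk - n_arm1
    arm_of = np.concatenate(
        [np.zeros(n_trunk, dtype=int), np.ones(n_arm1, dtype=int), np.full(n_arm2, 2)]
    )
    points = np.concatenate(
        [
            np.linspace(0.06, 0.80, n_trunk) * trunk_length,
            trunk_length + np.linspace(0.02, 0.9, n_arm1) * arm_length,
            trunk_length + np.linspace(0.05, 0.93, n_arm2) * arm_length,
        ]
    )
    signs = rng.choice([-1.0, 1.0], size=j_rel)

    def manifold(which: np.ndarray, lat: np.ndarray) -> np.ndarray:
        """Noise-free relevant block for branch labels `which` at latent `lat`."""
        lat = np.asarray(lat, dtype=float)[:, None]
        which = np.asarray(which, dtype=int)[:, None]
        # the coordinate a feature responds to: its own path's arc length;
        # trunk-program features follow every branch, arm-program features
        # are frozen at their bifurcation value on the other arm
        a = np.where(
            (which == 0) | (arm_of[None, :] == 0) | (which == arm_of[None, :]),
            lat,
            trunk_length,
        )
        z = (a - points[None, :]) / ramp_width
        value = 1.0 / (1.0 + np.exp(-z))
        # arm programs are off through the trunk and in the other lineage,
        # rising from exactly 0 at the junction to full amplitude along
        # their own arm
        base = 1.0 / (1.0 + np.exp(-(trunk_length - points) / ramp_width))
        is_arm = arm_of > 0
        value[:, is_arm] = np.clip(
            (value[:, is_arm] - base[is_arm]) / (1.0 - base[is_arm]), 0.0, None
        )
        return amplitude * signs[None, :] * value

    total = trunk_length + 2 * arm_length
    u = rng.uniform(0.0, total, size=n_samples)
    branch = np.zeros(n_samples, dtype=int)
    latent = np.empty(n_samples)
    on_trunk = u < trunk_length
    branch[~on_trunk] = np.where(u[~on_trunk] < trunk_length + arm_length, 1, 2)
    latent[on_trunk] = u[on_trunk]
    latent[~on_trunk] = trunk_length + (u[~on_trunk] - trunk_length) % arm_length
    backbone = manifold(branch, latent)

    # planted clusters: equal arc-length bins per branch
    cluster = np.empty(n_samples, dtype=int)
    trunk_bins = np.linspace(0, trunk_length, clusters_trunk + 1)
    arm_bins = np.linspace(0, arm_length, clusters_arm + 1)
    for i in range(n_samples):
        if branch[i] == 0:
            cluster[i] = np.clip(
                np.searchsorted(trunk_bins, latent[i], side="right") - 1,
                0,
                clusters_trunk - 1,
            )
        else:
            b = np.clip(
                np.searchsorted(arm_bins, latent[i] - trunk_length, side="right") - 1,
                0,
                clusters_arm - 1,
            )
            cluster[i] = clusters_trunk + (branch[i] - 1) * clusters_arm + b

    rel = backbone + rng.normal(0.0, noise_sd, size=backbone.shape)
    irrel = rng.normal(size=(n_samples, j_irrel))
    values = np.hstack([rel, irrel])
    perm = rng.permutation(j_rel + j_irrel)
    values = values[:, perm]
    relevant = np.argsort(perm)[:j_rel]  # new positions of the relevant block

    # dense polyline vertices of the true backbone (a tree joined at the
    # bifurcation) for oracle checks
    n_vert = 80
    trunk_lats = np.linspace(0.0, trunk_length, n_vert)
    verts = [manifold(np.zeros(n_vert, dtype=int), trunk_lats)]
    edges = [(k, k + 1) for k in range(n_vert - 1)]
    split_idx = n_vert - 1
    offset = n_vert
    for which in (1, 2):
        arm_lats = np.linspace(trunk_length, path_len, n_vert)[1:]
        verts.append(manifold(np.full(n_vert - 1, which), arm_lats))
        edges.append((split_idx, offset))
        edges += [(offset + k, offset + k + 1) for k in range(n_vert - 2)]
        offset += n_vert - 1

    sample_ids = [f"s{i:04d}" for i in range(n_samples)]
    feature_ids = [f"g{j:04d}" for j in range(j_rel + j_irrel)]
    matrix = SampleMatrix(values, sample_ids, feature_ids)
    truth = SyntheticTruth(
        latent,
        branch,
        cluster,
        relevant,
        np.vstack(verts),
        edges,
        noise_sd,
        int(seed),
    )
    return matrix, truth


def default_survival_link(u: np.ndarray) -> np.ndarray:
    """Monotone nonlinear link: longer survival for less-progressed tumors."""
    return 1.0 + 20.0 * np.asarray(u, dtype=float) ** 1.5


def simulate_survival(
    truth: SyntheticTruth,
    link=default_survival_link,
    noise_sd: float = 0.5,
    censor_rate: float = 0.2,
    seed: int = 0,
) -> ClinicalTable:
    """Survival outcomes tied monotonically to the progression coordinate.

    ``time = link(t_max - t) + noise`` with ``link`` strictly increasing,
    so more progressed samples (larger latent t) die sooner.  A fraction
    ``censor_rate`` of samples is censored independently at a uniform
    time before its event.
    """
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    t = truth.latent
    u = (t.max() - t) / max(t.max(), 1e-12)
    time = link(u)
    if np.any(np.diff(link(np.linspace(0, 1, 101))) <= 0):
        raise ValueError("link must be strictly monotone increasing")
    time = np.maximum(time + rng.normal(0.0, noise_sd, size=t.size), 1e-3)
    censored = rng.uniform(size=t.size) < censor_rate
    event = (~censored).astype(int)
    observed = np.where(censored, rng.uniform(0.0, time), time)
    return ClinicalTable(
        [f"s{i:04d}" for i in range(t.size)], observed, event
    )


def simulate_blobs(
    n_per: int = 100,
    c: int = 4,
    separation: float = 20.0,
    j: int = 2,
    sd: float = 1.0,
    seed: int = 0,
) -> tuple[SampleMatrix, np.ndarray]:
    """Isotropic Gaussian blobs with centers at pairwise distance >= separation."""
    if c < 2:
        raise ValueError("need at least 2 blobs")
    rng = np.random.default_rng(seed)
    centers = rng.normal(size=(c, j))
    d = np.linalg.norm(centers[:, None] - centers[None, :], axis=2)
    np.fill_diagonal(d, np.inf)
    centers *= separation / d.min()  # scale so the closest pair is exactly `separation` apart
    values = np.vstack(
        [centers[i] + rng.normal(0.0, sd, size=(n_per, j)) for i in range(c)]
    )
    labels = np.repeat(np.arange(c), n_per)
    ids = [f"s{i:04d}" for i in range(values.shape[0])]
    feats = [f"f{k}" for k in range(j)]
    return SampleMatrix(values, ids, feats), labels


def simulate_elbow(
    l_star: float = 20.0,
    slopes: tuple[float, float] = (-5.0, -0.2),
    n_points: int = 12,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """(length, error) records on two lines intersecting at ``l_star``.

    Slopes must be negative and the left arm steeper, mimicking a fitting
    error that drops fast then flattens as curve length grows.  Noise is
    Gaussian with sd ``noise_sd`` times the error range.
    """
    m1, m2 = slopes
    if not (m1 < m2 < 0):
        raise ValueError("need slopes m1 < m2 < 0")
    rng = np.random.default_rng(seed)
    lengths = np.linspace(0.2 * l_star, 2.0 * l_star, n_points)
    y_star = abs(m2) * 2.0 * l_star  # keeps errors positive over the range
    errors = np.where(
        lengths <= l_star,
        y_star + m1 * (lengths - l_star),
        y_star + m2 * (lengths - l_star),
    )
    if noise_sd > 0:
        errors = errors + rng.normal(0.0, noise_sd * (errors.max() - errors.min()), n_points)
    return lengths, errors
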