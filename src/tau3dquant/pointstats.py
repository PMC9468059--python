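"""Spatial statistics for 3D cell point patterns.

Nearest-neighbour distances, the Monte-Carlo nearest-neighbour index (NNI)
against a uniform-random null in the same mask, dense-cell detection at a
fraction of the mean NN distance, duo/minigroup component splitting, and
neighbouring-cell flags.

No analytic edge correction is applied: the Monte-Carlo null is simulated
inside the same mask as the observed pattern, which accounts for boundary
effects by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .phantom import make_point_pattern, points_in_mask


@dataclass
class NNIResult:
    """Observed vs Monte-Carlo-simulated nearest-neighbour distances."""

    n_points: int
    observed_nn_um: np.ndarray
    mean_observed_um: float
    sim_means_um: np.ndarray
    mean_simulated_um: float
    nni: float
    n_sims: int
    seed: int | None

    def __post_init__(self) -> None:
        self.observed_nn_um = np.asarray(self.observed_nn_um, dtype=float)
        self.sim_means_um = np.asarray(self.sim_means_um, dtype=float)
        if len(self.observed_nn_um) != self.n_points:
            raise ValueError("observed distances inconsistent with n_points")
        if len(self.sim_means_um) != self.n_sims or self.n_sims < 1:
            raise ValueError("simulation means inconsistent with n_sims")
        if not self.nni > 0:
            raise ValueError("nni must be positive")


@dataclass
class ClusterResult:
    """Dense-cell flags and connected duo/minigroup components.

    ``component_id`` is -1 for non-dense cells.  Component sizes are always
    at least 2: a dense cell's nearest neighbour lies below the (shared)
    threshold, so it is linked to at least one other dense cell.
    Components of 2 cells are duos, 3–9 are minigroups, larger ones are
    counted separately as large groups.
    """

    dense_flags: np.ndarray
    dense_threshold_um: float
    link_threshold_um: float
    component_id: np.ndarray
    component_sizes: dict[int, int]
    duo_count: int
    minigroup_count: int
    large_group_count: int
    neighbouring_flags: np.ndarray | None = None
    duos_per_100: float = float("nan")
    minigroups_per_100: float = float("nan")
    neighbouring_per_100: float = float("nan")


def nn_distances(points_um: np.ndarray) -> np.ndarray:
    """Per-point Euclidean nearest-neighbour distance in μm.

    Uses a KD-tree; agrees exactly with the all-pairs brute force.  Duplicate
    coordinates are allowed and yield a distance of 0 (flagged by a warning).
    """
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    if len(pts) < 2:
        raise ValueError("nearest-neighbour distances require at least 2 points")
    d, _ = cKDTree(pts).query(pts, k=2, workers=-1)
    out = d[:, 1]
    if np.any(out == 0):
        warnings.warn("duplicate coordinates present; their NN distance is 0")
    return out


def nni(
    points_um: np.ndarray,
    mask: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    n_sims: int = 100,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> NNIResult:
    """Monte-Carlo nearest-neighbour index of a pattern inside a mask.

    For each simulation, the same number of uniform-random points is drawn in
    the mask and its mean NN distance recorded.  The index is the observed
    mean NN distance divided by the mean of the per-simulation means; values
    below 1 indicate clustering, above 1 dispersion.
    """
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    if len(pts) < 2:
        raise ValueError("nni requires at least 2 points")
    if n_sims < 1:
        raise ValueError("n_sims must be at least 1")
    inside = points_in_mask(pts, mask, voxel_size_um)
    if not inside.all():
        offenders = np.flatnonzero(~inside)
        raise ValueError(
            f"{len(offenders)} point(s) lie outside the mask: indices "
            f"{offenders[:10].tolist()}{'...' if len(offenders) > 10 else ''}"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    observed = nn_distances(pts)
    sim_means = np.empty(n_sims)
    for s in range(n_sims):
        sim = make_point_pattern(mask, voxel_size_um, len(pts), "CSR", rng=rng)
        sim_means[s] = nn_distances(sim).mean()
    mean_obs = float(observed.mean())
    mean_sim = float(sim_means.mean())
    return NNIResult(
        n_points=len(pts),
        observed_nn_um=observed,
        mean_observed_um=mean_obs,
        sim_means_um=sim_means,
        mean_simulated_um=mean_sim,
        nni=mean_obs / mean_sim,
        n_sims=n_sims,
        seed=seed,
    )


def paired_sim_vs_obs_test(
    observed_means: np.ndarray, simulated_means: np.ndarray
) -> tuple[float, float]:
    """Classical paired t-test of per-case observed vs simulated mean NN distances.

    ``t = mean(d) / (sd(d) / sqrt(n))`` on the paired differences.  With zero
    variance of the differences the test degenerates: identical vectors give
    ``(0, 1)``; a constant nonzero difference gives ``(±inf, 0)`` by
    convention.
    """
    obs = np.asarray(observed_means, dtype=float)
    sim = np.asarray(simulated_means, dtype=float)
    if obs.shape != sim.shape or obs.ndim != 1:
        raise ValueError("paired test requires equal-length 1D vectors")
    n = len(obs)
    if n < 2:
        raise ValueError("paired test requires n >= 2 pairs")
    d = obs - sim
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def dense_cells(
    points_um: np.ndarray, factor: float = 0.75
) -> tuple[np.ndarray, float]:
    """Flag cells whose NN distance is strictly below ``factor`` × mean NN distance.

    The default factor is 0.75 (75% of the average 3D nearest-neighbour
    distance); the comparison is strict ("closer than").
    """
    if not 0.0 < factor <= 1.0:
        raise ValueError("factor must lie in (0, 1]")
    nn = nn_distances(points_um)
    threshold = float(factor * nn.mean())
    return nn < threshold, threshold


def split_components(
    points_um: np.ndarray,
    dense_flags: np.ndarray,
    link_threshold_um: float,
    n_at8_cells: int | None = None,
) -> ClusterResult:
    """Split dense cells into connected components by pairwise distance.

    Edges link dense cells strictly closer than ``link_threshold_um``
    (typically the dense threshold itself).  Size-2 components are duos,
    sizes 3–9 minigroups, larger components large groups.  Per-100 rates are
    filled when ``n_at8_cells`` is given.
    """
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    dense_flags = np.asarray(dense_flags, dtype=bool)
    if len(dense_flags) != len(pts):
        raise ValueError("dense_flags length must match points")
    component_id = np.full(len(pts), -1, dtype=int)
    sizes: dict[int, int] = {}
    dense_idx = np.flatnonzero(dense_flags)
    if len(dense_idx) > 0:
        sub = pts[dense_idx]
        tree = cKDTree(sub)
        pairs = tree.query_pairs(link_threshold_um, output_type="ndarray")
        if len(pairs):
            dist = np.linalg.norm(sub[pairs[:, 0]] - sub[pairs[:, 1]], axis=1)
            pairs = pairs[dist < link_threshold_um]  # strict inequality
        m = len(sub)
        if len(pairs):
            adj = coo_matrix(
                (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(m, m)
            )
        else:
            adj = coo_matrix((m, m))
        n_comp, labels = connected_components(adj, directed=False)
        component_id[dense_idx] = labels
        sizes = {int(c): int((labels == c).sum()) for c in range(n_comp)}
    duo = sum(1 for s in sizes.values() if s == 2)
    mini = sum(1 for s in sizes.values() if 3 <= s <= 9)
    large = sum(1 for s in sizes.values() if s > 9)
    result = ClusterResult(
        dense_flags=dense_flags,
        dense_threshold_um=float(link_threshold_um),
        link_threshold_um=float(link_threshold_um),
        component_id=component_id,
        component_sizes=sizes,
        duo_count=duo,
        minigroup_count=mini,
        large_group_count=large,
    )
    if n_at8_cells is not None:
        result.duos_per_100 = per_hundred(duo, n_at8_cells)
        result.minigroups_per_100 = per_hundred(mini, n_at8_cells)
    return result


def neighbouring_cells(
    points_um: np.ndarray,
    dense_flags: np.ndarray,
    th_mean_nn_um: float,
) -> np.ndarray:
    """Flag dense cells whose NN distance is ≤ the reference-population mean NN.

    A dense cell is "neighbouring" when its nearest pathological neighbour is
    at equal or shorter distance than the average NN distance of the
    marker-positive reference cells in the same scan (non-strict comparison).
    """
    if th_mean_nn_um < 0:
        raise ValueError("reference mean NN distance must be nonnegative")
    dense_flags = np.asarray(dense_flags, dtype=bool)
    nn = nn_distances(points_um)
    return dense_flags & (nn <= th_mean_nn_um)


def per_hundred(count: float, n_at8_cells: int) -> float:
    """Normalize a count to 100 pathological cells; NaN (with warning) if n=0."""
    if n_at8_cells == 0:
        warnings.warn("per-100 normalization undefined for 0 cells")
        return float("nan")
    return 100.0 * count / n_at8_cells


def cluster_analysis(
    points_um: np.ndarray,
    factor: float = 0.75,
    th_mean_nn_um: float | None = None,
) -> ClusterResult:
    """Convenience wrapper: dense flags → components → neighbouring → per-100."""
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    flags, threshold = dense_cells(pts, factor=factor)
    result = split_components(pts, flags, threshold, n_at8_cells=len(pts))
    if th_mean_nn_um is not None:
        result.neighbouring_flags = neighbouring_cells(pts, flags, th_mean_nn_um)
        result.neighbouring_per_100 = per_hundred(
            int(result.neighbouring_flags.sum()), len(pts)
        )
    return result
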