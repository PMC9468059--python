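"""Cell-body detection, body/process decomposition, and morphometrics.

Structuring elements, distance transforms, and separation thresholds are all
computed in physical micrometres so anisotropic voxel grids behave like their
isotropic physical counterparts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import skeletonize
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)


@dataclass
class Volume:
    """A single-channel 3D scalar image with physical voxel size.

    ``data`` is indexed ``(z, y, x)``; intensities must be nonnegative.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]
    channel: str = "TH"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if any(v <= 0 or not np.isfinite(v) for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive and finite")
        if self.data.size and self.data.min() < 0:
            raise ValueError("intensities must be nonnegative")

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_um))

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(
            n * v for n, v in zip(self.data.shape, self.voxel_size_um)
        )  # type: ignore[return-value]


@dataclass
class CompartmentMasks:
    """Exact partition of a thresholded foreground into body and process."""

    body_mask: np.ndarray
    process_mask: np.ndarray
    voxel_size_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.body_mask = np.asarray(self.body_mask, dtype=bool)
        self.process_mask = np.asarray(self.process_mask, dtype=bool)
        if self.body_mask.shape != self.process_mask.shape:
            raise ValueError("body and process masks must share a grid")
        if np.any(self.body_mask & self.process_mask):
            raise ValueError("body and process masks must be disjoint")

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_um))

    @property
    def body_volume_um3(self) -> float:
        return float(self.body_mask.sum()) * self.voxel_volume_um3

    @property
    def process_volume_um3(self) -> float:
        return float(self.process_mask.sum()) * self.voxel_volume_um3


@dataclass
class DetectionParams:
    """Settings for :func:`detect_cells`.

    The published processing-script parameters are not available, so the
    defaults here (Otsu threshold, 30 μm background radius, soma volume
    bounds 1,000–50,000 μm³, 12 μm maxima separation) are explicit,
    documented stand-ins.
    """

    background_radius_um: float | None = 30.0
    background_method: str = "gaussian"  # "gaussian" (fast) or "tophat" (exact)
    threshold: float | str = "otsu"
    min_soma_volume_um3: float = 1000.0
    max_soma_volume_um3: float = 50000.0
    min_separation_um: float = 12.0
    smooth_sigma_um: float = 3.0

    def __post_init__(self) -> None:
        if self.background_radius_um is not None and self.background_radius_um <= 0:
            raise ValueError("background_radius_um must be positive")
        if self.min_soma_volume_um3 <= 0 or self.max_soma_volume_um3 <= 0:
            raise ValueError("soma volume bounds must be positive")
        if self.min_soma_volume_um3 >= self.max_soma_volume_um3:
            raise ValueError("min soma volume must be below max")
        if self.min_separation_um <= 0 or self.smooth_sigma_um <= 0:
            raise ValueError("separation and smoothing scales must be positive")
        if self.background_method not in ("gaussian", "tophat"):
            raise ValueError("background_method must be 'gaussian' or 'tophat'")


def _ellipsoid_footprint(radius_um: float, voxel_size_um) -> np.ndarray:
    """Binary ellipsoid footprint of given physical radius on an anisotropic grid."""
    vs = np.asarray(voxel_size_um, dtype=float)
    r_vox = np.maximum(np.floor(radius_um / vs).astype(int), 0)
    if np.all(r_vox == 0):
        return np.ones((1, 1, 1), dtype=bool)
    axes = [np.arange(-r, r + 1) * v / radius_um for r, v in zip(r_vox, vs)]
    grids = np.meshgrid(*axes, indexing="ij")
    return grids[0] ** 2 + grids[1] ** 2 + grids[2] ** 2 <= 1.0


def _sigma_vox(sigma_um: float, voxel_size_um) -> tuple[float, ...]:
    return tuple(sigma_um / v for v in voxel_size_um)


def detect_cells(volume: Volume, params: DetectionParams | None = None) -> pd.DataFrame:
    """Detect cell bodies and return centroids (μm) with soma volumes.

    Pipeline: background subtraction (Gaussian-estimate or grey top-hat) →
    global threshold (Otsu or fixed) → hole filling → volume band-pass on
    connected components → watershed split of merged somas seeded by smoothed
    maxima of the physical distance transform, with maxima closer than
    ``min_separation_um`` merged.  Deterministic for fixed input and params.

    Returns a table with columns ``cell_id, z_um, y_um, x_um,
    soma_volume_um3``.
    """
    params = params or DetectionParams()
    vs = volume.voxel_size_um
    data = volume.data.astype(np.float32)
    empty = pd.DataFrame(
        columns=["cell_id", "z_um", "y_um", "x_um", "soma_volume_um3"]
    )
    if data.size == 0 or data.max() <= 0:
        return empty

    if params.background_radius_um is not None:
        if params.background_method == "gaussian":
            bg = ndimage.gaussian_filter(
                data, sigma=_sigma_vox(params.background_radius_um, vs)
            )
            data = np.clip(data - bg, 0.0, None)
        else:
            fp = _ellipsoid_footprint(params.background_radius_um, vs)
            data = data - ndimage.grey_opening(data, footprint=fp)

    if params.threshold == "otsu":
        thr = float(threshold_otsu(data))
    else:
        thr = float(params.threshold)
    fg = data > thr
    logger.info("threshold %.3g: %d foreground voxels", thr, int(fg.sum()))
    if not fg.any():
        return empty
    fg = ndimage.binary_fill_holes(fg)

    voxel_vol = volume.voxel_volume_um3
    labels, n_comp = ndimage.label(fg)
    sizes = np.bincount(labels.ravel())
    keep = (sizes * voxel_vol >= params.min_soma_volume_um3) & (
        sizes * voxel_vol <= params.max_soma_volume_um3
    )
    keep[0] = False
    fg = keep[labels]
    logger.info("volume band-pass kept %d/%d components", int(keep.sum()), n_comp)
    if not fg.any():
        return empty

    edt = ndimage.distance_transform_edt(fg, sampling=vs)
    smooth = ndimage.gaussian_filter(edt, sigma=_sigma_vox(params.smooth_sigma_um, vs))
    fp = _ellipsoid_footprint(params.min_separation_um, vs)
    is_max = (smooth == ndimage.maximum_filter(smooth, footprint=fp)) & fg
    peaks = np.argwhere(is_max)
    if len(peaks) == 0:
        return empty
    # merge maxima closer than min_separation_um in physical space (greedy,
    # highest smoothed distance first) to suppress watershed over-splitting
    vals = smooth[tuple(peaks.T)]
    order = np.argsort(-vals, kind="stable")
    peaks = peaks[order]
    coords = peaks * np.asarray(vs)
    accepted: list[int] = []
    tree_pts: list[np.ndarray] = []
    for i, c in enumerate(coords):
        if tree_pts:
            d = np.min(np.linalg.norm(np.asarray(tree_pts) - c, axis=1))
            if d < params.min_separation_um:
                continue
        accepted.append(i)
        tree_pts.append(c)
    peaks = peaks[accepted]
    logger.info("watershed seeded with %d maxima", len(peaks))

    markers = np.zeros(fg.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    segmented = watershed(-smooth, markers=markers, mask=fg)

    rows = []
    for prop in regionprops(segmented):
        vol = prop.num_pixels * voxel_vol
        if not params.min_soma_volume_um3 <= vol <= params.max_soma_volume_um3:
            continue
        cz, cy, cx = prop.centroid
        rows.append(
            {
                "z_um": cz * vs[0],
                "y_um": cy * vs[1],
                "x_um": cx * vs[2],
                "soma_volume_um3": vol,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(["z_um", "y_um", "x_um"]).reset_index(drop=True)
        out.insert(0, "cell_id", np.arange(len(out)))
    else:
        out = empty
    logger.info("detected %d cells", len(out))
    return out


def split_body_process(
    at8_foreground: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    opening_radius_um: float = 5.0,
    min_body_volume_um3: float = 1000.0,
) -> CompartmentMasks:
    """Partition a binary foreground into cell-body and process compartments.

    The body mask is the morphological opening with a ball of physical radius
    ``opening_radius_um`` (anisotropy-corrected), keeping only opened
    components above ``min_body_volume_um3``; the process mask is the exact
    remainder, so ``body ∪ process`` equals the input foreground and the two
    are disjoint on every input.

    The opening radius must exceed process radii (1–4 μm tubes vanish) while
    staying below soma radii; it must also cover at least one voxel per axis.
    """
    fg = np.asarray(at8_foreground, dtype=bool)
    vs = np.asarray(voxel_size_um, dtype=float)
    if opening_radius_um < vs.max():
        raise ValueError(
            f"opening radius {opening_radius_um} μm is below the voxel size "
            f"{tuple(vs)}; resample the volume to a finer grid"
        )
    fp = _ellipsoid_footprint(opening_radius_um, vs)
    opened = ndimage.binary_opening(fg, structure=fp)
    voxel_vol = float(np.prod(vs))
    if opened.any() and min_body_volume_um3 > 0:
        labels, _ = ndimage.label(opened)
        sizes = np.bincount(labels.ravel())
        keep = sizes * voxel_vol >= min_body_volume_um3
        keep[0] = False
        opened = keep[labels]
    body = opened & fg
    process = fg & ~body
    return CompartmentMasks(body, process, tuple(vs))


@dataclass
class Morphometrics:
    volume_um3: float
    surface_area_um2: float
    n_branches: int


def _exposed_face_area(mask: np.ndarray, voxel_size_um) -> float:
    """Total area of voxel faces between foreground and background.

    Overestimates the area of smooth surfaces by a factor of up to 1.5 for a
    sphere (face counting measures the L1 projection of the normal); the bias
    is deterministic and bounded, which keeps it exactly testable.
    """
    vs = np.asarray(voxel_size_um, dtype=float)
    area = 0.0
    for axis in range(3):
        face = float(np.prod(np.delete(vs, axis)))
        padded = np.pad(mask.astype(np.int8), 1)
        n_faces = int(np.abs(np.diff(padded, axis=axis)).sum())
        area += n_faces * face
    return area


def _skeleton_graph(skeleton: np.ndarray, voxel_size_um) -> nx.Graph:
    vs = np.asarray(voxel_size_um, dtype=float)
    coords = np.argwhere(skeleton)
    g = nx.Graph()
    g.add_nodes_from(map(tuple, coords))
    if len(coords) == 0:
        return g
    tree = cKDTree(coords * vs)
    # 26-connectivity: neighbours within one voxel step in every axis
    r = float(np.linalg.norm(vs)) + 1e-9
    for i, j in tree.query_pairs(r):
        ci, cj = coords[i], coords[j]
        if np.all(np.abs(ci - cj) <= 1):
            g.add_edge(tuple(ci), tuple(cj), length=float(np.linalg.norm((ci - cj) * vs)))
    return g


def _prune_spurs(g: nx.Graph, min_length_um: float) -> nx.Graph:
    """Remove endpoint branches shorter than ``min_length_um`` (one pass)."""
    g = g.copy()
    for endpoint in [n for n in g if g.degree(n) == 1]:
        if endpoint not in g:
            continue
        path = [endpoint]
        length = 0.0
        node = endpoint
        prev = None
        while True:
            nbrs = [n for n in g.neighbors(node) if n != prev]
            if g.degree(node) > 2 or not nbrs:
                path.pop()  # keep the junction (or isolated end) itself
                break
            nxt = nbrs[0]
            length += g.edges[node, nxt]["length"]
            prev, node = node, nxt
            path.append(node)
            if g.degree(node) != 2:
                path.pop()
                break
        if 0 < length < min_length_um and len(path) < g.number_of_nodes():
            g.remove_nodes_from(path)
    return g


def morphometrics(
    component: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    prune_spur_um: float = 7.0,
) -> Morphometrics:
    """Volume, voxel-face surface area, and skeleton branch count of a component.

    ``n_branches`` counts arcs emanating from the skeleton: degree-1 endpoints
    minus one, floored at zero, after pruning thinning spurs shorter than
    ``prune_spur_um`` (default twice a typical dendrite radius).
    """
    mask = np.asarray(component, dtype=bool)
    if not mask.any():
        raise ValueError("morphometrics of an empty component is undefined")
    vs = tuple(float(v) for v in voxel_size_um)
    volume = float(mask.sum()) * float(np.prod(vs))
    surface = _exposed_face_area(mask, vs)
    skel = skeletonize(mask)
    g = _skeleton_graph(skel, vs)
    if g.number_of_nodes() == 0:
        return Morphometrics(volume, surface, 0)
    g = _prune_spurs(g, prune_spur_um)
    endpoints = sum(1 for n in g if g.degree(n) <= 1)
    return Morphometrics(volume, surface, max(endpoints - 1, 0))


@dataclass
class FormThresholds:
    """Monotone cut-points on the process/soma volume ratio ``r``.

    ``r <= r_tangle`` (with no branches) → tangle-like; ``r <= r_severe`` →
    severe atrophy; ``r <= r_partial`` → partial atrophy; otherwise intact.
    All comparisons are non-strict at the cut, so a ratio just above
    ``r_partial`` is intact.
    """

    r_tangle: float = 0.05
    r_severe: float = 0.35
    r_partial: float = 0.75
    low_intensity_cut: float = 0.45  # fraction of full amplitude
    cv_cut: float = 0.25

    def __post_init__(self) -> None:
        if not 0 <= self.r_tangle <= self.r_severe <= self.r_partial:
            raise ValueError("form thresholds must satisfy r_tangle <= r_severe <= r_partial")


def classify_form(
    process_volume_um3: float,
    soma_volume_um3: float,
    n_branches: int | None = None,
    soma_mean_intensity: float | None = None,
    soma_intensity_cv: float | None = None,
    thresholds: FormThresholds | None = None,
    amplitude: float = 1.0,
) -> tuple[str, str]:
    """Classify a cell's form and intensity class from its morphometrics.

    ``n_branches=None`` means branch information is unavailable and the
    branch condition for tangles is treated as satisfied.  Intensity stats
    may be omitted, defaulting to the homogeneous class.  Deterministic.
    """
    thresholds = thresholds or FormThresholds()
    if soma_volume_um3 <= 0:
        raise ValueError("soma volume must be positive")
    r = process_volume_um3 / soma_volume_um3
    no_branches = n_branches is None or n_branches == 0
    if r <= thresholds.r_tangle and no_branches:
        form = "tangle_like"
    elif r <= thresholds.r_severe:
        form = "severe_atrophy"
    elif r <= thresholds.r_partial:
        form = "partial_atrophy"
    else:
        form = "intact_pretangle"

    intensity = "homogeneous"
    if (
        soma_mean_intensity is not None
        and soma_mean_intensity < thresholds.low_intensity_cut * amplitude
    ):
        intensity = "low"
    elif soma_intensity_cv is not None and soma_intensity_cv > thresholds.cv_cut:
        intensity = "inhomogeneous"
    return form, intensity


def match_centroids(
    detected_um: np.ndarray,
    truth_um: np.ndarray,
    max_dist_um: float = 10.0,
) -> tuple[float, float, list[tuple[int, int]]]:
    """Greedy one-to-one matching of detected vs ground-truth centroids.

    Candidate pairs within ``max_dist_um`` are accepted in order of
    increasing distance, each centroid used at most once.  Returns
    ``(precision, recall, matched_pairs)``.
    """
    det = np.atleast_2d(np.asarray(detected_um, dtype=float))
    tru = np.atleast_2d(np.asarray(truth_um, dtype=float))
    if det.shape[0] == 0 or tru.shape[0] == 0:
        return 0.0, 0.0, []
    tree = cKDTree(tru)
    pairs = []
    for i, p in enumerate(det):
        for j in tree.query_ball_point(p, max_dist_um):
            pairs.append((float(np.linalg.norm(p - tru[j])), i, j))
    pairs.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    matched = []
    for _, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        matched.append((i, j))
    precision = len(matched) / len(det)
    recall = len(matched) / len(tru)
    return precision, recall, matched
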