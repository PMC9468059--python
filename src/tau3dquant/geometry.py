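"""Subregion bookkeeping, dorso-ventral splitting, and concentric shell zoning.

All geometry is computed in physical micrometres on anisotropic voxel grids.
Array axes are ordered ``(z, y, x)`` with the dorso-ventral axis defaulting to
``y`` (axis 1); smaller ``y`` is dorsal by convention.  The physical origin sits
at the centre of voxel ``(0, 0, 0)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

#: canonical label integers for the four subregions
REGION_LABELS: dict[int, str] = {1: "core", 2: "shell", 3: "A4", 4: "subcoeruleus"}

#: shell index of voxels farther than the outermost shell edge
SHELL_OUTSIDE: int = -1
#: shell index of voxels not in the query mask
SHELL_NOT_IN_MASK: int = -2


@dataclass
class RegionMask:
    """A labelled 3D grid assigning voxels to subregions.

    Parameters
    ----------
    labels
        Integer array of shape ``(nz, ny, nx)``; 0 is background.
    voxel_size_um
        Physical voxel size ``(dz, dy, dx)`` in micrometres.
    label_names
        Mapping from positive label integers to region names.  Every nonzero
        value present in ``labels`` must be covered.
    """

    labels: np.ndarray
    voxel_size_um: tuple[float, float, float]
    label_names: dict[int, str] = field(default_factory=lambda: dict(REGION_LABELS))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer typed")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if len(self.voxel_size_um) != 3 or any(
            not np.isfinite(v) or v <= 0 for v in self.voxel_size_um
        ):
            raise ValueError("voxel_size_um must be three positive finite values")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.label_names)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from label_names")

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_um))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def _label_of(self, name: str) -> int:
        for value, n in self.label_names.items():
            if n == name:
                return value
        raise KeyError(f"unknown region name {name!r}")

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of the named subregion."""
        return self.labels == self._label_of(name)

    def region_volume_um3(self, name: str) -> float:
        return float(self.mask(name).sum()) * self.voxel_volume_um3

    def region_names(self) -> list[str]:
        """Names of regions actually present in the grid, in label order."""
        present = set(np.unique(self.labels)) - {0}
        return [self.label_names[v] for v in sorted(present)]


@dataclass
class ShellProfile:
    """Process volume per concentric shell around a set of cell bodies.

    ``shell_edges_um`` has length ``n_shells + 2``: ``[0, inner, inner+w, ...]``.
    ``volumes_um3``/``fractions`` have length ``n_shells + 1`` (index 0 is the
    soma-proximal band below the inner edge).  Fractions are normalized over
    the in-range shells and sum to 1 when any in-range volume exists.
    """

    shell_edges_um: np.ndarray
    volumes_um3: np.ndarray
    fractions: np.ndarray
    n_cells: int
    outside_volume_um3: float = 0.0
    empty: bool = False

    def __post_init__(self) -> None:
        self.shell_edges_um = np.asarray(self.shell_edges_um, dtype=float)
        self.volumes_um3 = np.asarray(self.volumes_um3, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if np.any(np.diff(self.shell_edges_um) <= 0):
            raise ValueError("shell edges must be strictly increasing")
        total = self.volumes_um3.sum()
        if total > 0 and abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1 when total volume > 0")


def split_dorsoventral(
    core_mask: np.ndarray, dv_axis: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Split a binary mask into two equal-volume halves along one axis.

    A single cut coordinate is chosen so the two halves' voxel counts are as
    equal as possible (exhaustive scan over all cut positions); ties are
    broken toward the dorsal (low-index) side, i.e. the dorsal half gets the
    extra slab.  The dorsal half is the low-index side of ``dv_axis``.

    Returns
    -------
    (dorsal_mask, ventral_mask)
        Disjoint boolean masks whose union is exactly ``core_mask``.
    """
    core_mask = np.asarray(core_mask, dtype=bool)
    total = int(core_mask.sum())
    if total == 0:
        raise ValueError("cannot split an empty mask")
    axes = tuple(a for a in range(core_mask.ndim) if a != dv_axis)
    slab_counts = core_mask.sum(axis=axes)
    cum = np.concatenate([[0], np.cumsum(slab_counts)])  # dorsal volume per cut
    imbalance = np.abs(2 * cum - total)
    best = imbalance.min()
    # ties toward dorsal: among minimizers take the largest cut index
    cut = int(np.flatnonzero(imbalance == best).max())
    idx = np.arange(core_mask.shape[dv_axis])
    shape = [1] * core_mask.ndim
    shape[dv_axis] = -1
    dorsal_side = (idx < cut).reshape(shape)
    dorsal = core_mask & dorsal_side
    ventral = core_mask & ~dorsal_side
    return dorsal, ventral


def dorsoventral_cut_um(
    core_mask: np.ndarray, voxel_size_um: tuple[float, float, float], dv_axis: int = 1
) -> float:
    """Physical coordinate of the equal-volume dorso-ventral cut plane.

    The cut lies between voxel indices ``cut-1`` and ``cut`` along ``dv_axis``;
    a point is dorsal iff its coordinate is below the returned value.
    """
    dorsal, _ = split_dorsoventral(core_mask, dv_axis=dv_axis)
    axes = tuple(a for a in range(core_mask.ndim) if a != dv_axis)
    slab = dorsal.sum(axis=axes)
    nz = np.flatnonzero(slab)
    cut_index = int(nz.max()) + 1 if nz.size else 0
    return (cut_index - 0.5) * float(voxel_size_um[dv_axis])


def shell_zones(
    cell_centroids_um: np.ndarray,
    query_mask: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    inner_edge_um: float = 50.0,
    width_um: float = 100.0,
    n_shells: int = 5,
) -> np.ndarray:
    """Assign each foreground voxel to the concentric shell of its nearest centroid.

    Shell index 0 covers distances in ``[0, inner_edge_um)``; shell ``k >= 1``
    covers ``[inner + (k-1)*width, inner + k*width)``.  Voxels beyond shell
    ``n_shells`` get :data:`SHELL_OUTSIDE`; voxels outside ``query_mask`` get
    :data:`SHELL_NOT_IN_MASK`.  Distances are Euclidean in physical μm; each
    voxel is represented by its centre.
    """
    pts = np.atleast_2d(np.asarray(cell_centroids_um, dtype=float))
    if pts.size == 0:
        raise ValueError("shell zoning requires at least one centroid")
    if inner_edge_um <= 0 or width_um <= 0 or n_shells < 1:
        raise ValueError("inner edge, width and n_shells must be positive")
    query_mask = np.asarray(query_mask, dtype=bool)
    out = np.full(query_mask.shape, SHELL_NOT_IN_MASK, dtype=np.int32)
    idx = np.argwhere(query_mask)
    if idx.size == 0:
        return out
    coords = idx * np.asarray(voxel_size_um, dtype=float)
    dist, _ = cKDTree(pts).query(coords, workers=-1)
    shell = np.where(
        dist < inner_edge_um,
        0,
        1 + np.floor((dist - inner_edge_um) / width_um).astype(np.int64),
    )
    shell = np.where(shell > n_shells, SHELL_OUTSIDE, shell)
    out[tuple(idx.T)] = shell
    return out


def shell_profile(
    process_mask: np.ndarray,
    cell_centroids_um: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    region_mask: np.ndarray | None = None,
    inner_edge_um: float = 50.0,
    width_um: float = 100.0,
    n_shells: int = 5,
) -> ShellProfile:
    """Process volume per concentric shell, optionally restricted to a subregion.

    An empty process mask yields a zero profile flagged ``empty`` rather than
    an error.
    """
    process_mask = np.asarray(process_mask, dtype=bool)
    if region_mask is not None:
        process_mask = process_mask & np.asarray(region_mask, dtype=bool)
    pts = np.atleast_2d(np.asarray(cell_centroids_um, dtype=float))
    edges = np.concatenate(
        [[0.0, inner_edge_um], inner_edge_um + width_um * np.arange(1, n_shells + 1)]
    )
    voxel_volume = float(np.prod(voxel_size_um))
    if not process_mask.any():
        zeros = np.zeros(n_shells + 1)
        return ShellProfile(edges, zeros, zeros.copy(), n_cells=len(pts), empty=True)
    zones = shell_zones(
        pts, process_mask, voxel_size_um, inner_edge_um, width_um, n_shells
    )
    volumes = np.array(
        [np.count_nonzero(zones == k) for k in range(n_shells + 1)], dtype=float
    )
    volumes *= voxel_volume
    outside = float(np.count_nonzero(zones == SHELL_OUTSIDE)) * voxel_volume
    total = volumes.sum()
    if total > 0:
        fractions = volumes / total
    else:
        fractions = np.zeros_like(volumes)
        warnings.warn("all process voxels fall beyond the outermost shell")
    return ShellProfile(
        edges, volumes, fractions, n_cells=len(pts), outside_volume_um3=outside
    )
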