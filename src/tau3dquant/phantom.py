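"""Synthetic two-channel volume phantoms with ground truth.

Generates labelled region masks (a tube-shaped cell-dense core with shell, A4
band and subcoeruleus satellites), seeded point patterns (CSR, clustered,
lattice), and full two-channel intensity volumes: ellipsoidal somas with
dendrite/axon tubes, stage-dependent pathological-cell fractions, a
configurable dorsal bias, cluster-process placement of pathological somas, and
microscope-style noise.  Every cell and painted voxel is recorded in a ground
truth table so downstream detection and quantification can be validated
without any external data.

Soma semi-axis defaults (about 10–20 μm) are assumptions chosen for plausible
cell sizes, not measured values; they are plain configuration.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .geometry import REGION_LABELS, RegionMask, dorsoventral_cut_um, split_dorsoventral

BRAAK_GROUPS = ("B0", "B12", "B34", "B6")

#: default fraction of marker-positive cells that carry pathology, per stage
#: group.  Free choices tuned only to give a monotone stage trend.
AT8_FRACTION_DEFAULTS: dict[str, float] = {
    "B0": 0.02,
    "B12": 0.05,
    "B34": 0.15,
    "B6": 0.60,
}

FORM_LABELS = ("intact_pretangle", "partial_atrophy", "severe_atrophy", "tangle_like")

#: process-volume multiplier applied per cell form (process completeness)
FORM_PROCESS_SCALE: dict[str, float] = {
    "intact_pretangle": 1.0,
    "partial_atrophy": 0.6,
    "severe_atrophy": 0.2,
    "tangle_like": 0.0,
}

FORM_DISTRIBUTION_DEFAULTS: dict[str, dict[str, float]] = {
    "B0": {"intact_pretangle": 1.0},
    "B12": {"intact_pretangle": 0.5, "partial_atrophy": 0.4, "severe_atrophy": 0.1},
    "B34": {
        "intact_pretangle": 0.25,
        "partial_atrophy": 0.40,
        "severe_atrophy": 0.25,
        "tangle_like": 0.10,
    },
    "B6": {
        "intact_pretangle": 0.10,
        "partial_atrophy": 0.20,
        "severe_atrophy": 0.40,
        "tangle_like": 0.30,
    },
}

INTENSITY_CLASSES = ("low", "inhomogeneous", "homogeneous")


@dataclass
class NoiseParams:
    """Intensity model: ``background + amplitude * shape + noise``."""

    background: float = 200.0
    amplitude: float = 2000.0
    gaussian_sigma: float = 50.0
    poisson: bool = False


@dataclass
class ClusterParams:
    """Cluster-process parameters for pathological soma placement.

    Parents are placed CSR; offspring are displaced by an isotropic Gaussian
    of ``sigma_um`` and resampled (not discarded) when they fall outside the
    mask, so requested sample sizes are exact.
    """

    n_parents: int = 40
    sigma_um: float = 30.0
    offspring_per_parent: int | None = None


@dataclass
class PhantomConfig:
    """Full parameterization of a synthetic two-channel scan.

    Geometry is in physical μm; arrays are ``(z, y, x)`` with the tube axis
    along ``z`` and the dorso-ventral axis along ``y`` (``dv_axis``).
    """

    grid_shape: tuple[int, int, int] = (400, 256, 256)
    voxel_size_um: tuple[float, float, float] = (2.0, 1.51, 1.51)
    core_radius_um: float = 100.0
    core_length_um: float = 600.0
    shell_thickness_um: float = 60.0
    region_densities: dict[str, float] = field(
        default_factory=lambda: {
            "core": 3000.0,  # cells per mm^3
            "shell": 300.0,
            "A4": 200.0,
            "subcoeruleus": 250.0,
        }
    )
    region_counts: dict[str, int] | None = None  # exact-count override
    braak_group: str = "B0"
    at8_fraction: float | None = None  # None -> stage default
    dorsal_bias: float = 0.5
    at8_mode: str = "thomas"  # "thomas" or "CSR" placement of pathological somas
    cluster_params: ClusterParams = field(default_factory=ClusterParams)
    body_fraction: float = 0.5
    soma_axes_um: tuple[float, float, float] = (15.0, 9.0, 9.0)  # semi-axes (z,y,x)
    dendrite_radius_um: float = 3.5
    axon_radius_um: float = 1.5
    dendrite_length_um: float = 150.0
    n_dendrites: int = 3
    duo_rate: float = 0.1  # fraction of core cells placed as "hugging" partners
    form_distribution: dict[str, float] | None = None  # None -> stage default
    intensity_distribution: dict[str, float] = field(
        default_factory=lambda: {"low": 0.2, "inhomogeneous": 0.3, "homogeneous": 0.5}
    )
    noise: NoiseParams = field(default_factory=NoiseParams)
    dv_axis: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if len(self.grid_shape) != 3 or any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be three positive voxel counts")
        if any(v <= 0 or not np.isfinite(v) for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive and finite")
        for name in (
            "core_radius_um",
            "core_length_um",
            "shell_thickness_um",
            "dendrite_radius_um",
            "axon_radius_um",
            "dendrite_length_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(a <= 0 for a in self.soma_axes_um):
            raise ValueError("soma semi-axes must be positive")
        if self.braak_group not in BRAAK_GROUPS:
            raise ValueError(f"braak_group must be one of {BRAAK_GROUPS}")
        for name in ("dorsal_bias", "body_fraction", "duo_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.at8_fraction is not None and not 0.0 <= self.at8_fraction <= 1.0:
            raise ValueError("at8_fraction must lie in [0, 1]")
        if self.at8_mode not in ("thomas", "CSR"):
            raise ValueError("at8_mode must be 'thomas' or 'CSR'")
        extent = self.extent_um
        if self.core_length_um > extent[0] or 2 * self.core_radius_um > min(
            extent[1], extent[2]
        ):
            raise ValueError(
                "core tube does not fit in the grid: "
                f"extent {extent} μm vs core length {self.core_length_um}, "
                f"diameter {2 * self.core_radius_um}"
            )

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical grid extent per axis in μm."""
        return tuple(
            n * v for n, v in zip(self.grid_shape, self.voxel_size_um)
        )  # type: ignore[return-value]

    @property
    def effective_at8_fraction(self) -> float:
        if self.at8_fraction is not None:
            return self.at8_fraction
        return AT8_FRACTION_DEFAULTS[self.braak_group]

    @property
    def effective_form_distribution(self) -> dict[str, float]:
        dist = self.form_distribution or FORM_DISTRIBUTION_DEFAULTS[self.braak_group]
        total = sum(dist.values())
        if total <= 0 or any(v < 0 for v in dist.values()):
            raise ValueError("form_distribution must be nonnegative with positive sum")
        unknown = set(dist) - set(FORM_LABELS)
        if unknown:
            raise ValueError(f"unknown form labels {sorted(unknown)}")
        return {k: v / total for k, v in dist.items()}

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        if isinstance(d.get("noise"), dict):
            d["noise"] = NoiseParams(**d["noise"])
        if isinstance(d.get("cluster_params"), dict):
            d["cluster_params"] = ClusterParams(**d["cluster_params"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-cell ground truth plus truth compartment masks for one phantom.

    ``cells`` columns: cell_id, z_um, y_um, x_um, marker (``TH``/``AT8+TH``),
    subregion, dorsal, form_label, intensity_class, soma_voxels,
    process_voxels, soma_volume_um3, process_volume_um3, full_cell_volume_um3.
    """

    cells: pd.DataFrame
    region_mask: RegionMask
    seed: int
    at8_body_mask: np.ndarray | None = None
    at8_process_mask: np.ndarray | None = None
    th_soma_mask: np.ndarray | None = None


@dataclass
class PhantomResult:
    th: "np.ndarray | object"  # imageproc.Volume (late import avoids a cycle)
    at8: "np.ndarray | object"
    mask: RegionMask
    truth: GroundTruth


# ---------------------------------------------------------------------------
# region masks
# ---------------------------------------------------------------------------


def _axis_coords(config: PhantomConfig):
    nz, ny, nx = config.grid_shape
    dz, dy, dx = config.voxel_size_um
    z = np.arange(nz) * dz
    y = np.arange(ny) * dy
    x = np.arange(nx) * dx
    return z, y, x


def make_region_masks(config: PhantomConfig) -> RegionMask:
    """Build the four-subregion label grid for a phantom configuration.

    The core is a caudo-rostrally elongated cylinder centred in the grid; the
    shell is an annulus around the rostral (high-``z``) third of the core; A4
    is a dorsomedial band; the subcoeruleus is a set of ventrolateral
    ellipsoids.  Labels are assigned with core > shell > A4 > subcoeruleus
    priority so regions are always disjoint.  Geometry depends only on the
    configuration, never on the seed.
    """
    z, y, x = _axis_coords(config)
    ez, ey, ex = config.extent_um
    cz, cy, cx = ez / 2.0, (ey - config.voxel_size_um[1]) / 2.0, (
        ex - config.voxel_size_um[2]
    ) / 2.0
    zz = z[:, None, None]
    yy = y[None, :, None]
    xx = x[None, None, :]
    r = config.core_radius_um
    half_len = config.core_length_um / 2.0

    radial2 = (yy - cy) ** 2 + (xx - cx) ** 2
    in_len = np.abs(zz - cz) <= half_len
    core = (radial2 <= r**2) & in_len

    # shell: annulus around the rostral third of the core
    outer = r + config.shell_thickness_um
    rostral = (zz >= cz + half_len / 3.0) & (zz <= cz + half_len)
    shell = (radial2 > r**2) & (radial2 <= outer**2) & rostral

    # A4: dorsomedial band just dorsal of the shell's outer radius
    band = max(0.4 * r, 2.0 * max(config.voxel_size_um))
    a4 = (
        (yy <= cy - outer)
        & (yy >= cy - outer - band)
        & (np.abs(xx - cx) <= 0.6 * r)
        & in_len
    )

    # subcoeruleus: three scattered ventrolateral ellipsoids (fixed layout)
    sub = np.zeros(config.grid_shape, dtype=bool)
    az, ay, ax_ = config.core_length_um / 10.0, 0.5 * r, 0.5 * r
    y0 = cy + outer + 0.8 * ay
    for k, (dzc, side) in enumerate([(-1.0, -1.0), (0.0, 1.0), (1.0, -1.0)]):
        zc = cz - config.core_length_um / 4.0 + dzc * config.core_length_um / 5.0
        xc = cx + side * 0.8 * r
        sub |= (
            ((zz - zc) / az) ** 2 + ((yy - y0) / ay) ** 2 + ((xx - xc) / ax_) ** 2
        ) <= 1.0

    labels = np.zeros(config.grid_shape, dtype=np.int16)
    for value, mask in ((4, sub), (3, a4), (2, shell), (1, core)):
        labels[mask] = value
    return RegionMask(labels, config.voxel_size_um, dict(REGION_LABELS))


# ---------------------------------------------------------------------------
# point patterns
# ---------------------------------------------------------------------------


def points_in_mask(
    points_um: np.ndarray,
    mask: np.ndarray,
    voxel_size_um: tuple[float, float, float],
) -> np.ndarray:
    """Boolean per-point membership in a voxel mask (nearest-voxel rule)."""
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    if pts.shape[0] == 0:
        return np.zeros(0, dtype=bool)
    idx = np.rint(pts / np.asarray(voxel_size_um, dtype=float)).astype(int)
    ok = np.all((idx >= 0) & (idx < np.asarray(mask.shape)), axis=1)
    out = np.zeros(len(pts), dtype=bool)
    inb = np.flatnonzero(ok)
    out[inb] = mask[tuple(idx[inb].T)]
    return out


def _csr_in_mask(mask: np.ndarray, voxel_size_um, n: int, rng: np.random.Generator):
    """Uniform points in a mask: pick a mask voxel, jitter within the voxel.

    Equivalent in distribution to bounding-box rejection sampling but exact in
    cost and sample size.
    """
    flat = np.flatnonzero(mask.ravel())
    if flat.size == 0:
        if n > 0:
            raise ValueError("cannot sample points in an empty mask")
        return np.zeros((0, 3))
    chosen = rng.choice(flat, size=n, replace=True)
    idx = np.column_stack(np.unravel_index(chosen, mask.shape)).astype(float)
    jitter = rng.uniform(-0.5, 0.5, size=(n, 3))
    return (idx + jitter) * np.asarray(voxel_size_um, dtype=float)


def make_point_pattern(
    mask: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    n: int | None = None,
    mode: str = "CSR",
    *,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    n_parents: int = 40,
    sigma_um: float = 30.0,
    offspring_per_parent: int | None = None,
    spacing_um: float | None = None,
    max_resample: int = 10_000,
) -> np.ndarray:
    """Generate a seeded point pattern (μm coordinates) inside a voxel mask.

    Modes
    -----
    ``CSR``
        ``n`` points uniform over the mask volume.
    ``thomas``
        Cluster process: ``n_parents`` CSR parents, offspring displaced by an
        isotropic Gaussian of ``sigma_um``.  With ``offspring_per_parent`` set,
        exactly that many per parent (``n`` ignored); otherwise ``n`` offspring
        are assigned to uniformly chosen parents.  Offspring landing outside
        the mask are resampled so the sample size is exact.
    ``lattice``
        Regular grid of spacing ``spacing_um`` (derived from ``n`` and the
        mask volume when omitted), restricted to the mask.

    Raises
    ------
    ValueError
        For an empty mask with ``n > 0``, or when thomas resampling exceeds
        ``max_resample`` attempts for a point (the cap is named in the
        message).
    """
    mask = np.asarray(mask, dtype=bool)
    if rng is None:
        rng = np.random.default_rng(seed)
    vs = np.asarray(voxel_size_um, dtype=float)

    if mode == "CSR":
        if n is None:
            raise ValueError("CSR mode requires n")
        return _csr_in_mask(mask, vs, int(n), rng)

    if mode == "thomas":
        if offspring_per_parent is not None:
            n_total = int(n_parents) * int(offspring_per_parent)
            parent_of = np.repeat(np.arange(n_parents), offspring_per_parent)
        else:
            if n is None:
                raise ValueError("thomas mode requires n or offspring_per_parent")
            n_total = int(n)
            parent_of = rng.integers(0, n_parents, size=n_total)
        if n_total == 0:
            return np.zeros((0, 3))
        parents = _csr_in_mask(mask, vs, int(n_parents), rng)
        pts = parents[parent_of] + rng.normal(0.0, sigma_um, size=(n_total, 3))
        bad = ~points_in_mask(pts, mask, vs)
        attempts = 0
        while bad.any():
            attempts += 1
            if attempts > max_resample:
                raise ValueError(
                    f"thomas offspring resampling exceeded the cap of "
                    f"{max_resample} iterations; sigma_um is likely too large "
                    "for the mask"
                )
            bad_idx = np.flatnonzero(bad)
            pts[bad_idx] = parents[parent_of[bad_idx]] + rng.normal(
                0.0, sigma_um, size=(len(bad_idx), 3)
            )
            still = ~points_in_mask(pts[bad_idx], mask, vs)
            bad = np.zeros(n_total, dtype=bool)
            bad[bad_idx[still]] = True
        return pts

    if mode == "lattice":
        if not mask.any():
            if n:
                raise ValueError("cannot sample points in an empty mask")
            return np.zeros((0, 3))
        if spacing_um is None:
            if n is None:
                raise ValueError("lattice mode requires n or spacing_um")
            vol = mask.sum() * float(np.prod(vs))
            spacing_um = (vol / max(n, 1)) ** (1.0 / 3.0)
        extent = np.asarray(mask.shape) * vs
        axes = [np.arange(spacing_um / 2.0, e, spacing_um) for e in extent]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        return grid[points_in_mask(grid, mask, vs)]

    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# painting primitives
# ---------------------------------------------------------------------------


def _paint_ellipsoid(canvas, center_um, radii_um, voxel_size_um, value=True):
    """Set voxels of an axis-aligned ellipsoid; returns indices painted."""
    vs = np.asarray(voxel_size_um, dtype=float)
    c = np.asarray(center_um, dtype=float)
    r = np.asarray(radii_um, dtype=float)
    lo = np.maximum(np.floor((c - r) / vs).astype(int), 0)
    hi = np.minimum(np.ceil((c + r) / vs).astype(int) + 1, canvas.shape)
    if np.any(lo >= hi):
        return (np.zeros(0, int),) * 3
    grids = np.meshgrid(
        *[(np.arange(l, h) * v - cc) / rr for l, h, v, cc, rr in zip(lo, hi, vs, c, r)],
        indexing="ij",
    )
    inside = grids[0] ** 2 + grids[1] ** 2 + grids[2] ** 2 <= 1.0
    if not inside.any():
        # guarantee at least the voxel containing the centre is painted
        idx = np.rint(c / vs).astype(int)
        if np.all((idx >= 0) & (idx < canvas.shape)):
            inside = np.zeros([h - l for l, h in zip(lo, hi)], dtype=bool)
            rel = np.clip(idx - lo, 0, np.array(inside.shape) - 1)
            inside[tuple(rel)] = True
        else:
            return (np.zeros(0, int),) * 3
    local = np.nonzero(inside)
    idxs = tuple(local[a] + lo[a] for a in range(3))
    canvas[idxs] = value
    return idxs


def _random_walk_polyline(rng, start_um, direction, step_um, n_steps, persistence=0.75):
    """Persistent random-walk polyline used for dendrite/axon centrelines."""
    pts = [np.asarray(start_um, dtype=float)]
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    for _ in range(n_steps):
        d = persistence * d + (1 - persistence) * rng.normal(size=3)
        d /= np.linalg.norm(d)
        pts.append(pts[-1] + step_um * d)
    return np.asarray(pts)


def _paint_tube_budgeted(canvas, occupied, polyline_um, radius_um, voxel_size_um,
                         budget_voxels):
    """Paint spheres along a polyline until ``budget_voxels`` new voxels are set.

    Only voxels not already in ``occupied`` count toward the budget.  Returns
    the number of new voxels painted.
    """
    vs = np.asarray(voxel_size_um, dtype=float)
    step = max(min(vs) * 0.5, radius_um * 0.5)
    painted = 0
    seg_lens = np.linalg.norm(np.diff(polyline_um, axis=0), axis=1)
    for a, b, L in zip(polyline_um[:-1], polyline_um[1:], seg_lens):
        n_sub = max(int(np.ceil(L / step)), 1)
        for t in np.linspace(0.0, 1.0, n_sub + 1):
            centre = a + t * (b - a)
            idxs = _paint_ellipsoid(
                canvas, centre, (radius_um,) * 3, vs, value=True
            )
            if len(idxs[0]):
                newly = ~occupied[idxs]
                painted += int(newly.sum())
                occupied[idxs] = True
            if painted >= budget_voxels:
                return painted
    return painted


# ---------------------------------------------------------------------------
# full phantom
# ---------------------------------------------------------------------------


def _draw_categorical(rng, dist: dict[str, float], size: int) -> np.ndarray:
    keys = list(dist)
    probs = np.asarray([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return np.asarray(keys)[rng.choice(len(keys), size=size, p=probs)]


def _region_cell_count(config: PhantomConfig, regions: RegionMask, name: str) -> int:
    if config.region_counts is not None and name in config.region_counts:
        return int(config.region_counts[name])
    dens = config.region_densities.get(name, 0.0)
    return int(round(dens * regions.region_volume_um3(name) / 1e9))


def _place_cells(config: PhantomConfig, regions: RegionMask, rng) -> pd.DataFrame:
    """Place TH+ centroids per region and choose the pathological subset."""
    vs = config.voxel_size_um
    at8_frac = config.effective_at8_fraction
    cp = config.cluster_params
    core_mask = regions.mask("core")
    dorsal_core, ventral_core = split_dorsoventral(core_mask, dv_axis=config.dv_axis)
    cut_um = dorsoventral_cut_um(core_mask, vs, dv_axis=config.dv_axis)

    rows = []
    for name in regions.region_names():
        mask = regions.mask(name)
        n = _region_cell_count(config, regions, name)
        if n == 0:
            continue
        soma_vol = 4.0 / 3.0 * np.pi * float(np.prod(config.soma_axes_um))
        if n * soma_vol > regions.region_volume_um3(name):
            raise ValueError(
                f"requested {n} somas exceed the available volume of region "
                f"{name!r}"
            )
        n_at8 = int(round(at8_frac * n))
        n_th_only = n - n_at8

        # pathological subset: clustered (or CSR) with an explicit dorsal bias
        # in the core, applied by sampling each half-mask separately so the
        # dorsal share is exactly binomial.
        at8_pts = np.zeros((0, 3))
        if n_at8 > 0:
            if name == "core":
                n_dorsal = int(rng.binomial(n_at8, config.dorsal_bias))
                halves = [(dorsal_core, n_dorsal), (ventral_core, n_at8 - n_dorsal)]
                parts = []
                for half_mask, n_half in halves:
                    if n_half == 0:
                        continue
                    if config.at8_mode == "thomas":
                        n_par = max(1, int(round(cp.n_parents * n_half / n_at8)))
                        parts.append(
                            make_point_pattern(
                                half_mask, vs, n_half, "thomas", rng=rng,
                                n_parents=n_par, sigma_um=cp.sigma_um,
                            )
                        )
                    else:
                        parts.append(
                            make_point_pattern(half_mask, vs, n_half, "CSR", rng=rng)
                        )
                at8_pts = np.concatenate(parts) if parts else at8_pts
            else:
                at8_pts = make_point_pattern(mask, vs, n_at8, "CSR", rng=rng)

        # remaining TH-only cells: CSR, with a fraction of core cells placed
        # as close "hugging" duo partners of existing cells
        n_partners = 0
        if name == "core" and config.duo_rate > 0 and n_th_only >= 2:
            n_partners = int(round(config.duo_rate * n_th_only / 2.0))
        n_single = n_th_only - n_partners
        th_pts = make_point_pattern(mask, vs, n_single, "CSR", rng=rng)
        if n_partners > 0 and len(th_pts) > 0:
            gap = 2.1 * min(config.soma_axes_um)  # just-touching soma pair
            anchors = th_pts[rng.choice(len(th_pts), size=n_partners, replace=False)]
            partners = []
            for a in anchors:
                for _ in range(200):
                    d = rng.normal(size=3)
                    d /= np.linalg.norm(d)
                    p = a + gap * d
                    if points_in_mask(p[None, :], mask, vs)[0]:
                        partners.append(p)
                        break
                else:
                    partners.append(a)  # degenerate fallback, still in mask
            th_pts = np.concatenate([th_pts, np.asarray(partners)])

        forms = _draw_categorical(rng, config.effective_form_distribution, n_at8)
        intens = _draw_categorical(rng, config.intensity_distribution, n_at8)
        for pts, marker in ((at8_pts, "AT8+TH"), (th_pts, "TH")):
            for i, p in enumerate(pts):
                rows.append(
                    {
                        "z_um": p[0],
                        "y_um": p[1],
                        "x_um": p[2],
                        "marker": marker,
                        "subregion": name,
                        "dorsal": bool(p[config.dv_axis] < cut_um),
                        "form_label": forms[i] if marker == "AT8+TH" else "unclassified",
                        "intensity_class": intens[i] if marker == "AT8+TH" else "homogeneous",
                    }
                )
    cells = pd.DataFrame(rows)
    if len(cells):
        cells.insert(0, "cell_id", np.arange(len(cells)))
    else:
        cells = pd.DataFrame(
            columns=[
                "cell_id", "z_um", "y_um", "x_um", "marker", "subregion",
                "dorsal", "form_label", "intensity_class",
            ]
        )
    return cells


def _soma_radii(config: PhantomConfig, subregion: str) -> tuple[float, float, float]:
    az, ay, ax = config.soma_axes_um
    if subregion == "subcoeruleus":
        return (ay, az, ax)  # dorso-ventrally oriented somas
    return (az, ay, ax)  # rostro-caudally oriented


def make_phantom(config: PhantomConfig) -> PhantomResult:
    """Generate the full two-channel phantom with ground truth.

    Marker-positive somas are painted in the TH channel; the pathological
    subset is additionally painted in the AT8 channel together with dendrite
    tubes and one thin axon per cell.  Per-cell process volume is budgeted so
    the configured body fraction is hit for intact cells, then scaled by the
    drawn form label (1 / 0.6 / 0.2 / 0).  Intensities are
    ``background + amplitude * shape + noise`` rendered to 16-bit.
    """
    from .imageproc import Volume  # local import: imageproc depends on geometry only

    rng = np.random.default_rng(config.seed)
    regions = make_region_masks(config)
    cells = _place_cells(config, regions, rng)
    vs = np.asarray(config.voxel_size_um, dtype=float)
    voxel_vol = float(np.prod(vs))

    th_shape = np.zeros(config.grid_shape, dtype=bool)
    at8_body = np.zeros(config.grid_shape, dtype=bool)
    at8_process = np.zeros(config.grid_shape, dtype=bool)
    at8_factor = np.zeros(config.grid_shape, dtype=np.float32)
    occupied = np.zeros(config.grid_shape, dtype=bool)  # body ∪ process

    bf = config.body_fraction
    soma_counts = np.zeros(len(cells), dtype=np.int64)
    proc_counts = np.zeros(len(cells), dtype=np.int64)

    for i, row in cells.iterrows():
        centre = np.array([row.z_um, row.y_um, row.x_um])
        radii = _soma_radii(config, row.subregion)
        idxs = _paint_ellipsoid(th_shape, centre, radii, vs, value=True)
        if row.marker != "AT8+TH":
            continue
        _paint_ellipsoid(at8_body, centre, radii, vs, value=True)
        n_soma = len(idxs[0])
        soma_counts[i] = n_soma
        occupied[idxs] = True
        # soma intensity signature
        if row.intensity_class == "low":
            at8_factor[idxs] = np.maximum(at8_factor[idxs], 0.3)
        elif row.intensity_class == "inhomogeneous":
            speckle = rng.uniform(0.4, 1.6, size=n_soma).astype(np.float32)
            at8_factor[idxs] = np.maximum(at8_factor[idxs], speckle)
        else:
            at8_factor[idxs] = np.maximum(at8_factor[idxs], 1.0)

        scale = FORM_PROCESS_SCALE[row.form_label]
        if bf >= 1.0 or scale == 0.0 or n_soma == 0:
            continue
        target = int(round(n_soma * (1.0 - bf) / bf * scale))
        if target == 0:
            continue
        painted = 0
        # one thin axon first, then dendrites until the budget is met
        step = config.dendrite_length_um / 8.0
        axon_dir = rng.normal(size=3)
        line = _random_walk_polyline(
            rng, centre, axon_dir, step, 16, persistence=0.9
        )
        painted += _paint_tube_budgeted(
            at8_process, occupied, line, config.axon_radius_um, vs, target - painted
        )
        tries = 0
        while painted < target and tries < 12 * max(config.n_dendrites, 1):
            tries += 1
            d = rng.normal(size=3)
            start = centre + d / np.linalg.norm(d) * np.asarray(radii)
            line = _random_walk_polyline(rng, start, d, step, 8, persistence=0.75)
            painted += _paint_tube_budgeted(
                at8_process, occupied, line, config.dendrite_radius_um, vs,
                target - painted,
            )
        proc_counts[i] = painted

    # soma takes precedence over process where another cell's tube crossed it
    at8_process &= ~at8_body
    at8_factor[at8_process & (at8_factor == 0)] = 0.8

    if len(cells):
        cells = cells.assign(
            soma_voxels=soma_counts,
            process_voxels=proc_counts,
            soma_volume_um3=soma_counts * voxel_vol,
            process_volume_um3=proc_counts * voxel_vol,
        )
        cells["full_cell_volume_um3"] = (
            cells.soma_volume_um3 + cells.process_volume_um3
        )

    noise = config.noise
    th_img = noise.background + noise.amplitude * th_shape.astype(np.float32)
    at8_img = noise.background + noise.amplitude * at8_factor
    for img in (th_img, at8_img):
        if noise.gaussian_sigma > 0:
            img += rng.normal(0.0, noise.gaussian_sigma, size=img.shape).astype(
                np.float32
            )
    if noise.poisson:
        th_img = rng.poisson(np.clip(th_img, 0, None)).astype(np.float32)
        at8_img = rng.poisson(np.clip(at8_img, 0, None)).astype(np.float32)
    th_u16 = np.clip(th_img, 0, 65535).astype(np.uint16)
    at8_u16 = np.clip(at8_img, 0, 65535).astype(np.uint16)

    truth = GroundTruth(
        cells=cells,
        region_mask=regions,
        seed=config.seed,
        at8_body_mask=at8_body,
        at8_process_mask=at8_process,
        th_soma_mask=th_shape,
    )
    return PhantomResult(
        th=Volume(th_u16, config.voxel_size_um, channel="TH"),
        at8=Volume(at8_u16, config.voxel_size_um, channel="AT8"),
        mask=regions,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_phantom(outdir, result: PhantomResult, config: PhantomConfig) -> dict:
    """Write a phantom to disk: 16-bit TIFF channels, labelled mask TIFF,
    ground-truth CSV, and the config as YAML.  Returns the path map."""
    import tifffile
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "th": outdir / "th.tif",
        "at8": outdir / "at8.tif",
        "mask": outdir / "region_mask.tif",
        "truth": outdir / "truth.csv",
        "config": outdir / "phantom_config.yaml",
        "labels": outdir / "region_labels.json",
    }
    tifffile.imwrite(paths["th"], result.th.data)
    tifffile.imwrite(paths["at8"], result.at8.data)
    tifffile.imwrite(paths["mask"], result.mask.labels.astype(np.uint16))
    result.truth.cells.to_csv(paths["truth"], index=False)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    with open(paths["labels"], "w") as fh:
        json.dump({str(k): v for k, v in result.mask.label_names.items()}, fh)
    return {k: str(v) for k, v in paths.items()}


def replace_config(config: PhantomConfig, **kwargs) -> PhantomConfig:
    """Functional update of a configuration (dataclasses.replace wrapper)."""
    return replace(config, **kwargs)
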