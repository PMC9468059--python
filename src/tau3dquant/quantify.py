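"""Regional burden quantification, dorso-ventral proportions, and scoring.

Volumes are reported in μm³ and densities per mm³ (SI-based units rather
than normalized arbitrary units).  Dorso-ventral additivity — dorsal plus
ventral equals the whole-region value, exactly — holds for every volume and
count column.
"""

from __future__ import annotations

import warnings
from enum import Enum

import numpy as np
import pandas as pd

from .geometry import RegionMask, split_dorsoventral
from .imageproc import CompartmentMasks


class ScoreGrade(Enum):
    """Ordered five-grade semiquantitative density score."""

    ZERO = (0, "0")
    TRACE = (1, "0/+")
    SPARSE = (2, "+")
    MODERATE = (3, "++")
    HIGH = (4, "+++")

    @property
    def rank(self) -> int:
        return self.value[0]

    @property
    def symbol(self) -> str:
        return self.value[1]

    def __lt__(self, other: "ScoreGrade") -> bool:
        return self.rank < other.rank

    def __le__(self, other: "ScoreGrade") -> bool:
        return self.rank <= other.rank


def semiquant_score(
    count: int, thresholds: tuple[float, float] = (10, 100)
) -> ScoreGrade:
    """Five-grade score of a structure count.

    Grade 0 iff the structure is absent (count 0); 0/+ iff exactly one is
    present; the sparse/moderate/high cut-points are configuration (defaults
    ``+ <= 10 < ++ <= 100 < +++``) and must be strictly increasing.  The
    score is monotone in the count.
    """
    t1, t2 = thresholds
    if not 1 < t1 < t2:
        raise ValueError("score thresholds must satisfy 1 < t1 < t2")
    if count < 0:
        raise ValueError("count must be nonnegative")
    if count == 0:
        return ScoreGrade.ZERO
    if count == 1:
        return ScoreGrade.TRACE
    if count <= t1:
        return ScoreGrade.SPARSE
    if count <= t2:
        return ScoreGrade.MODERATE
    return ScoreGrade.HIGH


def assign_subregion(cells: pd.DataFrame, regions: RegionMask) -> pd.DataFrame:
    """Add/overwrite the ``subregion`` column by centroid voxel membership.

    Centroid membership (rather than any-overlap) decides which subregion a
    cell belongs to; cells whose centroid voxel is background get
    ``"background"``.
    """
    out = cells.copy()
    if len(out) == 0:
        out["subregion"] = pd.Series(dtype=object)
        return out
    vs = np.asarray(regions.voxel_size_um)
    idx = np.rint(out[["z_um", "y_um", "x_um"]].to_numpy() / vs).astype(int)
    idx = np.clip(idx, 0, np.asarray(regions.shape) - 1)
    labels = regions.labels[tuple(idx.T)]
    out["subregion"] = [
        regions.label_names.get(int(v), "background") if v else "background"
        for v in labels
    ]
    return out


def regional_burden(
    compartments: CompartmentMasks,
    cells: pd.DataFrame,
    regions: RegionMask,
    dv_axis: int = 1,
) -> pd.DataFrame:
    """Per-subregion burden table with dorso-ventral variants for the core.

    Rows: one per subregion present in the mask.  Columns cover the three
    normalizations — signal volume per subregion volume, pathological-cell
    count per subregion volume (per mm³), and per 100 marker-positive cells —
    plus body/process proportions, with ``dorsal_``/``ventral_`` variants for
    the core (NaN elsewhere).

    ``cells`` needs columns ``z_um, y_um, x_um, marker`` and ``subregion``
    (see :func:`assign_subregion`); the pathological marker value is
    ``"AT8+TH"``.
    """
    if compartments.body_mask.shape != regions.shape:
        raise ValueError("compartment masks and region mask grids are misaligned")
    if "subregion" not in cells.columns:
        cells = assign_subregion(cells, regions)
    voxel_vol = regions.voxel_volume_um3
    at8_fg = compartments.body_mask | compartments.process_mask
    vs = regions.voxel_size_um

    rows = []
    for name in regions.region_names():
        rmask = regions.mask(name)
        region_vol = float(rmask.sum()) * voxel_vol
        body_vol = float((compartments.body_mask & rmask).sum()) * voxel_vol
        proc_vol = float((compartments.process_mask & rmask).sum()) * voxel_vol
        at8_vol = body_vol + proc_vol
        sub = cells[cells["subregion"] == name]
        n_at8 = int((sub["marker"] == "AT8+TH").sum())
        n_th = int(len(sub))  # pathological cells are a subset of TH+ cells
        row = {
            "subregion": name,
            "subregion_volume_um3": region_vol,
            "at8_volume_um3": at8_vol,
            "at8_volume_fraction": at8_vol / region_vol if region_vol else np.nan,
            "body_volume_um3": body_vol,
            "process_volume_um3": proc_vol,
            "body_volume_fraction": body_vol / at8_vol if at8_vol else 0.0,
            "process_volume_fraction": proc_vol / at8_vol if at8_vol else 0.0,
            "n_th_cells": n_th,
            "n_at8_cells": n_at8,
            "at8_cells_per_mm3": 1e9 * n_at8 / region_vol if region_vol else np.nan,
            "at8_per_100_th": 100.0 * n_at8 / n_th if n_th else np.nan,
        }
        for key in (
            "subregion_volume_um3", "at8_volume_um3", "n_at8_cells", "n_th_cells",
        ):
            row[f"dorsal_{key}"] = np.nan
            row[f"ventral_{key}"] = np.nan
        if name == "core":
            dorsal, ventral = split_dorsoventral(rmask, dv_axis=dv_axis)
            for half_name, hmask in (("dorsal", dorsal), ("ventral", ventral)):
                hvol = float(hmask.sum()) * voxel_vol
                hat8 = float((at8_fg & hmask).sum()) * voxel_vol
                in_half = _points_in(sub, hmask, vs)
                row[f"{half_name}_subregion_volume_um3"] = hvol
                row[f"{half_name}_at8_volume_um3"] = hat8
                row[f"{half_name}_n_at8_cells"] = int(
                    (sub["marker"][in_half] == "AT8+TH").sum()
                )
                row[f"{half_name}_n_th_cells"] = int(in_half.sum())
        rows.append(row)
    return pd.DataFrame(rows)


def _points_in(cells: pd.DataFrame, mask: np.ndarray, voxel_size_um) -> pd.Series:
    if len(cells) == 0:
        return pd.Series(np.zeros(0, dtype=bool), index=cells.index)
    idx = np.rint(
        cells[["z_um", "y_um", "x_um"]].to_numpy() / np.asarray(voxel_size_um)
    ).astype(int)
    idx = np.clip(idx, 0, np.asarray(mask.shape) - 1)
    return pd.Series(mask[tuple(idx.T)], index=cells.index)


def body_process_proportion(
    compartments: CompartmentMasks, region_mask: np.ndarray | None = None
) -> tuple[float, float]:
    """Body and process percentages of the total signal volume in a region.

    Always sums to 100 when defined; with zero total volume the proportions
    are undefined and returned as NaN with a warning.
    """
    body = compartments.body_mask
    proc = compartments.process_mask
    if region_mask is not None:
        region_mask = np.asarray(region_mask, dtype=bool)
        body = body & region_mask
        proc = proc & region_mask
    nb, np_ = int(body.sum()), int(proc.sum())
    total = nb + np_
    if total == 0:
        warnings.warn("zero total signal volume: body/process proportion undefined")
        return float("nan"), float("nan")
    return 100.0 * nb / total, 100.0 * np_ / total


def average_bilateral(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Average burden tables from multiple blocks of the same case by subregion."""
    if not tables:
        raise ValueError("no tables to average")
    merged = pd.concat(tables, ignore_index=True)
    return merged.groupby("subregion", sort=False, as_index=False).mean(
        numeric_only=True
    )


def group_summary(
    df: pd.DataFrame,
    value_cols: list[str],
    group_col: str = "braak_group",
    by: list[str] | None = None,
) -> pd.DataFrame:
    """Stage-level mean ± SEM per subregion (or other grouping).

    SEM uses ddof=1 and is NaN for single-case groups (reported as absent
    rather than zero).  Empty groups simply do not appear; group sizes are
    reported in ``n``.
    """
    keys = [group_col] + (by or [])
    grouped = df.groupby(keys, sort=False)
    out = []
    for name, g in grouped:
        if len(g) == 0:
            warnings.warn(f"group {name} is empty; omitted")
            continue
        rec = dict(zip(keys, name if isinstance(name, tuple) else (name,)))
        rec["n"] = len(g)
        for col in value_cols:
            rec[f"{col}_mean"] = g[col].mean()
            rec[f"{col}_sem"] = g[col].sem(ddof=1) if len(g) > 1 else np.nan
        out.append(rec)
    return pd.DataFrame(out)
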