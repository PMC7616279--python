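"""Tip/side partitioning of elongated structures and local density.

The long axis is the leading principal axis of the structure mask's
voxel-coordinate covariance (sign fixed toward positive projection of the
first image axis for determinism, override available).  Lumen voxels are
projected onto it; structure voxels beyond the lumen extrema are ``tip``,
the rest ``side``.  Densities are cells per region volume (um^-3) or, in
single-plane mode, per region area (um^-2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TIP, SIDE = 1, 2


@dataclass
class RegionPartition:
    axis: np.ndarray  # unit vector (z, y, x) in physical space
    lumen_extrema_um: tuple[float, float]  # (min, max) projections
    region_labels: np.ndarray  # 0 outside, TIP=1, SIDE=2
    voxel_size: tuple[float, float, float]
    planar: bool = False
    flagged_no_lumen: bool = False
    origin_um: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def tip_measure(self) -> float:
        return self._measure(TIP)

    @property
    def side_measure(self) -> float:
        return self._measure(SIDE)

    def _measure(self, code: int) -> float:
        vs = np.asarray(self.voxel_size, float)
        unit = float(vs[1] * vs[2]) if self.planar else float(np.prod(vs))
        return float((self.region_labels == code).sum() * unit)

    def assign_cells(self, centroids_um: np.ndarray) -> np.ndarray:
        """Region per cell by nucleus-centroid projection onto the long axis."""
        c = np.atleast_2d(np.asarray(centroids_um, float)) - self.origin_um
        proj = c @ self.axis
        lo, hi = self.lumen_extrema_um
        return np.where((proj > hi) | (proj < lo), "tip", "side")


def principal_axis(
    mask: np.ndarray, voxel_size: tuple[float, float, float]
) -> np.ndarray:
    """Leading principal axis of a mask's coordinate covariance (unit vector)."""
    vs = np.asarray(voxel_size, float)
    pts = np.argwhere(np.asarray(mask) > 0).astype(float) * vs
    if len(pts) < 2:
        raise ValueError("mask too small for a principal axis")
    cov = np.cov((pts - pts.mean(axis=0)).T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 1.02 * evals[-2]:
        raise ValueError("degenerate (isotropic) covariance: supply the axis explicitly")
    axis = evecs[:, -1]
    # deterministic sign: positive projection on the first axis with a
    # non-negligible component, scanning z, y, x
    for comp in axis:
        if abs(comp) > 1e-9:
            if comp < 0:
                axis = -axis
            break
    return axis


def partition_tip_side(
    spheroid_mask: np.ndarray,
    lumen_mask: np.ndarray,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    axis: np.ndarray | None = None,
    planar: bool = False,
) -> RegionPartition:
    """Partition a structure into tip and side regions along its long axis.

    With an empty lumen there are no extrema: the whole structure is
    labelled ``side`` and the partition is flagged.
    """
    sph = np.asarray(spheroid_mask) > 0
    lum = np.asarray(lumen_mask) > 0
    if sph.shape != lum.shape:
        raise ValueError("spheroid and lumen masks must share one grid")
    if not sph.any():
        raise ValueError("empty spheroid mask")
    vs = np.asarray(voxel_size, float)
    if axis is None:
        ax = principal_axis(sph, vs)
    else:
        ax = np.asarray(axis, float)
        ax = ax / np.linalg.norm(ax)

    pts = np.argwhere(sph).astype(float) * vs
    origin = pts.mean(axis=0)
    labels = np.zeros(sph.shape, dtype=np.uint8)
    if not lum.any():
        warnings.warn("no lumen: whole structure labelled side")
        labels[sph] = SIDE
        return RegionPartition(ax, (-np.inf, np.inf), labels, tuple(vs), planar, True, origin)

    lpts = np.argwhere(lum).astype(float) * vs - origin
    lproj = lpts @ ax
    lo, hi = float(lproj.min()), float(lproj.max())
    proj = (pts - origin) @ ax
    tip_sel = (proj > hi) | (proj < lo)
    flat = labels[sph]
    flat[tip_sel] = TIP
    flat[~tip_sel] = SIDE
    labels[sph] = flat
    return RegionPartition(ax, (lo, hi), labels, tuple(vs), planar, False, origin)


def local_density(
    partition: RegionPartition, cell_regions: np.ndarray | list[str]
) -> pd.DataFrame:
    """Cells per region measure (um^-3 in volume mode, um^-2 in planar mode).

    Zero-measure regions get a flagged NaN density.
    """
    regions = np.asarray(cell_regions)
    rows = []
    for name, code in (("tip", TIP), ("side", SIDE)):
        n = int((regions == name).sum())
        measure = partition._measure(code)
        if measure == 0 and n > 0:
            warnings.warn(f"{name} region has zero measure; density undefined")
            dens = np.nan
        elif measure == 0:
            dens = 0.0
        else:
            dens = n / measure
        rows.append(
            {
                "region": name,
                "n_cells": n,
                ("area_um2" if partition.planar else "volume_um3"): measure,
                "density": dens,
            }
        )
    return pd.DataFrame(rows)


def region_fractions(
    cell_regions: np.ndarray | list[str],
    cell_table: pd.DataFrame,
    delaminated_col: str = "delaminated",
    positive_col: str = "marker_class",
) -> pd.DataFrame:
    """Per-region delaminated and marker-positive fractions with logged counts."""
    df = cell_table.copy()
    df["region"] = np.asarray(cell_regions)
    rows = []
    for name in ("tip", "side"):
        sub = df[df.region == name]
        n = len(sub)
        row: dict = {"region": name, "n_cells": n}
        for col, out in ((delaminated_col, "fraction_delaminated"), (positive_col, "fraction_positive")):
            if col in df.columns:
                if n == 0:
                    row[f"n_{out.split('_')[1]}"] = 0
                    row[out] = np.nan
                else:
                    k = int(sub[col].astype(bool).sum())
                    row[f"n_{out.split('_')[1]}"] = k
                    row[out] = k / n
        rows.append(row)
    return pd.DataFrame(rows)
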