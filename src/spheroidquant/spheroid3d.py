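"""Spheroid and lumen morphometrics and per-cell geometric classifications.

All distances, areas, and volumes are physical (um, um^2, um^3) computed
with anisotropic voxel sizes.  The "radius of the spheroid" used to
normalise lumen distances is the volume-equivalent sphere radius
``(3V / 4 pi)^(1/3)``; ellipticity is the ratio of the longest to shortest
principal axis, estimated from the eigenvalues of the voxel-coordinate
covariance (axis length scales as the square root of the eigenvalue);
sphericity is ``pi^(1/3) (6V)^(2/3) / A`` with the surface area ``A`` from
a triangulated isosurface of the binary mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage import measure


@dataclass
class SpheroidMorphometrics:
    volume_um3: float
    surface_area_um2: float
    equivalent_radius_um: float
    ellipticity: float
    sphericity: float
    centroid_um: tuple[float, float, float]


def morphometrics(
    spheroid_mask: np.ndarray, voxel_size: tuple[float, float, float]
) -> SpheroidMorphometrics:
    """Geometric summary of a binary structure mask.

    If the mask has several connected components the largest is analysed
    and a warning is issued.
    """
    mask = np.asarray(spheroid_mask) > 0
    if not mask.any():
        raise ValueError("empty spheroid mask")
    vs = np.asarray(voxel_size, float)
    lab, n = ndi.label(mask)
    if n > 1:
        warnings.warn(f"spheroid mask has {n} connected components; analysing the largest")
        sizes = ndi.sum_labels(mask, lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    volume = float(mask.sum() * np.prod(vs))

    # light Gaussian smoothing before isosurfacing suppresses the voxel
    # staircase that otherwise inflates the area of smooth surfaces by ~8%
    padded = np.pad(mask.astype(np.float32), 4)
    smoothed = ndi.gaussian_filter(padded, sigma=1.0)
    verts, faces, _, _ = measure.marching_cubes(smoothed, level=0.5, spacing=tuple(vs))
    area = float(measure.mesh_surface_area(verts, faces))

    idx = np.argwhere(mask).astype(float) * vs
    centroid = idx.mean(axis=0)
    cov = np.cov((idx - centroid).T)
    evals = np.sort(np.linalg.eigvalsh(cov))
    ellipticity = float(np.sqrt(evals[-1] / evals[0])) if evals[0] > 0 else np.inf

    eq_radius = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    sphericity = float(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area)
    return SpheroidMorphometrics(
        volume_um3=volume,
        surface_area_um2=area,
        equivalent_radius_um=float(eq_radius),
        ellipticity=ellipticity,
        sphericity=sphericity,
        centroid_um=tuple(centroid),
    )


def lumen_topology(
    lumen_mask: np.ndarray,
    voxel_size: tuple[float, float, float],
    min_lumen_volume_um3: float = 30.0,
) -> tuple[int, pd.DataFrame, str]:
    """Count lumens (connected components above a volume filter) and classify.

    Returns ``(count, per-lumen table, class)`` with class ``none``,
    ``single``, or ``multi`` for 0, 1, or >= 2 lumens.
    """
    mask = np.asarray(lumen_mask) > 0
    vs = np.asarray(voxel_size, float)
    voxvol = float(np.prod(vs))
    lab, n = ndi.label(mask)
    rows = []
    for i in range(1, n + 1):
        comp = lab == i
        vol = float(comp.sum() * voxvol)
        if vol < min_lumen_volume_um3:
            continue
        centroid = tuple((np.argwhere(comp).mean(axis=0) * vs).tolist())
        rows.append({"lumen_id": len(rows) + 1, "volume_um3": vol, "centroid_um": centroid})
    count = len(rows)
    cls = "none" if count == 0 else ("single" if count == 1 else "multi")
    return count, pd.DataFrame(rows, columns=["lumen_id", "volume_um3", "centroid_um"]), cls


def norm_lumen_distance(
    nucleus_centroid_um: np.ndarray,
    lumen_centroid_um: np.ndarray,
    equivalent_radius_um: float,
) -> float:
    """Nucleus-to-lumen-centre distance divided by the equivalent spheroid radius."""
    if equivalent_radius_um <= 0:
        raise ValueError("equivalent radius must be positive")
    d = float(np.linalg.norm(np.asarray(nucleus_centroid_um, float) - np.asarray(lumen_centroid_um, float)))
    return d / float(equivalent_radius_um)


def nearest_lumen_surface_distance(
    nucleus_centroid_um: np.ndarray,
    lumen_mask: np.ndarray,
    voxel_size: tuple[float, float, float],
) -> float:
    """Minimum physical distance from a nucleus centroid to the lumen boundary."""
    mask = np.asarray(lumen_mask) > 0
    if not mask.any():
        raise ValueError("no lumen: surface distance undefined")
    vs = np.asarray(voxel_size, float)
    boundary = mask & ~ndi.binary_erosion(mask, border_value=0)
    pts = np.argwhere(boundary).astype(float) * vs
    d, _ = cKDTree(pts).query(np.asarray(nucleus_centroid_um, float), workers=1)
    return float(d)


def classify_delamination(
    cells: np.ndarray,
    lumen_mask: np.ndarray,
    contact_tolerance: int = 1,
    mitotic_ids: set[int] | None = None,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[pd.DataFrame, float | None]:
    """Per-cell lumen contact and the per-structure delaminated fraction.

    A cell is in contact iff any of its voxels lies within
    `contact_tolerance` voxels (Chebyshev) of a lumen voxel.  Non-contacting
    cells adjacent to a mitotic cell that sits between them and the lumen
    (the mitotic cell's centroid is nearer the lumen) are excluded from the
    delaminated count, mirroring the rule that cells underneath apically
    dividing cells are not scored.  Structures without a lumen return
    contact flags of NA and no fraction.
    """
    cells = np.asarray(cells)
    lum = np.asarray(lumen_mask) > 0
    if cells.shape != lum.shape:
        raise ValueError("cells and lumen masks must share one grid")
    mitotic_ids = set(int(i) for i in (mitotic_ids or ()))
    ids = [int(i) for i in np.unique(cells[cells > 0])]
    if not lum.any():
        df = pd.DataFrame(
            {
                "cell_id": ids,
                "lumen_contact": pd.array([pd.NA] * len(ids), dtype="boolean"),
                "excluded_mitotic_shadow": False,
                "mitotic": [i in mitotic_ids for i in ids],
            }
        )
        return df, None

    size = 2 * int(contact_tolerance) + 1
    near_lumen = ndi.maximum_filter(lum.astype(np.uint8), size=size).astype(bool)
    contact_ids = set(int(i) for i in np.unique(cells[near_lumen]) if i > 0)

    vs = np.asarray(voxel_size, float)
    dist = ndi.distance_transform_edt(~lum, sampling=vs)
    centdist = {
        i: float(dist[tuple(np.round(ndi.center_of_mass(cells == i)).astype(int))]) for i in ids
    }

    # adjacency between cell masks (within 1 voxel)
    grown = {i: ndi.binary_dilation(cells == i) for i in ids if i in mitotic_ids}
    rows = []
    for i in ids:
        contact = i in contact_ids
        excluded = False
        if not contact:
            for m, gm in grown.items():
                if m != i and (gm & (cells == i)).any() and centdist[m] < centdist[i]:
                    excluded = True
                    break
        rows.append(
            {
                "cell_id": i,
                "lumen_contact": contact,
                "excluded_mitotic_shadow": excluded,
                "mitotic": i in mitotic_ids,
            }
        )
    df = pd.DataFrame(rows)
    counted = df[~df.excluded_mitotic_shadow]
    fraction = float((~counted.lumen_contact).sum() / len(counted)) if len(counted) else None
    return df, fraction


def golgi_angle(
    lumen_center: np.ndarray,
    nucleus_com: np.ndarray,
    golgi_com: np.ndarray,
    threshold_deg: float = 60.0,
) -> tuple[float, str]:
    """Angle between the lumen-to-nucleus and nucleus-to-Golgi lines.

    Lines are treated as undirected, so the angle is folded to [0, 90]
    degrees; a perfectly apical Golgi scores 0.  Cells are unpolarized iff
    the angle strictly exceeds the threshold (default 60 degrees).
    """
    L = np.asarray(lumen_center, float)
    N = np.asarray(nucleus_com, float)
    G = np.asarray(golgi_com, float)
    v1 = N - L
    v2 = G - N
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("coincident points: Golgi angle undefined")
    cosang = abs(float(np.dot(v1, v2)) / (n1 * n2))
    angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    cls = "unpolarized" if angle > threshold_deg else "polarized"
    return angle, cls


def per_spheroid_fractions(
    cell_table: pd.DataFrame,
    plane: int | None = None,
    positive_col: str = "marker_class",
    mitotic_col: str | None = None,
    plane_col: str = "plane",
) -> dict:
    """Positive-cell fraction (and optionally mitotic index) on one plane.

    With ``plane=None`` all cells are counted (3D mode); otherwise only
    cells assigned to the designated z-plane.  Denominators are reported.
    """
    df = cell_table
    if plane is not None:
        if plane_col not in df.columns:
            raise KeyError(f"cell table lacks a {plane_col!r} column for plane selection")
        df = df[df[plane_col] == plane]
    n = len(df)
    if n == 0:
        raise ValueError("zero cells on the designated plane")
    out = {
        "n_cells": int(n),
        "plane": plane,
        "fraction_positive": float(df[positive_col].astype(bool).sum() / n),
    }
    if mitotic_col is not None and mitotic_col in df.columns:
        out["mitotic_index"] = float(df[mitotic_col].astype(bool).sum() / n)
    return out


def circularity_2d(mask_plane: np.ndarray) -> float:
    """``4 pi A / P^2`` of the largest object on a 2D plane, in (0, 1].

    The perimeter is the 4-direction Crofton estimate, which is unbiased
    for smooth outlines (a digitised disk scores ~0.99); for 1-pixel-thin
    or sharply angular objects it under-reads the perimeter and inflates
    circularity by up to ~20%.  The area is the pixel count.
    """
    mask = np.asarray(mask_plane) > 0
    if mask.ndim != 2:
        raise ValueError("circularity_2d expects a single 2D plane")
    if not mask.any():
        raise ValueError("empty mask")
    lab, n = ndi.label(mask)
    if n > 1:
        sizes = ndi.sum_labels(mask, lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    area = float(mask.sum())
    perimeter = float(measure.perimeter_crofton(mask, directions=4))
    return float(min(1.0, 4.0 * np.pi * area / perimeter**2))
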