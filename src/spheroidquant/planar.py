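"""2D-plane analyses: embryo ROI densities, chimera contribution, marker
area, epiblast length, and field-level positive-cell counting.

ROIs are polygon annotations supplied as input (drawn on the DAPI or
Brachyury channel).  Counting uses nucleus-centroid membership in the
polygon; area-based fractions use pixel intersection with the rasterised
polygon — the two procedures the source measurements distinguish.
Connected components use 8-connectivity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from shapely.geometry import Point, Polygon
from skimage.draw import polygon2mask


@dataclass
class RoiSpec:
    """A named polygon ROI with the z-planes it applies to.

    Vertices are (row, col) pixel coordinates; the polygon must be simple.
    """

    roi_id: str
    polygon: np.ndarray
    planes: list[int] = field(default_factory=lambda: [0])

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, float)
        if self.polygon.ndim != 2 or self.polygon.shape[0] < 3 or self.polygon.shape[1] != 2:
            raise ValueError("polygon must be an (n >= 3, 2) vertex array")
        if not Polygon(self.polygon).is_simple:
            raise ValueError(f"ROI {self.roi_id!r}: polygon is self-intersecting")

    @property
    def shapely(self) -> Polygon:
        return Polygon(self.polygon)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        return polygon2mask(shape, self.polygon)

    def area_um2(self, pixel_size_um: float) -> float:
        return float(self.shapely.area * pixel_size_um**2)


def load_rois(path: str | Path) -> list[RoiSpec]:
    """Read ROI polygons from a JSON list of {roi_id, polygon, planes}."""
    with open(path) as fh:
        raw = json.load(fh)
    return [RoiSpec(r["roi_id"], np.asarray(r["polygon"]), list(r.get("planes", [0]))) for r in raw]


def _as_stack(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    return arr[None] if arr.ndim == 2 else arr


def roi_cell_density(
    nuclei_labels: np.ndarray,
    roi: RoiSpec,
    pixel_size_um: float,
) -> tuple[float, list[float]]:
    """Nuclei-centroid count per ROI area (cells um^-2), averaged over planes."""
    stack = _as_stack(nuclei_labels)
    area = roi.area_um2(pixel_size_um)
    if area <= 0:
        raise ValueError("ROI of zero area")
    poly = roi.shapely
    per_plane = []
    for z in roi.planes:
        lab = stack[z]
        ids = np.unique(lab[lab > 0])
        if ids.size:
            centroids = ndi.center_of_mass(lab > 0, lab, ids)
            n = sum(poly.covers(Point(cy, cx)) for cy, cx in centroids)
        else:
            n = 0
        per_plane.append(n / area)
    return float(np.mean(per_plane)), per_plane


def contribution_fraction(
    nuclei_mask: np.ndarray,
    gfp_mask: np.ndarray,
    roi: RoiSpec,
) -> tuple[float, list[float]]:
    """Area of GFP+ nuclei over area of all nuclei inside the ROI, per plane.

    The GFP mask is intersected with the nuclei mask; the plane-averaged
    fraction is returned together with per-plane values.  Planes without
    nuclei in the ROI are flagged NaN and excluded from the average.
    """
    nuc = _as_stack(nuclei_mask) > 0
    gfp = _as_stack(gfp_mask) > 0
    if nuc.shape != gfp.shape:
        raise ValueError("nuclei and GFP masks must share one grid")
    roi_mask = roi.mask(nuc.shape[1:])
    per_plane = []
    for z in roi.planes:
        denom = int((nuc[z] & roi_mask).sum())
        if denom == 0:
            per_plane.append(np.nan)
            continue
        num = int((gfp[z] & nuc[z] & roi_mask).sum())
        per_plane.append(num / denom)
    finite = [v for v in per_plane if np.isfinite(v)]
    if not finite:
        raise ValueError(f"ROI {roi.roi_id!r}: no nuclei in any analysed plane")
    return float(np.mean(finite)), per_plane


def marker_area(
    marker_mask: np.ndarray,
    planes: list[int],
    pixel_area_um2: float,
) -> float:
    """Plane-averaged area of a binary marker mask, in um^2."""
    stack = _as_stack(marker_mask) > 0
    vals = [float(stack[z].sum() * pixel_area_um2) for z in planes]
    return float(np.mean(vals))


def epiblast_length(
    endpoint_proximal: tuple[float, float],
    endpoint_distal: tuple[float, float],
    pixel_size_um: float,
) -> float:
    """Euclidean distance between two annotated endpoints, in um."""
    p = np.asarray(endpoint_proximal, float)
    d = np.asarray(endpoint_distal, float)
    if np.allclose(p, d):
        raise ValueError("coincident endpoints")
    return float(np.linalg.norm(p - d) * pixel_size_um)


def count_positive_field(
    nuclei_mask: np.ndarray,
    marker_mask: np.ndarray,
    min_object_px: int = 20,
    overlap_threshold: float = 0.5,
) -> tuple[float, int, int]:
    """Fraction of nuclei overlapping the marker mask by more than 50%.

    Nuclei are 8-connected components of the binary nuclear mask with at
    least `min_object_px` pixels.  Returns (fraction, n_positive, n_total).
    """
    nuc = np.asarray(nuclei_mask) > 0
    mark = np.asarray(marker_mask) > 0
    if nuc.ndim != 2:
        raise ValueError("expects a single 2D field")
    if nuc.shape != mark.shape:
        raise ValueError("masks must share one grid")
    lab, n = ndi.label(nuc, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        raise ValueError("zero nuclei in field")
    sizes = ndi.sum_labels(nuc, lab, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_object_px) + 1
    if keep.size == 0:
        raise ValueError("zero nuclei above the size filter")
    overlap = ndi.sum_labels(mark.astype(float), lab, index=keep)
    positive = int((overlap / sizes[keep - 1] > overlap_threshold).sum())
    total = int(keep.size)
    return positive / total, positive, total
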