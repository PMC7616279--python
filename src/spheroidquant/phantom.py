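"""Seeded synthetic phantoms: spheroids, microcavity structures, embryo planes.

Each generator emits a multi-channel :class:`~spheroidquant.imgio.VoxelImage`,
a co-registered :class:`~spheroidquant.imgio.LabelSet`, and a
:class:`GroundTruth` record of every planted quantity, so downstream
measurements can be validated against construction rather than against
other image-analysis code.

The spheroid phantom is an epithelial monolayer of wedge-shaped cells
(spherical Voronoi of seed directions on the shell) around a central lumen,
with optional basally delaminated cells attached outside the monolayer.
Per-cell marker expression is log-normal; per-plane additive background
``b_z`` and multiplicative depth attenuation ``a_z`` emulate the imaging
artefacts the normalisation chain is designed to remove.  Attenuation is
applied to every fluorescence channel, which is what makes the planar DAPI
mean an informative depth reference.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .imgio import LabelSet, VoxelImage

# rendered signal amplitudes (arbitrary fluorescence units)
DAPI_LEVEL = 150.0
MEMBRANE_LEVEL = 120.0
LUMEN_RIM_LEVEL = 130.0
MARKER_BASELINE = 30.0
CYTO_BASELINE = 25.0
GFP_LEVEL = 140.0

SPHEROID_CHANNELS = {
    0: "dapi",
    1: "membrane",
    2: "lumen_marker",
    3: "nuclear_marker",
    4: "cytoplasmic_marker",
}
PLANE2D_CHANNELS = {0: "dapi", 1: "gfp", 2: "nuclear_marker"}


@dataclass
class PhantomSpec:
    """Parameters of a synthetic structure.

    Geometry-specific fields are ignored by the other generators.  All
    lengths are micrometres; the default voxel grid is isotropic 1 um.
    """

    geometry: str = "spheroid"
    seed: int = 0
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sd: float = 2.0
    background: float = 20.0  # mean additive offset; b_z varies per plane
    dapi_attenuation: float = 0.01  # per-um depth decay rate; a_z = exp(-rate * z_um)
    expression_cv: float = 0.15  # sd of ln(per-cell marker expression)

    # spheroid geometry
    spheroid_radius_um: float = 25.0
    lumen_radii_um: tuple[float, ...] = (10.0,)
    n_cells: int = 40
    n_delaminated: int = 3
    marker_positive_frac: float = 0.15
    marker_positive_ids: tuple[int, ...] | None = None
    m_plus: float = 4.0  # nuclear-marker multiplier of planted positives
    cyto_positive_frac: float = 0.0
    cyto_multiplier: float = 2.0
    golgi_lateral_frac: float = 0.2

    # microcavity geometry
    box_um: tuple[float, float, float] = (50.0, 200.0, 50.0)  # (z, y, x)
    long_axis: str = "y"
    lumen_span_frac: float = 0.6
    lumen_halfwidth_um: float = 10.0
    side_density: float = 2.0e-4  # cells per um^3 in side regions
    tip_side_ratio: float = 2.0
    marker_positive_region: str | None = None  # e.g. "tip": positives planted there only

    # 2D embryo plane
    plane_shape_px: tuple[int, int] = (300, 400)  # (y, x)
    pixel_size_um: float = 1.0
    anterior_roi: tuple[int, int, int, int] = (20, 280, 20, 170)  # (y0, y1, x0, x1)
    posterior_roi: tuple[int, int, int, int] = (20, 280, 230, 380)
    anterior_density: float = 1.0e-3  # cells per um^2
    posterior_density: float = 1.5e-3
    gfp_frac_anterior: float = 0.1
    gfp_frac_posterior: float = 0.4
    marker_area_um2: float = 900.0
    nucleus_radius_px: int = 3

    def __post_init__(self) -> None:
        if self.geometry not in ("spheroid", "microcavity", "plane2d"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.n_delaminated > self.n_cells:
            raise ValueError("n_delaminated exceeds n_cells")
        if self.m_plus <= 1:
            raise ValueError("marker-positive multiplier must exceed 1")
        if self.dapi_attenuation < 0:
            raise ValueError("attenuation rate must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown phantom spec fields: {sorted(unknown)}")
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                if isinstance(v, list):
                    v = tuple(v)
                kwargs[f.name] = v
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """Planted truth emitted alongside a phantom.

    ``cells`` is a per-cell table (cell_id, lumen_contact, delaminated,
    marker_positive, golgi_class, region, norm_lumen_distance, centroids,
    per-cell expression).  Per-plane vectors ``b_z``/``a_z`` and structure
    aggregates are stored directly.  ``extra_masks`` holds auxiliary binary
    masks (GFP nuclei, marker region) that have no slot in LabelSet.
    """

    cells: pd.DataFrame
    b_z: np.ndarray
    a_z: np.ndarray
    lumen_count: int
    spheroid_volume_um3: float
    lumen_centroid: tuple[float, float, float] | None = None
    equivalent_radius_um: float | None = None
    region_truth: dict | None = None
    roi_truth: dict | None = None
    extra_masks: dict[str, np.ndarray] = field(default_factory=dict)
    n_clipped_voxels: int = 0

    def to_json_dict(self) -> dict:
        return {
            "cells": self.cells.to_dict(orient="records"),
            "b_z": np.asarray(self.b_z, float).tolist(),
            "a_z": np.asarray(self.a_z, float).tolist(),
            "lumen_count": int(self.lumen_count),
            "spheroid_volume_um3": float(self.spheroid_volume_um3),
            "lumen_centroid": None
            if self.lumen_centroid is None
            else [float(v) for v in self.lumen_centroid],
            "equivalent_radius_um": None
            if self.equivalent_radius_um is None
            else float(self.equivalent_radius_um),
            "region_truth": self.region_truth,
            "roi_truth": self.roi_truth,
            "n_clipped_voxels": int(self.n_clipped_voxels),
        }

    def save_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1, default=float)


def generate(spec: PhantomSpec) -> tuple[VoxelImage, LabelSet, GroundTruth]:
    """Dispatch on ``spec.geometry``."""
    if spec.geometry == "spheroid":
        return make_spheroid_phantom(spec)
    if spec.geometry == "microcavity":
        return make_microcavity_phantom(spec)
    return make_embryo_plane_phantom(spec)


# ---------------------------------------------------------------- helpers


def _fibonacci_sphere(n: int, rng: np.random.Generator) -> np.ndarray:
    """n quasi-uniform unit vectors, randomly rotated (seeded)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5**0.5) * i
    z = 1 - 2 * i / n
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    pts = np.stack([z, r * np.sin(phi), r * np.cos(phi)], axis=1)
    # random rotation via QR of a Gaussian matrix
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return pts @ q.T


def _rotate_about(v: np.ndarray, axis: np.ndarray, theta: float) -> np.ndarray:
    """Rodrigues rotation of vector v about unit axis by theta radians."""
    axis = axis / np.linalg.norm(axis)
    return (
        v * np.cos(theta)
        + np.cross(axis, v) * np.sin(theta)
        + axis * np.dot(axis, v) * (1 - np.cos(theta))
    )


def _perpendicular(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    while True:
        w = rng.normal(size=3)
        w -= u * np.dot(w, u)
        n = np.linalg.norm(w)
        if n > 1e-8:
            return w / n


def _plane_fields(
    n_planes: int, dz_um: float, spec: PhantomSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    b_z = spec.background * rng.uniform(0.7, 1.3, size=n_planes)
    a_z = np.exp(-spec.dapi_attenuation * dz_um * np.arange(n_planes))
    return b_z, a_z


def _finish_image(
    channels: np.ndarray,
    signal_mask_scale: np.ndarray,
    b_z: np.ndarray,
    spec: PhantomSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Apply depth attenuation, per-plane background, noise, and clipping."""
    out = channels * signal_mask_scale[None, :, None, None]
    out += b_z[None, :, None, None]
    if spec.noise_sd > 0:
        out += rng.normal(0.0, spec.noise_sd, size=out.shape)
    n_clip = int(np.count_nonzero(out < 0))
    np.clip(out, 0.0, None, out=out)
    return out.astype(np.float32), n_clip


def _ellipsoid_mask(shape, center, semi_axes, voxel_size) -> np.ndarray:
    zz, yy, xx = np.meshgrid(
        (np.arange(shape[0]) * voxel_size[0] - center[0]) / semi_axes[0],
        (np.arange(shape[1]) * voxel_size[1] - center[1]) / semi_axes[1],
        (np.arange(shape[2]) * voxel_size[2] - center[2]) / semi_axes[2],
        indexing="ij",
    )
    return zz * zz + yy * yy + xx * xx <= 1.0


def _centroid_um(mask: np.ndarray, voxel_size) -> np.ndarray:
    idx = np.argwhere(mask)
    return idx.mean(axis=0) * np.asarray(voxel_size)


# ---------------------------------------------------------- spheroid


def make_spheroid_phantom(spec: PhantomSpec) -> tuple[VoxelImage, LabelSet, GroundTruth]:
    """Render a lumen-bearing spheroid with planted per-cell truth."""
    if spec.geometry != "spheroid":
        raise ValueError("spec.geometry must be 'spheroid'")
    rng = np.random.default_rng(spec.seed)
    vs = np.asarray(spec.voxel_size, float)
    R = spec.spheroid_radius_um
    lumen_radii = tuple(spec.lumen_radii_um)

    delam_r = 3.2  # delaminated cell radius, um
    margin = 2.0
    half = R + (2 * delam_r + margin if spec.n_delaminated else margin)
    shape = tuple(int(np.ceil(2 * half / vs[a])) + 1 for a in range(3))
    center = np.array([(s - 1) * v / 2 for s, v in zip(shape, vs)])

    coords = [np.arange(shape[a]) * vs[a] - center[a] for a in range(3)]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    rr = np.sqrt(zz * zz + yy * yy + xx * xx)

    # lumens: first centred, further ones offset inside the core
    lumen = np.zeros(shape, dtype=np.uint16)
    lumen_centers: list[np.ndarray] = []
    for k, lr in enumerate(lumen_radii):
        if len(lumen_radii) == 1:
            c = np.zeros(3)
        else:
            reach = 0.55 * R - lr
            if reach < 0:
                raise ValueError("lumen too large for multi-lumen placement")
            for _ in range(2000):
                c = rng.uniform(-reach, reach, size=3)
                if np.linalg.norm(c) + lr >= 0.55 * R:
                    continue
                if all(
                    np.linalg.norm(c - pc) > lr + pr + 1.0
                    for pc, pr in zip(lumen_centers, lumen_radii)
                ):
                    break
            else:
                raise ValueError("could not place lumens without overlap")
        lumen_centers.append(c)
        d = np.sqrt((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2)
        lumen[d <= lr] = k + 1

    shell_inner = max((np.linalg.norm(c) + lr for c, lr in zip(lumen_centers, lumen_radii)), default=0.3 * R)
    if shell_inner >= R - 4.0:
        raise ValueError("lumens too large for the requested spheroid radius")

    n_mono = spec.n_cells - spec.n_delaminated
    if n_mono < 1:
        raise ValueError("need at least one monolayer cell")
    # feasibility: each wedge needs room for a nucleus
    r_nuc_pos = shell_inner + 0.6 * (R - shell_inner)
    mean_spacing = np.sqrt(4 * np.pi / n_mono) * r_nuc_pos
    if mean_spacing < 4.6:
        raise ValueError(f"infeasible packing: {spec.n_cells} cells on a radius-{R} shell")

    dirs = _fibonacci_sphere(n_mono, rng)

    # wedge cells: every shell voxel goes to the angularly nearest seed
    shell = (rr > shell_inner) & (rr <= R) & (lumen == 0)
    cells = np.zeros(shape, dtype=np.uint16)
    pts = np.stack([zz[shell], yy[shell], xx[shell]], axis=1)
    unit = pts / np.linalg.norm(pts, axis=1, keepdims=True)
    _, nearest = cKDTree(dirs).query(unit, workers=1)
    cells[shell] = nearest.astype(np.uint16) + 1

    # nuclei: axis-aligned ellipsoids at 60% radial depth, clipped to the own cell
    nuclei = np.zeros(shape, dtype=np.uint16)
    semi = np.array([2.8, 2.2, 2.2])
    nucleus_centroids: dict[int, np.ndarray] = {}
    for i, u in enumerate(dirs):
        cid = i + 1
        c = u * r_nuc_pos + center
        ell = _ellipsoid_mask(shape, c, semi, vs) & (cells == cid)
        nuclei[ell] = cid
        if not ell.any():
            raise ValueError("nucleus rendering failed (cell too thin)")
        nucleus_centroids[cid] = _centroid_um(ell, vs) - center

    spheroid = (rr <= R) | (lumen > 0)

    # delaminated cells: spheres attached outside the monolayer
    delam_ids: list[int] = []
    delam_dirs: list[np.ndarray] = []
    for j in range(spec.n_delaminated):
        for _ in range(500):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            if all(np.dot(u, w) < np.cos(2.6 * delam_r / R) for w in delam_dirs):
                break
        else:
            raise ValueError("could not place delaminated cells without overlap")
        delam_dirs.append(u)
        cid = n_mono + j + 1
        c = u * (R + delam_r - 0.5) + center
        body = _ellipsoid_mask(shape, c, (delam_r,) * 3, vs) & (rr > R)
        cells[body] = cid
        spheroid |= body
        nuc = _ellipsoid_mask(shape, c, (2.0, 2.0, 2.0), vs) & body
        nuclei[nuc] = cid
        if not nuc.any():
            raise ValueError("delaminated nucleus rendering failed")
        nucleus_centroids[cid] = _centroid_um(nuc, vs) - center
        delam_ids.append(cid)

    all_ids = list(range(1, spec.n_cells + 1))

    # planted marker positives
    if spec.marker_positive_ids is not None:
        pos_ids = set(int(i) for i in spec.marker_positive_ids)
    else:
        n_pos = int(round(spec.marker_positive_frac * spec.n_cells))
        pos_ids = set(rng.choice(all_ids, size=n_pos, replace=False).tolist()) if n_pos else set()

    # per-cell log-normal expression
    expr = np.exp(rng.normal(0.0, spec.expression_cv, size=spec.n_cells))
    cyto_pos = set()
    if spec.cyto_positive_frac > 0:
        n_cp = int(round(spec.cyto_positive_frac * spec.n_cells))
        cyto_pos = set(rng.choice(all_ids, size=n_cp, replace=False).tolist())

    # Golgi: apical (toward nearest lumen centre) with <=30 deg jitter, or
    # lateral (70-90 deg) for a planted subset
    n_lat = int(round(spec.golgi_lateral_frac * n_mono))
    lateral_ids = set(rng.choice(range(1, n_mono + 1), size=n_lat, replace=False).tolist()) if n_lat else set()
    golgi: dict[int, tuple[np.ndarray, str]] = {}
    if lumen_centers:
        for cid in range(1, n_mono + 1):
            N = nucleus_centroids[cid]
            L = min(lumen_centers, key=lambda c: np.linalg.norm(N - c))
            apical = (L - N) / np.linalg.norm(L - N)
            perp = _perpendicular(apical, rng)
            if cid in lateral_ids:
                theta = np.deg2rad(rng.uniform(70.0, 90.0))
                cls = "unpolarized"
            else:
                theta = np.deg2rad(rng.uniform(0.0, 30.0))
                cls = "polarized"
            g_dir = _rotate_about(apical, perp, theta)
            golgi[cid] = (N + 2.5 * g_dir, cls)

    # channels (pre-attenuation signal)
    chans = np.zeros((5,) + shape, dtype=np.float64)
    chans[0][nuclei > 0] = DAPI_LEVEL
    from scipy import ndimage as ndi

    boundary = (ndi.maximum_filter(cells, size=3) != ndi.minimum_filter(cells, size=3)) & spheroid
    chans[1][boundary] = MEMBRANE_LEVEL
    rim = ndi.binary_dilation(lumen > 0) & (lumen == 0)
    chans[2][rim] = LUMEN_RIM_LEVEL
    for cid in all_ids:
        nuc = nuclei == cid
        level = MARKER_BASELINE * expr[cid - 1]
        if cid in pos_ids:
            level *= spec.m_plus
        chans[3][nuc] = level
        cyto = (cells == cid) & ~nuc
        clevel = CYTO_BASELINE * (spec.cyto_multiplier if cid in cyto_pos else 1.0)
        chans[4][cyto] = clevel

    b_z, a_z = _plane_fields(shape[0], vs[0], spec, rng)
    data, n_clip = _finish_image(chans, a_z, b_z, spec, rng)

    # truth table
    sph_vol = float(spheroid.sum() * np.prod(vs))
    eq_radius = (3 * sph_vol / (4 * np.pi)) ** (1 / 3)
    lumen_centroid = _centroid_um(lumen > 0, vs) - center if lumen_centers else None
    # lumen contact from construction: monolayer wedges touch the single
    # central lumen surface; verified independently via distance transform
    if lumen_centers:
        dist_to_lumen = ndi.distance_transform_edt(lumen == 0, sampling=vs)
    rows = []
    for cid in all_ids:
        N = nucleus_centroids[cid]
        if lumen_centers:
            contact = bool(dist_to_lumen[cells == cid].min() <= 1.5 * max(vs))
            nld = float(np.linalg.norm(N - lumen_centroid) / eq_radius)
        else:
            contact = False
            nld = np.nan
        g = golgi.get(cid)
        rows.append(
            {
                "cell_id": cid,
                "delaminated": cid in delam_ids,
                "lumen_contact": contact,
                "marker_positive": cid in pos_ids,
                "cyto_positive": cid in cyto_pos,
                "expression": float(expr[cid - 1]),
                "golgi_class": g[1] if g else "",
                "golgi_z": float(g[0][0]) if g else np.nan,
                "golgi_y": float(g[0][1]) if g else np.nan,
                "golgi_x": float(g[0][2]) if g else np.nan,
                "nucleus_z": float(N[0]),
                "nucleus_y": float(N[1]),
                "nucleus_x": float(N[2]),
                "norm_lumen_distance": nld,
                "region": "none",
            }
        )
    truth = GroundTruth(
        cells=pd.DataFrame(rows),
        b_z=b_z,
        a_z=a_z,
        lumen_count=len(lumen_centers),
        spheroid_volume_um3=sph_vol,
        lumen_centroid=tuple(lumen_centroid) if lumen_centroid is not None else None,
        equivalent_radius_um=eq_radius,
        n_clipped_voxels=n_clip,
    )
    for c in delam_ids:
        assert not truth.cells.loc[truth.cells.cell_id == c, "lumen_contact"].item()
    img = VoxelImage(data, tuple(vs), dict(SPHEROID_CHANNELS))
    labels = LabelSet(nuclei=nuclei, cells=cells, spheroid=spheroid.astype(np.uint16), lumen=lumen)
    return img, labels, truth


# ------------------------------------------------------- microcavity


def make_microcavity_phantom(spec: PhantomSpec) -> tuple[VoxelImage, LabelSet, GroundTruth]:
    """Elongated structure in a microcavity box with a planted tip:side density ratio."""
    if spec.geometry != "microcavity":
        raise ValueError("spec.geometry must be 'microcavity'")
    rng = np.random.default_rng(spec.seed)
    vs = np.asarray(spec.voxel_size, float)
    axis = {"z": 0, "y": 1, "x": 2}[spec.long_axis]
    # assign the longest requested extent to the requested long axis
    extents = sorted(spec.box_um, reverse=True)
    box = np.empty(3)
    box[axis] = extents[0]
    for a, v in zip([a for a in range(3) if a != axis], extents[1:]):
        box[a] = v
    margin = 2.0
    shape = tuple(int(np.ceil((box[a] + 2 * margin) / vs[a])) + 1 for a in range(3))
    center = np.array([(s - 1) * v / 2 for s, v in zip(shape, vs)])
    coords = [np.arange(shape[a]) * vs[a] - center[a] for a in range(3)]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    P = np.stack([zz, yy, xx])

    half = box / 2
    spheroid = np.all(np.abs(P) <= half[:, None, None, None], axis=0)

    # elongated lumen spanning the middle `lumen_span_frac` of the long axis
    lhalf = np.array([min(half[a] - 4.0, spec.lumen_halfwidth_um) for a in range(3)])
    lhalf[axis] = half[axis] * spec.lumen_span_frac
    lumen_mask = np.all(np.abs(P) <= lhalf[:, None, None, None], axis=0)
    lumen = lumen_mask.astype(np.uint16)

    lo, hi = -lhalf[axis], lhalf[axis]
    proj = P[axis]
    tip = spheroid & ((proj > hi) | (proj < lo))
    side = spheroid & ~tip
    voxvol = float(np.prod(vs))
    v_tip, v_side = float(tip.sum() * voxvol), float(side.sum() * voxvol)

    n_side = int(round(spec.side_density * v_side))
    n_tip = int(round(spec.tip_side_ratio * spec.side_density * v_tip))

    from scipy import ndimage as ndi

    allowed = ~ndi.binary_dilation(lumen_mask, iterations=2) & ndi.binary_erosion(
        spheroid, iterations=3, border_value=0
    )

    def _sample_centers(region: np.ndarray, n: int, min_sep: float) -> list[np.ndarray]:
        cand = np.argwhere(region & allowed)
        rng.shuffle(cand)
        chosen: list[np.ndarray] = []
        for idx in cand:
            p = idx * vs
            if all(np.linalg.norm(p - q) >= min_sep for q in chosen):
                chosen.append(p)
                if len(chosen) == n:
                    return chosen
        raise ValueError(f"infeasible packing: could not place {n} cells")

    tip_centers = _sample_centers(tip, n_tip, 5.5)
    side_centers = _sample_centers(side, n_side, 5.5)
    centers = tip_centers + side_centers
    regions = ["tip"] * n_tip + ["side"] * n_side
    n_cells = len(centers)

    # Voronoi cells over the structure (outside lumen)
    cells = np.zeros(shape, dtype=np.uint16)
    body = spheroid & ~lumen_mask
    pts = np.argwhere(body) * vs
    _, nearest = cKDTree(np.asarray(centers)).query(pts, workers=1)
    cells[body] = nearest.astype(np.uint16) + 1

    nuclei = np.zeros(shape, dtype=np.uint16)
    nucleus_centroids = {}
    for i, c in enumerate(centers):
        cid = i + 1
        nuc = _ellipsoid_mask(shape, c, (2.2, 2.2, 2.2), vs) & (cells == cid)
        if not nuc.any():
            raise ValueError("nucleus rendering failed")
        nuclei[nuc] = cid
        nucleus_centroids[cid] = _centroid_um(nuc, vs) - center

    pos_ids: set[int] = set()
    if spec.marker_positive_region == "tip":
        pos_ids = {i + 1 for i, r in enumerate(regions) if r == "tip"}
    elif spec.marker_positive_ids is not None:
        pos_ids = set(int(i) for i in spec.marker_positive_ids)
    elif spec.marker_positive_frac > 0:
        n_pos = int(round(spec.marker_positive_frac * n_cells))
        if n_pos:
            pos_ids = set(rng.choice(range(1, n_cells + 1), size=n_pos, replace=False).tolist())

    expr = np.exp(rng.normal(0.0, spec.expression_cv, size=n_cells))
    chans = np.zeros((5,) + shape, dtype=np.float64)
    chans[0][nuclei > 0] = DAPI_LEVEL
    boundary = (ndi.maximum_filter(cells, size=3) != ndi.minimum_filter(cells, size=3)) & spheroid
    chans[1][boundary] = MEMBRANE_LEVEL
    rim = ndi.binary_dilation(lumen_mask) & ~lumen_mask
    chans[2][rim] = LUMEN_RIM_LEVEL
    for cid in range(1, n_cells + 1):
        level = MARKER_BASELINE * expr[cid - 1] * (spec.m_plus if cid in pos_ids else 1.0)
        chans[3][nuclei == cid] = level

    b_z, a_z = _plane_fields(shape[0], vs[0], spec, rng)
    data, n_clip = _finish_image(chans, a_z, b_z, spec, rng)

    rows = []
    for i, (c, reg) in enumerate(zip(centers, regions)):
        cid = i + 1
        N = nucleus_centroids[cid]
        rows.append(
            {
                "cell_id": cid,
                "delaminated": False,
                "lumen_contact": True,
                "marker_positive": cid in pos_ids,
                "cyto_positive": False,
                "expression": float(expr[i]),
                "golgi_class": "",
                "golgi_z": np.nan,
                "golgi_y": np.nan,
                "golgi_x": np.nan,
                "nucleus_z": float(N[0]),
                "nucleus_y": float(N[1]),
                "nucleus_x": float(N[2]),
                "norm_lumen_distance": np.nan,
                "region": reg,
            }
        )
    region_truth = {
        "axis": spec.long_axis,
        "tip_volume_um3": v_tip,
        "side_volume_um3": v_side,
        "n_tip": n_tip,
        "n_side": n_side,
        "tip_density": n_tip / v_tip,
        "side_density": n_side / v_side,
        "planted_ratio": spec.tip_side_ratio,
    }
    truth = GroundTruth(
        cells=pd.DataFrame(rows),
        b_z=b_z,
        a_z=a_z,
        lumen_count=1,
        spheroid_volume_um3=float(spheroid.sum() * voxvol),
        lumen_centroid=tuple(_centroid_um(lumen_mask, vs) - center),
        equivalent_radius_um=(3 * spheroid.sum() * voxvol / (4 * np.pi)) ** (1 / 3),
        region_truth=region_truth,
        n_clipped_voxels=n_clip,
    )
    img = VoxelImage(data, tuple(vs), dict(SPHEROID_CHANNELS))
    labels = LabelSet(nuclei=nuclei, cells=cells, spheroid=spheroid.astype(np.uint16), lumen=lumen)
    return img, labels, truth


# ------------------------------------------------------ embryo plane


def make_embryo_plane_phantom(spec: PhantomSpec) -> tuple[VoxelImage, LabelSet, GroundTruth]:
    """2D plane with anterior/posterior ROIs, planted GFP subset, marker region."""
    if spec.geometry != "plane2d":
        raise ValueError("spec.geometry must be 'plane2d'")
    rng = np.random.default_rng(spec.seed)
    H, W = spec.plane_shape_px
    px = spec.pixel_size_um
    px_area = px * px
    rois = {"anterior": spec.anterior_roi, "posterior": spec.posterior_roi}
    a, p = spec.anterior_roi, spec.posterior_roi
    if not (a[1] <= p[0] or p[1] <= a[0] or a[3] <= p[2] or p[3] <= a[2]):
        raise ValueError("anterior and posterior ROIs overlap")
    for y0, y1, x0, x1 in rois.values():
        if not (0 <= y0 < y1 <= H and 0 <= x0 < x1 <= W):
            raise ValueError("ROI exceeds plane bounds")

    r = spec.nucleus_radius_px
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    disk = (dy * dy + dx * dx) <= r * r

    nuclei = np.zeros((H, W), dtype=np.uint16)
    rows = []
    gfp_ids: set[int] = set()
    roi_truth: dict = {}
    next_id = 1
    for name, (y0, y1, x0, x1) in rois.items():
        area_um2 = (y1 - y0) * (x1 - x0) * px_area
        dens = spec.anterior_density if name == "anterior" else spec.posterior_density
        n = int(round(dens * area_um2))
        frac = spec.gfp_frac_anterior if name == "anterior" else spec.gfp_frac_posterior
        n_gfp = int(round(frac * n))
        # integer centres, identical disk footprints, fully inside the ROI
        centers: list[tuple[int, int]] = []
        for _ in range(20000):
            cy = int(rng.integers(y0 + r + 1, y1 - r - 1))
            cx = int(rng.integers(x0 + r + 1, x1 - r - 1))
            if all((cy - qy) ** 2 + (cx - qx) ** 2 >= (2 * r + 2) ** 2 for qy, qx in centers):
                centers.append((cy, cx))
                if len(centers) == n:
                    break
        if len(centers) < n:
            raise ValueError(f"infeasible packing: {n} nuclei in ROI {name}")
        ids = list(range(next_id, next_id + n))
        next_id += n
        chosen_gfp = set(rng.choice(ids, size=n_gfp, replace=False).tolist()) if n_gfp else set()
        gfp_ids |= chosen_gfp
        for cid, (cy, cx) in zip(ids, centers):
            nuclei[cy - r : cy + r + 1, cx - r : cx + r + 1][disk] = cid
            rows.append(
                {
                    "cell_id": cid,
                    "delaminated": False,
                    "lumen_contact": False,
                    "marker_positive": False,
                    "cyto_positive": False,
                    "expression": 1.0,
                    "golgi_class": "",
                    "golgi_z": np.nan,
                    "golgi_y": np.nan,
                    "golgi_x": np.nan,
                    "nucleus_z": 0.0,
                    "nucleus_y": float(cy * px),
                    "nucleus_x": float(cx * px),
                    "norm_lumen_distance": np.nan,
                    "region": name,
                }
            )
        roi_truth[name] = {
            "polygon": [[y0, x0], [y0, x1], [y1, x1], [y1, x0]],
            "n_nuclei": n,
            "n_gfp": n_gfp,
            "area_um2": area_um2,
            "density": n / area_um2,
            "gfp_area_fraction": (n_gfp / n) if n else 0.0,
        }

    gfp_mask = np.isin(nuclei, sorted(gfp_ids)) if gfp_ids else np.zeros_like(nuclei, bool)

    # contiguous marker-positive region of planted area inside the posterior ROI
    side_px = int(round(np.sqrt(spec.marker_area_um2 / px_area)))
    y0, y1, x0, x1 = spec.posterior_roi
    my, mx = y0 + 2, x1 - 2 - side_px
    marker_mask = np.zeros((H, W), dtype=bool)
    marker_mask[my : my + side_px, mx : mx + side_px] = True
    marker_area_true = float(marker_mask.sum() * px_area)
    roi_truth["marker_area_um2"] = marker_area_true

    chans = np.zeros((3, H, W))
    chans[0][nuclei > 0] = DAPI_LEVEL
    chans[1][gfp_mask] = GFP_LEVEL
    chans[2][marker_mask] = MARKER_BASELINE * spec.m_plus
    b_z, a_z = _plane_fields(1, spec.voxel_size[0], spec, rng)
    data, n_clip = _finish_image(chans[:, None, :, :], a_z, b_z, spec, rng)

    cells_df = pd.DataFrame(rows)
    cells_df["gfp_positive"] = cells_df["cell_id"].isin(gfp_ids)
    truth = GroundTruth(
        cells=cells_df,
        b_z=b_z,
        a_z=a_z,
        lumen_count=0,
        spheroid_volume_um3=float(H * W * px_area),
        roi_truth=roi_truth,
        extra_masks={"gfp": gfp_mask[None], "marker": marker_mask[None]},
        n_clipped_voxels=n_clip,
    )
    img = VoxelImage(data, (spec.voxel_size[0], px, px), dict(PLANE2D_CHANNELS))
    ones = np.ones((1, H, W), dtype=np.uint16)
    labels = LabelSet(
        nuclei=nuclei[None],
        cells=nuclei[None].copy(),
        spheroid=ones,
        lumen=np.zeros((1, H, W), dtype=np.uint16),
    )
    return img, labels, truth
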