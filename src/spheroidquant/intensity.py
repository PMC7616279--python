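"""Background correction, DAPI normalization, and marker-positivity calls.

The normalization chain for 3D stacks is applied plane by plane:

1. **Background correction** — per z-plane, the background level ``b_z`` is
   the 75th-percentile intensity of pixels inside the spheroid mask but
   outside the nuclear mask; ``b_z`` is subtracted from every pixel of that
   plane.
2. **DAPI normalization** — every background-corrected pixel is divided by
   the mean (background-corrected) DAPI intensity over nuclear-mask pixels
   of its plane, cancelling depth-dependent attenuation.
3. **Batch normalization** — per-cell values, which are approximately
   log-normal, are divided by the geometric mean of their experiment.

Quantiles use sorted linear interpolation at rank ``q * (n - 1)``.
Negative pixels after subtraction are kept by default to preserve
linearity; set ``clip_negative`` to truncate at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class NormalizationParams:
    background_quantile: float = 0.75
    clip_negative: bool = False
    experiment_id: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.background_quantile < 1:
            raise ValueError("background_quantile must lie in (0, 1)")


def background_correct_stack(
    channel: np.ndarray,
    spheroid_mask: np.ndarray,
    nuclei_mask: np.ndarray,
    params: NormalizationParams | None = None,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Subtract the per-plane non-nuclear background from one channel.

    Parameters
    ----------
    channel, spheroid_mask, nuclei_mask
        ``(z, y, x)`` arrays on one grid; masks may be boolean or labelled.

    Returns
    -------
    corrected : float array, same shape
    b_z : per-plane background vector (NaN for skipped planes)
    skipped : indices of planes with no non-nuclear in-spheroid pixels
    """
    params = params or NormalizationParams()
    channel = np.asarray(channel, dtype=float)
    sph = np.asarray(spheroid_mask) > 0
    nuc = np.asarray(nuclei_mask) > 0
    if channel.shape != sph.shape or channel.shape != nuc.shape:
        raise ValueError("channel and masks must share one grid")
    if not sph.any():
        raise ValueError("spheroid mask is empty")
    region = sph & ~nuc
    n_planes = channel.shape[0]
    b_z = np.full(n_planes, np.nan)
    corrected = channel.copy()
    skipped: list[int] = []
    for z in range(n_planes):
        vals = channel[z][region[z]]
        if vals.size == 0:
            skipped.append(z)
            if sph[z].any():
                warnings.warn(f"plane {z}: no non-nuclear spheroid pixels; excluded")
            continue
        b_z[z] = float(np.quantile(vals, params.background_quantile))
        corrected[z] -= b_z[z]
    if params.clip_negative:
        np.clip(corrected, 0.0, None, out=corrected)
    return corrected, b_z, skipped


def dapi_normalize_stack(
    corrected: np.ndarray,
    dapi: np.ndarray,
    nuclei_mask: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Divide each plane by its mean DAPI intensity over nuclear pixels.

    `dapi` should already be background-corrected.  Planes without nuclear
    pixels or with non-positive planar DAPI mean are excluded (set to NaN)
    and reported.
    """
    corrected = np.asarray(corrected, dtype=float)
    dapi = np.asarray(dapi, dtype=float)
    nuc = np.asarray(nuclei_mask) > 0
    if corrected.shape != dapi.shape or corrected.shape != nuc.shape:
        raise ValueError("channel, dapi, and nuclei mask must share one grid")
    n_planes = corrected.shape[0]
    normalized = np.full_like(corrected, np.nan)
    dapi_means = np.full(n_planes, np.nan)
    excluded: list[int] = []
    for z in range(n_planes):
        vals = dapi[z][nuc[z]]
        if vals.size == 0:
            excluded.append(z)
            continue
        m = float(vals.mean())
        if m <= 0:
            warnings.warn(f"plane {z}: non-positive planar DAPI mean; excluded")
            excluded.append(z)
            continue
        dapi_means[z] = m
        normalized[z] = corrected[z] / m
    return normalized, dapi_means, excluded


def nuclear_mean(
    normalized: np.ndarray,
    nuclei_labels: np.ndarray,
    ids: list[int] | None = None,
) -> pd.Series:
    """Mean normalized intensity over each nucleus's voxels (NaN planes skipped)."""
    normalized = np.asarray(normalized, dtype=float)
    lab = np.asarray(nuclei_labels)
    if normalized.shape != lab.shape:
        raise ValueError("channel and label mask must share one grid")
    present = np.unique(lab[lab > 0])
    if ids is None:
        ids = [int(i) for i in present]
    else:
        missing = set(int(i) for i in ids) - set(int(i) for i in present)
        if missing:
            raise KeyError(f"label ids not present in mask: {sorted(missing)}")
    out = {}
    for i in ids:
        vals = normalized[lab == i]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[int(i)] = float(np.nanmean(vals))
    return pd.Series(out, name="nuclear_mean_norm")


def lognorm_batch(values: pd.Series, batch: pd.Series | str) -> tuple[pd.Series, int]:
    """Divide each value by the geometric mean of its batch.

    Non-positive (or NaN) values are excluded from the geometric mean and
    set to NaN in the output; the count of exclusions is returned.  A batch
    with no usable value raises.
    """
    values = pd.Series(values, dtype=float)
    if isinstance(batch, str):
        batch = pd.Series([batch] * len(values), index=values.index)
    batch = pd.Series(batch)
    usable = (values > 0) & np.isfinite(values)
    n_excluded = int((~usable).sum())
    out = pd.Series(np.nan, index=values.index, name="nuclear_mean_batchnorm")
    for b, idx in values.groupby(batch).groups.items():
        v = values.loc[idx]
        ok = usable.loc[idx]
        if not ok.any():
            raise ValueError(f"batch {b!r} has no usable (positive) values")
        gm = float(np.exp(np.log(v[ok]).mean()))
        out.loc[idx[ok]] = v[ok] / gm
    return out, n_excluded


def cyto_mean(
    marker_plane: np.ndarray,
    cells_plane: np.ndarray,
    nuclei_plane: np.ndarray,
    dapi_plane: np.ndarray,
) -> pd.Series:
    """Per-cell cytoplasmic mean on a single representative plane.

    Mean marker intensity over (cell minus nucleus) pixels, divided by the
    mean DAPI intensity over all nuclear pixels of the plane.  Cells fully
    covered by their nucleus on this plane are flagged NaN.
    """
    marker = np.asarray(marker_plane, float)
    cells = np.asarray(cells_plane)
    nuc = np.asarray(nuclei_plane)
    dvals = np.asarray(dapi_plane, float)[nuc > 0]
    if dvals.size == 0:
        raise ValueError("plane has no nuclear pixels for DAPI normalization")
    dapi_mean = float(dvals.mean())
    if dapi_mean <= 0:
        raise ValueError("non-positive planar DAPI mean")
    out = {}
    for cid in np.unique(cells[cells > 0]):
        sel = (cells == cid) & (nuc == 0)
        if not sel.any():
            warnings.warn(f"cell {cid}: fully nuclear on this plane; value undefined")
            out[int(cid)] = np.nan
            continue
        out[int(cid)] = float(marker[sel].mean()) / dapi_mean
    return pd.Series(out, name="cyto_mean_norm")


def classify_marker(
    values: pd.Series,
    method: str = "gmm2",
    threshold: float | None = None,
) -> tuple[pd.Series, float]:
    """Call marker-positive cells from normalized nuclear means.

    ``fixed_threshold`` uses the supplied boundary; ``otsu`` minimises
    intra-class variance; ``gmm2`` fits a two-component Gaussian mixture in
    log space and places the boundary at posterior 0.5.  Returns the boolean
    calls and the decision boundary used.
    """
    values = pd.Series(values, dtype=float)
    finite = values.dropna()
    if len(finite) < 2:
        raise ValueError("need at least 2 cells to classify")
    if method == "fixed_threshold":
        if threshold is None:
            raise ValueError("fixed_threshold requires a threshold")
        boundary = float(threshold)
    elif method == "otsu":
        if float(finite.max() - finite.min()) == 0.0:
            raise ValueError("degenerate (all-equal) values; use fixed_threshold")
        from skimage.filters import threshold_otsu

        # intensities are approximately log-normal: threshold in log space
        # when possible so the two clusters are symmetric
        if (finite > 0).all():
            boundary = float(np.exp(threshold_otsu(np.log(finite.to_numpy()))))
        else:
            boundary = float(threshold_otsu(finite.to_numpy()))
    elif method == "gmm2":
        if float(finite.max() - finite.min()) == 0.0:
            raise ValueError("degenerate (all-equal) values; use fixed_threshold")
        if (finite <= 0).any():
            raise ValueError("gmm2 operates in log space; values must be positive")
        from sklearn.mixture import GaussianMixture

        logv = np.log(finite.to_numpy()).reshape(-1, 1)
        gmm = GaussianMixture(n_components=2, random_state=0, n_init=3).fit(logv)
        lo, hi = np.sort(gmm.means_.ravel())
        grid = np.linspace(lo, hi, 2001).reshape(-1, 1)
        post = gmm.predict_proba(grid)
        upper = int(np.argmax(gmm.means_.ravel()))
        cross = np.argmax(post[:, upper] >= 0.5)
        boundary = float(np.exp(grid[cross, 0]))
    else:
        raise ValueError(f"unknown method {method!r}")
    calls = pd.Series(values > boundary, index=values.index, name="marker_class")
    calls[values.isna()] = False
    return calls, boundary


def split_low_high(values: pd.Series) -> pd.Series:
    """Median split over the pooled dataset: low iff value <= median."""
    values = pd.Series(values, dtype=float)
    finite = values.dropna()
    if len(finite) < 2:
        raise ValueError("need at least 2 values for a median split")
    med = float(finite.median())
    out = pd.Series(
        np.where(values.isna(), None, np.where(values <= med, "low", "high")),
        index=values.index,
        name="level_class",
    )
    return out


def monolayer_correct(
    marker: np.ndarray,
    nuclei_mask: np.ndarray,
    dapi: np.ndarray,
    background_quantile: float = 0.75,
) -> np.ndarray:
    """Two-step background correction and DAPI normalization for a 2D plane.

    Step 1 subtracts the 75th percentile of non-nuclear pixels; step 2
    subtracts the nuclear background level, taken as the median of
    nuclear-mask pixels after step 1 (most nuclei are assumed to sit at
    background-level expression); step 3 divides by the mean raw DAPI
    intensity over nuclear pixels.
    """
    marker = np.asarray(marker, float)
    nuc = np.asarray(nuclei_mask) > 0
    dapi = np.asarray(dapi, float)
    if marker.ndim != 2:
        raise ValueError("monolayer correction expects a single 2D plane")
    if marker.shape != nuc.shape or marker.shape != dapi.shape:
        raise ValueError("plane and masks must share one grid")
    non_nuc = marker[~nuc]
    if non_nuc.size == 0:
        raise ValueError("no non-nuclear pixels")
    if not nuc.any():
        raise ValueError("nuclear mask is empty")
    step1 = marker - float(np.quantile(non_nuc, background_quantile))
    nuclear_bg = float(np.median(step1[nuc]))
    step2 = step1 - nuclear_bg
    dapi_mean = float(dapi[nuc].mean())
    if dapi_mean <= 0:
        raise ValueError("non-positive DAPI mean over nuclei")
    return step2 / dapi_mean
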