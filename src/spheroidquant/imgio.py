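"""Readers/writers for image stacks, label masks, tables, and configuration.

Conventions
-----------
* Axis order is ``(channel, z, y, x)`` for images and ``(z, y, x)`` for
  masks; 2D inputs are represented as single-plane 3D so every downstream
  operation has one code path.
* Coordinates are 0-based voxel indices; physical quantities are derived
  from per-axis voxel sizes in micrometres (z may differ from y/x).
* Label masks are unsigned 16-bit on disk; 0 is always background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

CHANNEL_ROLES = frozenset(
    {
        "dapi",
        "membrane",
        "lumen_marker",
        "nuclear_marker",
        "cytoplasmic_marker",
        "gfp",
        "other",
    }
)


@dataclass
class VoxelImage:
    """Multi-channel intensity stack with physical voxel sizes.

    Parameters
    ----------
    data
        Array indexed ``(channel, z, y, x)``; 2D data ``(channel, y, x)``
        is promoted to a single z-plane on construction.
    voxel_size
        Physical size per spatial axis ``(z, y, x)`` in micrometres.
    channel_roles
        Mapping from channel index to role tag (``dapi``, ``membrane``,
        ``lumen_marker``, ``nuclear_marker``, ``cytoplasmic_marker``,
        ``gfp``, ``other``).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_roles: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:  # (c, y, x) -> (c, 1, y, x)
            self.data = self.data[:, None, :, :]
        if self.data.ndim != 4:
            raise ValueError(
                f"image data must be (c, z, y, x) or (c, y, x); got shape {self.data.shape}"
            )
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 strictly positive values, got {self.voxel_size}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("image intensities must be >= 0 on ingest")
        n_chan = self.data.shape[0]
        for idx, role in self.channel_roles.items():
            if not 0 <= idx < n_chan:
                raise ValueError(f"channel role map references channel {idx}, stack has {n_chan}")
            if role not in CHANNEL_ROLES:
                raise ValueError(f"unknown channel role {role!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def channel(self, role: str) -> np.ndarray:
        """Return the ``(z, y, x)`` array of the first channel with `role`."""
        for idx, r in self.channel_roles.items():
            if r == role:
                return self.data[idx]
        raise KeyError(f"no channel with role {role!r}")

    def has_channel(self, role: str) -> bool:
        return any(r == role for r in self.channel_roles.values())


@dataclass
class LabelSet:
    """Co-registered integer masks on the same grid as a :class:`VoxelImage`.

    ``nuclei`` and ``cells`` are labelled objects, ``spheroid`` marks the
    whole structure, ``lumen`` carries one id per lumen.  0 is background
    everywhere.
    """

    nuclei: np.ndarray
    cells: np.ndarray
    spheroid: np.ndarray
    lumen: np.ndarray

    def __post_init__(self) -> None:
        masks = {}
        shape = None
        for name in ("nuclei", "cells", "spheroid", "lumen"):
            arr = np.asarray(getattr(self, name))
            if arr.ndim == 2:
                arr = arr[None, :, :]
            if arr.ndim != 3:
                raise ValueError(f"{name} mask must be 2D or 3D, got shape {arr.shape}")
            if not np.issubdtype(arr.dtype, np.integer) and arr.dtype != bool:
                raise TypeError(f"{name} mask must be integer-valued, got dtype {arr.dtype}")
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError(f"{name} mask shape {arr.shape} differs from {shape}")
            masks[name] = arr
        for name, arr in masks.items():
            setattr(self, name, arr)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.nuclei.shape

    def validate(self) -> None:
        """Check cross-mask invariants (nucleus-to-cell mapping, lumen/nuclei disjoint)."""
        if np.any((self.lumen > 0) & (self.nuclei > 0)):
            raise ValueError("lumen voxels overlap nuclei voxels")
        for nid in np.unique(self.nuclei[self.nuclei > 0]):
            owners = np.unique(self.cells[self.nuclei == nid])
            owners = owners[owners > 0]
            if owners.size > 1:
                raise ValueError(f"nucleus {nid} overlaps multiple cells {owners.tolist()}")

    def nucleus_to_cell(self) -> dict[int, int]:
        """Map each nucleus id to the cell id that holds the majority of its voxels."""
        out: dict[int, int] = {}
        for nid in np.unique(self.nuclei[self.nuclei > 0]):
            owners = self.cells[self.nuclei == nid]
            owners = owners[owners > 0]
            if owners.size:
                vals, counts = np.unique(owners, return_counts=True)
                out[int(nid)] = int(vals[np.argmax(counts)])
        return out


def read_image(
    path: str | Path,
    voxel_size: tuple[float, float, float],
    channel_roles: dict[int, str],
    axes: str | None = None,
) -> VoxelImage:
    """Read a TIFF stack into a :class:`VoxelImage`.

    `axes` disambiguates 3D arrays: ``"ZYX"`` (single channel, default)
    or ``"CYX"`` (multi-channel 2D plane).  4D arrays are taken as CZYX,
    2D arrays as a single-channel single-plane image.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"file not found: {path}")
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, None, :, :]
    elif arr.ndim == 3:
        if axes is None:
            axes = "ZYX"
        if axes.upper() == "ZYX":
            arr = arr[None, :, :, :]
        elif axes.upper() == "CYX":
            arr = arr[:, None, :, :]
        else:
            raise ValueError(f"unsupported axes {axes!r} for 3D data")
    elif arr.ndim != 4:
        raise ValueError(f"cannot interpret TIFF with shape {arr.shape}")
    return VoxelImage(arr, voxel_size, dict(channel_roles))


def write_image(img: VoxelImage, path: str | Path) -> None:
    tifffile.imwrite(Path(path), np.ascontiguousarray(img.data.astype(np.float32)), photometric="minisblack")


def read_labels(path: str | Path, expected_shape: tuple[int, ...] | None = None) -> np.ndarray:
    """Read one integer label mask, preserving labels exactly.

    Raises on non-integer pixel type or (if given) a shape mismatch with
    the companion image's spatial axes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"file not found: {path}")
    arr = tifffile.imread(path)
    if not np.issubdtype(arr.dtype, np.integer):
        raise TypeError(f"label mask must be integer-valued, got dtype {arr.dtype}")
    if expected_shape is not None and arr.shape != tuple(expected_shape):
        raise ValueError(f"label shape {arr.shape} does not match expected {tuple(expected_shape)}")
    return arr


def write_labels(mask: np.ndarray, path: str | Path) -> None:
    mask = np.asarray(mask)
    if mask.dtype == bool:
        mask = mask.astype(np.uint16)
    if not np.issubdtype(mask.dtype, np.integer):
        raise TypeError("label mask must be integer-valued")
    if mask.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("label ids exceed 16-bit range")
    tifffile.imwrite(Path(path), np.ascontiguousarray(mask.astype(np.uint16)), photometric="minisblack")


_KEY_COLUMNS = ("experiment_id", "structure_id", "cell_id")

_FRACTION_COLUMNS = (
    "fraction_positive",
    "fraction_delaminated",
    "mitotic_index",
    "contribution",
    "sphericity",
)


def _validate_table(df: pd.DataFrame) -> None:
    keys = [c for c in _KEY_COLUMNS if c in df.columns]
    if keys and len(df):
        if df.duplicated(subset=keys).any():
            dup = df[df.duplicated(subset=keys)][keys].iloc[0].tolist()
            raise ValueError(f"duplicate table key {tuple(zip(keys, dup))}")
    for col in df.columns:
        if col in _FRACTION_COLUMNS or col.startswith("fraction_"):
            vals = pd.to_numeric(df[col], errors="coerce").dropna()
            if len(vals) and ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"column {col!r} must lie in [0, 1]")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a validated cell/spheroid table as CSV (stable column order)."""
    _validate_table(df)
    df.to_csv(Path(path), index=False, float_format="%.8g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a YAML mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
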