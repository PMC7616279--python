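"""End-to-end orchestration: configuration, quantification runs, reports.

`run_quantify` wires the stages together for one structure: read image and
masks, normalise the nuclear-marker channel, classify marker-positive
cells, measure morphometrics/lumen topology/distances, call delamination,
and (optionally) partition tip/side regions.  Outputs are per-cell and
per-structure CSV tables plus a machine-parsable run log.

Runs are deterministic given configuration and seed; every output records
the configuration hash.  Inferential statistics are deliberately excluded
from reports: descriptive summaries (mean, SEM, contingency counts) only.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import imgio, intensity, microcavity, spheroid3d
from .imgio import LabelSet, VoxelImage


@dataclass
class PipelineConfig:
    image: str
    nuclei: str
    cells: str
    spheroid: str
    lumen: str
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    channel_roles: dict[int, str] = field(default_factory=dict)
    experiment_id: str = "exp1"
    structure_id: str = "s1"
    background_quantile: float = 0.75
    clip_negative: bool = False
    classifier: str = "gmm2"
    classifier_threshold: float | None = None
    contact_tolerance: int = 1
    golgi_threshold_deg: float = 60.0
    min_lumen_volume_um3: float = 30.0
    mitotic_ids: tuple[int, ...] = ()
    partition_regions: bool = False
    plane: int | None = None  # single-plane fraction counting; None = 3D
    seed: int = 0

    def __post_init__(self) -> None:
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.channel_roles = {int(k): str(v) for k, v in self.channel_roles.items()}
        required = {"dapi", "nuclear_marker"}
        missing = required - set(self.channel_roles.values())
        if missing:
            raise ValueError(f"channel role map lacks required roles: {sorted(missing)}")
        if self.classifier not in ("fixed_threshold", "otsu", "gmm2"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.classifier == "fixed_threshold" and self.classifier_threshold is None:
            raise ValueError("fixed_threshold classifier requires classifier_threshold")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        cfg = imgio.load_config(path)
        for key in ("voxel_size", "mitotic_ids"):
            if key in cfg and isinstance(cfg[key], list):
                cfg[key] = tuple(cfg[key])
        return cls(**cfg)

    def to_dict(self) -> dict:
        d = {}
        for k, v in self.__dict__.items():
            if isinstance(v, tuple):
                v = list(v)
            d[k] = v
        return d

    def hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def quantify_structure(
    img: VoxelImage,
    labels: LabelSet,
    cfg: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame | None, list[str]]:
    """Quantify one structure already in memory.

    Returns (cells table, spheroids table, regions table or None, log lines).
    """
    log: list[str] = [f"config_hash={cfg.hash()}"]
    vs = cfg.voxel_size
    params = intensity.NormalizationParams(cfg.background_quantile, cfg.clip_negative)

    morph = spheroid3d.morphometrics(labels.spheroid, vs)
    n_lumen, lumen_stats, lumen_class = spheroid3d.lumen_topology(
        labels.lumen, vs, cfg.min_lumen_volume_um3
    )
    log.append(f"lumen_count={n_lumen} lumen_class={lumen_class}")

    dapi_corr, _, _ = intensity.background_correct_stack(
        img.channel("dapi"), labels.spheroid, labels.nuclei, params
    )
    marker_corr, b_z, skipped = intensity.background_correct_stack(
        img.channel("nuclear_marker"), labels.spheroid, labels.nuclei, params
    )
    log.append(f"background_planes_skipped={len(skipped)}")
    marker_norm, _, excluded = intensity.dapi_normalize_stack(marker_corr, dapi_corr, labels.nuclei)
    log.append(f"dapi_planes_excluded={len(excluded)}")
    means = intensity.nuclear_mean(marker_norm, labels.nuclei)
    batchnorm, n_nonpos = intensity.lognorm_batch(means, cfg.experiment_id)
    log.append(f"nonpositive_values_excluded={n_nonpos}")
    calls, boundary = intensity.classify_marker(
        batchnorm, method=cfg.classifier, threshold=cfg.classifier_threshold
    )
    log.append(f"classifier={cfg.classifier} boundary={boundary:.6g}")

    delam, fraction_delam = spheroid3d.classify_delamination(
        labels.cells, labels.lumen, cfg.contact_tolerance, set(cfg.mitotic_ids), vs
    )
    delam = delam.set_index("cell_id")

    # per-nucleus centroids (physical um) and plane assignment
    ids = sorted(means.index)
    centroids = {}
    for i in ids:
        pts = np.argwhere(labels.nuclei == i)
        centroids[i] = pts.mean(axis=0) * np.asarray(vs)
    lumen_centroid = None
    if n_lumen >= 1:
        all_lumen = np.argwhere(labels.lumen > 0)
        lumen_centroid = all_lumen.mean(axis=0) * np.asarray(vs)
        if n_lumen > 1:
            log.append("multi_lumen_structure: nearest-lumen distances flagged")

    rows = []
    for i in ids:
        c = centroids[i]
        row = {
            "experiment_id": cfg.experiment_id,
            "structure_id": cfg.structure_id,
            "cell_id": i,
            "plane": int(round(c[0] / vs[0])),
            "nuclear_mean_norm": means.get(i, np.nan),
            "nuclear_mean_batchnorm": batchnorm.get(i, np.nan),
            "marker_class": bool(calls.get(i, False)),
            "lumen_contact": delam.lumen_contact.get(i, pd.NA),
            "excluded_mitotic_shadow": bool(delam.excluded_mitotic_shadow.get(i, False)),
            "mitotic": bool(delam.mitotic.get(i, False)),
        }
        if lumen_centroid is not None:
            row["norm_lumen_distance"] = spheroid3d.norm_lumen_distance(
                c, lumen_centroid, morph.equivalent_radius_um
            )
            row["nearest_lumen_surface_distance_um"] = (
                spheroid3d.nearest_lumen_surface_distance(c, labels.lumen, vs)
            )
        else:
            row["norm_lumen_distance"] = np.nan
            row["nearest_lumen_surface_distance_um"] = np.nan
        rows.append(row)
    cells_df = pd.DataFrame(rows)

    frac = spheroid3d.per_spheroid_fractions(
        cells_df, plane=cfg.plane, positive_col="marker_class", mitotic_col="mitotic"
    )
    spheroid_row = {
        "experiment_id": cfg.experiment_id,
        "structure_id": cfg.structure_id,
        "volume_um3": morph.volume_um3,
        "surface_area_um2": morph.surface_area_um2,
        "equivalent_radius_um": morph.equivalent_radius_um,
        "ellipticity": morph.ellipticity,
        "sphericity": morph.sphericity,
        "lumen_count": n_lumen,
        "lumen_class": lumen_class,
        "n_cells": len(cells_df),
        "fraction_positive": frac["fraction_positive"],
        "mitotic_index": frac.get("mitotic_index", np.nan),
        "fraction_delaminated": np.nan if fraction_delam is None else fraction_delam,
    }
    spheroids_df = pd.DataFrame([spheroid_row])
    log.append(f"cells_in={len(cells_df)} classified_positive={int(cells_df.marker_class.sum())}")

    regions_df = None
    if cfg.partition_regions:
        part = microcavity.partition_tip_side(labels.spheroid, labels.lumen, vs)
        cents = np.array([centroids[i] for i in ids])
        cell_regions = part.assign_cells(cents)
        cells_df["region"] = cell_regions
        dens = microcavity.local_density(part, cell_regions)
        fr = microcavity.region_fractions(
            cell_regions,
            cells_df.assign(delaminated=~cells_df.lumen_contact.astype(bool)),
            delaminated_col="delaminated",
            positive_col="marker_class",
        )
        regions_df = dens.merge(fr.drop(columns="n_cells"), on="region")
        regions_df.insert(0, "structure_id", cfg.structure_id)
        regions_df.insert(0, "experiment_id", cfg.experiment_id)
        log.append(f"partition tip_volume={part.tip_measure:.6g} side_volume={part.side_measure:.6g}")

    return cells_df, spheroids_df, regions_df, log


def run_quantify(cfg: PipelineConfig, out_prefix: str | Path) -> dict[str, Path]:
    """Load inputs from disk, quantify, and write CSV tables plus a run log."""
    from . import __version__

    img = imgio.read_image(cfg.image, cfg.voxel_size, cfg.channel_roles)
    shape = img.spatial_shape
    labels = LabelSet(
        nuclei=imgio.read_labels(cfg.nuclei, shape),
        cells=imgio.read_labels(cfg.cells, shape),
        spheroid=imgio.read_labels(cfg.spheroid, shape),
        lumen=imgio.read_labels(cfg.lumen, shape),
    )
    cells_df, spheroids_df, regions_df, log = quantify_structure(img, labels, cfg)

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "cells": out_prefix.with_name(out_prefix.name + "_cells.csv"),
        "spheroids": out_prefix.with_name(out_prefix.name + "_spheroids.csv"),
        "log": out_prefix.with_name(out_prefix.name + "_log.txt"),
    }
    imgio.write_table(cells_df, paths["cells"])
    imgio.write_table(spheroids_df, paths["spheroids"])
    if regions_df is not None:
        paths["regions"] = out_prefix.with_name(out_prefix.name + "_regions.csv")
        imgio.write_table(regions_df, paths["regions"])
    header = [f"spheroidquant version={__version__}", f"seed={cfg.seed}"]
    paths["log"].write_text("\n".join(header + log) + "\n")
    return paths


def run_report(
    cells: pd.DataFrame,
    spheroids: pd.DataFrame,
    out_dir: str | Path,
    make_plots: bool = True,
) -> dict[str, Path]:
    """Descriptive per-condition summaries mirroring figure-panel statistics.

    Mean and SEM of per-structure fractions (SEM is NA for single
    structures), a lumen-class contingency table, and simple histograms.
    No inferential statistics are computed.
    """
    if len(spheroids) == 0:
        raise ValueError("empty spheroid table")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    metrics = [
        c
        for c in ("fraction_positive", "fraction_delaminated", "mitotic_index", "n_cells")
        if c in spheroids.columns
    ]
    rows = []
    for exp, grp in spheroids.groupby("experiment_id"):
        for m in metrics:
            vals = pd.to_numeric(grp[m], errors="coerce").dropna()
            n = len(vals)
            rows.append(
                {
                    "experiment_id": exp,
                    "metric": m,
                    "n": n,
                    "mean": float(vals.mean()) if n else np.nan,
                    "sem": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                }
            )
    summary = pd.DataFrame(rows)
    contingency = (
        spheroids.groupby(["experiment_id", "lumen_class"]).size().rename("count").reset_index()
        if "lumen_class" in spheroids.columns
        else pd.DataFrame()
    )
    paths = {
        "summary": out_dir / "summary.csv",
        "lumen_contingency": out_dir / "lumen_contingency.csv",
    }
    summary.to_csv(paths["summary"], index=False, float_format="%.8g")
    contingency.to_csv(paths["lumen_contingency"], index=False)

    if make_plots and "n_cells" in spheroids.columns:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 3))
        ax.hist(spheroids["n_cells"].dropna(), bins=15, color="steelblue")
        ax.set_xlabel("cells per structure")
        ax.set_ylabel("structures")
        fig.tight_layout()
        paths["histogram"] = out_dir / "cells_per_structure.png"
        fig.savefig(paths["histogram"], dpi=120)
        plt.close(fig)
    return paths
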