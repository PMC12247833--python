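"""End-to-end orchestration: configuration, stage sequencing, manifest.

A single declarative :class:`PipelineConfig` drives the full analysis of a
batch of images: segment (ingest or built-in) → expand & filter → measure →
calibrate thresholds across the batch → classify → stromal model & signed
distances → distance profiles → sensitivity grid. Every output file is
listed in a manifest with a SHA-256 checksum; re-running with identical
inputs reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .core import ChannelStack
from .calibration import propagate_thresholds
from .classification import classify_by_threshold
from .features import measure_cells, measurement_column, write_cell_table
from .profile import profile, DEFAULT_RANGE_UM
from .segmentation import (
    expand_cells,
    filter_by_area,
    geometries_from_labels,
    ingest_labels,
    segment_nuclei_builtin,
)
from .sensitivity import run_grid
from .stroma import build_stromal_model, signed_distance

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage and image it occurred in."""

    def __init__(self, stage: str, image_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on image {image_id!r}: {cause}")
        self.stage = stage
        self.image_id = image_id
        self.cause = cause


@dataclass
class PipelineConfig:
    """Declarative configuration of a full run.

    Channel roles are mapped by name; statistic/compartment choices select
    the measurement column each classification uses (e.g. maximum whole-cell
    intensity for a stromal-sensing marker, median cytoplasmic cytokeratin
    for the cancer gate).
    """

    # channel-name map
    nuclear_channel: str = "DAPI"
    matrix_channel: str = "FN"
    cancer_marker_channel: str = "KER"
    analysis_marker_channel: str = "MARKER"

    pixel_size_um: float | None = None   # None: taken from each image
    expansion_radius_um: float = 5.0
    area_percentiles: tuple[float, float] = (5.0, 99.0)

    # stromal model; sigma default 15 µm suits diffuse cytoplasmic markers,
    # 10 µm suits punctate nuclear markers
    stroma_sigma_um: float = 15.0
    stroma_threshold: float = 50.0

    # measurement columns used for classification
    analysis_marker_compartment: str = "Cell"
    analysis_marker_statistic: str = "max"
    cancer_marker_compartment: str = "Cytoplasm"
    cancer_marker_statistic: str = "median"

    # threshold calibration
    reference_image_id: str | None = None  # None: first image of the batch
    reference_marker_threshold: float | None = None
    reference_cancer_threshold: float | None = None

    # profiles & statistics
    bin_width_um: float = 10.0
    profile_range_um: tuple[float, float] = DEFAULT_RANGE_UM
    n_boot: int = 500
    seed: int = 0

    # sensitivity grid; factors multiply the configured sigma / threshold
    sensitivity_sigma_factors: tuple[float, ...] = (0.8, 1.0, 1.2)
    sensitivity_threshold_factors: tuple[float, ...] = (0.8, 1.0, 1.2)
    wilcoxon_pairing: str | None = None  # must be set: "images" or "grid_points"

    # ------------------------------------------------------------------
    @property
    def marker_column(self) -> str:
        return measurement_column(
            self.analysis_marker_compartment,
            self.analysis_marker_channel,
            self.analysis_marker_statistic,
        )

    @property
    def cancer_column(self) -> str:
        return measurement_column(
            self.cancer_marker_compartment,
            self.cancer_marker_channel,
            self.cancer_marker_statistic,
        )

    def validate(self, stacks: Mapping[str, ChannelStack]) -> None:
        for stack in stacks.values():
            for role, name in (
                ("nuclear", self.nuclear_channel),
                ("matrix", self.matrix_channel),
                ("cancer marker", self.cancer_marker_channel),
                ("analysis marker", self.analysis_marker_channel),
            ):
                if name not in stack.channels:
                    raise ValueError(
                        f"configured {role} channel {name!r} is missing from "
                        f"image {stack.image_id!r} (has {stack.names})"
                    )
        if self.expansion_radius_um < 0 or self.bin_width_um <= 0:
            raise ValueError("lengths/radii must be positive")
        if self.wilcoxon_pairing not in ("images", "grid_points"):
            raise ValueError(
                "wilcoxon_pairing must be set to 'images' or 'grid_points'"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in (
            "area_percentiles",
            "profile_range_um",
            "sensitivity_sigma_factors",
            "sensitivity_threshold_factors",
        ):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig,
    images: Sequence[ChannelStack] | Mapping[str, ChannelStack],
    out_dir: str | Path,
    labels: Mapping[str, np.ndarray] | None = None,
) -> dict:
    """Run the full pipeline on a batch of images and write all artifacts.

    ``labels`` optionally supplies pre-computed nuclei label images per image
    id (the external-segmenter route); otherwise the built-in segmenter runs
    on the nuclear channel. Returns the manifest dictionary.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(images, Mapping):
        stacks = dict(images)
    else:
        stacks = {s.image_id: s for s in images}
    if not stacks:
        raise ValueError("no images given")
    config.validate(stacks)

    manifest: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "images": list(stacks),
        "stages": {},
        "outputs": {},
        "complete": False,
    }
    outputs: dict[str, Path] = {}

    def record(name: str, path: Path) -> None:
        outputs[name] = path

    tables: dict[str, pd.DataFrame] = {}
    models: dict[str, object] = {}
    try:
        for image_id, stack in stacks.items():
            t0 = time.perf_counter()
            px = config.pixel_size_um or stack.pixel_size_um
            stage = "segment"
            try:
                if labels and image_id in labels:
                    nuc_labels = np.asarray(labels[image_id])
                else:
                    nuc_labels = segment_nuclei_builtin(
                        stack[config.nuclear_channel], px
                    )
                cell_labels = expand_cells(nuc_labels, config.expansion_radius_um, px)
                geoms = geometries_from_labels(nuc_labels, cell_labels, px)
                if not geoms:
                    raise ValueError("no cells segmented")
                kept, _ = filter_by_area(geoms, *config.area_percentiles)
                stage = "measure"
                table = measure_cells(stack, kept)
                stage = "stroma"
                model = build_stromal_model(
                    stack[config.matrix_channel],
                    config.stroma_sigma_um,
                    config.stroma_threshold,
                    px,
                )
                models[image_id] = model
                pts = table[["centroid_x_um", "centroid_y_um"]].to_numpy()
                table["signed_distance_um"] = signed_distance(model, pts)
                tables[image_id] = table
                mask_path = out_dir / f"{image_id}_stroma_mask.tif"
                model.write_mask_tiff(mask_path)
                record(f"{image_id}/stroma_mask", mask_path)
                border_path = out_dir / f"{image_id}_stroma_border.geojson"
                model.write_border_geojson(border_path)
                record(f"{image_id}/stroma_border", border_path)
            except Exception as exc:
                raise PipelineError(stage, image_id, exc) from exc
            logger.info(
                "image %s: %d cells in %.1f s",
                image_id,
                len(tables[image_id]),
                time.perf_counter() - t0,
            )
        manifest["stages"]["per_image"] = "ok"

        # ---------------------------------------------------------- calibrate
        stage = "calibrate"
        reference = config.reference_image_id or next(iter(stacks))
        try:
            marker_values = tables[reference][config.marker_column].dropna()
            ref_thr = (
                config.reference_marker_threshold
                if config.reference_marker_threshold is not None
                else float(np.percentile(marker_values, 90))
            )
            marker_map = propagate_thresholds(
                tables, config.marker_column, reference, ref_thr
            )
            cancer_values = tables[reference][config.cancer_column].dropna()
            ref_cancer_thr = (
                config.reference_cancer_threshold
                if config.reference_cancer_threshold is not None
                else float(np.percentile(cancer_values, 50))
            )
            cancer_map = propagate_thresholds(
                tables, config.cancer_column, reference, ref_cancer_thr
            )
        except Exception as exc:
            raise PipelineError(stage, reference, exc) from exc
        marker_map_path = out_dir / "threshold_map_marker.json"
        marker_map.to_json(marker_map_path)
        record("threshold_map_marker", marker_map_path)
        cancer_map_path = out_dir / "threshold_map_cancer.json"
        cancer_map.to_json(cancer_map_path)
        record("threshold_map_cancer", cancer_map_path)
        manifest["stages"]["calibrate"] = "ok"

        # ----------------------------------------------------------- classify
        stage = "classify"
        for image_id in list(tables):
            try:
                t = classify_by_threshold(tables[image_id], marker_map, "class_marker")
                t = classify_by_threshold(t, cancer_map, "class_cancer")
            except Exception as exc:
                raise PipelineError(stage, image_id, exc) from exc
            tables[image_id] = t
        combined = pd.concat(tables.values(), ignore_index=True)
        table_path = out_dir / "cells.csv"
        write_cell_table(combined, table_path)
        record("cells", table_path)
        manifest["stages"]["classify"] = "ok"

        # ------------------------------------------------------------ profile
        stage = "profile"
        try:
            pop = combined["class_cancer"] & combined["class_marker"]
            prof = profile(
                combined,
                config.marker_column,
                population=pop,
                bin_width_um=config.bin_width_um,
                range_um=config.profile_range_um,
                n_boot=config.n_boot,
                seed=config.seed,
                population_label="cancer+ marker+",
            )
            prof_path = out_dir / "profile_marker_positive.csv"
            prof.to_csv(prof_path)
            record("profile_marker_positive", prof_path)
            try:
                from .plotting import plot_profile

                fig_path = out_dir / "profile_marker_positive.png"
                plot_profile(prof, fig_path)
                record("profile_figure", fig_path)
            except Exception:  # plotting is best-effort
                logger.exception("profile figure could not be rendered")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, "batch", exc) from exc
        manifest["stages"]["profile"] = "ok"

        # -------------------------------------------------------- sensitivity
        stage = "sensitivity"
        try:
            sigmas = [
                f * config.stroma_sigma_um for f in config.sensitivity_sigma_factors
            ]
            thrs = [
                f * config.stroma_threshold
                for f in config.sensitivity_threshold_factors
            ]
            sens = run_grid(
                stacks,
                combined,
                sigmas,
                thrs,
                config.marker_column,
                pairing=config.wilcoxon_pairing,
                matrix_channel=config.matrix_channel,
                n_boot=config.n_boot,
                seed=config.seed,
            )
            sens_csv = out_dir / "sensitivity_grid.csv"
            sens_json = out_dir / "sensitivity_summary.json"
            sens.write(sens_csv, sens_json)
            record("sensitivity_grid", sens_csv)
            record("sensitivity_summary", sens_json)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, "batch", exc) from exc
        manifest["stages"]["sensitivity"] = "ok"
        manifest["complete"] = True
    finally:
        manifest["outputs"] = {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in outputs.items()
            if p.exists()
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
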