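"""Run configuration: YAML parsing, validation and the pipeline driver.

A run takes its input either from a ``simulate`` block (synthetic panel
with ground truth) or from a ``manifest`` CSV pointing at acquired TIFF
stacks (columns: path, class_label, experiment_id, optionally label_path
for precomputed masks — scenes with a label_path skip segmentation).
Exactly one of the two must be present. Significance thresholds are fixed
at 0.05/0.01 and are deliberately not configurable.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .io import (CellLabelMap, ImageStack, read_label_map, read_stack,
                 write_label_map)
from .quantify import QuantTable, quantify_scene
from .scenes import (DEFAULT_PANEL_FOLDS, DEFAULT_REFERENCE, SceneSpec,
                     render_class_panel, write_panel)
from .segmentation import SegmentationParams, segment_pipeline
from .stats import (aggregate_replicates, comparisons_to_frame,
                    experiment_comparisons, summaries_to_frame)

__all__ = ["SimulateBlock", "StatsBlock", "RunConfig", "validate_config",
           "config_from_dict", "config_to_dict", "run"]

log = logging.getLogger("symquant")


@dataclass
class SimulateBlock:
    folds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PANEL_FOLDS))
    reference: str = DEFAULT_REFERENCE
    n_experiments: int = 3
    n_scenes_per_class: int = 1
    scene: SceneSpec = field(default_factory=SceneSpec)

    def __post_init__(self) -> None:
        if self.n_experiments < 1 or self.n_scenes_per_class < 1:
            raise ValueError("n_experiments and n_scenes_per_class must be ≥ 1")
        if self.reference not in self.folds:
            raise ValueError(
                f"reference {self.reference!r} missing from simulate.folds")


@dataclass
class StatsBlock:
    reference: str = DEFAULT_REFERENCE
    mode: str = "auto"
    pooling: str = "per_experiment"

    def __post_init__(self) -> None:
        if self.mode not in ("auto", "exact", "normal"):
            raise ValueError(f"unknown stats.mode {self.mode!r}")
        if self.pooling not in ("per_experiment", "pooled"):
            raise ValueError(f"unknown stats.pooling {self.pooling!r}")


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "symquant_run"
    log_level: str = "info"
    simulate: SimulateBlock | None = None
    manifest: str | None = None
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    stats: StatsBlock = field(default_factory=StatsBlock)
    subtract_background: bool = False
    qc_overlays: bool = False

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.manifest is None):
            raise ValueError(
                "config must contain exactly one of 'simulate' or 'manifest'")
        if self.log_level not in ("info", "debug"):
            raise ValueError("log_level must be 'info' or 'debug'")


def _build(cls, data: Mapping[str, Any], where: str):
    """Instantiate a (nested) dataclass from a mapping, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if f.name == "scene" and isinstance(value, Mapping):
            value = _build(SceneSpec, value, f"{where}.scene")
        if f.name == "cell_radius_range" and isinstance(value, (list, tuple)):
            value = tuple(float(x) for x in value)
        kwargs[f.name] = value
    return cls(**kwargs)


def config_from_dict(data: Mapping[str, Any]) -> RunConfig:
    data = dict(data)
    if isinstance(data.get("simulate"), Mapping):
        data["simulate"] = _build(SimulateBlock, data["simulate"], "simulate")
    if isinstance(data.get("segmentation"), Mapping):
        data["segmentation"] = _build(
            SegmentationParams, data["segmentation"], "segmentation")
    if isinstance(data.get("stats"), Mapping):
        data["stats"] = _build(StatsBlock, data["stats"], "stats")
    return _build(RunConfig, data, "config")


def config_to_dict(config: RunConfig) -> dict[str, Any]:
    """Effective configuration as plain data; reparses to an equal config."""
    def conv(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return [conv(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    out = {k: conv(v) for k, v in dataclasses.asdict(config).items()}
    return out


def validate_config(path: str | Path) -> RunConfig:
    """Parse, default and validate a YAML config file."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: config must be a mapping")
    return config_from_dict(data)


def _simulate_inputs(config: RunConfig, outdir: Path) -> pd.DataFrame:
    sim = config.simulate
    scene_dir = outdir / "scenes"
    frames = []
    seed_rng = np.random.default_rng(config.seed)
    for e in range(1, sim.n_experiments + 1):
        exp_seed = int(seed_rng.integers(0, 2 ** 31))
        scenes = render_class_panel(
            sim.scene, sim.folds, sim.n_scenes_per_class, seed=exp_seed,
            reference=sim.reference, experiment_id=f"E{e}")
        manifest = write_panel(scenes, scene_dir / f"E{e}")
        manifest["seed"] = exp_seed
        frames.append(manifest)
    manifest = pd.concat(frames, ignore_index=True)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def _load_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path, dtype=str)
    required = {"path", "class_label", "experiment_id"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    return manifest


def run(config: RunConfig, outdir: str | Path | None = None) -> Path:
    """Execute the full pipeline; returns the output directory.

    Writes: manifest.csv (for simulated input), labels/, cells.csv,
    group_stats.csv, replicate_summary.csv and run_log.yaml. Reruns with an
    identical config produce bit-identical tables. Per-scene failures are
    logged and skipped; if any scene failed, a RuntimeError is raised after
    the statistics stage is written for the surviving scenes.
    """
    outdir = Path(outdir if outdir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper()))

    if config.simulate is not None:
        manifest = _simulate_inputs(config, outdir)
    else:
        manifest = _load_manifest(config.manifest)

    label_dir = outdir / "labels"
    label_dir.mkdir(exist_ok=True)
    table = QuantTable()
    failures: list[str] = []
    for i, row in manifest.iterrows():
        try:
            stack = read_stack(row["path"], str(row["class_label"]),
                               str(row["experiment_id"]))
            if "label_path" in manifest.columns and isinstance(
                    row.get("label_path"), str) and row["label_path"]:
                labels = read_label_map(row["label_path"])  # provided masks
            else:
                labels = segment_pipeline(stack, config.segmentation)
                write_label_map(labels, label_dir / f"scene_{i:03d}_labels.tif")
            scene_table = quantify_scene(
                stack, labels, config.segmentation.projection,
                subtract_background=config.subtract_background)
            log.info("scene %d (%s): %d cells, total V %.6g", i,
                     row["class_label"], len(scene_table),
                     sum(r.V for r in scene_table.records))
            table.extend(scene_table)
            if config.qc_overlays:
                _write_overlay(stack, labels, outdir / "overlays" / f"scene_{i:03d}.png")
        except Exception as exc:  # noqa: BLE001 - per-scene isolation
            log.error("scene %d (%s) failed: %s", i, row.get("path"), exc)
            failures.append(f"{row.get('path')}: {exc}")

    frame = table.to_frame()
    # global cell_id unique across scenes for the pooled table
    frame["cell_id"] = np.arange(1, len(frame) + 1)
    frame.to_csv(outdir / "cells.csv", index=False, float_format="%.17g")

    reference = config.stats.reference
    if config.stats.pooling == "pooled":
        from .stats import compare_classes
        comps_by_exp = {"pooled": compare_classes(frame, reference,
                                                  mode=config.stats.mode)}
    else:
        comps_by_exp = experiment_comparisons(frame, reference,
                                              mode=config.stats.mode)
    stats_rows = []
    for exp, comps in comps_by_exp.items():
        cframe = comparisons_to_frame(comps)
        cframe.insert(0, "experiment_id", exp)
        stats_rows.append(cframe)
    pd.concat(stats_rows, ignore_index=True).to_csv(
        outdir / "group_stats.csv", index=False, float_format="%.17g")

    summaries = aggregate_replicates(list(comps_by_exp.values()))
    summaries_to_frame(summaries).to_csv(
        outdir / "replicate_summary.csv", index=False, float_format="%.17g")

    with open(outdir / "run_log.yaml", "w") as fh:
        yaml.safe_dump({"effective_config": config_to_dict(config)}, fh,
                       sort_keys=False)

    if failures:
        raise RuntimeError(
            f"{len(failures)} scene(s) failed: " + "; ".join(failures))
    return outdir


def _write_overlay(stack: ImageStack, labels: CellLabelMap, path: Path) -> None:
    """QC PNG: normalized projection with segmentation boundaries marked."""
    import imageio.v3 as iio
    from skimage.segmentation import mark_boundaries

    path.parent.mkdir(parents=True, exist_ok=True)
    im = stack.pixels.sum(axis=0)
    lo, hi = im.min(), im.max()
    base = (im - lo) / (hi - lo) if hi > lo else np.zeros_like(im)
    rgb = mark_boundaries(base, labels.labels, color=(1, 0, 0), mode="thick")
    iio.imwrite(path, (np.clip(rgb, 0, 1) * 255).astype(np.uint8))
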