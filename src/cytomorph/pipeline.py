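"""End-to-end orchestration: generate -> preprocess -> segment -> measure ->
quantify -> statistics, with manifests and deterministic seeding.

A run is driven by a :class:`RunConfig` (serializable to YAML).  The global
seed fans out to per-stage, per-field child seeds through
``numpy.random.SeedSequence([seed, stage_index, field_index])``, so each
stage is independently reproducible and identical configs give byte-identical
CSV outputs.

:func:`simulate_experiment` renders a full synthetic "study" — a grid of
conditions (substrate x timepoint x serum), each with its own generator
parameters — and runs the measurement and statistics stages on it, recording
the per-condition ground truth so injected effects can be checked against
what the statistics recover.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .ctcf import QuantConfig, quantify_marker
from .group_stats import boxplot_summary, dunn_test
from .imageproc import flatfield_correct, label_regions, threshold_mask
from .morphometry import Calibration, PhenotypeThresholds, measure_cells
from .scenegen import NUCLEAR_CHANNEL, SceneConfig, render_scene, write_scene

__all__ = [
    "PipelineValidationError",
    "SegmentationConfig",
    "RunConfig",
    "RunManifest",
    "Condition",
    "ExperimentDesign",
    "segment_scene",
    "run_pipeline",
    "simulate_experiment",
    "measure_with_truth",
    "compare_conditions",
]

DESCRIPTOR_COLUMNS = ["csi", "nsi", "ar", "cl_um", "np_ratio", "protrusion_um"]


class PipelineValidationError(ValueError):
    """Configuration failed validation before any computation."""


@dataclass
class SegmentationConfig:
    """Threshold-and-label segmentation options.

    ``flatfield_first`` controls whether illumination correction is applied
    before thresholding (it is always available separately for intensity
    quantification).
    """

    cell_channel: str = "phalloidin"
    flatfield_first: bool = True
    smoothing_scale_px: float = 100.0
    threshold_method: str = "otsu"
    min_cell_area_px: int = 200
    min_nucleus_area_px: int = 30


@dataclass
class RunConfig:
    """Full configuration of a pipeline run."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    n_fields: int = 8
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    quant: QuantConfig = field(default_factory=QuantConfig)
    thresholds: PhenotypeThresholds = field(default_factory=PhenotypeThresholds)
    seed: int = 0
    outdir: str = "cytomorph_run"

    def validate(self) -> None:
        if self.n_fields < 1:
            raise PipelineValidationError("n_fields must be >= 1")
        if self.scene.scale_um_per_px <= 0:
            raise PipelineValidationError("calibration scale must be positive")
        if self.segmentation.cell_channel not in self.scene.channel_levels:
            raise PipelineValidationError(
                f"segmentation channel {self.segmentation.cell_channel!r} is "
                f"not rendered by the scene config"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "scene" in d and isinstance(d["scene"], dict):
            d["scene"] = SceneConfig.from_dict(d["scene"])
        for key, typ in (
            ("segmentation", SegmentationConfig),
            ("quant", QuantConfig),
            ("thresholds", PhenotypeThresholds),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise PipelineValidationError(f"{path}: expected a mapping")
        try:
            return cls.from_dict(data)
        except (TypeError, ValueError) as exc:
            raise PipelineValidationError(f"{path}: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        plain = json.loads(json.dumps(self.to_dict()))  # tuples -> lists
        Path(path).write_text(yaml.safe_dump(plain))


@dataclass
class RunManifest:
    """Record of a completed run: resolved config, counts, checksums."""

    config: dict
    stage_counts: dict[str, int]
    warnings: list[str]
    output_checksums: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def _child_seed(seed: int, *path: int) -> int:
    """Derive a stage/field seed below 2**31 from the global seed."""
    ss = np.random.SeedSequence([int(seed), *map(int, path)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def segment_scene(
    channels: dict[str, np.ndarray], seg: SegmentationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold-and-label segmentation of cells and nuclei.

    Returns (cell label image, nucleus label image).
    """
    if seg.cell_channel not in channels:
        raise PipelineValidationError(
            f"channel {seg.cell_channel!r} missing from scene"
        )
    cell_img = np.asarray(channels[seg.cell_channel], dtype=float)
    nuc_img = np.asarray(channels[NUCLEAR_CHANNEL], dtype=float)
    if seg.flatfield_first:
        cell_img = flatfield_correct(cell_img, seg.smoothing_scale_px)
        nuc_img = flatfield_correct(nuc_img, seg.smoothing_scale_px)
    cell_mask = threshold_mask(cell_img, seg.threshold_method).mask
    nuc_mask = threshold_mask(nuc_img, seg.threshold_method).mask
    cells = label_regions(cell_mask, seg.min_cell_area_px)
    nuclei = label_regions(nuc_mask, seg.min_nucleus_area_px)
    return cells, nuclei


def _measure_field(
    cfg: RunConfig, field_index: int, write_dir: Path | None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render, segment and measure one field; returns (morphometry, ctcf)."""
    scene_cfg = dataclasses.replace(
        cfg.scene, seed=_child_seed(cfg.seed, 0, field_index)
    )
    channels, truth = render_scene(scene_cfg)
    if write_dir is not None:
        write_scene(write_dir, channels, truth, prefix=f"field{field_index:02d}")
    cells, nuclei = segment_scene(channels, cfg.segmentation)
    cal = Calibration(scene_cfg.scale_um_per_px)
    morpho = measure_cells(cells, nuclei, cal, cfg.thresholds)
    morpho.insert(0, "scene_id", field_index)
    ctcf_frames = []
    for name in scene_cfg.channel_levels:
        qcfg = dataclasses.replace(
            cfg.quant, seed=_child_seed(cfg.seed, 1, field_index)
        )
        table, _ = quantify_marker(channels[name], cells, qcfg)
        table.insert(0, "channel", name)
        table.insert(0, "scene_id", field_index)
        ctcf_frames.append(table)
    ctcf_table = pd.concat(ctcf_frames, ignore_index=True)
    return morpho, ctcf_table


def run_pipeline(config: RunConfig, write_scenes: bool = False) -> RunManifest:
    """Execute a full single-condition run and write its outputs.

    Writes ``run_config.json`` (before any computation), ``morphometry.csv``,
    ``ctcf.csv``, ``stats.json`` and ``manifest.json`` under
    ``config.outdir``.  Identical config and seed give byte-identical CSVs.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "run_config.json").write_text(
        json.dumps(config.to_dict(), indent=1, sort_keys=True)
    )
    warnings: list[str] = []
    morpho_frames, ctcf_frames = [], []
    for i in range(config.n_fields):
        try:
            m, c = _measure_field(
                config, i, outdir / "scenes" if write_scenes else None
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'measure' failed on field {i}: {exc}") from exc
        morpho_frames.append(m)
        ctcf_frames.append(c)
    morpho = pd.concat(morpho_frames, ignore_index=True)
    ctcf_table = pd.concat(ctcf_frames, ignore_index=True)
    morpho_path = outdir / "morphometry.csv"
    ctcf_path = outdir / "ctcf.csv"
    morpho.to_csv(morpho_path, index=False)
    ctcf_table.to_csv(ctcf_path, index=False)

    stats: dict[str, Any] = {"descriptors": {}, "phenotype": {}}
    for col in DESCRIPTOR_COLUMNS:
        vals = morpho[col].dropna().to_numpy()
        if len(vals):
            stats["descriptors"][col] = dataclasses.asdict(boxplot_summary(vals))
            stats["descriptors"][col]["mean"] = float(vals.mean())
            stats["descriptors"][col]["sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    counts = morpho["phenotype"].value_counts().to_dict()
    stats["phenotype"] = {
        "counts": {str(k): int(v) for k, v in counts.items()},
        "elongated_polarized_fraction": float(
            (morpho["phenotype"] == "elongated_polarized").mean()
        )
        if len(morpho)
        else float("nan"),
    }
    stats_path = outdir / "stats.json"
    stats_path.write_text(json.dumps(stats, indent=1, sort_keys=True))

    outputs = [outdir / "run_config.json", morpho_path, ctcf_path, stats_path]
    manifest = RunManifest(
        config=config.to_dict(),
        stage_counts={
            "fields": config.n_fields,
            "cells_measured": int(len(morpho)),
            "ctcf_records": int(len(ctcf_table)),
        },
        warnings=warnings,
        output_checksums={p.name: _sha256(p) for p in outputs},
    )
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest


# ---------------------------------------------------------------------------
# simulated experiments


@dataclass
class Condition:
    """One experimental condition and its generator-parameter overrides.

    ``overrides`` may set any :class:`~cytomorph.scenegen.SceneConfig` field
    (for example a different protrusion-length range); they define that
    condition's ground truth.
    """

    substrate: str
    timepoint: str = "D2"
    serum: str = "+FBS"
    overrides: dict[str, Any] = field(default_factory=dict)
    n_fields: int = 2

    @property
    def key(self) -> str:
        return f"{self.substrate}|{self.timepoint}|{self.serum}"


@dataclass
class ExperimentDesign:
    """A grid of conditions sharing a base scene configuration."""

    base_scene: SceneConfig = field(default_factory=SceneConfig)
    conditions: list[Condition] = field(default_factory=list)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    thresholds: PhenotypeThresholds = field(default_factory=PhenotypeThresholds)
    seed: int = 0

    def validate(self) -> None:
        if not self.conditions:
            raise PipelineValidationError("design has no conditions")
        keys = [c.key for c in self.conditions]
        if len(set(keys)) != len(keys):
            raise PipelineValidationError("duplicate condition keys")
        for c in self.conditions:
            unknown = set(c.overrides) - {
                f.name for f in dataclasses.fields(SceneConfig)
            }
            if unknown:
                raise PipelineValidationError(
                    f"condition {c.key}: unknown scene overrides {sorted(unknown)}"
                )

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentDesign":
        d = dict(d)
        if "base_scene" in d and isinstance(d["base_scene"], dict):
            d["base_scene"] = SceneConfig.from_dict(d["base_scene"])
        if "segmentation" in d and isinstance(d["segmentation"], dict):
            d["segmentation"] = SegmentationConfig(**d["segmentation"])
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            d["thresholds"] = PhenotypeThresholds(**d["thresholds"])
        if "conditions" in d:
            d["conditions"] = [
                Condition(**c) if isinstance(c, dict) else c
                for c in d["conditions"]
            ]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentDesign":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise PipelineValidationError(f"{path}: expected a mapping")
        try:
            return cls.from_dict(data)
        except (TypeError, ValueError) as exc:
            raise PipelineValidationError(f"{path}: {exc}") from exc


def simulate_experiment(
    design: ExperimentDesign,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Render and measure a full synthetic study.

    Returns the long-format per-cell group table (substrate, timepoint,
    serum, scene_id, cell_id + descriptors) and a ground-truth record of
    each condition's generator parameters, enabling end-to-end recovery
    checks of injected effects.
    """
    design.validate()
    frames = []
    truth: dict[str, Any] = {}
    for ci, cond in enumerate(design.conditions):
        scene_base = dataclasses.replace(design.base_scene, **cond.overrides)
        truth[cond.key] = {
            "overrides": cond.overrides,
            "scene": scene_base.to_dict(),
        }
        cal = Calibration(scene_base.scale_um_per_px)
        for fi in range(cond.n_fields):
            scene_cfg = dataclasses.replace(
                scene_base, seed=_child_seed(design.seed, 2, ci, fi)
            )
            channels, _ = render_scene(scene_cfg)
            cells, nuclei = segment_scene(channels, design.segmentation)
            table = measure_cells(cells, nuclei, cal, design.thresholds)
            table.insert(0, "scene_id", fi)
            table.insert(0, "serum", cond.serum)
            table.insert(0, "timepoint", cond.timepoint)
            table.insert(0, "substrate", cond.substrate)
            frames.append(table)
    return pd.concat(frames, ignore_index=True), truth


def measure_with_truth(
    scene_cfg: SceneConfig,
    seg: SegmentationConfig | None = None,
    thresholds: PhenotypeThresholds | None = None,
    true_shape: bool = True,
) -> pd.DataFrame:
    """Render a scene, measure it through the full segmentation pipeline and
    join each measured cell with its generator ground truth.

    Measured cells are matched to true cells through the ground-truth label
    under the measured centroid.  Adds columns ``true_phenotype``,
    ``true_extent_px`` (body + protrusion), ``true_protrusion_px`` and, when
    ``true_shape``, ``true_ar``/``true_feret_px`` measured on the true mask
    (the moment aspect ratio of a polarized cell has no closed form, so the
    true mask is the reference).  Unmatched cells (segmentation artifacts)
    are dropped.
    """
    from .morphometry import aspect_ratio, region_properties

    channels, truth = render_scene(scene_cfg)
    cells, nuclei = segment_scene(channels, seg or SegmentationConfig())
    cal = Calibration(scene_cfg.scale_um_per_px)
    table = measure_cells(cells, nuclei, cal, thresholds)
    gt_lab = truth.label_image
    rows = []
    for _, row in table.iterrows():
        r = int(round(row["centroid_y"]))
        c = int(round(row["centroid_x"]))
        if not (0 <= r < gt_lab.shape[0] and 0 <= c < gt_lab.shape[1]):
            continue
        g = int(gt_lab[r, c])
        if g == 0:
            continue
        cell = truth.cells[g - 1]
        rec = row.to_dict()
        rec["true_phenotype"] = cell.params.phenotype
        rec["true_extent_px"] = cell.params.extent_px
        rec["true_protrusion_px"] = cell.params.protrusion_length_px
        if true_shape:
            props = region_properties(gt_lab, g)
            rec["true_ar"] = aspect_ratio(props)
            rec["true_feret_px"] = props.feret_max_px
        rows.append(rec)
    return pd.DataFrame(rows)


def compare_conditions(
    group_table: pd.DataFrame,
    descriptor: str,
    by: str = "substrate",
    adjustment: str = "bonferroni",
):
    """Dunn's post-hoc comparison of one descriptor across condition groups."""
    if descriptor not in group_table.columns:
        raise PipelineValidationError(f"unknown descriptor {descriptor!r}")
    labels, groups = [], []
    for key, sub in group_table.groupby(by, sort=True):
        vals = sub[descriptor].dropna().to_numpy()
        if len(vals):
            labels.append(str(key))
            groups.append(vals)
    return dunn_test(groups, labels=labels, adjustment=adjustment)
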