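"""Synthetic fluorescence-scene generation with full ground truth.

Generates multi-channel fluorescence micrographs of two cell phenotypes:

* ``mesenchymal`` — spread, fibroblast-like cells modelled as ellipses with an
  optional low-frequency boundary ripple;
* ``polarized`` — elongated cells with an elliptical body enlargement at one
  pole and a single long, linearly tapering protrusion at the opposite pole,
  the morphology that marks neuronal-like conversion.

Each scene carries complete ground truth (per-cell parameters, binary cell
and nucleus masks, the noise-free channel images and the true shading field)
so that every downstream measurement can be validated against known values.

The intensity model is multiplicative: ``(signal + background) * shading``
followed by additive Gaussian noise and optional Poisson noise, matching the
flat-field assumption of the illumination-correction stage.  Output images
are 16-bit unsigned, clipped.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import tifffile

__all__ = [
    "CellParams",
    "SceneConfig",
    "PlacedCell",
    "SceneGroundTruth",
    "PlacementError",
    "make_mesenchymal_mask",
    "make_polarized_mask",
    "render_scene",
    "write_scene",
    "read_scene_config",
]

Phenotype = Literal["mesenchymal", "polarized"]

NUCLEAR_CHANNEL = "dapi"


class PlacementError(RuntimeError):
    """Raised when a cell cannot be placed without mask overlap."""


@dataclass
class CellParams:
    """True geometric and intensity parameters of one synthetic cell.

    Lengths are full axis lengths in pixels.  ``orientation_deg`` is the
    angle of the body major axis, measured counter-clockwise from the image
    x-axis (y pointing up), in [0, 180).  ``nucleus_offset_frac`` displaces
    the nucleus centre along the major axis toward the protrusion neck, as a
    fraction of the body semi-major axis.
    """

    phenotype: Phenotype
    body_major_px: float
    body_minor_px: float
    orientation_deg: float
    nucleus_major_px: float
    nucleus_minor_px: float
    protrusion_length_px: float = 0.0
    protrusion_width_px: float = 0.0
    nucleus_offset_frac: float = 0.0
    channel_levels: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.body_major_px >= self.body_minor_px > 0):
            raise ValueError(
                "body axes must satisfy body_major_px >= body_minor_px > 0"
            )
        if self.nucleus_major_px >= self.body_major_px or (
            self.nucleus_minor_px >= self.body_minor_px
        ):
            raise ValueError("nucleus axes must be smaller than body axes")
        if not (self.nucleus_major_px >= self.nucleus_minor_px > 0):
            raise ValueError("nucleus axes must be positive, major >= minor")
        if self.phenotype == "polarized":
            if self.protrusion_length_px <= 0 or self.protrusion_width_px <= 0:
                raise ValueError(
                    "polarized cells require positive protrusion length/width"
                )
        elif self.protrusion_length_px != 0 or self.protrusion_width_px != 0:
            raise ValueError("mesenchymal cells must have no protrusion")
        if not 0 <= self.nucleus_offset_frac <= 1:
            raise ValueError("nucleus_offset_frac must lie in [0, 1]")
        if any(v < 0 for v in self.channel_levels.values()):
            raise ValueError("channel levels must be >= 0")

    @property
    def extent_px(self) -> float:
        """Tip-to-far-pole length: body major axis plus protrusion length."""
        return self.body_major_px + self.protrusion_length_px


def _uniform_range(rng: np.random.Generator, lohi: tuple[float, float]) -> float:
    lo, hi = lohi
    if hi < lo:
        raise ValueError(f"invalid range {lohi}")
    return float(rng.uniform(lo, hi))


@dataclass
class SceneConfig:
    """Configuration of one synthetic field of view.

    Defaults describe the study conditions: a 1388x1040 px camera field at
    0.32 um/px (20x objective), with the parameter ranges given in pixels at
    that calibration.  Tests and examples typically pass smaller frames with
    correspondingly scaled cells; every default is exposed here.

    Parameter ranges are uniform ``(low, high)`` intervals.  ``channel_levels``
    maps marker channel names to intensity ranges; the nuclear channel
    (``"dapi"``) is rendered from the nucleus masks at ``dapi_level``.
    """

    width_px: int = 1388
    height_px: int = 1040
    n_cells: int = 12
    polarized_fraction: float = 0.43
    seed: int = 0
    scale_um_per_px: float = 0.32

    # mesenchymal (spread) bodies: AR ~ 1-2, diameter ~ 20-30 um at 0.32 um/px
    mesenchymal_major_px: tuple[float, float] = (70.0, 110.0)
    mesenchymal_minor_px: tuple[float, float] = (50.0, 80.0)
    # polarized bodies are narrower, with one long protrusion (41-116 um range
    # reported for the fastest-converting substrate maps to ~128-360 px)
    polarized_major_px: tuple[float, float] = (50.0, 80.0)
    polarized_minor_px: tuple[float, float] = (28.0, 45.0)
    protrusion_length_px: tuple[float, float] = (128.0, 360.0)
    protrusion_width_px: tuple[float, float] = (6.0, 10.0)

    nucleus_frac: tuple[float, float] = (0.35, 0.5)
    nucleus_offset_frac: tuple[float, float] = (0.3, 0.5)

    channel_levels: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"phalloidin": (120.0, 160.0)}
    )
    dapi_level: tuple[float, float] = (150.0, 200.0)

    background_level: float = 100.0
    shading_amplitude: float = 0.3
    shading_sigma_frac: float = 0.4  # sigma as fraction of min(frame dims)
    noise_gaussian_sd: float = 5.0
    poisson_noise: bool = False

    ripple_amplitude: float = 0.0
    placement_margin_px: int = 5
    max_placement_retries: int = 100

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("frame dimensions must be positive")
        if not 0 <= self.polarized_fraction <= 1:
            raise ValueError("polarized_fraction must lie in [0, 1]")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.scale_um_per_px <= 0:
            raise ValueError("scale_um_per_px must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        for key in (
            "mesenchymal_major_px",
            "mesenchymal_minor_px",
            "polarized_major_px",
            "polarized_minor_px",
            "protrusion_length_px",
            "protrusion_width_px",
            "nucleus_frac",
            "nucleus_offset_frac",
            "dapi_level",
        ):
            if key in d:
                d[key] = tuple(d[key])
        if "channel_levels" in d:
            d["channel_levels"] = {
                k: tuple(v) for k, v in d["channel_levels"].items()
            }
        return cls(**d)


@dataclass
class PlacedCell:
    """One cell of a rendered scene: parameters, position and true masks."""

    index: int
    params: CellParams
    center_xy: tuple[float, float]
    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    nucleus_center_xy: tuple[float, float]


@dataclass
class SceneGroundTruth:
    """Everything the generator knows about a scene.

    ``clean_channels`` are the noise-free, shading-free signal images
    (signal + background); ``shading`` is the true multiplicative field.
    """

    config: SceneConfig
    cells: list[PlacedCell]
    shading: np.ndarray
    clean_channels: dict[str, np.ndarray]

    @property
    def label_image(self) -> np.ndarray:
        """Cell masks as a label image (labels 1..n in placement order)."""
        lab = np.zeros(self.shading.shape, dtype=np.int32)
        for cell in self.cells:
            lab[cell.cell_mask] = cell.index + 1
        return lab

    @property
    def nucleus_label_image(self) -> np.ndarray:
        lab = np.zeros(self.shading.shape, dtype=np.int32)
        for cell in self.cells:
            lab[cell.nucleus_mask] = cell.index + 1
        return lab


def _rotated_coords(
    shape: tuple[int, int], center_xy: tuple[float, float], orientation_deg: float
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates along (u) and across (v) the cell axis, y-up convention."""
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    dx = xs - center_xy[0]
    dy = -(ys - center_xy[1])  # y up so angles are counter-clockwise
    th = np.deg2rad(orientation_deg)
    u = dx * np.cos(th) + dy * np.sin(th)
    v = -dx * np.sin(th) + dy * np.cos(th)
    return u, v


def _ellipse_mask(
    shape: tuple[int, int],
    center_xy: tuple[float, float],
    major_px: float,
    minor_px: float,
    orientation_deg: float,
    ripple_amplitude: float = 0.0,
    ripple_waves: int = 3,
    ripple_phase: float = 0.0,
) -> np.ndarray:
    u, v = _rotated_coords(shape, center_xy, orientation_deg)
    a, b = major_px / 2.0, minor_px / 2.0
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    if ripple_amplitude > 0:
        phi = np.arctan2(v, u)
        rho = rho / (1.0 + ripple_amplitude * np.cos(ripple_waves * phi + ripple_phase))
    return rho <= 1.0


def make_mesenchymal_mask(
    params: CellParams,
    frame_shape: tuple[int, int],
    center_xy: tuple[float, float] | None = None,
    ripple_amplitude: float = 0.0,
    ripple_waves: int = 3,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Rasterize a spread fibroblast-like cell as an (optionally rippled) ellipse.

    The ripple is a low-frequency radial modulation of the boundary; its
    amplitude is a fraction of the local radius and should stay <= 0.1 so the
    perturbation does not exceed ~10% of the minor axis.  With a fixed ``rng``
    state the ripple phase, and hence the mask, is reproducible.
    """
    if params.phenotype != "mesenchymal":
        raise ValueError("params.phenotype must be 'mesenchymal'")
    if center_xy is None:
        center_xy = (frame_shape[1] / 2.0, frame_shape[0] / 2.0)
    phase = 0.0
    if ripple_amplitude > 0:
        if ripple_amplitude > 0.1:
            raise ValueError("ripple_amplitude must be <= 0.1")
        phase = float((rng or np.random.default_rng()).uniform(0, 2 * np.pi))
    mask = _ellipse_mask(
        frame_shape,
        center_xy,
        params.body_major_px,
        params.body_minor_px,
        params.orientation_deg,
        ripple_amplitude,
        ripple_waves,
        phase,
    )
    if not mask.any():
        raise ValueError("cell does not intersect the frame")
    return mask


def make_polarized_mask(
    params: CellParams,
    frame_shape: tuple[int, int],
    center_xy: tuple[float, float] | None = None,
) -> np.ndarray:
    """Rasterize a polarized cell: elliptical body fused with one tapering protrusion.

    The protrusion emanates from the body pole at +major/2 along the
    orientation axis and tapers linearly from ``protrusion_width_px`` at the
    neck to 2 px at the tip, so the tip-to-far-pole extent equals
    ``body_major_px + protrusion_length_px``.
    """
    if params.phenotype != "polarized":
        raise ValueError("params.phenotype must be 'polarized'")
    if params.protrusion_length_px <= 0:
        raise ValueError("protrusion_length_px must be > 0 for polarized cells")
    if center_xy is None:
        center_xy = (frame_shape[1] / 2.0, frame_shape[0] / 2.0)
    body = _ellipse_mask(
        frame_shape,
        center_xy,
        params.body_major_px,
        params.body_minor_px,
        params.orientation_deg,
    )
    u, v = _rotated_coords(frame_shape, center_xy, params.orientation_deg)
    a = params.body_major_px / 2.0
    L = params.protrusion_length_px
    w0 = params.protrusion_width_px
    # start a couple of px inside the body so the union is connected
    start = a - 2.0
    frac = np.clip((u - a) / L, 0.0, 1.0)
    half_width = (w0 + (2.0 - w0) * frac) / 2.0
    protrusion = (u >= start) & (u <= a + L) & (np.abs(v) <= half_width)
    mask = body | protrusion
    if not mask.any():
        raise ValueError("cell does not intersect the frame")
    return mask


def make_cell_mask(
    params: CellParams,
    frame_shape: tuple[int, int],
    center_xy: tuple[float, float] | None = None,
    **kwargs,
) -> np.ndarray:
    if params.phenotype == "polarized":
        return make_polarized_mask(params, frame_shape, center_xy)
    return make_mesenchymal_mask(params, frame_shape, center_xy, **kwargs)


def _nucleus_center(
    params: CellParams, center_xy: tuple[float, float]
) -> tuple[float, float]:
    off = params.nucleus_offset_frac * params.body_major_px / 2.0
    th = np.deg2rad(params.orientation_deg)
    # offset toward the protrusion neck (+u direction); y-up convention
    return (center_xy[0] + off * np.cos(th), center_xy[1] - off * np.sin(th))


def _sample_cell_params(cfg: SceneConfig, rng: np.random.Generator) -> CellParams:
    polarized = rng.random() < cfg.polarized_fraction
    if polarized:
        major = _uniform_range(rng, cfg.polarized_major_px)
        minor = _uniform_range(rng, cfg.polarized_minor_px)
        length = _uniform_range(rng, cfg.protrusion_length_px)
        width = _uniform_range(rng, cfg.protrusion_width_px)
        offset = _uniform_range(rng, cfg.nucleus_offset_frac)
    else:
        major = _uniform_range(rng, cfg.mesenchymal_major_px)
        minor = _uniform_range(rng, cfg.mesenchymal_minor_px)
        length = width = 0.0
        offset = 0.0
    major, minor = max(major, minor), min(major, minor)
    nfrac = _uniform_range(rng, cfg.nucleus_frac)
    levels = {
        name: _uniform_range(rng, lohi) for name, lohi in cfg.channel_levels.items()
    }
    levels[NUCLEAR_CHANNEL] = _uniform_range(rng, cfg.dapi_level)
    return CellParams(
        phenotype="polarized" if polarized else "mesenchymal",
        body_major_px=major,
        body_minor_px=minor,
        orientation_deg=float(rng.uniform(0.0, 180.0)),
        nucleus_major_px=nfrac * major,
        nucleus_minor_px=nfrac * minor,
        protrusion_length_px=length,
        protrusion_width_px=width,
        nucleus_offset_frac=offset,
        channel_levels=levels,
    )


def _shading_field(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field: a 2-D Gaussian bump, normalized to mean 1."""
    h, w = cfg.height_px, cfg.width_px
    if cfg.shading_amplitude == 0:
        return np.ones((h, w))
    sigma = cfg.shading_sigma_frac * min(h, w)
    cx = rng.uniform(0.3 * w, 0.7 * w)
    cy = rng.uniform(0.3 * h, 0.7 * h)
    ys, xs = np.mgrid[0:h, 0:w]
    bump = np.exp(-(((xs - cx) ** 2) + (ys - cy) ** 2) / (2 * sigma**2))
    fieldim = 1.0 + cfg.shading_amplitude * bump
    return fieldim / fieldim.mean()


def _place_cells(cfg: SceneConfig, rng: np.random.Generator) -> list[PlacedCell]:
    from scipy.ndimage import binary_dilation

    shape = (cfg.height_px, cfg.width_px)
    occupied = np.zeros(shape, dtype=bool)
    margin = max(int(cfg.placement_margin_px), 0)
    struct = np.ones((2 * margin + 1, 2 * margin + 1), dtype=bool) if margin else None
    cells: list[PlacedCell] = []
    for idx in range(cfg.n_cells):
        params = _sample_cell_params(cfg, rng)
        placed = False
        for _ in range(cfg.max_placement_retries):
            cx = rng.uniform(0, cfg.width_px)
            cy = rng.uniform(0, cfg.height_px)
            mask = make_cell_mask(
                params, shape, (cx, cy), ripple_amplitude=cfg.ripple_amplitude, rng=rng
            )
            # reject masks clipped by the frame: their true area must be intact
            if _touches_border(mask):
                continue
            dilated = binary_dilation(mask, struct) if struct is not None else mask
            if (dilated & occupied).any():
                continue
            occupied |= dilated
            ncx, ncy = _nucleus_center(params, (cx, cy))
            nucleus = _ellipse_mask(
                shape,
                (ncx, ncy),
                params.nucleus_major_px,
                params.nucleus_minor_px,
                params.orientation_deg,
            )
            cells.append(
                PlacedCell(idx, params, (cx, cy), mask, nucleus & mask, (ncx, ncy))
            )
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place cell {idx + 1}/{cfg.n_cells} without overlap "
                f"after {cfg.max_placement_retries} retries; reduce n_cells or "
                f"cell sizes, or enlarge the frame"
            )
    return cells


def _touches_border(mask: np.ndarray) -> bool:
    return bool(
        mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any()
    )


def render_scene(
    config: SceneConfig,
) -> tuple[dict[str, np.ndarray], SceneGroundTruth]:
    """Render all channels of one synthetic field and return ground truth.

    Channels are the marker channels named in ``config.channel_levels`` plus
    the nuclear channel ``"dapi"``.  Rendering is fully determined by the
    config (including its seed): identical configs give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.height_px, config.width_px)
    cells = _place_cells(config, rng)
    shading = _shading_field(config, rng)

    channel_names = list(config.channel_levels) + [NUCLEAR_CHANNEL]
    clean: dict[str, np.ndarray] = {}
    for name in channel_names:
        signal = np.zeros(shape)
        for cell in cells:
            level = cell.params.channel_levels.get(name, 0.0)
            target = cell.nucleus_mask if name == NUCLEAR_CHANNEL else cell.cell_mask
            signal[target] += level
        clean[name] = signal + config.background_level

    channels: dict[str, np.ndarray] = {}
    for name in channel_names:
        img = clean[name] * shading
        if config.poisson_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if config.noise_gaussian_sd > 0:
            img = img + rng.normal(0.0, config.noise_gaussian_sd, size=shape)
        channels[name] = np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    return channels, SceneGroundTruth(config, cells, shading, clean)


# ---------------------------------------------------------------------------
# scene I/O


def write_scene(
    outdir: str | Path,
    channels: dict[str, np.ndarray],
    truth: SceneGroundTruth,
    prefix: str = "scene",
) -> dict[str, Path]:
    """Write channel TIFFs, mask label TIFFs and a ground-truth JSON.

    Returns a map of logical names to written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, img in channels.items():
        p = outdir / f"{prefix}_{name}.tif"
        tifffile.imwrite(p, img)
        written[f"channel:{name}"] = p
    for name, lab in (
        ("cells", truth.label_image),
        ("nuclei", truth.nucleus_label_image),
    ):
        p = outdir / f"{prefix}_labels_{name}.tif"
        tifffile.imwrite(p, lab.astype(np.uint16))
        written[f"labels:{name}"] = p
    gt = {
        "config": truth.config.to_dict(),
        "cells": [
            {
                "index": c.index,
                "center_xy": list(c.center_xy),
                "nucleus_center_xy": list(c.nucleus_center_xy),
                "params": dataclasses.asdict(c.params),
            }
            for c in truth.cells
        ],
    }
    p = outdir / f"{prefix}_ground_truth.json"
    p.write_text(json.dumps(gt, indent=1))
    written["ground_truth"] = p
    return written


def read_scene_config(path: str | Path) -> SceneConfig:
    """Read a scene config from a YAML/JSON key-value file."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of config keys")
    return SceneConfig.from_dict(data)
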