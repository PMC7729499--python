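"""Shared fixtures: small, fast synthetic-scene configurations.

The recovery fixtures render a few hundred cells once per session (they are
shared by the morphometry property tests and the acceptance suite).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from cytomorph import SceneConfig
from cytomorph.pipeline import SegmentationConfig, measure_with_truth


def small_scene(seed: int = 0, **overrides) -> SceneConfig:
    """A 512x512 test scene at 1 um/px with modestly sized cells."""
    base = dict(
        width_px=512,
        height_px=512,
        n_cells=8,
        polarized_fraction=0.5,
        seed=seed,
        scale_um_per_px=1.0,
        mesenchymal_major_px=(55, 80),
        mesenchymal_minor_px=(38, 55),
        polarized_major_px=(36, 50),
        polarized_minor_px=(20, 30),
        protrusion_length_px=(80, 150),
        protrusion_width_px=(6, 10),
        noise_gaussian_sd=5.0,
    )
    base.update(overrides)
    return SceneConfig(**base)


SEG = SegmentationConfig(min_cell_area_px=150, min_nucleus_area_px=20)


def _recovery_table(noise_sd: float, n_target: int = 300) -> pd.DataFrame:
    frames = []
    seed = 0
    total = 0
    while total < n_target:
        cfg = small_scene(
            seed=seed, noise_gaussian_sd=noise_sd, shading_amplitude=0.0
        )
        tab = measure_with_truth(cfg, SEG)
        frames.append(tab)
        total += len(tab)
        seed += 1
    return pd.concat(frames, ignore_index=True).iloc[:n_target]


@pytest.fixture(scope="session")
def recovery_noise_free() -> pd.DataFrame:
    """300 measured cells from noise-free, shading-free scenes, with truth."""
    return _recovery_table(noise_sd=0.0)


@pytest.fixture(scope="session")
def recovery_default_noise() -> pd.DataFrame:
    """300 measured cells at the default Gaussian noise level, with truth."""
    return _recovery_table(noise_sd=5.0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
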