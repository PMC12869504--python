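"""Shared fixtures: a small, fully ground-truthed phantom and its pipeline run.

The small phantom keeps the unit suite fast: a 128×128×80-voxel canvas with
a 95/45 µm annulus.  Canal densities are raised relative to the full-size
presets so that each region still receives canals at this reduced cortex
volume; the WT-style regional structure (posterior-dominant canals, ×2
peri-canal volume multiplier in the posterior only) is preserved.
"""

from __future__ import annotations

import numpy as np
import pytest

import cortimap as cm


SMALL_GEOMETRY = dict(
    shape=(80, 128, 128),
    outer_radius_um=95.0,
    wall_thickness_um=45.0,
    canal_radius_um=(3.0, 5.0),
    canal_surface_margin_um=14.0,
    canal_density_per_mm3={"posterior": 4400.0, "lateral": 1500.0,
                           "medial": 1500.0, "anterior": 1500.0},
    lacuna_density_per_mm3=40_000.0,
    noise_count=40,
)


@pytest.fixture(scope="session")
def small_kwargs() -> dict:
    return dict(SMALL_GEOMETRY)


@pytest.fixture(scope="session")
def wt_small_result(small_kwargs) -> cm.PipelineResult:
    """Full pipeline run (native orientation) on the small WT-like phantom."""
    config = cm.RunConfig(
        phantom_preset="wt", seed=7, orient=False, phantom_overrides=small_kwargs
    )
    return cm.run_pipeline(config)


@pytest.fixture(scope="session")
def wt_small_truth(wt_small_result) -> cm.PhantomTruth:
    return wt_small_result.truth


def random_blob_mask(rng: np.random.Generator, shape: tuple[int, int, int],
                     p: float = 0.35, smooth: bool = True) -> np.ndarray:
    """Random binary mask with some spatial structure (for oracle tests)."""
    from scipy import ndimage as ndi

    noise = rng.random(shape)
    if smooth:
        noise = ndi.uniform_filter(noise, size=3)
    return noise < p
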