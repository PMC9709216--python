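"""Shared phantom fixtures.

The expensive phantoms are session-scoped so the recovery, metric and
acceptance tests all reuse one generation + one pipeline run each.
Study conditions (frozen):

* slab 64³ @ 2 µm, uniform axis HA=30°, IA=0°, kappa=inf, seed 11;
  estimator sigma=1, window 13 (uniform field → window limited only by
  homogeneity, ~3 aggregate diameters);
* shell 128³ @ 2 µm, HA +60°→−60°, IA=0°, kappa=20, seed 2; window 7
  (< wall/3 so the transmural HA variation is resolved);
* shell 128³ @ 2 µm, same HA law, kappa=inf, seed 4; window 7 — the
  noise-free twin used for depth, geometry and classification checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import myoarch as ma
from myoarch.pipeline import PipelineConfig, PipelineResult, run_pipeline_arrays

SLAB_WINDOW = 13
SHELL_WINDOW = 7


@dataclass
class SlabStudy:
    spec: ma.PhantomSpec
    volume: ma.ImageVolume
    mask: np.ndarray
    truth: ma.TruthField
    orient: ma.OrientationField


@dataclass
class ShellStudy:
    spec: ma.PhantomSpec
    volume: ma.ImageVolume
    mask: np.ndarray
    truth: ma.TruthField
    geometry: ma.ProlateGeometry
    result: PipelineResult


def axis_error_deg(v3: np.ndarray, truth_axis: np.ndarray) -> np.ndarray:
    """Per-voxel angle (degrees) between two sign-free axis fields."""
    dot = np.abs(np.sum(v3 * truth_axis, axis=-1))
    return np.degrees(np.arccos(np.clip(dot, 0.0, 1.0)))


def estimate_orientation(volume, mask, window, sigma=1.0):
    grad = ma.compute_gradient(volume, sigma=sigma)
    tens = ma.compute_structure_tensor(grad, window=window, mask=mask)
    return ma.eigendecompose(tens, mask=mask)


@pytest.fixture(scope="session")
def slab_study() -> SlabStudy:
    spec = ma.PhantomSpec(shape=(64, 64, 64), geometry_kind="slab",
                          ha_endo_deg=30.0, ia_deg=0.0, seed=11)
    volume, mask, truth = ma.make_slab_phantom(spec)
    orient = estimate_orientation(volume, mask > 0, SLAB_WINDOW)
    return SlabStudy(spec, volume, mask, truth, orient)


@pytest.fixture(scope="session")
def shell_study() -> ShellStudy:
    """128³ shell with kappa=20 orientation noise, full fitted pipeline."""
    spec = ma.PhantomSpec(shape=(128, 128, 128), ha_endo_deg=60.0,
                          ha_epi_deg=-60.0, kappa=20.0, seed=2)
    volume, mask, truth, geometry = ma.make_shell_phantom(spec)
    cfg = PipelineConfig(tensor_window=SHELL_WINDOW)
    result = run_pipeline_arrays(volume, mask, cfg)
    return ShellStudy(spec, volume, mask, truth, geometry, result)


@pytest.fixture(scope="session")
def disordered_shell_study() -> ShellStudy:
    """128³ shell with strong orientation noise (kappa=1), full pipeline.

    Weak orientation noise is largely absorbed by the structure tensor's
    spatial averaging; kappa=1 (~40° angular spread) leaves disarray the
    estimator can actually see.
    """
    spec = ma.PhantomSpec(shape=(128, 128, 128), ha_endo_deg=60.0,
                          ha_epi_deg=-60.0, kappa=1.0, seed=4)
    volume, mask, truth, geometry = ma.make_shell_phantom(spec)
    cfg = PipelineConfig(tensor_window=SHELL_WINDOW)
    result = run_pipeline_arrays(volume, mask, cfg)
    return ShellStudy(spec, volume, mask, truth, geometry, result)


@pytest.fixture(scope="session")
def clean_shell_study() -> ShellStudy:
    """128³ noise-free-orientation shell (kappa=inf), full pipeline."""
    spec = ma.PhantomSpec(shape=(128, 128, 128), ha_endo_deg=60.0,
                          ha_epi_deg=-60.0, seed=4)
    volume, mask, truth, geometry = ma.make_shell_phantom(spec)
    cfg = PipelineConfig(tensor_window=SHELL_WINDOW)
    result = run_pipeline_arrays(volume, mask, cfg)
    return ShellStudy(spec, volume, mask, truth, geometry, result)
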