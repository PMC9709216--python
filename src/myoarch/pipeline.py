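"""End-to-end orientation-quantification pipeline.

Stages: isotropic resampling → structure tensor → eigen-decomposition →
FA → LV prolate geometry → HA/IA maps → MDI → wall sectors / apico-basal
levels → angle classifications → transmural profile fits → AHA segment
summaries. Everything is deterministic given the configuration.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from . import geometry as geo
from . import metrics, profiles, tensor
from .glyphs import export_glyphs
from .tensor import OrientationField
from .volume import ImageVolume, read_volume, write_nrrd, resample_isotropic

logger = logging.getLogger("myoarch")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "run_pipeline_arrays", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on, YAML round-trippable."""

    volume_path: str = ""
    mask_path: str = ""
    output_dir: str = "myoarch_out"
    voxel_size_um: list[float] | None = None   # required for TIFF inputs
    smoothing_sigma: float = 1.0               # voxels, before gradients
    tensor_window: int = 3                     # odd cube side, voxels
    degeneracy_tau: float = 0.05
    erode_mask_voxels: int = 1                 # analysis-mask erosion
    mdi_window: int = 11
    ha_threshold_deg: float = 20.0
    ia_low_deg: float = 15.0
    ia_high_deg: float = 45.0
    level_positions: list[float] = field(default_factory=lambda: [0.75, 0.5, 0.25])
    level_thickness_voxels: int = 5
    projected_angles: bool = False
    seed: int = 0
    log_level: str = "INFO"
    glyph_slices: int | None = None            # z-slice for glyph export

    def validate(self) -> None:
        for name in ("ha_threshold_deg", "ia_low_deg", "ia_high_deg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tensor_window % 2 != 1 or self.mdi_window % 2 != 1:
            raise ValueError("tensor_window and mdi_window must be odd")


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=True))


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text())
    return PipelineConfig(**data)


@dataclass
class PipelineResult:
    """In-memory bundle of every map and table the pipeline produces."""

    orient: OrientationField
    fa: np.ndarray
    mdi: metrics.DisarrayMap
    ha: np.ndarray
    ia: np.ndarray
    depth: np.ndarray
    sectors: np.ndarray
    levels: np.ndarray
    aha: np.ndarray
    geometry: geo.ProlateGeometry
    analysis_mask: np.ndarray
    profile_fits: pd.DataFrame
    region_summary: pd.DataFrame
    aha_summary: pd.DataFrame
    voxel_size_um: float


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-12s %6.2f s", name, t1 - t0)
    return t1


def run_pipeline_arrays(volume: ImageVolume, mask: np.ndarray,
                        config: PipelineConfig | None = None,
                        geometry: geo.ProlateGeometry | None = None,
                        ) -> PipelineResult:
    """Run the full pipeline on in-memory arrays.

    ``mask`` is a label volume (0 background, 1 LV free wall, 2 septum,
    3 RV free wall). If ``geometry`` is None the LV prolate frame is
    fitted from the mask.
    """
    cfg = config or PipelineConfig()
    cfg.validate()
    t0 = time.perf_counter()
    if not volume.is_isotropic:
        mask_vol = resample_isotropic(
            ImageVolume(np.asarray(mask), volume.voxel_size_um), order=0)
        volume = resample_isotropic(volume)
        mask = mask_vol.values
        t0 = _stage("resample", t0)
    voxel = float(volume.voxel_size_um[0])
    labels = np.asarray(mask)
    wall = labels > 0
    if labels.shape != volume.shape:
        raise ValueError(f"mask shape {labels.shape} does not match volume "
                         f"{volume.shape}")

    analysis = wall
    if cfg.erode_mask_voxels > 0:
        analysis = ndimage.binary_erosion(wall,
                                          iterations=cfg.erode_mask_voxels)
    grad = tensor.compute_gradient(volume, sigma=cfg.smoothing_sigma)
    t0 = _stage("gradient", t0)
    tens = tensor.compute_structure_tensor(grad, window=cfg.tensor_window,
                                           mask=analysis)
    t0 = _stage("tensor", t0)
    orient = tensor.eigendecompose(tens, mask=analysis, tau=cfg.degeneracy_tau)
    n_valid = int(orient.valid.sum())
    logger.info("valid axis voxels: %d / %d (%.1f%%)", n_valid,
                int(analysis.sum()), 100.0 * n_valid / max(analysis.sum(), 1))
    t0 = _stage("eigen", t0)
    fa = tensor.fractional_anisotropy(orient.eigenvalues, orient.valid)
    t0 = _stage("fa", t0)

    cavity, outside = profiles.find_shell_surfaces(wall)
    if geometry is None:
        geometry = geo.fit_lv_ellipsoid(labels, voxel, cavity=cavity)
    t0 = _stage("geometry", t0)
    ha, ia = geo.compute_angles(orient.v3, orient.valid, geometry, voxel,
                                projected=cfg.projected_angles)
    t0 = _stage("angles", t0)
    mdi = metrics.compute_mdi(orient, window=cfg.mdi_window,
                              voxel_size_um=voxel)
    t0 = _stage("mdi", t0)

    # continue the shell past the open basal rim before the distance
    # transforms, so depths near the cut behave like mid-shell
    if abs(geometry.long_axis[2]) > 0.9:
        basal_sign = +1 if geometry.long_axis[2] >= 0 else -1
        wall_ext = profiles.extend_wall_basally(wall, basal_sign)
        cav_e, out_e = profiles.find_shell_surfaces(wall_ext)
        depth = profiles.transmural_depth(wall_ext, cav_e, out_e, voxel)
        depth[~wall] = np.nan
    else:
        depth = profiles.transmural_depth(wall, cavity, outside, voxel)
    sectors, levels = profiles.define_walls_and_levels(
        labels, geometry, voxel,
        level_positions=tuple(cfg.level_positions),
        slab_thickness_voxels=cfg.level_thickness_voxels)
    try:
        aha = metrics.aha_segmentation(labels, geometry, voxel)
    except ValueError:
        aha = np.zeros_like(labels, dtype=np.int16)
        logger.warning("AHA segmentation skipped (no RV anchor)")
    t0 = _stage("regions", t0)

    fits = profiles.fit_all_profiles(depth, ha, ia, sectors, levels)
    region_masks = {"lv_free_wall": labels == 1, "septum": labels == 2,
                    "rv_free_wall": labels == 3}
    region_masks = {k: v for k, v in region_masks.items() if v.any()}
    summary = metrics.summarize_regions(
        region_masks, ha, ia, fa=fa, mdi=mdi.values,
        ha_threshold=cfg.ha_threshold_deg, ia_low=cfg.ia_low_deg,
        ia_high=cfg.ia_high_deg)
    aha_masks = {f"aha_{s:02d}": aha == s for s in range(1, 17)
                 if (aha == s).any()}
    aha_summary = metrics.summarize_regions(
        aha_masks, ha, ia, fa=fa, mdi=mdi.values,
        ha_threshold=cfg.ha_threshold_deg, ia_low=cfg.ia_low_deg,
        ia_high=cfg.ia_high_deg) if aha_masks else pd.DataFrame()
    _stage("summaries", t0)
    return PipelineResult(orient=orient, fa=fa, mdi=mdi, ha=ha, ia=ia,
                          depth=depth, sectors=sectors, levels=levels,
                          aha=aha, geometry=geometry, analysis_mask=analysis,
                          profile_fits=fits, region_summary=summary,
                          aha_summary=aha_summary, voxel_size_um=voxel)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-to-files pipeline: read inputs, run, write the report bundle.

    Outputs under ``config.output_dir``: NRRD maps (FA, MDI, HA, IA,
    depth, sector/level/AHA labels), CSV tables (profile fits, region and
    AHA summaries), a VTK glyph file for one slice, the config snapshot,
    and a plain-text run log.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level.upper())
    try:
        vs = tuple(config.voxel_size_um) if config.voxel_size_um else None
        volume = read_volume(config.volume_path, vs)
        mask_vol = read_volume(config.mask_path, vs)
        logger.info("volume %s %s at %s µm", config.volume_path,
                    volume.shape, volume.voxel_size_um)
        result = run_pipeline_arrays(volume, mask_vol.values, config)
        voxel = result.voxel_size_um
        for name, arr in (("fa", result.fa), ("mdi", result.mdi.values),
                          ("ha", result.ha), ("ia", result.ia),
                          ("depth", result.depth)):
            write_nrrd(out / f"{name}.nrrd", np.asarray(arr, np.float32),
                       (voxel,) * 3)
        for name, arr in (("sectors", result.sectors),
                          ("levels", result.levels), ("aha", result.aha)):
            write_nrrd(out / f"{name}.nrrd", arr.astype(np.int16),
                       (voxel,) * 3)
        write_nrrd(out / "v3.nrrd",
                   np.moveaxis(result.orient.v3, -1, 0).astype(np.float32),
                   (voxel,) * 3, vector_axis=True)
        result.profile_fits.to_csv(out / "profile_fits.csv", index=False)
        result.region_summary.to_csv(out / "region_summary.csv", index=False)
        result.aha_summary.to_csv(out / "aha_summary.csv", index=False)
        z = config.glyph_slices
        if z is None:
            z = int(np.argwhere(result.orient.valid)[:, 2].mean())
        try:
            export_glyphs(out / "glyphs.vtk", result.orient.v3, result.ha,
                          result.orient.valid, voxel, z_slices=z)
        except ValueError as exc:
            logger.warning("glyph export skipped: %s", exc)
        save_config(config, out / "config_snapshot.yaml")
        g = result.geometry
        (out / "geometry.txt").write_text(
            "# LV prolate geometry (µm)\n"
            f"centre: {g.centre.tolist()}\n"
            f"long_axis: {g.long_axis.tolist()}\n"
            f"Ra: {g.Ra}\nRb: {g.Rb}\nf: {g.f}\n")
        return result
    finally:
        logger.removeHandler(handler)
        handler.close()
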