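"""Transmural depth, wall sectors/levels, and linear profile fits.

Transmural depth is the normalised position across the wall,
``d = dist_endo / (dist_endo + dist_epi)`` from Euclidean distance
transforms to the endocardial and epicardial boundary surfaces (0 at the
endocardium, 1 at the epicardium; the septum runs LV-endo → RV-endo by
convention, reversible via ``septum_reversed``).

Per wall sector and apico-basal level, the transmural course of an angle
map is summarised by an ordinary least-squares line ``y = β1·d + β0``
pooled over all valid voxels of the cell, with the linearity coefficient
R² (defined as 0 when the angle variance is 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import ProlateGeometry

__all__ = [
    "ProfileFit",
    "find_shell_surfaces",
    "transmural_depth",
    "extend_wall_basally",
    "reverse_depth_in",
    "define_walls_and_levels",
    "fit_transmural_profile",
    "fit_all_profiles",
    "LV_SECTOR_NAMES",
    "RV_SECTOR_NAMES",
    "LEVEL_NAMES",
]

LV_SECTOR_NAMES = {1: "anterior", 2: "septal", 3: "posterior", 4: "lateral"}
RV_SECTOR_NAMES = {5: "rv_anterior", 6: "rv_lateral", 7: "rv_posterior"}
LEVEL_NAMES = {1: "apical", 2: "mid", 3: "basal"}


@dataclass
class ProfileFit:
    """OLS fit of angle (degrees) against normalised transmural depth."""

    sector: str
    level: str
    angle_type: str
    beta1: float    # degrees per unit depth
    beta0: float    # degrees at the endocardium
    r2: float
    n: int


def find_shell_surfaces(mask: np.ndarray,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Split the background of a closed wall into (cavity, outside).

    The connected background component touching the volume border is the
    outside; everything else is cavity. Raises if the wall encloses no
    cavity (boundary surfaces are then ambiguous).
    """
    wall = np.asarray(mask) > 0
    bg = ~wall
    # ventricular shells are open at the basal truncation, so the cavity
    # connects to the outside in 3D; close it slice-wise instead — in
    # short-axis (z) slices the wall is a ring and 2D hole filling
    # recovers the cavity
    cavity = np.zeros_like(wall)
    for z in range(wall.shape[2]):
        filled = ndimage.binary_fill_holes(wall[:, :, z])
        cavity[:, :, z] = filled & ~wall[:, :, z]
    outside = bg & ~cavity
    if not cavity.any():
        raise ValueError(
            "wall encloses no cavity in any short-axis slice: endo/epi "
            "surfaces are ambiguous (pass explicit seeds)")
    return cavity, outside


def extend_wall_basally(wall: np.ndarray, basal_sign: int = +1,
                        n_keep: int = 2) -> np.ndarray:
    """Continue an open shell past its basal truncation.

    At the open basal rim the background wraps around the cut face, so
    endo/epi distance transforms bend the depth field over roughly one
    wall thickness there. Replicating the last closed wall ring
    (``n_keep`` slices below the rim) into every slice beyond it makes
    the rim region behave like mid-shell; depths are then read back on
    the original wall only. ``basal_sign`` is +1 when the base is at the
    high-z end of the sectioning axis, −1 otherwise.
    """
    wall = np.asarray(wall, bool)
    has_wall = np.flatnonzero(wall.any(axis=(0, 1)))
    if len(has_wall) == 0:
        raise ValueError("empty mask")
    out = wall.copy()
    if basal_sign >= 0:
        rim = has_wall[-1]
        src = max(rim - n_keep, has_wall[0])
        out[:, :, rim + 1:] = wall[:, :, src][:, :, None]
    else:
        rim = has_wall[0]
        src = min(rim + n_keep, has_wall[-1])
        out[:, :, :rim] = wall[:, :, src][:, :, None]
    return out


def transmural_depth(wall: np.ndarray, endo_seed: np.ndarray,
                     epi_seed: np.ndarray,
                     voxel_size_um: float | tuple = 1.0) -> np.ndarray:
    """Normalised transmural depth map over ``wall`` (NaN elsewhere).

    ``endo_seed`` / ``epi_seed`` mark the regions the endocardial and
    epicardial distances are measured to (typically the cavity and the
    outside background from :func:`find_shell_surfaces`).
    """
    wall = np.asarray(wall, bool)
    endo_seed = np.asarray(endo_seed, bool)
    epi_seed = np.asarray(epi_seed, bool)
    if not endo_seed.any() or not epi_seed.any():
        raise ValueError("empty endo or epi seed region")
    vs = np.broadcast_to(np.atleast_1d(voxel_size_um), (3,)).astype(float)
    d_endo = ndimage.distance_transform_edt(~endo_seed, sampling=vs)
    d_epi = ndimage.distance_transform_edt(~epi_seed, sampling=vs)
    depth = np.full(wall.shape, np.nan, dtype=np.float32)
    tot = d_endo + d_epi
    with np.errstate(invalid="ignore"):
        depth[wall] = (d_endo[wall] / np.maximum(tot[wall], 1e-12)).astype(
            np.float32)
    return depth


def reverse_depth_in(depth: np.ndarray, region: np.ndarray) -> np.ndarray:
    """Flip the transmural direction (d → 1 − d) inside ``region``.

    Used to switch the septum between the default LV-endo → RV-endo
    convention and its reverse; a flip negates fitted slopes exactly.
    """
    out = np.asarray(depth).copy()
    region = np.asarray(region, bool)
    out[region] = 1.0 - out[region]
    return out


def define_walls_and_levels(mask: np.ndarray, geometry: ProlateGeometry,
                            voxel_size_um: float | tuple,
                            lv_labels: tuple[int, ...] = (1, 2),
                            rv_label: int = 3,
                            anchor: np.ndarray | None = None,
                            level_positions: tuple[float, ...] = (0.75, 0.5, 0.25),
                            slab_thickness_voxels: int = 5,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Circumferential wall sectors and apico-basal level slabs.

    Sectors: LV quadrants (anterior 1 / septal 2 / posterior 3 /
    lateral 4, 90° each, the septal quadrant centred on the RV-facing
    anchor) and RV thirds (5–7) over the RV label's angular span. Levels:
    slabs of ``slab_thickness_voxels`` axial thickness centred at
    ``level_positions`` (fractions of the base→apex extent measured from
    the base; the defaults place apical=0.75, mid=0.5, basal=0.25 — label
    values 1/2/3 respectively). Voxels outside every slab get level 0.
    """
    labels = np.asarray(mask)
    wall = labels > 0
    if not wall.any():
        raise ValueError("empty mask")
    vs = np.broadcast_to(np.atleast_1d(voxel_size_um), (3,)).astype(float)
    lv = np.isin(labels, lv_labels)
    rv = labels == rv_label
    if anchor is None:
        if not rv.any():
            raise ValueError("RV label absent and no anchor supplied: the "
                             "septum direction is undefined")
        anchor = np.argwhere(rv).mean(axis=0) * vs - geometry.centre
    anchor = np.asarray(anchor, dtype=float)
    anchor = anchor - geometry.long_axis * (anchor @ geometry.long_axis)
    nrm = np.linalg.norm(anchor)
    if nrm == 0:
        raise ValueError("anchor is parallel to the long axis")
    anchor /= nrm
    e2 = np.cross(geometry.long_axis, anchor)

    sectors = np.zeros(labels.shape, dtype=np.int16)
    pts_lv = np.argwhere(lv) * vs - geometry.centre
    phi = np.degrees(np.arctan2(pts_lv @ e2, pts_lv @ anchor))
    # quadrants counterclockwise from the septum (centred at φ = 0)
    quad = np.floor(((phi + 45.0) % 360.0) / 90.0).astype(int) % 4
    sectors[lv] = np.array([2, 1, 4, 3])[quad]  # septal, anterior, lateral, posterior
    if rv.any():
        pts_rv = np.argwhere(rv) * vs - geometry.centre
        phi_rv = np.degrees(np.arctan2(pts_rv @ e2, pts_rv @ anchor))
        lo, hi = phi_rv.min(), phi_rv.max()
        third = np.clip(((phi_rv - lo) / max(hi - lo, 1e-9) * 3).astype(int),
                        0, 2)
        sectors[rv] = third + 5

    levels = np.zeros(labels.shape, dtype=np.int16)
    pts = np.argwhere(wall) * vs - geometry.centre
    z = pts @ geometry.long_axis
    zmin, zmax = z.min(), z.max()
    frac = (zmax - z) / max(zmax - zmin, 1e-12)  # 0 at base, 1 at apex
    half_um = 0.5 * slab_thickness_voxels * float(vs.min())
    lev = np.zeros(len(pts), dtype=np.int16)
    for k, pos in enumerate(level_positions):
        centre_z = zmax - pos * (zmax - zmin)
        in_slab = np.abs(z - centre_z) <= half_um
        lev[in_slab] = k + 1
    levels[wall] = lev
    return sectors, levels


def fit_transmural_profile(depth: np.ndarray, angle: np.ndarray,
                           cell: np.ndarray, *, sector: str = "",
                           level: str = "", angle_type: str = "HA",
                           min_n: int = 20) -> ProfileFit | None:
    """Pooled per-voxel OLS of angle against depth inside ``cell``.

    Returns None (cell skipped) when fewer than ``min_n`` voxels carry
    both a finite depth and a finite angle.
    """
    cell = np.asarray(cell, bool)
    d = np.asarray(depth)[cell].astype(float)
    y = np.asarray(angle)[cell].astype(float)
    ok = np.isfinite(d) & np.isfinite(y)
    d, y = d[ok], y[ok]
    if len(d) < min_n:
        return None
    var_y = float(np.var(y))
    if var_y == 0.0 or float(np.var(d)) == 0.0:
        beta1 = 0.0
        beta0 = float(np.mean(y))
        r2 = 0.0
    else:
        beta1, beta0 = np.polyfit(d, y, 1)
        resid = y - (beta1 * d + beta0)
        r2 = 1.0 - float(np.sum(resid**2)) / (len(y) * var_y)
    return ProfileFit(sector=sector, level=level, angle_type=angle_type,
                      beta1=float(beta1), beta0=float(beta0),
                      r2=float(np.clip(r2, 0.0, 1.0)), n=int(len(d)))


def fit_all_profiles(depth: np.ndarray, ha: np.ndarray, ia: np.ndarray,
                     sectors: np.ndarray, levels: np.ndarray,
                     min_n: int = 20) -> pd.DataFrame:
    """Fits for every sector × level × angle-type cell, as a tidy table."""
    names = {**LV_SECTOR_NAMES, **RV_SECTOR_NAMES}
    rows = []
    for s_id, s_name in names.items():
        s_mask = np.asarray(sectors) == s_id
        if not s_mask.any():
            continue
        for l_id, l_name in LEVEL_NAMES.items():
            cell = s_mask & (np.asarray(levels) == l_id)
            for angle_type, amap in (("HA", ha), ("IA", ia)):
                fit = fit_transmural_profile(
                    depth, amap, cell, sector=s_name, level=l_name,
                    angle_type=angle_type, min_n=min_n)
                if fit is not None:
                    rows.append({"sector": fit.sector, "level": fit.level,
                                 "angle_type": fit.angle_type,
                                 "beta1_deg": fit.beta1,
                                 "beta0_deg": fit.beta0,
                                 "r2": fit.r2, "n": fit.n})
    return pd.DataFrame(rows)
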