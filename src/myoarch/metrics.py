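"""Organisation metrics and regional summaries.

The myocardial disarray index (MDI) measures, per voxel, how uniformly
the myocyte long axes (tertiary eigenvectors, sign-free) point within a
cubic neighbourhood (default 11×11×11 voxels — 22 µm at 2 µm voxels, 33 µm
at 3 µm). The default estimator forms the mean dyadic (orientation)
tensor ``T̄ = ⟨v3 v3ᵀ⟩`` over valid neighbours and maps its dominant
eigenvalue to

    MDI = (3·λ_max(T̄) − 1) / 2,

which is 1 for perfectly aligned axes and 0 for an isotropic axis
distribution, and is invariant to per-voxel sign flips. An alternative
estimator (mean |v3_centre · v3_neighbour|) is available for
cross-checking on small volumes.

Angular classifications follow the standard thresholds: helical angle
|HA| ≤ 20° circumferential, HA > 20° longitudinal-positive, HA < −20°
longitudinal-negative; intrusion angle bins |IA| ≤ 15°, 15° < |IA| ≤ 45°,
|IA| > 45°.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import ProlateGeometry
from .tensor import OrientationField

__all__ = [
    "DisarrayMap",
    "compute_mdi",
    "classify_ha",
    "classify_ia",
    "classify_angles",
    "aha_segmentation",
    "angle_histogram",
    "summarize_regions",
    "AHA_SEPTAL_SEGMENTS",
]

AHA_SEPTAL_SEGMENTS = (2, 3, 8, 9, 14)


@dataclass
class DisarrayMap:
    """Per-voxel MDI ∈ [0, 1] (NaN where undefined) plus window metadata."""

    values: np.ndarray
    window: int
    window_extent_um: float


def compute_mdi(orient: OrientationField, mask: np.ndarray | None = None,
                window: int = 11, voxel_size_um: float = 2.0,
                min_valid_frac: float = 0.5,
                method: str = "dyadic") -> DisarrayMap:
    """Myocardial disarray index over a cubic neighbourhood.

    MDI is defined only where at least ``min_valid_frac`` of the window
    voxels carry a valid myocardial axis; elsewhere it is NaN.
    """
    if window % 2 != 1 or window < 3:
        raise ValueError(f"window must be odd and ≥ 3, got {window}")
    valid = orient.valid if mask is None else (orient.valid
                                               & np.asarray(mask, bool))
    v3 = np.where(valid[..., None], orient.v3, 0.0).astype(np.float32)
    extent = float(window * voxel_size_um)
    if method == "dyadic":
        nwin = window**3
        count = ndimage.uniform_filter(valid.astype(np.float32), size=window,
                                       mode="constant", cval=0.0) * nwin
        comps = {}
        for i in range(3):
            for j in range(i, 3):
                s = ndimage.uniform_filter(v3[..., i] * v3[..., j],
                                           size=window, mode="constant",
                                           cval=0.0) * nwin
                comps[(i, j)] = s
        defined = count >= min_valid_frac * nwin
        idx = np.nonzero(defined)
        n = count[idx]
        T = np.empty((len(n), 3, 3), dtype=np.float64)
        for i in range(3):
            for j in range(i, 3):
                T[:, i, j] = comps[(i, j)][idx] / n
                T[:, j, i] = T[:, i, j]
        lam_max = np.linalg.eigvalsh(T)[:, 2]
        mdi = np.full(valid.shape, np.nan, dtype=np.float32)
        mdi[idx] = np.clip((3.0 * lam_max - 1.0) / 2.0, 0.0, 1.0)
        return DisarrayMap(mdi, window, extent)
    if method == "mean_abs_dot":
        half = window // 2
        nwin = window**3
        acc = np.zeros(valid.shape, dtype=np.float64)
        cnt = np.zeros(valid.shape, dtype=np.int64)
        for dx in range(-half, half + 1):
            for dy in range(-half, half + 1):
                for dz in range(-half, half + 1):
                    sh_v = np.roll(v3, (dx, dy, dz), axis=(0, 1, 2))
                    sh_m = np.roll(valid, (dx, dy, dz), axis=(0, 1, 2))
                    dot = np.abs(np.sum(v3 * sh_v, axis=-1))
                    acc += np.where(valid & sh_m, dot, 0.0)
                    cnt += (valid & sh_m)
        defined = valid & (cnt >= min_valid_frac * nwin)
        mdi = np.full(valid.shape, np.nan, dtype=np.float32)
        mdi[defined] = (acc[defined] / cnt[defined]).astype(np.float32)
        return DisarrayMap(mdi, window, extent)
    raise ValueError(f"unknown MDI method {method!r}")


# ---------------------------------------------------------------------------
# Angle classifications
# ---------------------------------------------------------------------------

def classify_ha(ha: np.ndarray, ha_threshold: float = 20.0,
                ) -> dict[str, float]:
    """Fractions of circumferential / longitudinal± myocytes by HA."""
    vals = np.asarray(ha, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("empty region: no valid HA values to classify")
    n = vals.size
    circ = np.abs(vals) <= ha_threshold
    return {
        "frac_circ": float(circ.sum() / n),
        "frac_long_pos": float((vals > ha_threshold).sum() / n),
        "frac_long_neg": float((vals < -ha_threshold).sum() / n),
    }


def classify_ia(ia: np.ndarray, ia_low: float = 15.0, ia_high: float = 45.0,
                ) -> dict[str, float]:
    """Fractions of myocytes in the |IA| ≤ 15°, (15°, 45°], > 45° bins."""
    vals = np.asarray(ia, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("empty region: no valid IA values to classify")
    n = vals.size
    a = np.abs(vals)
    return {
        "frac_IA_le15": float((a <= ia_low).sum() / n),
        "frac_IA_15_45": float(((a > ia_low) & (a <= ia_high)).sum() / n),
        "frac_IA_gt45": float((a > ia_high).sum() / n),
    }


def classify_angles(ha: np.ndarray, ia: np.ndarray,
                    region: np.ndarray | None = None,
                    ha_threshold: float = 20.0,
                    ia_low: float = 15.0, ia_high: float = 45.0,
                    ) -> dict[str, float]:
    """HA and IA classification fractions over a region mask."""
    if region is not None:
        region = np.asarray(region, bool)
        ha, ia = np.asarray(ha)[region], np.asarray(ia)[region]
    out = classify_ha(ha, ha_threshold)
    out.update(classify_ia(ia, ia_low, ia_high))
    return out


def angle_histogram(angles: np.ndarray, bin_width: float = 5.0,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Counts over [−90, 90] in fixed-width bins; NaNs ignored."""
    vals = np.asarray(angles, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    edges = np.arange(-90.0, 90.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram(vals, bins=edges)
    return counts, edges


# ---------------------------------------------------------------------------
# AHA 17-segment model (segment 17 excluded)
# ---------------------------------------------------------------------------

def aha_segmentation(mask: np.ndarray, geometry: ProlateGeometry,
                     voxel_size_um: float | tuple,
                     lv_labels: tuple[int, ...] = (1, 2),
                     rv_label: int = 3,
                     anchor: np.ndarray | None = None,
                     apex_cap_frac: float = 1.0 / 9.0) -> np.ndarray:
    """Partition the LV wall into AHA segments 1–16.

    Long-axis thirds (basal / mid / apical from the base) are split into
    circumferential sectors anchored at the mid-septum, i.e. the
    direction from the LV centre toward the RV centroid: 6×60° sectors in
    the basal and mid thirds, 4×90° in the apical third. The apical cap
    (innermost ``apex_cap_frac`` of the long-axis extent — the would-be
    segment 17) is excluded and labelled 0, as are non-LV voxels.
    """
    labels = np.asarray(mask)
    lv = np.isin(labels, lv_labels)
    if not lv.any():
        raise ValueError("no LV wall voxels to segment")
    vs = np.broadcast_to(np.atleast_1d(voxel_size_um), (3,)).astype(float)
    if anchor is None:
        rv = labels == rv_label
        if not rv.any():
            raise ValueError(
                "RV label absent: cannot anchor the septum direction; "
                "pass an explicit anchor vector")
        rv_centroid = np.argwhere(rv).mean(axis=0) * vs
        anchor = rv_centroid - geometry.centre
    anchor = np.asarray(anchor, dtype=float)
    anchor = anchor - geometry.long_axis * (anchor @ geometry.long_axis)
    nrm = np.linalg.norm(anchor)
    if nrm == 0:
        raise ValueError("anchor is parallel to the long axis")
    anchor /= nrm
    e2 = np.cross(geometry.long_axis, anchor)

    pts = np.argwhere(lv) * vs - geometry.centre
    z = pts @ geometry.long_axis
    phi = np.degrees(np.arctan2(pts @ e2, pts @ anchor))  # 0 at mid-septum
    zmin, zmax = z.min(), z.max()
    frac_from_base = (zmax - z) / max(zmax - zmin, 1e-12)

    seg = np.zeros(len(pts), dtype=np.int16)
    # 60° wedges ordered counterclockwise from the septum; segments 2 and 3
    # straddle the anchor so the septal pair faces the RV
    wedge6 = np.floor(((phi + 60.0) % 360.0) / 60.0).astype(int) % 6
    # wedge 0 covers φ ∈ [−60, 0) → segment 2; wedge 1 covers [0, 60) → 3 ...
    sector6 = np.array([2, 3, 4, 5, 6, 1])
    lab6 = sector6[wedge6]
    basal = frac_from_base < 1.0 / 3.0
    mid = (frac_from_base >= 1.0 / 3.0) & (frac_from_base < 2.0 / 3.0)
    seg[basal] = lab6[basal]
    seg[mid] = lab6[mid] + 6
    # apical third: 90° wedges, segment 14 centred on the septum
    sector4 = np.array([14, 15, 16, 13])  # wedge k: φ ∈ [−45+90k, 45+90k)
    wedge4 = np.floor(((phi + 45.0) % 360.0) / 90.0).astype(int) % 4
    apical = (frac_from_base >= 2.0 / 3.0) & (frac_from_base <= 1.0 - apex_cap_frac)
    seg[apical] = sector4[wedge4[apical]]

    out = np.zeros(labels.shape, dtype=np.int16)
    out[lv] = seg
    return out


# ---------------------------------------------------------------------------
# Regional summaries
# ---------------------------------------------------------------------------

def summarize_regions(regions: dict[str, np.ndarray],
                      ha: np.ndarray, ia: np.ndarray,
                      fa: np.ndarray | None = None,
                      mdi: np.ndarray | None = None,
                      ha_threshold: float = 20.0,
                      ia_low: float = 15.0, ia_high: float = 45.0,
                      ) -> pd.DataFrame:
    """One tidy summary row per named region mask.

    All maps must share one shape; NaNs (invalid voxels) are excluded
    from every statistic. Regions with no valid voxels are skipped.
    """
    shape = np.asarray(ha).shape
    for name, m in regions.items():
        if np.asarray(m).shape != shape:
            raise ValueError(f"region {name!r} shape {np.asarray(m).shape} "
                             f"does not match maps {shape}")
    rows = []
    for name, m in regions.items():
        m = np.asarray(m, bool)
        ha_r = np.asarray(ha)[m]
        ok = np.isfinite(ha_r)
        if not ok.any():
            continue
        row: dict[str, object] = {"region": name, "n_voxels": int(ok.sum())}
        for label, arr in (("FA", fa), ("MDI", mdi)):
            if arr is None:
                continue
            v = np.asarray(arr)[m]
            v = v[np.isfinite(v)]
            row[f"mean_{label}"] = float(v.mean()) if v.size else np.nan
            row[f"sd_{label}"] = float(v.std()) if v.size else np.nan
        row.update(classify_angles(np.asarray(ha)[m], np.asarray(ia)[m],
                                   ha_threshold=ha_threshold,
                                   ia_low=ia_low, ia_high=ia_high))
        rows.append(row)
    return pd.DataFrame(rows)
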