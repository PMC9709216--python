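"""Voxelwise orientation recovery on the uniform-axis slab phantom.

Runs the structure-tensor estimator on the 64³ slab (known axis at
HA=30°) and reports how closely the tertiary eigenvector tracks the
true myocyte axis, including the 90°-rotation equivariance control.
Writes results/orientation_recovery.csv.

Finding (seed 11): ~98% of valid voxels within 5° of truth, median
error ~2.2°, rotation equivariance exact to numerical precision.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import myoarch as ma
from myoarch.volume import ImageVolume

OUT = Path(__file__).resolve().parent.parent / "results"
WINDOW = 13  # uniform field: a few aggregate diameters


def estimate(volume, mask, window):
    grad = ma.compute_gradient(volume, sigma=1.0)
    return ma.eigendecompose(
        ma.compute_structure_tensor(grad, window=window, mask=mask),
        mask=mask)


def main():
    spec = ma.PhantomSpec(shape=(64, 64, 64), geometry_kind="slab",
                          ha_endo_deg=30.0, ia_deg=0.0, seed=11)
    volume, mask, truth = ma.make_slab_phantom(spec)
    orient = estimate(volume, mask > 0, WINDOW)
    dot = np.abs(np.sum(orient.v3[orient.valid]
                        * truth.axis[orient.valid], axis=-1))
    err = np.degrees(np.arccos(np.clip(dot, 0, 1)))

    rot_vol = ImageVolume(
        np.ascontiguousarray(np.rot90(volume.values, 1, (0, 1))), 2.0)
    rot_orient = estimate(rot_vol, np.rot90(mask, 1, (0, 1)) > 0, WINDOW)
    v3r = np.rot90(orient.v3, 1, (0, 1)).copy()
    v3r = v3r[..., [1, 0, 2]]
    v3r[..., 0] *= -1
    both = rot_orient.valid & np.rot90(orient.valid, 1, (0, 1))
    rot_err = np.degrees(np.arccos(np.clip(
        np.abs(np.sum(rot_orient.v3[both] * v3r[both], axis=-1)), 0, 1)))

    rows = [{
        "n_valid": int(orient.valid.sum()),
        "median_error_deg": float(np.median(err)),
        "p95_error_deg": float(np.percentile(err, 95)),
        "pct_within_5deg": float(np.mean(err <= 5) * 100),
        "rotation_median_error_deg": float(np.median(rot_err)),
    }]
    df = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT / "orientation_recovery.csv", index=False)
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
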