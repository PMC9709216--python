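"""Recovery of the linear transmural helical-angle law on the shell.

Runs the full pipeline (fitted geometry, no ground-truth leakage) on
the kappa=20 shell bearing HA(d) = +60° − 120°·d and fits the
per-sector, per-level transmural lines. Writes the complete fit table
to results/transmural_fits.csv.

Finding (seed 2): mid-level lateral-wall HA slope ≈ −115 to −118° per
unit depth against a true −120°, R² ≈ 0.95, with the endo-positive →
epi-negative progression throughout the left ventricle.
"""

from pathlib import Path

import myoarch as ma
from myoarch.pipeline import PipelineConfig, run_pipeline_arrays

OUT = Path(__file__).resolve().parent.parent / "results"
WINDOW = 7  # below wall/3 so the transmural variation is resolved


def main():
    spec = ma.PhantomSpec(shape=(128, 128, 128), ha_endo_deg=60.0,
                          ha_epi_deg=-60.0, kappa=20.0, seed=2)
    volume, mask, truth, _ = ma.make_shell_phantom(spec)
    res = run_pipeline_arrays(volume, mask,
                              PipelineConfig(tensor_window=WINDOW))
    OUT.mkdir(parents=True, exist_ok=True)
    res.profile_fits.to_csv(OUT / "transmural_fits.csv", index=False)
    g = res.geometry
    print(f"fitted LV frame: Ra={g.Ra:.1f} µm Rb={g.Rb:.1f} µm "
          f"f={g.f:.1f} µm")
    ha = res.profile_fits[res.profile_fits.angle_type == "HA"]
    print(ha.to_string(index=False))
    row = ha[(ha.sector == "lateral") & (ha.level == "mid")].iloc[0]
    print(f"\nmid lateral: beta1 = {row.beta1_deg:.1f} deg/depth "
          f"(true -120), R2 = {row.r2:.3f}")


if __name__ == "__main__":
    main()
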