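# myoarch

Structure-tensor quantification of ventricular myoarchitecture from 3D
grayscale microscopy volumes (e.g. high-resolution episcopic microscopy,
HREM, of embryonic hearts at 2–3 µm isotropic voxels).

Given an intensity volume and a companion label mask of the compact
myocardium (LV free wall, septum, RV free wall), the pipeline computes:

* **Myocyte orientation.** Per voxel, the structure tensor
  `J = Σ g gᵀ` of central-difference intensity gradients `g` over a small
  window; its eigenvector `v₃` of smallest eigenvalue points along the
  direction of least intensity variation — the myocyte long axis. In a
  prolate-spheroidal frame fitted to the LV (semi-foci distance
  `f = √(Ra² − Rb²)`), the axis is summarised by the **helical angle**
  `α_H = asin(v₃·l̂)` (angle to the local short-axis plane) and the
  **intrusion angle** `α_I = asin(v₃·r̂)` (angle to the epicardial
  tangential plane), both in degrees ∈ [−90, 90].
* **Organisation.** The **fractional anisotropy** of the gradient
  eigenvalues, `FA = √(3/2)·‖λ − λ̂‖ / ‖λ‖`, and the **myocardial
  disarray index**, `MDI = (3·λ_max(⟨v₃v₃ᵀ⟩) − 1)/2` over an 11×11×11
  neighbourhood (22 µm at 2 µm voxels) — 1 for perfectly aligned axes,
  0 for isotropic disarray.
* **Transmural profiles.** Normalised wall depth `d ∈ [0, 1]`
  (endo → epi, via distance transforms), and per wall-sector /
  apico-basal-level OLS fits `α_H = β₁·d + β₀` with linearity `R²`.
* **Regional summaries.** Angle classification fractions
  (|HA| ≤ 20° circumferential; |IA| bins 15°/45°), histograms, mean
  FA/MDI per wall region and per AHA 17-segment-model segment
  (apical cap excluded), plus legacy-VTK orientation glyph export.

Because no public dataset accompanies this kind of study, the package
ships a first-class synthetic-data generator: prolate-shell and slab
phantoms textured with curved, tightly packed myocyte-aggregate rods
following a prescribed fiber field (linear transmural HA law, tunable
orientation noise), with full ground truth for parameter-recovery
validation.

## Worked example

```python
import myoarch as ma
from myoarch.pipeline import PipelineConfig, run_pipeline_arrays

spec = ma.PhantomSpec(ha_endo_deg=60, ha_epi_deg=-60, kappa=20, seed=2)
volume, mask, truth, _ = ma.make_shell_phantom(spec)   # 128³, 2 µm voxels
res = run_pipeline_arrays(volume, mask, PipelineConfig(tensor_window=7))

g = res.geometry
print(f"Ra={g.Ra:.1f} Rb={g.Rb:.1f} f={g.f:.1f}")
fits = res.profile_fits
row = fits[(fits.sector == "lateral") & (fits.level == "mid")
           & (fits.angle_type == "HA")].iloc[0]
print(f"beta1={row.beta1_deg:.1f} beta0={row.beta0_deg:.1f} r2={row.r2:.3f}")
```

prints (phantom truth: Ra=100 µm, Rb=65 µm, HA slope −120°/depth):

```
Ra=104.8 Rb=67.3 f=80.2
beta1=-117.4 beta0=53.7 r2=0.953
```

i.e. the fitted LV frame matches the generating ellipsoid to a few
percent and the transmural helical-angle gradient of the mid-level
lateral wall is recovered within ~2% despite per-voxel orientation
noise. The numbered scripts under `analysis/` run the full study
(phantom generation, orientation recovery, HA-law recovery, disarray
index versus noise, regional summaries) and write their tables under
`results/`.

A thin CLI wraps the same library calls:

```sh
myoarch phantom out/ --kind prolate_shell --size 128 --seed 2
myoarch run out/volume.nrrd out/mask.nrrd --output-dir out/report --tensor-window 7
```

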