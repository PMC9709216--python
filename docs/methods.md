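# Methods

## Orientation model

Myocyte aggregates appear in inverted episcopic-microscopy contrast as
bright, elongated structures on a dark background. Intensity varies
strongly across an aggregate and weakly along it, so the direction of
least intensity variation estimates the local myocyte long axis. The
estimator is the classic structure tensor: per-voxel gradients
`g = ∇I` by central differences (one-sided at the image border, after
optional Gaussian pre-smoothing with `smoothing_sigma`, default 1.0
voxel), aggregated over a cubic window as `J(x) = Σ_w g(w) g(w)ᵀ`, with
voxels outside the myocardial mask excluded from every sum so that no
background gradients leak in. `J` is symmetric positive semi-definite;
its eigenvalues are sorted `λ₁ ≥ λ₂ ≥ λ₃ ≥ 0` and the eigenvector `v₃`
of `λ₃` is the axis estimate. A voxel is flagged invalid when the
tensor trace vanishes or `λ₂ − λ₃ < τ·λ₁` (default `τ = 0.05`): the
axis is then degenerate (locally isotropic texture) and all downstream
maps propagate NaN there.

`v₃` is an axis, not a vector. All scalar outputs are sign-free by
construction (angles are computed after the pipeline-wide
sign-disambiguation `v₃·ĉ ≥ 0`, tie broken by `v₃·l̂ ≥ 0`; the disarray
index uses the dyadic product), and the tests assert that a global sign
flip changes nothing.

### Window (outer scale) selection

The aggregation window trades variance against spatial resolution:

* it must span at least one aggregate diameter so the window sees the
  full fan of transverse gradients (a window inside a single flank sees
  gradients of essentially one direction, leaving the axis
  under-determined);
* it must stay well below the length scale over which the true
  orientation field varies, or the transmural angle gradient is
  over-smoothed.

The pipeline default is a 3×3×3 window. The validation studies use
larger, scale-matched windows: 13 voxels (26 µm, ≈ 3 aggregate
diameters) on the spatially uniform slab field, where only homogeneity
limits the window, and 7 voxels (14 µm, ≈ one third of the shell's
~21-voxel wall) on the shell, where the helical angle sweeps 120°
across the wall. The analysis mask is additionally eroded by 1 voxel
(`erode_mask_voxels`) before orientation statistics so that the strong
tissue/background step gradient at the segmented surface does not
contaminate boundary tensors; transmural depth is still computed on the
full mask.

## Prolate geometry and angles

The LV is modelled as a truncated prolate spheroid. The frame is
fitted from the labelled mask alone:

* **long axis** — principal axis of the cavity blood-pool voxel cloud.
  The wall cloud itself is unsuitable: a basally truncated thick shell
  has more transverse than axial variance, and excluded labels (the RV)
  pull its centroid sideways.
* **semi-axes** — free ellipsoid fits of partial cup surfaces are
  ill-posed (a huge ellipsoid, in the limit a paraboloid, fits any cup),
  so `Ra`/`Rb` come from four sharp extremal measurements tied together
  by confocality: the apical pole positions of cavity (endocardial) and
  wall (epicardial) give the pole separation `Δ = a_epi − a_endo`; the
  maximal transverse radii give the equatorial semi-axes `b_endo`,
  `b_epi`; confocality (`a² − b²` equal for both surfaces) then yields
  `a_endo + a_epi = (b_epi² − b_endo²)/Δ` with no centre estimate
  needed. Mid-wall `Ra`, `Rb` are the endo/epi means. On the default
  phantom this recovers `Ra`, `Rb` within ~5% and `f` within ~6–9%
  across box sizes and voxel sizes.

Local frames are the exact analytic prolate frame: radial `r̂ = ∂p/∂λ`
(endo→epi), longitudinal `l̂` (apex→base), circumferential
`ĉ = l̂ × r̂` (right-handed, `ĉ × l̂ = r̂`, continuous across the θ
seam). Helical and intrusion angles are the literal angle between the
axis and the respective plane (`asin` of the normal component); the
projected `atan2` variant is available behind `projected_angles` but
off by default.

The RV has no ellipsoid of its own; RV voxels use the LV prolate frame.
Apex/base disambiguation: the base is the end with the larger cavity
cross-section.

## Transmural depth

`d = dist_endo / (dist_endo + dist_epi)` from Euclidean distance
transforms seeded by the cavity (endo) and the outer background (epi).
The cavity of an open shell is recovered by 2D hole-filling per
short-axis slice (the basal truncation makes cavity and outside
connected in 3D). Before the transforms the wall is continued past the
open basal rim by replicating the last closed ring — otherwise the
background wrapping around the cut face bends the depth field over
roughly one wall thickness near the base. With both measures the depth
map matches the phantom's analytic (confocal-λ) depth to ≤ 0.05 at the
90th percentile; the residual difference concentrates at the apex,
where equal-physical-distance and equal-λ mid-surfaces differ most.
The septum is measured LV-endo → RV-endo by convention;
`reverse_depth_in` flips it (and exactly negates fitted slopes).

## Disarray index

`MDI = (3·λ_max(T̄) − 1)/2` with `T̄` the mean dyadic tensor of `v₃`
over an 11×11×11 window (22 µm at 2 µm voxels, 33 µm at 3 µm),
defined where ≥ 50% of window voxels carry a valid axis: 1 for
perfectly aligned axes, 0 for isotropic. The formula is the standard
sign-free order parameter for axial data. An alternative
neighbour-dot-product variant (`method="mean_abs_dot"`, mean
|v₃ᶜ·v₃ʲ|) is implemented as an explicit window loop for cross-checks
on small volumes; both variants share the aligned-field endpoint.

An important caveat, measured on phantoms: the structure tensor's
spatial averaging *absorbs* voxel-scale orientation noise. A field with
kappa = 20 noise (≈ 11° mean deviation) yields pipeline MDI barely
below the noise-free value, because within-window disarray is averaged
away before `v₃` is ever extracted. MDI computed through the image
pipeline therefore measures disarray at and above the window scale;
the kappa-ladder validation (1 → ~0.93 → ~0.78 → ~0.03 for
kappa ∈ {∞, 20, 5, 0}) is computed on the drawn axis fields directly,
which is what the index itself is defined on.

## Synthetic phantoms

The generator produces the study conditions, not a tunable benchmark:

* **Geometry.** Slab (trivial frame, uniform axis) or truncated
  prolate shell. Default shell: mid-wall `Ra = 100 µm`, `Rb = 65 µm`
  (embryonic scale), wall spanning λ ∈ (0.7, 1.3)·λ_mid — a
  proportionally thick embryonic wall, 18–43 µm — at 2 µm voxels in a
  128³ box; basal truncation by a flat cut normal to the long axis
  (the cavity stays open through the cut, as at a real valve plane —
  a conical cut in prolate μ would leave a cut face that distance-based
  depth misreads as endocardium).
* **Fiber field.** `HA(d) = ha_endo + (ha_epi − ha_endo)·d` (default
  +60° → −60°), constant intrusion angle (default 0°), built in the
  exact local frame. Optional axially symmetric orientation noise of
  concentration kappa: tangent-space Gaussian of sd `1/√(2κ)` radians,
  exact isotropic draws at κ = 0, identity at κ = ∞ — any family with
  monotone dispersion in κ serves, and only that monotonicity is used.
* **Texture.** Curved capsule rods seeded at Poisson-random wall
  positions (default 4.4·10⁻⁴ /µm³), traced along the local (noisy)
  fiber field for 100 µm, rendered as tubes of 3 µm radius with a
  conical bright-core profile, composited by maximum, plus Gaussian
  intensity noise (sd 0.1 of the rod peak). Each element was forced by
  the estimator's physics: straight short capsules leave end-cap
  gradients along the fiber axis (median axis error ~15°); additive
  compositing washes out contrast where rods overlap; flat-interior
  profiles leave the tube cores textureless; and 3 µm is a
  single-to-few-myocyte minor radius that the 2 µm grid resolves.
  The intensity statistics of real HREM myocardium are not published,
  so the rod model is an explicit assumption: passing recovery tests
  shows the estimator works on resolvable fiber-textured tissue with
  this contrast and noise, not that it works on any particular real
  dataset. Real data differ in ways the phantom does not emulate —
  optical blur, uneven staining, trabecular remnants, segmentation
  error.

Determinism: one `numpy` generator seeded from `PhantomSpec.seed`
drives rod placement, orientation noise and intensity noise; identical
spec + seed reproduce the volume bit-for-bit.

## Validation results (recomputed by `scripts/acceptance.py`)

* Slab, κ = ∞: ~98% of valid voxels within 5° of the true axis,
  median ~2.2°; 90°-rotation equivariance exact.
* Shell, κ = 20: mid-level lateral HA slope −117°/depth against a true
  −120° (±15 tolerance), R² ≈ 0.95, endo-positive → epi-negative
  progression in every LV sector.
* Geometry: `Ra`, `Rb` within 5%, `f` within 10%; depth error ≤ 0.05
  (p90); 16 AHA segments labelled; FA and MDI within [0, 1] everywhere
  defined.
* MDI ladder strictly monotone with the endpoints 1 and ≈ 0.03.

### Known limitation: threshold classification at the resolution limit

Comparing angle-classification fractions of the *estimated* field
against brute-force counts on the *true* field on the default shell,
the circumferential/longitudinal-negative pair disagrees by ≈ 2.0–2.6
percentage points (the other four fractions agree well within 2
points). The mechanism is geometric: a window on a curved shell
contains more voxels on its outer (deeper) side, so the aggregated
orientation is volume-weighted toward the deeper, more negative helical
angle — a mid-wall bias of ≈ −1.5° that carries true HA in (−20°, −16°]
across the −20° threshold. The bias bottoms out near window 7–9 and
persists for every window between 3 and 11 voxels; it scales with
window² × curvature and would shrink on thicker-walled (older or
larger) ventricles. Distribution-level agreement on phantoms should
therefore be read with a ~2-point resolution floor at embryonic wall
thicknesses.

## Numerical choices

* Gradients and tensor components in float32; eigen-solves in float64
  on masked voxels only. PSD tolerance for the tensor is
  single-precision-scaled (1e−5 of the largest trace); diagonal
  components are clamped at 0 against separable-filter residue.
* Profile fits: pooled per-voxel OLS per sector × level cell (≥ 20
  voxels, else the cell is skipped); `R² := 0` when the angle variance
  is 0. Apico-basal levels at 25/50/75% of the base–apex extent,
  5-slice slabs; LV quadrants and RV thirds anchored at the mid-septum
  (direction to the RV centroid).
* AHA: long-axis thirds; 6×60° sectors (basal, mid) and 4×90°
  (apical) anchored at the mid-septum; the innermost 1/9 of the
  long-axis extent is the excluded apical cap. Wedge indices are
  computed modulo the sector count to absorb the floating-point
  wrap-around at ±180°.
* Histogram bins 5° over [−90°, 90°]; classification thresholds
  |HA| ≤ 20°, |IA| ≤ 15° / ≤ 45°, boundaries inclusive.
* Study sizes (64³ slab, 128³ shells) were chosen so each phantom
  resolves its wall with ≥ 18 voxels while a full generation + pipeline
  pass stays in the tens of seconds.
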