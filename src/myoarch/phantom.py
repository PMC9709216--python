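"""Synthetic cardiac-wall phantoms with known fiber fields.

The generator emulates the data regime of high-resolution episcopic
microscopy (HREM) of the embryonic ventricular wall: a bright, rod-like
texture of myocyte aggregates on a dark background, sampled at 2–3 µm
isotropic voxels, inside either

* a rectangular **slab** with a spatially uniform fiber axis (the unit-test
  geometry: circumferential = +x, longitudinal = +y, radial = +z), or
* a truncated **prolate-spheroidal shell** whose fiber field follows the
  classic linear transmural helical-angle law
  ``HA(d) = ha_endo + (ha_epi − ha_endo)·d`` (d = 0 endocardium, 1
  epicardium) with a constant prescribed intrusion angle.

Texture model: curved capsule-shaped bright rods seeded at
Poisson-random wall positions, each traced along the local (optionally
noise-perturbed) fiber field and rendered as a tube with a conical
radial profile, composited by maximum and topped with Gaussian intensity
noise. It mimics tightly packed eosin-stained myocyte aggregates in
inverted HREM contrast without modelling optics; the intensity
statistics of real HREM myocardium are not published, so the rod model
is an explicit assumption.

Orientation noise is axially symmetric with concentration ``kappa``:
``kappa = inf`` leaves axes untouched, ``kappa = 0`` draws isotropic axes,
and intermediate values use a tangent-space Gaussian whose angular spread
decreases monotonically in ``kappa``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .geometry import ProlateGeometry, local_basis_grid, angles_from_axes
from .volume import ImageVolume

__all__ = [
    "PhantomSpec",
    "TruthField",
    "make_slab_phantom",
    "make_shell_phantom",
    "perturb_axes",
    "sample_axes",
]

# mask label values, matching the convention of real segmentations
LABEL_LV_FREE_WALL = 1
LABEL_SEPTUM = 2
LABEL_RV_FREE_WALL = 3


@dataclass
class PhantomSpec:
    """Parameters of a synthetic wall phantom.

    Defaults describe an embryonic-scale shell (mid-wall ellipsoid
    Ra = 100 µm, Rb = 65 µm, ~20–43 µm wall) at 2 µm isotropic voxels in a
    128³ box, bearing the canonical +60° → −60° transmural helical-angle
    law with zero intrusion and no orientation noise.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size_um: float = 2.0
    geometry_kind: str = "prolate_shell"   # or "slab"
    Ra_um: float = 100.0                   # mid-wall major semi-axis
    Rb_um: float = 65.0                    # mid-wall minor semi-axis
    wall_lambda_range: tuple[float, float] = (0.7, 1.3)  # × mid-wall λ
    base_truncation_deg: float = 120.0     # μ span kept, measured from apex
    ha_endo_deg: float = 60.0
    ha_epi_deg: float = -60.0
    ia_deg: float = 0.0
    kappa: float = np.inf                  # orientation-noise concentration
    rod_length_um: float = 100.0
    rod_radius_um: float = 3.0
    rod_density: float = 4.4e-4            # rods per µm³ of wall
    noise_sd: float = 0.1                  # additive Gaussian, rod peak = 1
    seed: int = 0

    def validate(self) -> None:
        pos = {
            "voxel_size_um": self.voxel_size_um,
            "rod_length_um": self.rod_length_um,
            "rod_radius_um": self.rod_radius_um,
            "rod_density": self.rod_density,
        }
        for name, val in pos.items():
            if not val > 0:
                raise ValueError(f"{name} must be positive, got {val}")
        if any(s < 8 for s in self.shape):
            raise ValueError(f"shape axes must be ≥ 8 voxels, got {self.shape}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be ≥ 0, got {self.noise_sd}")
        if self.kappa < 0:
            raise ValueError(f"kappa must be ≥ 0, got {self.kappa}")
        for name in ("ha_endo_deg", "ha_epi_deg", "ia_deg"):
            v = getattr(self, name)
            if abs(v) > 90:
                raise ValueError(f"{name} must lie in [-90, 90], got {v}")
        if self.geometry_kind not in ("slab", "prolate_shell"):
            raise ValueError(f"unknown geometry_kind {self.geometry_kind!r}")
        if self.geometry_kind == "prolate_shell":
            if not self.Ra_um > self.Rb_um > 0:
                raise ValueError(
                    f"need Ra_um > Rb_um > 0 for a prolate shell, got "
                    f"Ra_um={self.Ra_um}, Rb_um={self.Rb_um} "
                    "(Ra_um = Rb_um is a degenerate sphere)")
            lo, hi = self.wall_lambda_range
            if not 0 < lo < hi:
                raise ValueError(
                    f"wall_lambda_range must satisfy 0 < lo < hi, got "
                    f"{self.wall_lambda_range}")
            if not 0 < self.base_truncation_deg <= 180:
                raise ValueError(
                    f"base_truncation_deg must lie in (0, 180], got "
                    f"{self.base_truncation_deg}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = list(self.shape)
        d["wall_lambda_range"] = list(self.wall_lambda_range)
        return d


@dataclass
class TruthField:
    """Ground-truth fiber field of a phantom.

    ``axis`` is the true (sign-free) unit myocyte axis per voxel;
    ``ha``/``ia`` are the angles the pipeline's own conventions assign to
    that axis in the phantom's local frame; ``depth`` is the true
    normalised transmural position; all defined where ``mask`` is set.
    """

    axis: np.ndarray   # (nx, ny, nz, 3) float32, unit-norm in mask
    ha: np.ndarray     # degrees, NaN outside mask
    ia: np.ndarray
    depth: np.ndarray  # ∈ [0, 1], NaN outside mask
    mask: np.ndarray   # bool


# ---------------------------------------------------------------------------
# Orientation noise
# ---------------------------------------------------------------------------

def sample_axes(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniformly distributed unit axes, (n, 3)."""
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def perturb_axes(axes: np.ndarray, kappa: float,
                 rng: np.random.Generator | int) -> np.ndarray:
    """Axially-symmetric perturbation of unit axes with concentration kappa.

    ``kappa = inf`` is the identity; ``kappa = 0`` replaces every axis by
    an isotropic draw; finite ``kappa > 0`` adds a zero-mean Gaussian of
    sd ``1/sqrt(2·kappa)`` radians in the tangent plane and renormalises.
    The exact distribution family is unimportant downstream — only the
    monotone dispersion in kappa is relied on.
    """
    if kappa < 0:
        raise ValueError(f"kappa must be ≥ 0, got {kappa}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    a = np.asarray(axes, dtype=np.float64)
    flat = a.reshape(-1, 3)
    if np.isinf(kappa):
        return np.asarray(axes).copy()
    if kappa == 0:
        out = sample_axes(len(flat), rng)
        return out.reshape(a.shape).astype(axes.dtype, copy=False)
    # tangent basis per axis
    helper = np.where(np.abs(flat[:, :1]) < 0.9,
                      np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]))
    t1 = np.cross(flat, helper)
    t1 /= np.linalg.norm(t1, axis=-1, keepdims=True)
    t2 = np.cross(flat, t1)
    sd = 1.0 / np.sqrt(2.0 * kappa)
    g = rng.standard_normal((len(flat), 2)) * sd
    out = flat + g[:, :1] * t1 + g[:, 1:] * t2
    out /= np.linalg.norm(out, axis=-1, keepdims=True)
    return out.reshape(a.shape).astype(axes.dtype, copy=False)


# ---------------------------------------------------------------------------
# Texture rendering
# ---------------------------------------------------------------------------

def _trace_fiber_path(start: np.ndarray, axis_field: np.ndarray,
                      mask: np.ndarray, half_len: float, step: float,
                      ) -> np.ndarray:
    """Polyline through ``start`` following the axis field both ways.

    Positions are in voxel units; directions come from the nearest voxel
    of the (sign-ambiguous) axis field, sign-aligned with the previous
    step so the path does not fold back on itself.
    """
    shape = np.array(mask.shape)
    n_steps = max(int(np.ceil(half_len / step)), 1)

    def march(sign0: float) -> list[np.ndarray]:
        pts = []
        p = start.astype(np.float64).copy()
        nearest = tuple(np.clip(np.round(p).astype(int), 0, shape - 1))
        d = axis_field[nearest].astype(np.float64) * sign0
        for _ in range(n_steps):
            p = p + d * step
            pts.append(p.copy())
            nearest = tuple(np.clip(np.round(p).astype(int), 0, shape - 1))
            d_new = axis_field[nearest].astype(np.float64)
            if not np.any(d_new):
                break  # left the field; keep a straight tail direction
            if d_new @ d < 0:
                d_new = -d_new
            d = d_new
        return pts

    fwd = march(1.0)
    bwd = march(-1.0)
    return np.array(bwd[::-1] + [start.astype(np.float64)] + fwd)


def _render_rods(shape: tuple[int, int, int], voxel: float,
                 mask: np.ndarray, axis_field: np.ndarray,
                 spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Superpose curved capsule rods that follow the local axis field.

    Each rod is a polyline traced along the (possibly noisy) fiber field
    from a Poisson-random wall position, rendered as a tube with a
    conical radial intensity profile (bright core, dark edge) so that
    every interior voxel carries a transverse gradient. Rods composite by
    maximum, so densely packed aggregates keep their individual cores
    instead of washing out to a flat field.
    """
    vol = np.zeros(shape, dtype=np.float32)
    wall_idx = np.argwhere(mask)
    if len(wall_idx) == 0:
        return vol
    wall_volume_um3 = len(wall_idx) * voxel**3
    n_rods = int(rng.poisson(spec.rod_density * wall_volume_um3))
    picks = rng.integers(0, len(wall_idx), size=n_rods)
    jitter = rng.uniform(-0.5, 0.5, size=(n_rods, 3))
    centres = wall_idx[picks] + jitter            # voxel units
    half_len = 0.5 * spec.rod_length_um / voxel   # voxel units
    radius = spec.rod_radius_um / voxel
    soft_radius = radius + 0.5
    step = 1.0                                    # path step, voxels
    grids = [np.arange(s, dtype=np.float32) for s in shape]
    for c in centres:
        path = _trace_fiber_path(c, axis_field, mask, half_len, step)
        lo = np.maximum(np.floor(path.min(0) - soft_radius - 1).astype(int), 0)
        hi = np.minimum(np.ceil(path.max(0) + soft_radius + 1).astype(int) + 1,
                        shape)
        if np.any(lo >= hi):
            continue
        X, Y, Z = np.meshgrid(grids[0][lo[0]:hi[0]], grids[1][lo[1]:hi[1]],
                              grids[2][lo[2]:hi[2]], indexing="ij")
        prof = np.zeros(X.shape, dtype=np.float32)
        # max over segments = conical profile of the distance to the path
        for p0, p1 in zip(path[:-1], path[1:]):
            seg = p1 - p0
            seg_len2 = float(seg @ seg)
            if seg_len2 == 0:
                continue
            dx, dy, dz = X - p0[0], Y - p0[1], Z - p0[2]
            t = np.clip((dx * seg[0] + dy * seg[1] + dz * seg[2]) / seg_len2,
                        0.0, 1.0)
            d2 = ((dx - t * seg[0]) ** 2 + (dy - t * seg[1]) ** 2
                  + (dz - t * seg[2]) ** 2)
            np.maximum(prof, np.clip(1.0 - np.sqrt(d2) / soft_radius,
                                     0.0, 1.0), out=prof)
        np.maximum(vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]], prof,
                   out=vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]])
    return vol


def _finalize_volume(rods: np.ndarray, spec: PhantomSpec,
                     rng: np.random.Generator) -> ImageVolume:
    vals = rods + rng.normal(0.0, spec.noise_sd,
                             size=rods.shape).astype(np.float32)
    return ImageVolume(vals.astype(np.float32), (spec.voxel_size_um,) * 3)


# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------

def _axis_from_angles(ha_deg: np.ndarray, ia_deg: float,
                      c: np.ndarray, l_: np.ndarray, r: np.ndarray,
                      ) -> np.ndarray:
    """Rotate ĉ by HA toward l̂, then by IA toward r̂."""
    ha = np.radians(np.asarray(ha_deg, dtype=np.float64))
    ia = np.radians(float(ia_deg))
    in_plane = np.cos(ha)[..., None] * c + np.sin(ha)[..., None] * l_
    return np.cos(ia) * in_plane + np.sin(ia) * r


def _truth_from_axes(axes: np.ndarray, mask: np.ndarray, depth: np.ndarray,
                     r: np.ndarray, c: np.ndarray, l_: np.ndarray,
                     ) -> TruthField:
    ha_v, ia_v = angles_from_axes(axes, r, c, l_)
    shape = mask.shape
    axis = np.zeros(shape + (3,), dtype=np.float32)
    ha = np.full(shape, np.nan, dtype=np.float32)
    ia = np.full(shape, np.nan, dtype=np.float32)
    dep = np.full(shape, np.nan, dtype=np.float32)
    axis[mask] = axes
    ha[mask] = ha_v
    ia[mask] = ia_v
    dep[mask] = depth
    return TruthField(axis=axis, ha=ha, ia=ia, depth=dep, mask=mask)


def make_slab_phantom(spec: PhantomSpec,
                      ) -> tuple[ImageVolume, np.ndarray, TruthField]:
    """Rectangular wall slab with a spatially uniform fiber axis.

    The trivial frame is circumferential = +x, longitudinal = +y,
    radial = +z; depth runs along +z. The mask excludes a 2-voxel border
    so that no image-boundary gradients enter downstream statistics.
    """
    spec.validate()
    if spec.geometry_kind != "slab":
        raise ValueError(f"geometry_kind must be 'slab', got "
                         f"{spec.geometry_kind!r}")
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    mask = np.zeros(shape, dtype=np.uint8)
    mask[2:-2, 2:-2, 2:-2] = LABEL_LV_FREE_WALL
    inside = mask > 0

    c = np.array([1.0, 0.0, 0.0])
    l_ = np.array([0.0, 1.0, 0.0])
    r = np.array([0.0, 0.0, 1.0])
    n = int(inside.sum())
    base_axis = _axis_from_angles(np.full(n, spec.ha_endo_deg), spec.ia_deg,
                                  c, l_, r)
    axes = perturb_axes(base_axis, spec.kappa, rng)

    zidx = np.argwhere(inside)[:, 2].astype(np.float64)
    depth = (zidx - 2) / max(shape[2] - 5, 1)

    frames = (np.broadcast_to(r, (n, 3)), np.broadcast_to(c, (n, 3)),
              np.broadcast_to(l_, (n, 3)))
    truth = _truth_from_axes(axes, inside, depth, *frames)
    vol = _finalize_volume(
        _render_rods(shape, spec.voxel_size_um, inside, truth.axis, spec, rng),
        spec, rng)
    return vol, mask, truth


def make_shell_phantom(spec: PhantomSpec,
                       ) -> tuple[ImageVolume, np.ndarray, TruthField,
                                  ProlateGeometry]:
    """Truncated prolate-spheroidal shell bearing the linear HA law.

    The returned mask uses segmentation labels 1/2/3: a 90° circumferential
    wedge centred on the θ = 0 direction is relabelled 'septum' (2) and the
    two flanking 30° wedges 'RV free wall' (3) so regional code paths are
    exercisable; geometrically everything is the one LV shell.
    """
    spec.validate()
    if spec.geometry_kind != "prolate_shell":
        raise ValueError(f"geometry_kind must be 'prolate_shell', got "
                         f"{spec.geometry_kind!r}")
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    voxel = spec.voxel_size_um
    centre = (np.array(shape, dtype=float) - 1) / 2 * voxel
    geometry = ProlateGeometry(centre=centre, long_axis=[0.0, 0.0, 1.0],
                               Ra=spec.Ra_um, Rb=spec.Rb_um,
                               theta_ref=[1.0, 0.0, 0.0])
    lam_mid = geometry.lambda_mid
    lam_endo = spec.wall_lambda_range[0] * lam_mid
    lam_epi = spec.wall_lambda_range[1] * lam_mid
    # basal truncation: a flat cut normal to the long axis at the height
    # where the mid-wall ellipsoid reaches the requested colatitude span
    # (the cavity stays open through the cut, as at a real valve plane)
    z_cut = (np.cos(np.pi - np.radians(spec.base_truncation_deg))
             * geometry.f * np.cosh(lam_mid))

    # the shell must fit inside the box: epi apex pole along −z, epi
    # equator across
    f = geometry.f
    a_epi = f * np.cosh(lam_epi)
    b_epi = f * np.sinh(lam_epi)
    half_extent = (np.array(shape, dtype=float) - 1) / 2 * voxel
    if a_epi > half_extent[2] or b_epi > min(half_extent[0], half_extent[1]):
        raise ValueError(
            f"shell does not fit inside the volume (epi pole {a_epi:.0f} µm"
            f", epi equator {b_epi:.0f} µm vs half-extents "
            f"{half_extent.round(0)}): enlarge shape or shrink Ra_um/Rb_um")

    coords = np.stack(np.meshgrid(*[np.arange(s) * voxel for s in shape],
                                  indexing="ij"), axis=-1)
    lam, mu, theta = geometry.prolate_coords(coords.reshape(-1, 3))
    lam = lam.reshape(shape)
    mu = mu.reshape(shape)
    theta = theta.reshape(shape)
    zrel = coords[..., 2] - centre[2]
    inside = (lam >= lam_endo) & (lam <= lam_epi) & (zrel <= z_cut)
    # the local frame is singular exactly on the long axis; voxel centres
    # only land there when the grid centre does, so drop just those
    rho = np.linalg.norm((coords - centre)[..., :2], axis=-1)
    inside &= rho > 1e-6 * voxel
    if not inside.any():
        raise ValueError("shell does not intersect the volume; enlarge "
                         "shape or shrink Ra_um/Rb_um")

    # reject unresolvable walls: thickness at the apex is the thinnest
    f = geometry.f
    min_thickness_um = f * (lam_epi - lam_endo) * np.sinh(lam_endo)
    if min_thickness_um < 3 * voxel:
        raise ValueError(
            f"wall thinner than 3 voxels ({min_thickness_um:.1f} µm at "
            f"{voxel} µm voxels): transmural profiles are unresolvable")

    mask = np.zeros(shape, dtype=np.uint8)
    th = np.degrees(theta)
    mask[inside] = LABEL_LV_FREE_WALL
    mask[inside & (np.abs(th) <= 45)] = LABEL_SEPTUM
    mask[inside & (np.abs(th) > 45) & (np.abs(th) <= 75)] = LABEL_RV_FREE_WALL

    pts = coords[inside]
    r, c, l_ = local_basis_grid(pts, geometry)
    depth = (lam[inside] - lam_endo) / (lam_epi - lam_endo)
    ha_true = spec.ha_endo_deg + (spec.ha_epi_deg - spec.ha_endo_deg) * depth
    base_axes = _axis_from_angles(ha_true, spec.ia_deg, c, l_, r)
    axes = perturb_axes(base_axes, spec.kappa, rng)

    truth = _truth_from_axes(axes, inside, depth, r, c, l_)
    vol = _finalize_volume(
        _render_rods(shape, voxel, inside, truth.axis, spec, rng), spec, rng)
    return vol, mask, truth, geometry
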