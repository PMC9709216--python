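"""LV prolate-spheroidal geometry and myocyte orientation angles.

The left ventricle is modelled as a truncated prolate spheroid. A point is
described by prolate coordinates (λ transmural, μ longitudinal, θ
circumferential) relative to the fitted centre and long axis; with
semi-foci distance ``f`` the surfaces of constant λ are confocal ellipsoids
with semi-axes ``a = f·cosh λ`` (along the long axis) and
``b = f·sinh λ`` (across it).

The local orthonormal frame at a wall point consists of

* ``r`` — radial unit vector, endocardium → epicardium (∂/∂λ direction),
* ``c`` — circumferential unit vector (∂/∂θ direction),
* ``l`` — longitudinal unit vector, apex → base,

right-handed with ``c × l = r``. The myocyte long axis ``v3`` (sign-free)
is summarised by two angles, both in degrees ∈ [−90, +90]:

* helical angle HA — angle between ``v3`` and the local radial–
  circumferential (short-axis) plane: ``HA = asin(v3 · l)``;
* intrusion angle IA — angle between ``v3`` and the local epicardial
  tangential plane: ``IA = asin(v3 · r)``.

Because an axis has no intrinsic sign, ``v3`` is first sign-disambiguated
so that ``v3 · c ≥ 0`` (ties broken by ``v3 · l ≥ 0``); this is the
pipeline-wide convention that makes the angle signs well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProlateGeometry",
    "semi_foci",
    "fit_lv_ellipsoid",
    "local_basis",
    "local_basis_grid",
    "compute_angles",
    "disambiguate_sign",
]


def semi_foci(Ra: float, Rb: float) -> float:
    """Semi-foci distance f = sqrt(Ra² − Rb²) of the LV ellipsoid (µm)."""
    if Rb <= 0:
        raise ValueError(f"Rb must be positive, got {Rb}")
    if Rb > Ra:
        raise ValueError(f"Rb ({Rb}) must not exceed Ra ({Ra})")
    return float(np.sqrt(Ra * Ra - Rb * Rb))


@dataclass
class ProlateGeometry:
    """Fitted LV ellipsoid defining the prolate-spheroidal frame.

    ``centre`` is in µm (volume-corner origin), ``long_axis`` is a unit
    vector pointing apex → base, ``Ra``/``Rb`` are the major/minor
    semi-axes of the mid-wall ellipsoid in µm.
    """

    centre: np.ndarray
    long_axis: np.ndarray
    Ra: float
    Rb: float
    theta_ref: np.ndarray | None = None  # unit vector defining θ = 0

    def __post_init__(self) -> None:
        self.centre = np.asarray(self.centre, dtype=float)
        axis = np.asarray(self.long_axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("long_axis must be non-zero")
        self.long_axis = axis / n
        if not (self.Ra > self.Rb > 0):
            raise ValueError(
                f"need Ra > Rb > 0, got Ra={self.Ra}, Rb={self.Rb} "
                "(degenerate prolate frame)")
        if self.theta_ref is None:
            # any unit vector orthogonal to the long axis
            trial = np.eye(3)[np.argmin(np.abs(self.long_axis))]
            ref = trial - self.long_axis * (trial @ self.long_axis)
            self.theta_ref = ref / np.linalg.norm(ref)
        else:
            ref = np.asarray(self.theta_ref, dtype=float)
            ref = ref - self.long_axis * (ref @ self.long_axis)
            self.theta_ref = ref / np.linalg.norm(ref)

    @property
    def f(self) -> float:
        """Semi-foci distance (µm)."""
        return semi_foci(self.Ra, self.Rb)

    @property
    def lambda_mid(self) -> float:
        """Prolate λ of the mid-wall ellipsoid: atanh(Rb/Ra)."""
        return float(np.arctanh(self.Rb / self.Ra))

    # -- coordinates --------------------------------------------------------

    def prolate_coords(self, points: np.ndarray) -> tuple[np.ndarray, ...]:
        """Prolate (λ, μ, θ) of Cartesian points (..., 3) in µm.

        μ is the colatitude from the basal pole of the long axis (base
        μ = 0, apex μ = π); θ is the azimuth about the long axis measured
        counterclockwise from ``theta_ref`` (right-hand rule about the
        apex→base axis).
        """
        p = np.asarray(points, dtype=float) - self.centre
        z = p @ self.long_axis
        perp = p - np.multiply.outer(z, self.long_axis)
        rho = np.linalg.norm(perp, axis=-1)
        f = self.f
        d1 = np.sqrt((z + f) ** 2 + rho**2)   # distance to basal focus at +f
        d2 = np.sqrt((z - f) ** 2 + rho**2)
        # note: basal pole taken at +f·long_axis, apical pole at −f·long_axis
        cosh_lam = np.clip((d1 + d2) / (2 * f), 1.0, None)
        cos_mu = np.clip((d1 - d2) / (2 * f), -1.0, 1.0)
        lam = np.arccosh(cosh_lam)
        mu = np.arccos(cos_mu)
        e2 = np.cross(self.long_axis, self.theta_ref)
        theta = np.arctan2(perp @ e2, perp @ self.theta_ref)
        return lam, mu, theta


def _frames_from_prolate(geometry: ProlateGeometry, points: np.ndarray,
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised local (r, c, l) frames at Cartesian points (..., 3)."""
    p = np.asarray(points, dtype=float) - geometry.centre
    zhat = geometry.long_axis
    z = p @ zhat
    perp = p - np.multiply.outer(z, zhat)
    rho = np.linalg.norm(perp, axis=-1)
    if np.any(rho <= 0):
        raise ValueError("point on the long axis: θ (and the local frame) "
                         "is undefined there")
    rho_hat = perp / rho[..., None]
    lam, mu, _ = geometry.prolate_coords(points)
    f = geometry.f
    sl, cl = np.sinh(lam), np.cosh(lam)
    sm, cm = np.sin(mu), np.cos(mu)
    # ∂p/∂λ = f·(sinh λ cos μ) ẑ + f·(cosh λ sin μ) ρ̂  → radial, endo→epi
    r = (f * sl * cm)[..., None] * zhat + (f * cl * sm)[..., None] * rho_hat
    r /= np.linalg.norm(r, axis=-1, keepdims=True)
    # ∂p/∂μ points base→apex (μ grows apex-ward); l is apex→base
    l_ = (f * cl * sm)[..., None] * zhat - (f * sl * cm)[..., None] * rho_hat
    l_ /= np.linalg.norm(l_, axis=-1, keepdims=True)
    c = np.cross(l_, r)  # = θ̂; right-handed with c × l = r
    return r, c, l_


def local_basis(point: np.ndarray, geometry: ProlateGeometry,
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Local (r̂, ĉ, l̂) frame at a single Cartesian point (µm)."""
    r, c, l_ = _frames_from_prolate(geometry, np.asarray(point, float)[None])
    return r[0], c[0], l_[0]


def local_basis_grid(points: np.ndarray, geometry: ProlateGeometry,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Local frames for an (N, 3) array of Cartesian points (µm)."""
    return _frames_from_prolate(geometry, points)


# ---------------------------------------------------------------------------
# Ellipsoid fit
# ---------------------------------------------------------------------------

def _fit_axisymmetric_ellipse(rho: np.ndarray, z: np.ndarray,
                              ) -> tuple[float, float, float]:
    """LSQ fit of α·ρ² + β·z² + γ·z = 1; returns (a, b, z0).

    ``a`` is the semi-axis along z, ``b`` across, ``z0`` the centre offset
    along the axis.
    """
    A = np.column_stack([rho**2, z**2, z])
    coef, *_ = np.linalg.lstsq(A, np.ones_like(z), rcond=None)
    alpha, beta, gamma = coef
    if alpha <= 0 or beta <= 0:
        raise ValueError("degenerate surface: ellipsoid fit did not converge "
                         "to a bounded shape")
    z0 = -gamma / (2 * beta)
    rhs = 1.0 + gamma**2 / (4 * beta)
    return float(np.sqrt(rhs / beta)), float(np.sqrt(rhs / alpha)), float(z0)


def fit_lv_ellipsoid(mask: np.ndarray, voxel_size_um: float | tuple,
                     lv_labels: tuple[int, ...] = (1, 2),
                     cavity: np.ndarray | None = None,
                     min_voxels: int = 1000) -> ProlateGeometry:
    """Fit the LV prolate frame from a labelled wall mask.

    The long axis is the principal axis of the cavity blood pool; the
    mid-wall semi-axes Ra/Rb are the means of the endo- and epicardial
    semi-axes, which come from four extremal measurements (apical pole
    positions and equatorial radii of cavity and wall) closed by the
    confocality of the two surfaces. The apex→base orientation is
    resolved by the cavity (larger cavity cross-section at the base).
    """
    labels = np.asarray(mask)
    wall = np.isin(labels, lv_labels)
    n = int(wall.sum())
    if n < min_voxels:
        raise ValueError(f"LV mask too small to fit an ellipsoid "
                         f"({n} voxels < {min_voxels})")
    vs = np.broadcast_to(np.atleast_1d(voxel_size_um), (3,)).astype(float)
    idx = np.argwhere(wall)
    pts = idx * vs
    # the long axis comes from the cavity blood-pool cloud when one is
    # available — a truncated thick shell's own principal axis is not a
    # reliable symmetry-axis estimate — otherwise from the wall cloud
    axis_pts = (np.argwhere(cavity) * vs if cavity is not None
                and cavity.any() else pts)
    centre = axis_pts.mean(axis=0)
    centred = axis_pts - centre
    cov = centred.T @ centred / len(axis_pts)
    evals, evecs = np.linalg.eigh(cov)
    if evals[2] < 1e-9 * evals.sum() or evals[1] < 1e-9 * evals.sum():
        raise ValueError("degenerate LV mask: voxels are (nearly) coplanar")
    axis = evecs[:, 2]  # largest-variance direction
    # keep the cavity centroid as the reference point: the wall centroid
    # is pulled sideways by whichever labels are excluded (e.g. the RV),
    # which would inflate every transverse radius
    centred = pts - centre

    # orient apex→base: more cavity (or wall ring) mass at the basal end
    z = centred @ axis
    zr = z.max() - z.min()
    if cavity is not None and cavity.any():
        zc = (np.argwhere(cavity) * vs - centre) @ axis
        hi = (zc > zc.min() + 0.8 * (zc.max() - zc.min())).sum()
        lo = (zc < zc.min() + 0.2 * (zc.max() - zc.min())).sum()
    else:
        rho = np.linalg.norm(centred - np.outer(z, axis), axis=1)
        hi = rho[z > z.max() - 0.2 * zr].mean()
        lo = rho[z < z.min() + 0.2 * zr].mean()
    if lo > hi:
        axis = -axis
        z = -z

    # Ra/Rb from four sharp extremal measurements tied together by
    # confocality. The cavity's apical extreme is the endocardial pole
    # and the wall's is the epicardial pole, giving the pole separation
    # delta = a_epi - a_endo; the cavity's and wall's maximal transverse
    # radii are the equatorial semi-axes b_endo and b_epi. Because endo
    # and epi are confocal, a_epi**2 - a_endo**2 = b_epi**2 - b_endo**2,
    # so a_epi + a_endo = (b_epi**2 - b_endo**2) / delta -- no centre or
    # equator-plane estimate is needed, which free ellipsoid fits of
    # basally-truncated cup surfaces cannot deliver robustly.
    if cavity is None or not cavity.any():
        raise ValueError("a cavity mask is required to identify the "
                         "endocardial surface (see find_shell_surfaces)")
    cav_rel = np.argwhere(cavity) * vs - centre
    z_cav = cav_rel @ axis
    rho_cav = np.linalg.norm(cav_rel - np.outer(z_cav, axis), axis=1)
    rho_wall = np.linalg.norm(centred - np.outer(z, axis), axis=1)
    half = 0.5 * float(vs.max())
    delta = float(z_cav.min() - z.min())          # a_epi - a_endo
    b_endo = float(np.percentile(rho_cav, 99.8)) + half
    b_epi = float(np.percentile(rho_wall, 99.8)) + half
    if delta <= half or b_epi <= b_endo:
        raise ValueError("wall thickness unresolved at the apex: cannot "
                         "separate the endo and epi surfaces")
    a_sum = (b_epi**2 - b_endo**2) / delta
    a_endo = 0.5 * (a_sum - delta)
    a_epi = 0.5 * (a_sum + delta)
    Ra = float(0.5 * (a_endo + a_epi))
    Rb = float(0.5 * (b_endo + b_epi))
    if not (a_endo > b_endo > 0 and Ra > Rb):
        raise ValueError(f"fitted shell is not prolate (Ra={Ra:.1f}, "
                         f"Rb={Rb:.1f}); spherical or oblate shells have "
                         "no prolate frame")
    # centre: on the axis, one endocardial semi-axis above the cavity pole
    perp = (np.argwhere(cavity) * vs).mean(axis=0)
    perp = perp - axis * (perp @ axis)
    z0 = float(z_cav.min()) + (centre @ axis) + a_endo
    centre = perp + axis * z0
    return ProlateGeometry(centre=centre, long_axis=axis, Ra=Ra, Rb=Rb)


# ---------------------------------------------------------------------------
# Angles
# ---------------------------------------------------------------------------

def disambiguate_sign(axes: np.ndarray, c: np.ndarray, l_: np.ndarray,
                      ) -> np.ndarray:
    """Flip axis vectors so that v·c ≥ 0 (ties: v·l ≥ 0)."""
    dc = np.sum(axes * c, axis=-1)
    dl = np.sum(axes * l_, axis=-1)
    flip = (dc < 0) | ((dc == 0) & (dl < 0))
    out = axes.copy()
    out[flip] *= -1.0
    return out


def angles_from_axes(axes: np.ndarray, r: np.ndarray, c: np.ndarray,
                     l_: np.ndarray, *, projected: bool = False,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """HA and IA (degrees) of unit axes given local frames.

    Default: HA = asin(v·l), IA = asin(v·r) — the literal angle between
    the vector and the short-axis / tangential plane. ``projected=True``
    uses the in-plane projection variant HA = atan2(v·l, v·c),
    IA = atan2(v·r, v·c) instead.
    """
    v = disambiguate_sign(axes, c, l_)
    vc = np.sum(v * c, axis=-1)
    vl = np.sum(v * l_, axis=-1)
    vr = np.sum(v * r, axis=-1)
    if projected:
        ha = np.degrees(np.arctan2(vl, vc))
        ia = np.degrees(np.arctan2(vr, vc))
    else:
        ha = np.degrees(np.arcsin(np.clip(vl, -1.0, 1.0)))
        ia = np.degrees(np.arcsin(np.clip(vr, -1.0, 1.0)))
    return ha, ia


def compute_angles(v3: np.ndarray, valid: np.ndarray,
                   geometry: ProlateGeometry,
                   voxel_size_um: float | tuple,
                   *, projected: bool = False, atol: float = 1e-3,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel HA/IA maps (degrees) from a v3 eigenvector field.

    ``v3`` has shape (nx, ny, nz, 3); ``valid`` is the boolean validity
    mask. Invalid voxels are NaN in the output maps.
    """
    valid = np.asarray(valid, bool)
    vs = np.broadcast_to(np.atleast_1d(voxel_size_um), (3,)).astype(float)
    idx = np.argwhere(valid)
    vecs = np.asarray(v3)[valid].astype(float)
    norms = np.linalg.norm(vecs, axis=-1)
    if vecs.size and np.any(np.abs(norms - 1.0) > max(atol, 1e-3)):
        worst = float(np.abs(norms - 1.0).max())
        raise ValueError(f"v3 must be unit-norm at valid voxels "
                         f"(worst deviation {worst:.2e})")
    pts = idx * vs
    r, c, l_ = local_basis_grid(pts, geometry)
    ha_v, ia_v = angles_from_axes(vecs, r, c, l_, projected=projected)
    ha = np.full(valid.shape, np.nan, dtype=np.float32)
    ia = np.full(valid.shape, np.nan, dtype=np.float32)
    ha[valid] = ha_v
    ia[valid] = ia_v
    return ha, ia
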