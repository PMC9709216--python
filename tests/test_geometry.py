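"""Prolate frame, semi-foci distance, local bases, angles, resampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import myoarch as ma
from myoarch.geometry import (ProlateGeometry, angles_from_axes, local_basis,
                              local_basis_grid, semi_foci)
from myoarch.volume import ImageVolume, resample_isotropic


GEOM = ProlateGeometry(centre=[0.0, 0.0, 0.0], long_axis=[0, 0, 1],
                       Ra=100.0, Rb=65.0, theta_ref=[1, 0, 0])


class TestSemiFoci:
    def test_three_four_five(self):
        assert semi_foci(5.0, 3.0) == pytest.approx(4.0, abs=1e-12)

    def test_degenerate_sphere(self):
        assert semi_foci(7.0, 7.0) == 0.0

    def test_embryonic_scale(self):
        # sqrt(400² − 250²) = sqrt(97500)
        assert semi_foci(400.0, 250.0) == pytest.approx(312.2499, abs=1e-3)

    def test_rb_larger_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            semi_foci(3.0, 5.0)


class TestLocalBasis:
    def test_equatorial_frame(self):
        r, c, l_ = local_basis([80.0, 0.0, 0.0], GEOM)
        assert np.allclose(r, [1, 0, 0], atol=1e-9)
        assert np.allclose(c, [0, 1, 0], atol=1e-9)
        assert np.allclose(l_, [0, 0, 1], atol=1e-9)

    @given(st.floats(30, 150), st.floats(-np.pi, np.pi),
           st.floats(-60, 60))
    @settings(deadline=None, max_examples=100)
    def test_orthonormal_right_handed(self, rho, theta, z):
        p = [rho * np.cos(theta), rho * np.sin(theta), z]
        r, c, l_ = local_basis(p, GEOM)
        for v in (r, c, l_):
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-9)
        assert abs(r @ c) + abs(r @ l_) + abs(c @ l_) < 1e-9
        assert np.allclose(np.cross(c, l_), r, atol=1e-9)

    def test_reflection_flips_circumferential(self):
        """Mirroring a point through the long axis reverses θ parity: ĉ
        reflects like an axial vector while r̂ and l̂ reflect like polar
        ones."""
        p = np.array([50.0, 30.0, 20.0])
        pm = np.array([50.0, -30.0, 20.0])
        r1, c1, l1 = local_basis(p, GEOM)
        r2, c2, l2 = local_basis(pm, GEOM)
        mirror = np.array([1, -1, 1.0])
        assert np.allclose(r2, r1 * mirror, atol=1e-9)
        assert np.allclose(l2, l1 * mirror, atol=1e-9)
        assert np.allclose(c2, -c1 * mirror, atol=1e-9)

    def test_on_axis_rejected(self):
        with pytest.raises(ValueError, match="long axis"):
            local_basis([0.0, 0.0, 30.0], GEOM)


class TestAnglesFromAxes:
    def test_circumferential_fiber(self):
        r, c, l_ = local_basis([80.0, 0.0, 0.0], GEOM)
        ha, ia = angles_from_axes(c[None], r[None], c[None], l_[None])
        assert ha[0] == pytest.approx(0.0, abs=1e-9)
        assert ia[0] == pytest.approx(0.0, abs=1e-9)

    def test_45_degree_helix(self):
        r, c, l_ = local_basis([80.0, 0.0, 0.0], GEOM)
        v = (c + l_) / np.sqrt(2)
        ha, ia = angles_from_axes(v[None], r[None], c[None], l_[None])
        assert ha[0] == pytest.approx(45.0, abs=1e-9)
        assert ia[0] == pytest.approx(0.0, abs=1e-9)

    def test_pure_intrusion_component(self):
        r, c, l_ = local_basis([80.0, 0.0, 0.0], GEOM)
        v = 0.6 * c + 0.8 * r
        ha, ia = angles_from_axes(v[None], r[None], c[None], l_[None])
        assert ha[0] == pytest.approx(0.0, abs=1e-9)
        assert ia[0] == pytest.approx(np.degrees(np.arcsin(0.8)), abs=1e-6)

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-80, 80, (200, 3))
        pts = pts[np.linalg.norm(pts[:, :2], axis=1) > 10]
        r, c, l_ = local_basis_grid(pts, GEOM)
        v = rng.normal(size=(len(pts), 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        ha1, ia1 = angles_from_axes(v, r, c, l_)
        ha2, ia2 = angles_from_axes(-v, r, c, l_)
        assert np.allclose(ha1, ha2, atol=1e-9)
        assert np.allclose(ia1, ia2, atol=1e-9)

    def test_ha_continuity_across_theta_seam(self):
        """A circumferential fiber ring gives HA=0 everywhere, with no
        jump where θ wraps at ±π."""
        theta = np.linspace(-np.pi, np.pi, 721)
        pts = np.stack([80 * np.cos(theta), 80 * np.sin(theta),
                        np.zeros_like(theta)], axis=1)
        r, c, l_ = local_basis_grid(pts, GEOM)
        # fiber = 30° helix built in each local frame, then recovered
        v = np.cos(np.radians(30)) * c + np.sin(np.radians(30)) * l_
        ha, ia = angles_from_axes(v, r, c, l_)
        assert np.allclose(ha, 30.0, atol=1e-9)
        assert np.max(np.abs(np.diff(ha))) < 1e-9


class TestFitLVEllipsoid:
    def test_shell_recovery(self, clean_shell_study):
        """Fitted mid-wall semi-axes and semi-foci track the phantom."""
        s = clean_shell_study
        g = s.result.geometry
        assert g.Ra == pytest.approx(s.spec.Ra_um, rel=0.05)
        assert g.Rb == pytest.approx(s.spec.Rb_um, rel=0.05)
        assert g.f == pytest.approx(s.geometry.f, rel=0.10)
        assert abs(g.long_axis @ s.geometry.long_axis) > 0.999

    def test_large_heart_coarse_voxels(self):
        """A fetal-scale Ra=400/Rb=250 µm shell at 8 µm voxels."""
        from myoarch.profiles import find_shell_surfaces
        spec = ma.PhantomSpec(shape=(128, 128, 128), voxel_size_um=8.0,
                              Ra_um=400.0, Rb_um=250.0, seed=1,
                              rod_density=1e-6, noise_sd=0.0)
        _, mask, _, geom0 = ma.make_shell_phantom(spec)
        cavity, _ = find_shell_surfaces(mask)
        g = ma.fit_lv_ellipsoid(mask, 8.0, cavity=cavity)
        assert g.Ra == pytest.approx(400.0, rel=0.05)
        assert g.Rb == pytest.approx(250.0, rel=0.05)
        assert g.f == pytest.approx(geom0.f, rel=0.10)

    def test_tiny_mask_rejected(self):
        mask = np.zeros((10, 10, 10), np.uint8)
        mask[4:6, 4:6, 4:6] = 1
        with pytest.raises(ValueError, match="too small"):
            ma.fit_lv_ellipsoid(mask, 2.0)

    def test_spherical_shell_rejected(self):
        """A spherical shell has no prolate frame."""
        n = 64
        x, y, z = np.meshgrid(*[np.arange(n) - (n - 1) / 2] * 3,
                              indexing="ij")
        rad = np.sqrt(x**2 + y**2 + z**2)
        mask = ((rad > 20) & (rad < 26) & (z < 14)).astype(np.uint8)
        cavity = (rad <= 20)
        with pytest.raises(ValueError, match="prolate|equator"):
            ma.fit_lv_ellipsoid(mask, 2.0, cavity=cavity)


class TestResampleIsotropic:
    def test_isotropic_identity(self):
        vol = ImageVolume(np.random.default_rng(0).normal(size=(8, 8, 8)),
                          2.0)
        out = resample_isotropic(vol)
        assert out is vol

    def test_z_scaling_arithmetic(self):
        vol = ImageVolume(np.zeros((40, 40, 100), np.float32),
                          (2.0, 2.0, 3.0))
        out = resample_isotropic(vol)
        assert out.shape == (40, 40, 150)
        assert out.voxel_size_um == (2.0, 2.0, 2.0)
        assert out.is_isotropic

    def test_linear_ramp_preserved(self):
        z = np.arange(60, dtype=np.float32)
        vals = np.broadcast_to(z[None, None, :], (16, 16, 60)).copy()
        vol = ImageVolume(vals, (2.0, 2.0, 3.0))
        out = resample_isotropic(vol)
        # interior stays a linear ramp in physical coordinates
        got = out.values[8, 8, 5:-5]
        x = np.arange(out.shape[2])[5:-5]
        fit = np.polyfit(x, got, 1)
        resid = got - np.polyval(fit, x)
        assert np.abs(resid).max() < 1e-4
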