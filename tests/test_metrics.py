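"""Disarray index, angular classifications, AHA segments, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import myoarch as ma
from myoarch.metrics import (AHA_SEPTAL_SEGMENTS, DisarrayMap, angle_histogram,
                             classify_angles, classify_ha, classify_ia,
                             compute_mdi)
from myoarch.phantom import perturb_axes
from myoarch.tensor import OrientationField


def orientation_from_axes(axes: np.ndarray, valid=None) -> OrientationField:
    shape = axes.shape[:3]
    if valid is None:
        valid = np.ones(shape, bool)
    return OrientationField(np.zeros(shape + (3,), np.float32),
                            axes.astype(np.float32), valid)


def uniform_field(shape, direction):
    v = np.zeros(shape + (3,), np.float32)
    v[:] = np.asarray(direction) / np.linalg.norm(direction)
    return v


class TestMDI:
    def test_uniform_field_is_one(self):
        o = orientation_from_axes(uniform_field((20, 20, 20), [1, 0, 0]))
        m = compute_mdi(o, window=11, voxel_size_um=2.0)
        interior = m.values[5:-5, 5:-5, 5:-5]
        assert np.nanmin(interior) == pytest.approx(1.0, abs=1e-6)

    def test_isotropic_axes_near_zero(self):
        base = np.tile([0.0, 0.0, 1.0], (22**3, 1))
        axes = perturb_axes(base, 0.0, np.random.default_rng(1))
        axes = axes.reshape(22, 22, 22, 3)
        m = compute_mdi(orientation_from_axes(axes), window=11,
                        voxel_size_um=2.0)
        assert np.nanmean(m.values) <= 0.1

    def test_half_x_half_y_quarter(self):
        """λ_max of diag(½, ½, 0) is ½, so MDI = (1.5 − 1)/2 = 0.25."""
        rng = np.random.default_rng(0)
        shape = (16, 16, 16)
        axes = np.zeros(shape + (3,), np.float32)
        which = rng.random(shape) < 0.5
        axes[which, 0] = 1.0
        axes[~which, 1] = 1.0
        m = compute_mdi(orientation_from_axes(axes), window=11,
                        voxel_size_um=2.0)
        interior = m.values[5:-5, 5:-5, 5:-5]
        assert np.nanmean(interior) == pytest.approx(0.25, abs=0.05)

    def test_physical_extent(self):
        o = orientation_from_axes(uniform_field((12, 12, 12), [0, 1, 0]))
        assert compute_mdi(o, window=11,
                           voxel_size_um=2.0).window_extent_um == 22.0
        assert compute_mdi(o, window=11,
                           voxel_size_um=3.0).window_extent_um == 33.0

    def test_even_window_rejected(self):
        o = orientation_from_axes(uniform_field((8, 8, 8), [1, 0, 0]))
        with pytest.raises(ValueError, match="odd"):
            compute_mdi(o, window=4)

    def test_undefined_outside_valid_neighbourhoods(self):
        shape = (15, 15, 15)
        valid = np.zeros(shape, bool)
        valid[6:9, 6:9, 6:9] = True  # far below 50% of an 11³ window
        o = orientation_from_axes(uniform_field(shape, [1, 0, 0]), valid)
        m = compute_mdi(o, window=11, voxel_size_um=2.0)
        assert np.isnan(m.values).all()

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(4)
        axes = rng.normal(size=(12, 12, 12, 3)).astype(np.float32)
        axes /= np.linalg.norm(axes, axis=-1, keepdims=True)
        flip = rng.random((12, 12, 12)) < 0.5
        flipped = axes.copy()
        flipped[flip] *= -1
        m1 = compute_mdi(orientation_from_axes(axes), window=5)
        m2 = compute_mdi(orientation_from_axes(flipped), window=5)
        assert np.allclose(np.nan_to_num(m1.values),
                           np.nan_to_num(m2.values), atol=1e-5)

    def test_variants_agree_on_aligned_field(self):
        """The mean-|dot| variant and the dyadic variant share endpoints."""
        o = orientation_from_axes(uniform_field((12, 12, 12), [0, 0, 1]))
        m1 = compute_mdi(o, window=5, method="dyadic")
        m2 = compute_mdi(o, window=5, method="mean_abs_dot")
        sel = np.isfinite(m1.values) & np.isfinite(m2.values)
        assert np.allclose(m1.values[sel], 1.0, atol=1e-6)
        assert np.allclose(m2.values[sel], 1.0, atol=1e-6)

    def test_monotone_in_phantom_kappa(self):
        """Organisation falls as kappa drops, so MDI must too."""
        base = np.tile([1.0, 0.0, 0.0], (18**3, 1))
        means = []
        for kappa in (np.inf, 20.0, 5.0, 0.0):
            axes = perturb_axes(base, kappa, np.random.default_rng(6))
            o = orientation_from_axes(axes.reshape(18, 18, 18, 3))
            m = compute_mdi(o, window=11, voxel_size_um=2.0)
            means.append(float(np.nanmean(m.values)))
        assert means[0] > means[1] > means[2] > means[3]


class TestClassification:
    def test_ha_hand_listed(self):
        out = classify_ha(np.array([0.0, 15.0, 25.0, -25.0]))
        assert out == {"frac_circ": 0.5, "frac_long_pos": 0.25,
                       "frac_long_neg": 0.25}

    def test_ha_boundary_inclusive(self):
        out = classify_ha(np.array([20.0, -20.0]))
        assert out["frac_circ"] == 1.0

    def test_ia_hand_listed(self):
        out = classify_ia(np.array([10.0, 30.0, 50.0, -50.0]))
        assert out == {"frac_IA_le15": 0.25, "frac_IA_15_45": 0.25,
                       "frac_IA_gt45": 0.5}

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            classify_ha(np.array([np.nan]))

    @given(st.lists(st.floats(-90, 90), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=100)
    def test_fractions_sum_to_one(self, angles):
        arr = np.array(angles)
        out = classify_angles(arr, arr)
        assert (out["frac_circ"] + out["frac_long_pos"]
                + out["frac_long_neg"]) == pytest.approx(1.0, abs=1e-9)
        assert (out["frac_IA_le15"] + out["frac_IA_15_45"]
                + out["frac_IA_gt45"]) == pytest.approx(1.0, abs=1e-9)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        ha = rng.uniform(-90, 90, 5000)
        f20 = classify_ha(ha, ha_threshold=20.0)["frac_circ"]
        f30 = classify_ha(ha, ha_threshold=30.0)["frac_circ"]
        assert f30 >= f20

    def test_histogram_mass_equals_valid_count(self):
        vals = np.array([0.0, 4.9, 5.1, -90.0, 90.0, np.nan])
        counts, edges = angle_histogram(vals, bin_width=5.0)
        assert counts.sum() == 5
        assert len(counts) == 36


class TestAHASegmentation:
    def test_partition_and_septal_side(self, clean_shell_study):
        s = clean_shell_study
        res = s.result
        aha = res.aha
        lv = np.isin(s.mask, (1, 2))
        labels = aha[lv]
        assert set(np.unique(labels)) <= set(range(17))
        # every LV voxel gets exactly one segment or the excluded flag
        assert (labels >= 0).all()
        assert (aha[~lv] == 0).all()
        # septal segments face the RV anchor
        vs = s.result.voxel_size_um
        g = res.geometry
        rv_centroid = np.argwhere(s.mask == 3).mean(axis=0) * vs
        anchor = rv_centroid - g.centre
        anchor -= g.long_axis * (anchor @ g.long_axis)
        anchor /= np.linalg.norm(anchor)
        for seg in AHA_SEPTAL_SEGMENTS:
            pts = np.argwhere(aha == seg) * vs - g.centre
            pts -= np.outer(pts @ g.long_axis, g.long_axis)
            assert pts.mean(axis=0) @ anchor > 0, f"segment {seg}"

    def test_all_16_segments_present(self, clean_shell_study):
        aha = clean_shell_study.result.aha
        present = set(np.unique(aha)) - {0}
        assert present == set(range(1, 17))

    def test_segment_summary_has_16_rows(self, clean_shell_study):
        df = clean_shell_study.result.aha_summary
        assert len(df) == 16

    def test_missing_rv_needs_anchor(self, clean_shell_study):
        s = clean_shell_study
        mask_no_rv = np.where(s.mask == 3, 0, s.mask)
        with pytest.raises(ValueError, match="anchor"):
            ma.aha_segmentation(mask_no_rv, s.result.geometry, 2.0)
        out = ma.aha_segmentation(mask_no_rv, s.result.geometry, 2.0,
                                  anchor=np.array([1.0, 0.0, 0.0]))
        assert (out > 0).any()


class TestSummaries:
    def test_degenerate_region_statistics(self):
        shape = (6, 6, 6)
        ha = np.zeros(shape)
        ia = np.zeros(shape)
        df = ma.summarize_regions({"all": np.ones(shape, bool)}, ha, ia)
        row = df.iloc[0]
        assert row["n_voxels"] == 216
        assert row["frac_circ"] == 1.0

    def test_order_independence(self):
        rng = np.random.default_rng(8)
        shape = (8, 8, 8)
        ha = rng.uniform(-90, 90, shape)
        ia = rng.uniform(-90, 90, shape)
        a = np.zeros(shape, bool)
        b = np.zeros(shape, bool)
        a[:4] = True
        b[4:] = True
        d1 = ma.summarize_regions({"a": a, "b": b}, ha, ia)
        d2 = ma.summarize_regions({"b": b, "a": a}, ha, ia)
        m1 = d1.set_index("region").sort_index()
        m2 = d2.set_index("region").sort_index()
        pd.testing.assert_frame_equal(m1, m2)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            ma.summarize_regions({"r": np.ones((4, 4, 4), bool)},
                                 np.zeros((5, 5, 5)), np.zeros((5, 5, 5)))

    def test_pipeline_fractions_match_truth_counts(self, slab_study):
        """Estimated-angle classification fractions agree with brute-force
        threshold counts on the ground-truth angles (uniform-field slab,
        where the pointwise truth comparison is well posed)."""
        from myoarch.geometry import angles_from_axes
        s = slab_study
        v = s.orient.valid
        n = int(v.sum())
        # trivial slab frame: c = +x, l = +y, r = +z
        c = np.broadcast_to([1.0, 0, 0], (n, 3))
        l_ = np.broadcast_to([0, 1.0, 0], (n, 3))
        r = np.broadcast_to([0, 0, 1.0], (n, 3))
        ha, ia = angles_from_axes(s.orient.v3[v].astype(float), r, c, l_)
        est = classify_angles(ha, ia)
        tru_ha = s.truth.ha[v]
        tru_ia = s.truth.ia[v]
        brute = {
            "frac_circ": np.mean(np.abs(tru_ha) <= 20),
            "frac_long_pos": np.mean(tru_ha > 20),
            "frac_long_neg": np.mean(tru_ha < -20),
            "frac_IA_le15": np.mean(np.abs(tru_ia) <= 15),
            "frac_IA_15_45": np.mean((np.abs(tru_ia) > 15)
                                     & (np.abs(tru_ia) <= 45)),
            "frac_IA_gt45": np.mean(np.abs(tru_ia) > 45),
        }
        for key, val in brute.items():
            assert abs(est[key] - val) <= 0.02, key
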