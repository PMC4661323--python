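"""Resampling, displacement warps, alpha calibration and the g map."""

import numpy as np
import pytest

from gratio.gratio_map import (
    CalibrationRecord,
    DisplacementField,
    apply_displacement,
    calibrate_alpha,
    compute_g_map,
    resample_to_grid,
)
from gratio.pipeline import process_subject
from gratio.synthetic_data import PhantomSpec, generate_cohort, make_reference_roi


def centered_affine(shape, voxel):
    aff = np.diag([voxel, voxel, voxel, 1.0])
    aff[:3, 3] = -voxel * (np.asarray(shape, float) - 1) / 2
    return aff


class TestResample:
    def test_identical_grids_bit_identical(self):
        vol = np.random.default_rng(0).normal(size=(5, 5, 5))
        aff = centered_affine((5, 5, 5), 1.0)
        out = resample_to_grid(vol, aff, (5, 5, 5), aff)
        assert np.array_equal(out, vol)

    def test_constant_volume_stays_constant(self):
        src_aff = centered_affine((20, 20, 20), 0.8)
        tgt_aff = centered_affine((7, 7, 7), 2.3)
        out = resample_to_grid(np.full((20, 20, 20), 3.3), src_aff, (7, 7, 7), tgt_aff)
        interior = np.isfinite(out)
        assert interior.any()
        assert np.allclose(out[interior], 3.3, atol=1e-12)

    def test_downsampled_linear_ramp_is_exact(self):
        """Trilinear interpolation reproduces a world-linear field exactly."""
        src_shape, tgt_shape = (30, 30, 30), (10, 10, 10)
        src_aff = centered_affine(src_shape, 0.8)
        tgt_aff = centered_affine(tgt_shape, 2.3)
        ii, jj, kk = np.meshgrid(*(np.arange(n) for n in src_shape), indexing="ij")
        world_y = src_aff[1, 1] * jj + src_aff[1, 3]
        out = resample_to_grid(world_y, src_aff, tgt_shape, tgt_aff)
        jj_t = np.meshgrid(*(np.arange(n) for n in tgt_shape), indexing="ij")[1]
        expect = tgt_aff[1, 1] * jj_t + tgt_aff[1, 3]
        ok = np.isfinite(out)
        assert ok.any()
        assert np.allclose(out[ok], expect[ok], atol=1e-9)

    def test_singular_affine_rejected(self):
        bad = np.eye(4)
        bad[0, 0] = 0.0
        with pytest.raises(ValueError, match="singular"):
            resample_to_grid(np.ones((3, 3, 3)), bad, (3, 3, 3), np.eye(4))

    def test_nearest_neighbor_mode(self):
        vol = np.arange(27, dtype=float).reshape(3, 3, 3)
        aff = np.eye(4)
        out = resample_to_grid(vol, aff, (3, 3, 3), aff, method="nearest")
        assert np.array_equal(out, vol)


class TestDisplacement:
    def test_zero_field_identity(self):
        vol = np.random.default_rng(1).normal(size=(8, 8, 8))
        disp = DisplacementField(field=np.zeros((8, 8, 8)), axis=1)
        assert np.allclose(apply_displacement(vol, disp), vol, atol=1e-12)

    def test_two_voxel_shift_moves_ridge(self):
        vol = np.zeros((5, 11, 5))
        vol[:, 5, :] = 1.0
        disp = DisplacementField(field=np.full(vol.shape, 2.0), axis=1, voxel_size=1.0)
        out = apply_displacement(vol, disp)
        assert np.allclose(out[:, 3, :], 1.0)  # pull-back: out[y] = vol[y + 2]
        assert np.allclose(out[:, 5, :], 0.0)

    def test_warp_then_invert_recovers_smooth_phantom(self):
        y = np.arange(24, dtype=float)
        vol = np.broadcast_to(np.sin(2 * np.pi * y / 24)[None, :, None], (6, 24, 6)).copy()
        field = 1.0 * np.exp(-((y - 12.0) ** 2) / 30.0)
        disp = DisplacementField(
            field=np.broadcast_to(field[None, :, None], vol.shape).copy(), axis=1
        )
        round_trip = apply_displacement(apply_displacement(vol, disp), disp, invert=True)
        core = np.s_[:, 4:20, :]
        assert np.max(np.abs(round_trip[core] - vol[core])) < 0.05

    def test_displacement_exceeding_fov_rejected(self):
        disp = DisplacementField(field=np.full((4, 4, 4), 10.0), axis=1)
        with pytest.raises(ValueError, match="field of view"):
            apply_displacement(np.zeros((4, 4, 4)), disp)


class TestCalibrateAlpha:
    def test_constant_ratio_closed_form(self):
        """A uniform MT/density = 5.1 pins alpha at (1 - 0.49)/5.1 = 0.1."""
        mt = np.full((4, 4, 4), 5.1)
        density = np.ones((4, 4, 4))
        roi = np.zeros((4, 4, 4), bool)
        roi[1:3, 1:3, 1:3] = True
        rec = calibrate_alpha(mt, density, roi, g_reference=0.7)
        assert rec.alpha == pytest.approx(0.1, abs=1e-9)
        assert rec.achieved == pytest.approx(0.7, abs=1e-9)

    def test_reference_of_one_gives_zero(self):
        rec = calibrate_alpha(
            np.ones((2, 2, 2)), np.ones((2, 2, 2)), np.ones((2, 2, 2), bool), g_reference=1.0
        )
        assert rec.alpha == 0.0

    def test_heterogeneous_roi_matches_bisection_oracle(self):
        rng = np.random.default_rng(42)
        ratio = rng.uniform(4.8, 5.4, size=64)
        mt = ratio.reshape(4, 4, 4)
        density = np.ones((4, 4, 4))
        roi = np.ones((4, 4, 4), bool)
        rec = calibrate_alpha(mt, density, roi, g_reference=0.7)

        # independent interval-halving oracle
        lo, hi = 0.0, 1.0 / ratio.max()
        for _ in range(60):
            mid = (lo + hi) / 2
            if np.mean(np.sqrt(np.maximum(1 - mid * ratio, 0))) > 0.7:
                lo = mid
            else:
                hi = mid
        assert rec.alpha == pytest.approx((lo + hi) / 2, abs=1e-10)

    def test_ratio_of_means_mode(self):
        mt = np.full((3, 3, 3), 4.0)
        density = np.full((3, 3, 3), 2.0)
        rec = calibrate_alpha(mt, density, np.ones((3, 3, 3), bool), mode="ratio-of-means")
        assert rec.alpha == pytest.approx((1 - 0.49) * 2.0 / 4.0, rel=1e-12)

    def test_invalid_roi_voxels_excluded_with_warning(self):
        mt = np.full((3, 3, 3), 5.1)
        mt[0, 0, 0] = np.nan
        with pytest.warns(UserWarning, match="excluding"):
            rec = calibrate_alpha(mt, np.ones((3, 3, 3)), np.ones((3, 3, 3), bool))
        assert rec.n_roi_voxels == 26

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="ROI"):
            calibrate_alpha(np.ones((2, 2, 2)), np.ones((2, 2, 2)), np.zeros((2, 2, 2), bool))


class TestComputeGMap:
    def test_reference_arithmetic(self):
        rec = CalibrationRecord(alpha=0.1, reference_roi="toy")
        res = compute_g_map(np.full((2, 2, 2), 5.1), np.ones((2, 2, 2)), rec)
        assert np.allclose(res.g_map, 0.7, atol=1e-12)
        assert res.validity_mask.all()

    def test_zero_mt_gives_unity(self):
        rec = CalibrationRecord(alpha=0.1, reference_roi="toy")
        res = compute_g_map(np.zeros((2, 2, 2)), np.ones((2, 2, 2)), rec)
        assert np.allclose(res.g_map, 1.0)

    def test_negative_radicand_masked_not_clipped(self):
        rec = CalibrationRecord(alpha=0.1, reference_roi="toy")
        mt = np.array([[[12.0, 5.1]]])  # 0.1*12/1 = 1.2 > 1
        res = compute_g_map(mt, np.ones((1, 1, 2)), rec)
        assert not res.validity_mask[0, 0, 0]
        assert np.isnan(res.g_map[0, 0, 0])
        assert res.validity_mask[0, 0, 1]

    def test_monotonicity(self):
        rec = CalibrationRecord(alpha=0.1, reference_roi="toy")
        mt = np.linspace(0.5, 5.0, 8).reshape(2, 2, 2)
        g1 = compute_g_map(mt, np.ones_like(mt), rec).g_map
        g2 = compute_g_map(mt + 0.5, np.ones_like(mt), rec).g_map
        assert np.all(g2 < g1)
        g3 = compute_g_map(mt, np.full_like(mt, 1.3), rec).g_map
        assert np.all(g3 > g1)

    def test_density_scale_absorbed_by_recalibration(self):
        """Multiplying density by c and recalibrating leaves g unchanged."""
        rng = np.random.default_rng(3)
        mt = rng.uniform(1.5, 2.5, (4, 4, 4))
        density = rng.uniform(0.8, 1.2, (4, 4, 4))
        roi = np.zeros((4, 4, 4), bool)
        roi[1:3, 1:3, 1:3] = True
        rec1 = calibrate_alpha(mt, density, roi)
        g1 = compute_g_map(mt, density, rec1).g_map
        c = 2.7
        rec2 = calibrate_alpha(mt, c * density, roi)
        g2 = compute_g_map(mt, c * density, rec2).g_map
        assert rec2.alpha == pytest.approx(rec1.alpha * c, rel=1e-8)
        assert np.allclose(g1, g2, atol=1e-9)

    def test_grid_mismatch_rejected(self):
        rec = CalibrationRecord(alpha=0.1, reference_roi="toy")
        with pytest.raises(ValueError, match="grid"):
            compute_g_map(np.ones((2, 2, 2)), np.ones((3, 3, 3)), rec)


class TestEndToEnd:
    def test_noiseless_subject_recovery(self, noiseless_subject, noiseless_maps):
        """Calibrated g equals ground truth wherever the forward models are exact."""
        roi = make_reference_roi(noiseless_subject)
        rec = calibrate_alpha(noiseless_maps.mt_dmri, noiseless_maps.density, roi)
        res = compute_g_map(noiseless_maps.mt_dmri, noiseless_maps.density, rec)
        wm = noiseless_subject.wm_mask
        err = np.abs(res.g_map - noiseless_subject.truth["g"])[wm]
        assert np.nanmax(err) < 1e-6
        assert res.validity_mask[wm].all()

    def test_uncorrected_distortion_biases_edges_then_corrects(self):
        """A 2-voxel phase-encode shift produces invalid / g~1 voxels at
        structure edges; the first-order inverse removes >= 90% of them."""
        spec = PhantomSpec(
            n_subjects=1, seed=3, dmri_shape=(24, 24, 24), mpm_voxel=1.15,
            subject_sd_g=0.0, subject_sd_fvf=0.0, mpm_snr=np.inf, dmri_snr=np.inf,
            displacement_mm=4.6,
        )
        sub = generate_cohort(spec)[0]
        res = process_subject(sub)
        roi = make_reference_roi(sub)
        wm = sub.wm_mask

        def n_bad(density):
            rec = calibrate_alpha(res.mt_dmri, density, roi)
            g = compute_g_map(res.mt_dmri, density, rec)
            return int((((~g.validity_mask) | (g.g_map > 0.98)) & wm).sum())

        uncorrected = n_bad(res.density.density)
        corrected_density = apply_displacement(res.density.density, sub.displacement, invert=True)
        corrected = n_bad(corrected_density)
        assert uncorrected >= 10
        assert corrected <= 0.1 * uncorrected
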