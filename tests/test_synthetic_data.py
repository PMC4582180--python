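"""Generators: closed-form curves, PDE stacks, dye images, group tables."""

import numpy as np
import pytest

import sjtools as sj
from sjtools.synthetic_data import FrapSimParams, FrapStackGeometry, DyeSimParams


class TestRecoveryCurve:
    def test_bleach_depth_origin_and_closed_form_point(self):
        curve, _ = sj.simulate_recovery_curve(FrapSimParams(tau_d=120, f_m=0.5))
        assert curve.post_values[0] == 0.0
        # t = 3 tau_D recovers exactly half the mobile fraction
        at_360 = curve.values[np.where(curve.times == 360.0)][0]
        assert at_360 == pytest.approx(0.25, abs=1e-12)

    @pytest.mark.parametrize("tau_d,f_m", [(33.0, 0.40), (270.0, 0.43), (1770.0, 0.29)])
    def test_zero_noise_curve_equals_model_everywhere(self, tau_d, f_m):
        curve, _ = sj.simulate_recovery_curve(FrapSimParams(tau_d=tau_d, f_m=f_m))
        t, r = curve.recovery()
        np.testing.assert_allclose(r, sj.recovery_model(t, tau_d, f_m), atol=1e-14)
        np.testing.assert_allclose(curve.prebleach_values, 1.0, atol=1e-14)

    def test_fading_multiplies_all_samples(self):
        lam = 0.003
        faded, truth = sj.simulate_recovery_curve(
            FrapSimParams(tau_d=120, f_m=0.5, fade_rate=lam)
        )
        clean, _ = sj.simulate_recovery_curve(FrapSimParams(tau_d=120, f_m=0.5))
        t_acq = faded.times - faded.times[0]
        np.testing.assert_allclose(faded.values, clean.values * np.exp(-lam * t_acq), atol=1e-14)
        # unbleached reference carries the same fade so correction is testable
        np.testing.assert_allclose(truth.extras["reference"], np.exp(-lam * t_acq), atol=1e-14)

    def test_integer_typed_parameters_are_coerced(self):
        # curve values must stay float even for all-int inputs
        curve, _ = sj.simulate_recovery_curve(
            FrapSimParams(tau_d=270, f_m=0.43, frame_interval=30, n_frames=21)
        )
        assert curve.values.dtype == float
        assert curve.values[-1] == pytest.approx(sj.recovery_model(600.0, 270.0, 0.43))

    def test_same_seed_bitwise_reproducible(self):
        p = dict(tau_d=120, f_m=0.5, noise_sd=0.05, seed=11)
        c1, _ = sj.simulate_recovery_curve(FrapSimParams(**p))
        c2, _ = sj.simulate_recovery_curve(FrapSimParams(**p))
        assert np.array_equal(c1.values, c2.values)

    @pytest.mark.parametrize(
        "kw",
        [
            {"tau_d": -1, "f_m": 0.5},
            {"tau_d": 120, "f_m": 1.5},
            {"tau_d": 120, "f_m": 0.5, "noise_sd": -0.1},
            {"tau_d": 120, "f_m": 0.5, "n_prebleach": 0},
            {"tau_d": 120, "f_m": 0.5, "frame_interval": 0.0},
        ],
    )
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            FrapSimParams(**kw)


class TestFrapStack:
    def test_frozen_membrane_stays_at_postbleach_value(self):
        # no diffusion, no noise, no drift: bleached profile is static
        p = FrapSimParams(tau_d=np.inf, f_m=0.5, n_frames=6)
        stack, truth = sj.simulate_frap_stack(p, FrapStackGeometry(shape=(32, 120), membrane_row=16, col_range=(5, 115)))
        post = stack.data[stack.bleach_frame:]
        for frame in post[1:]:
            np.testing.assert_allclose(frame, post[0], atol=1e-9)
        assert np.all(truth.roi_means[stack.bleach_frame:] == truth.roi_means[stack.bleach_frame])

    def test_drift_ground_truth_by_construction(self):
        p = FrapSimParams(tau_d=120, f_m=0.5, n_frames=9, drift_per_frame=(1.0, 0.0))
        _, truth = sj.simulate_frap_stack(p, FrapStackGeometry(shape=(96, 200), membrane_row=48, col_range=(10, 190)))
        np.testing.assert_array_equal(truth.shifts[:, 0], np.arange(len(truth.shifts)))
        np.testing.assert_array_equal(truth.shifts[:, 1], 0.0)

    def test_pde_readout_matches_closed_form(self):
        p = FrapSimParams(tau_d=132.0, f_m=0.65)
        _, truth = sj.simulate_frap_stack(p, FrapStackGeometry())
        t = p.times()
        post = t >= 0
        f0 = truth.roi_means[post][0]
        r = (truth.roi_means[post] - f0) / (1 - f0)
        sup = np.max(np.abs(r - sj.recovery_model(t[post], 132.0, 0.65)))
        assert sup < 0.02

    def test_pde_convergence_under_refinement(self):
        # spatial refinement reduces the deviation from the analytic solution
        devs = []
        for px in (0.4, 0.2, 0.1):
            p = FrapSimParams(tau_d=60.0, f_m=1.0, pixel_size=px, n_frames=11)
            n_cols = int(36 / px)
            geo = FrapStackGeometry(shape=(16, n_cols + 10), membrane_row=8,
                                    col_range=(5, 5 + n_cols), texture_amplitude=0.0)
            _, truth = sj.simulate_frap_stack(p, geo)
            t = p.times()
            post = t >= 0
            f0 = truth.roi_means[post][0]
            r = (truth.roi_means[post] - f0) / (1 - f0)
            devs.append(np.max(np.abs(r - sj.recovery_model(t[post], 60.0, 1.0))))
        assert devs[2] < devs[0]

    def test_geometry_outside_frame_rejected(self):
        with pytest.raises(ValueError):
            sj.simulate_frap_stack(
                FrapSimParams(tau_d=120, f_m=0.5),
                FrapStackGeometry(shape=(32, 100), membrane_row=40, col_range=(5, 95)),
            )

    def test_stack_bitwise_reproducible(self):
        geo = FrapStackGeometry(shape=(32, 120), membrane_row=16, col_range=(5, 115))
        mk = lambda: sj.simulate_frap_stack(
            FrapSimParams(tau_d=120, f_m=0.5, noise_sd=0.02, n_frames=5, seed=3), geo
        )[0].data
        assert np.array_equal(mk(), mk())


class TestDyeImage:
    def test_ground_truth_mean_with_saturated_blob(self):
        roi = sj.RoiSpec(rect=(20, 60, 20, 60))
        blob = sj.RoiSpec(rect=(30, 48, 30, 48))  # ~20% of ROI
        img, truth = sj.simulate_dye_image(
            DyeSimParams(cord_roi=roi, cord_mean=60.0, saturated=[blob])
        )
        assert truth.roi_means[0] == 60.0
        assert np.all(img[blob.mask(img.shape)] == 255)

    def test_no_saturation_means_plain_roi_mean(self):
        roi = sj.RoiSpec(rect=(20, 60, 20, 60))
        img, truth = sj.simulate_dye_image(DyeSimParams(cord_roi=roi, cord_mean=77.0))
        assert truth.roi_means[0] == pytest.approx(img[roi.mask(img.shape)].mean())

    def test_noisy_ground_truth_equals_pixelwise_oracle(self):
        roi = sj.RoiSpec(rect=(20, 60, 20, 60))
        blob = sj.RoiSpec(rect=(30, 40, 30, 40))
        img, truth = sj.simulate_dye_image(
            DyeSimParams(cord_roi=roi, cord_mean=60.0, saturated=[blob], noise_sd=2.0, seed=5)
        )
        keep = roi.mask(img.shape) & (img < 255)
        assert truth.roi_means[0] == pytest.approx(img[keep].mean(), abs=1e-12)

    def test_cord_mean_must_stay_below_saturation(self):
        with pytest.raises(ValueError):
            DyeSimParams(cord_mean=255.0, bit_depth=8)


class TestGroupMeasurements:
    def test_determinism_and_labels(self):
        t1 = sj.simulate_group_measurements([0, 1], sd=1.0, n_per_group=5, seed=9)
        t2 = sj.simulate_group_measurements([0, 1], sd=1.0, n_per_group=5, seed=9)
        assert t1.equals(t2)
        assert list(t1["group"].unique()) == ["group0", "group1"]

    def test_strong_separation_gives_tiny_anova_p(self):
        table = sj.simulate_group_measurements([0.0, 5.0], sd=0.1, n_per_group=8, seed=1)
        assert sj.anova_oneway(table).p < 1e-10

    def test_too_few_per_group_rejected(self):
        with pytest.raises(ValueError):
            sj.simulate_group_measurements([0, 1], sd=1.0, n_per_group=1)
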