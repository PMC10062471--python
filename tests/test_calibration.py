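"""Two-stage calibration: segment extraction, downsampling, fits, application."""

import dataclasses

import numpy as np
import pytest

from insolegrf import calibration as cb
from insolegrf import pipeline, processing, synthetic
from insolegrf.timeseries import SampledSignal, uniform


def processed_cal_pair(trial, config):
    """(fp_force, aligned resistance) as the pipeline prepares them."""
    fp = processing.butterworth_lowpass(trial.fp_force, config.fp_cutoff_hz,
                                        config.fp_order)
    res = processing.resample_uniform(trial.ips_resistance, 2000.0)
    res = processing.binomial_filter(res, config.ips_binomial_n)
    v = np.interp(fp.t, res.t, res.values)
    return fp, SampledSignal(t=fp.t, values=v, unit="ohm", nominal_rate=2000.0)


class TestExtractLoadingPhases:
    def test_three_step_trial_gives_three_segments(self, subject_clean, config):
        trial = synthetic.generate_calibration_trial(subject_clean, "hind",
                                                     seed=4, noise=False)
        fp, res = processed_cal_pair(trial, config)
        segs = cb.extract_loading_phases(fp, res, subject_clean.body_weight)
        assert len(segs) == 3

    def test_segments_end_at_step_maximum(self, subject_clean, config):
        trial = synthetic.generate_calibration_trial(subject_clean, "hind",
                                                     seed=4, noise=False)
        fp, res = processed_cal_pair(trial, config)
        for r_seg, f_seg in cb.extract_loading_phases(fp, res,
                                                      subject_clean.body_weight):
            assert f_seg[-1] == pytest.approx(f_seg.max())
            assert f_seg[-1] == pytest.approx(subject_clean.body_weight, rel=1e-3)
            # loading phase: resistance falls as force rises
            assert r_seg[0] > r_seg[-1]

    def test_too_few_steps_reported(self, subject_clean, config):
        trial = synthetic.generate_calibration_trial(subject_clean, "hind",
                                                     seed=4, noise=False,
                                                     n_steps=2)
        fp, res = processed_cal_pair(trial, config)
        with pytest.raises(ValueError, match="found 2"):
            cb.extract_loading_phases(fp, res, subject_clean.body_weight,
                                      n_steps=3)


class TestUniformResistanceDownsample:
    def test_1500_ohm_span_gives_11_grid_points(self):
        r = np.linspace(2000.0, 500.0, 100)
        f = np.linspace(0.0, 700.0, 100)
        grid, fg = cb.uniform_resistance_downsample(r, f, step=150.0)
        assert len(grid) == 11
        np.testing.assert_allclose(np.diff(grid), -150.0, atol=1e-9)

    def test_linear_relation_interpolated_exactly(self):
        r = np.linspace(3000.0, 1000.0, 50)
        f = 0.5 * (3000.0 - r)  # exactly linear in R
        grid, fg = cb.uniform_resistance_downsample(r, f)
        np.testing.assert_allclose(fg, 0.5 * (3000.0 - grid), atol=1e-9)

    def test_small_span_falls_back_with_warning(self):
        r = np.array([2000.0, 1950.0])
        f = np.array([0.0, 10.0])
        with pytest.warns(UserWarning, match="span"):
            grid, fg = cb.uniform_resistance_downsample(r, f)
        assert len(grid) == 2


class TestFitSensorPolynomial:
    def test_exact_quadratic_recovered(self):
        g = np.linspace(1e-4, 5e-3, 40)
        f = 2.0 + 3.0 * g + 4.0 * g ** 2
        cal = cb.fit_sensor_polynomial(1.0 / g, f)
        assert cal.a0 == pytest.approx(2.0, rel=1e-6)
        assert cal.a1 == pytest.approx(3.0, rel=1e-6)
        assert cal.a2 == pytest.approx(4.0, rel=1e-6)
        assert cal.fit_r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_force_degenerates_to_nan_r2(self):
        r = np.linspace(2000.0, 500.0, 20)
        with pytest.warns(UserWarning, match="degenerate"):
            cal = cb.fit_sensor_polynomial(r, np.zeros(20))
        assert np.isnan(cal.fit_r2)
        assert abs(cal.a0) < 1e-6 and abs(cal.a1) < 1e-6

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            cb.fit_sensor_polynomial(np.array([100.0, 100.0, 200.0]),
                                     np.array([1.0, 1.0, 2.0]))

    def test_noiseless_pipeline_fit_is_tight(self, sensor_cals_clean):
        for cal in sensor_cals_clean.values():
            assert cal.fit_r2 >= 0.99

    def test_noisy_pipeline_fit_still_strong(self, sensor_cals):
        for cal in sensor_cals.values():
            assert cal.fit_r2 >= 0.95


class TestApplySensorCalibration:
    def test_constant_resistance_gives_constant_force(self, sensor_cals):
        cal = sensor_cals["hind"]
        sig = uniform(np.full(10, 800.0), 10, "ohm")
        force, extra = cb.apply_sensor_calibration(sig, cal)
        assert np.ptp(force.values) == 0.0
        assert force.unit == "N"
        assert not extra.any()

    def test_noiseless_round_trip_within_2_percent_bw(
            self, subject_clean, sensor_cals_clean):
        for region in ("hind", "fore"):
            cal = sensor_cals_clean[region]
            sensor = subject_clean.sensor(region)
            cov = subject_clean.coverage(region)
            truth = np.linspace(0.0, subject_clean.body_weight, 200)
            r = sensor.resistance(truth * cov)
            fhat, _ = cb.apply_sensor_calibration(
                uniform(r[::-1], 10, "ohm"), cal)
            err = np.abs(fhat.values[::-1] - truth).max()
            assert err <= 0.02 * subject_clean.body_weight

    def test_unloaded_resistance_maps_near_zero_force(self, subject_clean,
                                                      sensor_cals_clean):
        cal = sensor_cals_clean["hind"]
        sig = uniform(np.full(5, cal.r_max_ohm), 10, "ohm")
        force, _ = cb.apply_sensor_calibration(sig, cal)
        assert abs(force.values[0]) <= 0.03 * subject_clean.body_weight

    def test_extrapolation_flagged_outside_fitted_range(self, sensor_cals):
        cal = sensor_cals["hind"]
        sig = uniform(np.array([cal.r_min_ohm * 0.5, cal.r_min_ohm * 1.5]),
                      10, "ohm")
        _, extra = cb.apply_sensor_calibration(sig, cal)
        assert extra.tolist() == [True, False]

    def test_non_positive_resistance_rejected(self, sensor_cals):
        sig = SampledSignal(t=[0.0, 0.1], values=[100.0, -5.0], unit="ohm")
        with pytest.raises(ValueError, match="positive"):
            cb.apply_sensor_calibration(sig, sensor_cals["hind"])

    def test_cross_subject_application_rejected(self, sensor_cals):
        sig = uniform(np.full(5, 800.0), 10, "ohm")
        with pytest.raises(ValueError, match="refusing"):
            cb.apply_sensor_calibration(sig, sensor_cals["hind"],
                                        subject_id="SOMEONE_ELSE")


class TestFitTotalForce:
    def test_exact_coefficients_recovered(self):
        rng = np.random.default_rng(0)
        h = rng.uniform(100, 700, 30)
        f = rng.uniform(100, 700, 30)
        cal = cb.fit_total_force(1.2 * h + 0.9 * f, h, f)
        assert cal.c_hind == pytest.approx(1.2, abs=1e-9)
        assert cal.c_fore == pytest.approx(0.9, abs=1e-9)

    def test_plain_sum_gives_unit_coefficients(self):
        h = np.array([100.0, 300.0, 50.0, 600.0])
        f = np.array([400.0, 100.0, 500.0, 80.0])
        cal = cb.fit_total_force(h + f, h, f)
        assert cal.c_hind == pytest.approx(1.0) and cal.c_fore == pytest.approx(1.0)

    def test_collinear_design_rejected(self):
        h = np.array([100.0, 200.0, 300.0])
        with pytest.raises(ValueError, match="collinear"):
            cb.fit_total_force(2 * h, h, 2.0 * h)

    def test_implausible_coefficients_warn(self):
        with pytest.warns(UserWarning, match="plausible"):
            cb.TotalForceCalibration(c_hind=5.0, c_fore=1.0)


class TestTotalAndMidfootForce:
    def make_pair(self, h, f):
        return (uniform(np.asarray(h, float), 10, "N"),
                uniform(np.asarray(f, float), 10, "N"))

    def test_unit_coefficients_give_plain_sum_and_zero_midfoot(self):
        h, f = self.make_pair([100.0, 0.0], [50.0, 0.0])
        cal = cb.TotalForceCalibration(c_hind=1.0, c_fore=1.0)
        np.testing.assert_allclose(cb.total_force(h, f, cal).values, [150.0, 0.0])
        np.testing.assert_allclose(cb.estimate_midfoot(h, f, cal).values, 0.0)

    def test_worked_midfoot_example(self):
        h, f = self.make_pair([100.0], [50.0])
        cal = cb.TotalForceCalibration(c_hind=1.5, c_fore=1.2)
        assert cb.estimate_midfoot(h, f, cal).values[0] == pytest.approx(60.0)

    def test_midfoot_closes_the_force_balance(self):
        rng = np.random.default_rng(1)
        h, f = self.make_pair(rng.uniform(0, 700, 40), rng.uniform(0, 700, 40))
        cal = cb.TotalForceCalibration(c_hind=1.31, c_fore=1.07)
        lhs = cb.estimate_midfoot(h, f, cal).values + h.values + f.values
        np.testing.assert_allclose(lhs, cb.total_force(h, f, cal).values,
                                   rtol=1e-12)

    def test_linearity_in_each_argument(self):
        h, f = self.make_pair([100.0, 200.0], [50.0, 75.0])
        cal = cb.TotalForceCalibration(c_hind=1.4, c_fore=0.8)
        doubled = cb.total_force(h.with_values(2 * h.values), f, cal).values
        np.testing.assert_allclose(
            doubled, 2 * cb.total_force(h, f, cal).values - cal.c_fore * f.values)

    def test_misaligned_inputs_rejected(self):
        h = uniform(np.zeros(5), 10, "N")
        f = uniform(np.zeros(5), 10, "N", t0=0.03)
        cal = cb.TotalForceCalibration(c_hind=1.0, c_fore=1.0)
        with pytest.raises(ValueError, match="grid"):
            cb.total_force(h, f, cal)


class TestParameterRecovery:
    def test_noiseless_recovery_of_generator_coefficients(self, subject_clean,
                                                          config):
        """With a light smoothing filter (isolating the calibration logic
        from bandwidth attenuation) the total-force fit recovers the
        generator's implied coefficient 1/(1 - midfoot share) within 5%."""
        cfg = dataclasses.replace(config, ips_binomial_n=100, noise=False)
        cals = {r: pipeline.process_calibration_trial(
            synthetic.generate_calibration_trial(subject_clean, r, seed=i + 2,
                                                 noise=False), cfg)
            for i, r in enumerate(("hind", "fore"))}
        procs = []
        for speed in (0.5, 1.0, 1.5):
            trial = synthetic.generate_walking_trial(
                subject_clean, speed, seed=21, noise=False, clock_offset=0.0,
                peak_cv=0.0, timing_cv=0.0)
            procs.append(pipeline.process_walking_trial(trial, cals, cfg))
        total = pipeline.fit_total_calibration(procs, cfg)
        truth = subject_clean.true_total_coefficient
        assert total.c_hind == pytest.approx(truth, rel=0.05)
        assert total.c_fore == pytest.approx(truth, rel=0.05)
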