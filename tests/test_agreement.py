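"""Peak extraction, Bland-Altman statistics, cross-validation machinery."""

import numpy as np
import pytest

from insolegrf import agreement as ag
from insolegrf.timeseries import uniform


def double_peak_cycle(pk1=110.0, pk2=105.0, t1_frac=0.25, t2_frac=0.75,
                      duration=1.0, rate=2000.0, valley=70.0):
    """Synthetic single-cycle force in %BW with peaks at given cycle fractions."""
    t = np.arange(int(duration * rate)) / rate
    u = t / duration
    f = valley * np.ones_like(u)
    for pk, c in ((pk1, t1_frac), (pk2, t2_frac)):
        lobe = np.abs(u - c) < 0.12
        f[lobe] += (pk - valley) * np.cos(np.pi * (u[lobe] - c) / 0.24) ** 2
    f[u < 0.05] *= u[u < 0.05] / 0.05  # ramp in from 0
    return uniform(f, rate, "%BW")


class TestExtract2pk:
    def test_fp_rule_finds_both_peaks(self):
        cyc = double_peak_cycle()
        pk = ag.extract_2pk(cyc, "fp")
        assert pk.pk1 == pytest.approx(110.0, abs=1e-6)
        assert pk.pk2 == pytest.approx(105.0, abs=1e-6)
        assert pk.t1 == pytest.approx(0.25, abs=1e-3)
        assert pk.t2 == pytest.approx(0.75, abs=1e-3)

    def test_fp_rule_splits_at_30_percent(self):
        # second peak inside the first 30%: rule reports the 30%-window max
        cyc = double_peak_cycle(t1_frac=0.10, t2_frac=0.40)
        pk = ag.extract_2pk(cyc, "fp")
        assert pk.t1 < 0.30 < pk.t2

    def test_ips_rule_takes_two_largest_wide_peaks(self):
        t = np.arange(2000) / 2000.0
        f = np.zeros_like(t)
        for height, c in ((110.0, 0.25), (105.0, 0.7), (60.0, 0.5)):
            lobe = np.abs(t - c) < 0.08
            f[lobe] += height * np.cos(np.pi * (t[lobe] - c) / 0.16) ** 2
        pk = ag.extract_2pk(uniform(f, 2000, "%BW"), "ips")
        assert pk.pk1 == pytest.approx(110.0, abs=0.5)
        assert pk.pk2 == pytest.approx(105.0, abs=0.5)

    def test_narrow_spike_excluded_by_width_rule(self):
        cyc = double_peak_cycle()
        f = cyc.values.copy()
        i = 1000
        f[i - 10:i + 10] += 150.0  # 0.01-s-wide spike, taller than both peaks
        pk = ag.extract_2pk(cyc.with_values(f), "ips")
        assert pk.pk1 == pytest.approx(110.0, abs=1.0)
        assert pk.pk2 == pytest.approx(105.0, abs=1.0)

    def test_ips_cycle_without_two_wide_peaks_returns_none(self):
        t = np.arange(2000) / 2000.0
        f = 100.0 * np.exp(-((t - 0.4) / 0.1) ** 2)  # single lobe
        assert ag.extract_2pk(uniform(f, 2000, "%BW"), "ips") is None

    def test_peak_order_is_temporal(self):
        # taller peak later in the cycle: pk1 must still be the earlier one
        t = np.arange(2000) / 2000.0
        f = np.zeros_like(t)
        for height, c in ((105.0, 0.25), (115.0, 0.7)):
            lobe = np.abs(t - c) < 0.08
            f[lobe] += height * np.cos(np.pi * (t[lobe] - c) / 0.16) ** 2
        pk = ag.extract_2pk(uniform(f, 2000, "%BW"), "ips")
        assert pk.pk1 == pytest.approx(105.0, abs=0.5)
        assert pk.t1 < pk.t2


class TestExtractMax:
    def test_constant_cycle(self):
        cyc = uniform(np.full(100, 80.0), 100, "%BW")
        assert ag.extract_max(cyc) == 80.0

    def test_equals_larger_of_the_two_peaks(self):
        cyc = double_peak_cycle()
        pk = ag.extract_2pk(cyc, "fp")
        assert ag.extract_max(cyc) == pytest.approx(max(pk.pk1, pk.pk2))

    def test_empty_cycle_rejected(self):
        with pytest.raises(ValueError):
            ag.extract_max(uniform(np.zeros(0), 100, "%BW"))


class TestBlandAltman:
    def test_identical_pairs_give_zero_bias_and_width(self):
        x = np.array([100.0, 105.0, 95.0, 110.0])
        ba = ag.bland_altman(x, x)
        assert ba.mod == 0.0 and ba.two_s == 0.0
        assert ba.loa_low == 0.0 and ba.loa_high == 0.0

    def test_hand_computed_small_sample(self):
        fp = np.array([100.0, 100.0, 100.0])
        ips = fp + np.array([-1.0, 0.0, 1.0])
        ba = ag.bland_altman(ips, fp)
        assert ba.mod == pytest.approx(0.0)
        assert ba.sd_diff == pytest.approx(1.0)
        assert ba.two_s == pytest.approx(1.96)
        assert ba.loa_low == pytest.approx(-1.96)
        assert ba.loa_high == pytest.approx(1.96)

    def test_monte_carlo_normal_differences(self):
        rng = np.random.default_rng(7)
        n = 10000
        fp = rng.uniform(40, 120, n)
        d = rng.normal(2.0, 5.0, n)
        ba = ag.bland_altman(fp + d, fp)
        se_mod = 5.0 / np.sqrt(n)
        se_two_s = 1.96 * 5.0 / np.sqrt(2 * (n - 1))
        assert abs(ba.mod - 2.0) <= 3 * se_mod
        assert abs(ba.two_s - 9.8) <= 3 * se_two_s

    def test_loa_multiplier_is_exact(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            fp = rng.uniform(0, 100, 50)
            ips = fp + rng.normal(0, 10, 50)
            ba = ag.bland_altman(ips, fp)
            assert ba.two_s == 1.96 * ba.sd_diff  # exact, not approx
            assert ba.loa_low == ba.mod - ba.two_s
            assert ba.loa_high == ba.mod + ba.two_s

    def test_known_bias_injection_shifts_mod_only(self):
        rng = np.random.default_rng(9)
        fp = rng.uniform(40, 120, 2000)
        ips = fp + rng.normal(0.0, 4.0, 2000)
        base = ag.bland_altman(ips, fp)
        shifted = ag.bland_altman(ips + 3.0, fp)
        assert shifted.mod - base.mod == pytest.approx(3.0, abs=1e-9)
        assert shifted.two_s == pytest.approx(base.two_s, rel=1e-9)

    def test_regression_of_bias_on_magnitude(self):
        rng = np.random.default_rng(10)
        fp = rng.uniform(40.0, 120.0, 5000)
        d = 0.30 * fp - 30.0 + rng.normal(0, 1.0, 5000)
        ba = ag.bland_altman(fp + d, fp)
        # abscissa is the pair mean = fp + d/2, so the fitted slope is
        # s' = s/(1+s/2); the noise enters both axes, so the residual SD
        # shrinks to sigma * (1 - s'/2)
        slope_expected = 0.30 / 1.15
        assert ba.slope == pytest.approx(slope_expected, abs=0.02)
        assert ba.resid_sd == pytest.approx(1.0 - slope_expected / 2, rel=0.05)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            ag.bland_altman(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestStratifiedSplits:
    def test_exactly_eight_distinct_splits(self):
        speeds = [0.5, 0.5, 1.0, 1.0, 1.5, 1.5]
        splits = ag.enumerate_stratified_splits(speeds)
        assert len(splits) == 8
        assert len({tuple(sorted(c)) for c, _ in splits}) == 8

    def test_each_fold_has_one_trial_per_speed(self):
        speeds = [0.5, 1.0, 1.5, 0.5, 1.0, 1.5]
        for cal, test in ag.enumerate_stratified_splits(speeds):
            assert sorted(speeds[i] for i in cal) == [0.5, 1.0, 1.5]
            assert sorted(speeds[i] for i in test) == [0.5, 1.0, 1.5]
            assert set(cal).isdisjoint(test)

    def test_missing_repetition_rejected(self):
        with pytest.raises(ValueError, match="exactly 2"):
            ag.enumerate_stratified_splits([0.5, 0.5, 1.0, 1.5, 1.5])


class TestCrossValidation:
    @staticmethod
    def fake_analysis(cal_trials, test_trials):
        rng = np.random.default_rng(sum(test_trials))
        fp = rng.uniform(80, 120, 20)
        ips = fp + rng.normal(1.0, 2.0, 20)
        ba = ag.bland_altman(ips, fp)
        return {"2PK": ba, "MAX": ba}

    def test_eight_iterations_and_summary(self):
        trials = list(range(6))
        speeds = [0.5, 0.5, 1.0, 1.0, 1.5, 1.5]
        cv = ag.stratified_two_fold_cv(trials, speeds, self.fake_analysis)
        assert cv.n_iterations == 8
        s = cv.summary("MAX")
        assert 0.0 < s["mod_mean"] < 2.5
        assert 0 <= cv.representative_subset < 8

    def test_deterministic_given_identical_inputs(self):
        trials = list(range(6))
        speeds = [0.5, 0.5, 1.0, 1.0, 1.5, 1.5]
        a = ag.stratified_two_fold_cv(trials, speeds, self.fake_analysis)
        b = ag.stratified_two_fold_cv(trials, speeds, self.fake_analysis)
        for ita, itb in zip(a.iterations, b.iterations):
            assert ita["MAX"].mod == itb["MAX"].mod


def _ba(mod, two_s):
    sd = two_s / 1.96
    return ag.BlandAltmanResult(
        mod=mod, sd_diff=sd, two_s=two_s, loa_low=mod - two_s,
        loa_high=mod + two_s, p_value_mod_vs_zero=1.0, n_pairs=10,
        slope=0.0, intercept=mod, resid_sd=sd)


class TestRepresentativeSubset:
    def cv_from(self, stats):
        its = tuple({"MAX": _ba(m, s)} for m, s in stats)
        return ag.CrossValidationResult(iterations=its,
                                        splits=tuple(((), ()) for _ in its))

    def test_all_identical_ties_to_first(self):
        cv = self.cv_from([(1.0, 10.0)] * 8)
        assert ag.select_representative_subset(cv) == 0

    def test_displaced_iteration_is_not_chosen(self):
        # mean MoD is (7*6 + 1)/8 = 5.375: the cluster near the mean must
        # win over the single iteration displaced by ~4.4 %BW
        stats = [(6.0, 10.0)] * 7 + [(1.0, 10.0)]
        cv = self.cv_from(stats)
        assert ag.select_representative_subset(cv) != 7

    def test_removing_the_selected_iteration_changes_selection(self):
        stats = [(0.0, 10.0), (1.0, 10.0), (2.0, 10.0), (5.0, 12.0)]
        cv = self.cv_from(stats)
        chosen = ag.select_representative_subset(cv)
        remaining = [s for i, s in enumerate(stats) if i != chosen]
        cv2 = self.cv_from(remaining)
        assert ag.select_representative_subset(cv2) != chosen

    def test_overlap_coefficient_monotone_in_displacement(self):
        base = ag._normal_overlap(0.0, 1.0, 0.0, 1.0)
        assert base == pytest.approx(1.0, abs=1e-9)
        prev = base
        for d in (0.5, 1.0, 2.0, 4.0):
            o = ag._normal_overlap(d, 1.0, 0.0, 1.0)
            assert o < prev
            prev = o

    def test_overlap_with_unequal_variances(self):
        # against a reference normal, overlap shrinks as the SD ratio grows
        o1 = ag._normal_overlap(0.0, 1.0, 0.0, 2.0)
        o2 = ag._normal_overlap(0.0, 1.0, 0.0, 4.0)
        assert 0 < o2 < o1 < 1
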