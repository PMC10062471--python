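"""End-to-end orchestration: simulate -> process -> calibrate -> analyze -> PWB.

Per-trial processing order: resample the insole record to the FP rate,
binomial-filter it, synchronize clocks on the stomp, convert resistance to
force with the per-sensor calibration, zero the unloaded baseline, clamp
swing-phase noise, then detect heel strikes in both instruments and pair
gait cycles.  Per subject, the secondary (total-force) calibration and the
Bland-Altman assessments run inside stratified two-fold cross-validation,
and the representative iteration's MAX error model drives the PWB
overload-detection simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement, calibration, events, processing, pwb, synthetic
from .io import RunConfig
from .timeseries import SampledSignal

ASSESSMENTS = ("2PK", "MAX")


# --------------------------------------------------------------------------
# per-trial processing
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ProcessedTrial:
    """A walking trial after filtering, synchronization and calibration."""

    subject: synthetic.SubjectModel
    speed: float
    rep: int
    fp_force: SampledSignal       # filtered resultant, N, FP grid
    hind_force: SampledSignal     # calibrated + zeroed + clamped, N, FP grid
    fore_force: SampledSignal
    hind_resistance: SampledSignal  # processed, FP grid, FP clock
    clock_offset: float
    paired_cycles: tuple          # ((fp_t0, fp_t1), (ips_t0, ips_t1)) per cycle
    fp_hs: np.ndarray
    ips_hs: np.ndarray
    n_dropped_cycles: int


def _align_to_grid(sig: SampledSignal, grid: SampledSignal,
                   shift: float = 0.0) -> SampledSignal:
    """Interpolate a signal onto another signal's time grid after a shift."""
    v = np.interp(grid.t, sig.t + shift, sig.values)
    return SampledSignal(t=grid.t, values=v, unit=sig.unit,
                         nominal_rate=grid.nominal_rate)


def _pair_cycles(fp_cycles, ips_cycles, max_offset_frac: float = 0.3):
    """Match cycles of the two instruments by nearest start time."""
    pairs = []
    ips_starts = np.array([c[0] for c in ips_cycles])
    if len(ips_starts) == 0:
        return pairs
    for fc in fp_cycles:
        dur = fc[1] - fc[0]
        j = int(np.argmin(np.abs(ips_starts - fc[0])))
        if abs(ips_starts[j] - fc[0]) <= max_offset_frac * dur:
            pairs.append((fc, ips_cycles[j]))
    return pairs


def _drop_stomp_events(times: np.ndarray, stomp_time: float,
                       guard_s: float = 1.0) -> np.ndarray:
    return times[np.abs(times - stomp_time) > guard_s]


def _drop_long_cycles(cycles):
    """Remove cycles much longer than the median (gaps, e.g. stomp-to-walk)."""
    if not cycles:
        return cycles
    durs = np.array([c[1] - c[0] for c in cycles])
    med = np.median(durs)
    return [c for c, d in zip(cycles, durs) if d <= 1.5 * med]


def process_walking_trial(
    trial: synthetic.WalkingTrial,
    sensor_cals: dict,
    config: RunConfig = RunConfig(),
    rep: int = 0,
) -> ProcessedTrial:
    """Run the full signal chain on one walking trial."""
    subject = trial.subject
    resultant = processing.resultant_force(trial.fp_fx, trial.fp_fy, trial.fp_fz)
    fp_force = processing.butterworth_lowpass(
        resultant, config.fp_cutoff_hz, config.fp_order,
        zero_phase=config.fp_zero_phase)

    # insole chain: resample -> binomial filter (still on the IPS clock)
    resampled, filtered = {}, {}
    for region, raw in (("hind", trial.ips_hind), ("fore", trial.ips_fore)):
        resampled[region] = processing.resample_uniform(raw, config.ips_resample_hz)
        filtered[region] = processing.binomial_filter(resampled[region],
                                                      config.ips_binomial_n)

    # synchronize on the *unfiltered* record: the heavy binomial filter
    # attenuates the narrow stomp dip far more than the wide stance dips
    offset = events.synchronize_stomp(resampled["hind"], fp_force,
                                      window_s=config.sync_window_s)

    region_force = {}
    region_res = {}
    for region in ("hind", "fore"):
        r_aligned = _align_to_grid(filtered[region], fp_force, shift=offset)
        region_res[region] = r_aligned
        unloaded = processing.detect_unloaded(r_aligned, config.ips_baseline_frac)
        force, _ = calibration.apply_sensor_calibration(
            r_aligned, sensor_cals[region], subject_id=subject.subject_id)
        force, _ = processing.zero_baseline(
            force, resistance=r_aligned, baseline_frac=config.ips_baseline_frac,
            trial_label=f"{subject.subject_id} speed={trial.speed}")
        region_force[region] = processing.clamp_swing(force, unloaded)

    # heel strikes in both instruments, stomp events removed
    stomp_t = events.stomp_event_time(fp_force, "force", config.sync_window_s)
    fp_hs = _drop_stomp_events(
        events.detect_hs_fp(fp_force, config.hs_threshold_n, config.hs_debounce_s),
        stomp_t)
    hind_res = region_res["hind"]
    baseline_r = float(np.mean(hind_res.values[
        processing.detect_unloaded(hind_res, config.ips_baseline_frac)]))
    ips_hs = _drop_stomp_events(
        events.detect_hs_ips(hind_res, baseline_r, config.ips_baseline_frac,
                             config.ips_min_dip_s),
        stomp_t)

    n_dropped = 0
    pairs = []
    if len(fp_hs) >= 2 and len(ips_hs) >= 2:
        fp_cycles = _drop_long_cycles(list(events.segment_cycles(fp_hs).cycles))
        ips_cycles = _drop_long_cycles(list(events.segment_cycles(ips_hs).cycles))
        pairs = _pair_cycles(fp_cycles, ips_cycles)
        n_dropped = max(len(fp_cycles), len(ips_cycles)) - len(pairs)

    return ProcessedTrial(
        subject=subject, speed=trial.speed, rep=rep,
        fp_force=fp_force, hind_force=region_force["hind"],
        fore_force=region_force["fore"], hind_resistance=hind_res,
        clock_offset=offset, paired_cycles=tuple(pairs),
        fp_hs=fp_hs, ips_hs=ips_hs, n_dropped_cycles=n_dropped)


def process_calibration_trial(
    trial: synthetic.CalibrationTrial,
    config: RunConfig = RunConfig(),
) -> calibration.SensorCalibration:
    """Stage-one sensor calibration from a raw calibration trial."""
    fp_force = processing.butterworth_lowpass(
        trial.fp_force, config.fp_cutoff_hz, config.fp_order,
        zero_phase=config.fp_zero_phase)
    res = processing.resample_uniform(trial.ips_resistance, config.ips_resample_hz)
    res = processing.binomial_filter(res, config.ips_binomial_n)
    res = _align_to_grid(res, fp_force)
    return calibration.calibrate_sensor(trial, fp_force, res,
                                        step=config.resistance_step_ohm)


# --------------------------------------------------------------------------
# peak extraction and assessment
# --------------------------------------------------------------------------

def peak_rows(proc: ProcessedTrial, config: RunConfig = RunConfig()) -> np.ndarray:
    """(F_fp, F_hind, F_fore) rows at the two FP peaks of each paired cycle,
    in newtons — the input to the total-force (secondary) calibration."""
    rows = []
    for (fp_cyc, _ips_cyc) in proc.paired_cycles:
        seg = proc.fp_force.crop(*fp_cyc)
        pk = agreement.extract_2pk(seg, "fp", cycle_start=fp_cyc[0],
                                   cycle_end=fp_cyc[1])
        if pk is None:
            continue
        for t_pk, f_pk in ((pk.t1, pk.pk1), (pk.t2, pk.pk2)):
            i = int(np.clip(np.searchsorted(proc.fp_force.t, t_pk),
                            0, len(proc.fp_force) - 1))
            rows.append((f_pk, proc.hind_force.values[i], proc.fore_force.values[i]))
    return np.asarray(rows, dtype=float)


def fit_total_calibration(procs, config: RunConfig = RunConfig()):
    """Pool peak rows over trials (all speeds) and fit Eq.-style scaling."""
    rows = [peak_rows(p, config) for p in procs]
    rows = np.vstack([r for r in rows if r.size])
    return calibration.fit_total_force(
        rows[:, 0], rows[:, 1], rows[:, 2],
        subject_id=procs[0].subject.subject_id)


def assessment_pairs(
    procs,
    total_cal,
    config: RunConfig = RunConfig(),
) -> dict:
    """Pooled (ips, fp) measurement pairs in %BW for each assessment."""
    out = {"2PK": ([], []), "MAX": ([], [])}
    for proc in procs:
        bw = proc.subject.body_weight
        ips_total = calibration.total_force(
            proc.hind_force, proc.fore_force, total_cal,
            subject_id=proc.subject.subject_id)
        ips_pbw = processing.normalize_bw(ips_total, bw)
        fp_pbw = processing.normalize_bw(proc.fp_force, bw)
        for (fp_cyc, ips_cyc) in proc.paired_cycles:
            fp_seg = fp_pbw.crop(*fp_cyc)
            ips_seg = ips_pbw.crop(*ips_cyc)
            if len(fp_seg) == 0 or len(ips_seg) == 0:
                continue
            out["MAX"][0].append(agreement.extract_max(ips_seg))
            out["MAX"][1].append(agreement.extract_max(fp_seg))
            fp_pk = agreement.extract_2pk(fp_seg, "fp", cycle_start=fp_cyc[0],
                                          cycle_end=fp_cyc[1])
            ips_pk = agreement.extract_2pk(
                ips_seg, "ips", min_width_s=config.ips_min_peak_width_s)
            if fp_pk is not None and ips_pk is not None:
                out["2PK"][0].extend([ips_pk.pk1, ips_pk.pk2])
                out["2PK"][1].extend([fp_pk.pk1, fp_pk.pk2])
    return {k: (np.asarray(v[0]), np.asarray(v[1])) for k, v in out.items()}


def _cv_analysis(config: RunConfig):
    """The analysis callback handed to the cross-validator: refit the
    total-force calibration on the calibration fold, Bland-Altman on the
    test fold."""
    def analyze(cal_procs, test_procs):
        total_cal = fit_total_calibration(cal_procs, config)
        pairs = assessment_pairs(test_procs, total_cal, config)
        return {name: agreement.bland_altman(ips, fp)
                for name, (ips, fp) in pairs.items()}
    return analyze


# --------------------------------------------------------------------------
# per-subject and cohort runs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectResult:
    subject: synthetic.SubjectModel
    sensor_cals: dict
    total_cal: calibration.TotalForceCalibration  # fitted on all six trials
    cv: agreement.CrossValidationResult
    pwb_mc: pwb.PWBResult
    pwb_analytic: pwb.PWBResult
    error_model: tuple  # (slope, intercept, resid_sd) driving the PWB run


def generate_subject_trials(subject, config: RunConfig, seed: int):
    """Two calibration trials and reps x speeds walking trials."""
    rng = np.random.default_rng(seed)
    cal_trials = {
        region: synthetic.generate_calibration_trial(
            subject, region, seed=int(rng.integers(2 ** 31)), noise=config.noise)
        for region in ("hind", "fore")
    }
    walking = []
    for speed in config.speeds:
        for rep in range(config.reps):
            walking.append((speed, rep, synthetic.generate_walking_trial(
                subject, speed, seed=int(rng.integers(2 ** 31)),
                duration=config.trial_duration_s, noise=config.noise,
                clock_offset=config.clock_offset_s)))
    return cal_trials, walking


def run_subject(subject, config: RunConfig, seed: int) -> SubjectResult:
    """The complete per-subject analysis."""
    cal_trials, walking = generate_subject_trials(subject, config, seed)
    sensor_cals = {region: process_calibration_trial(t, config)
                   for region, t in cal_trials.items()}
    procs = [process_walking_trial(t, sensor_cals, config, rep=rep)
             for (_speed, rep, t) in walking]
    speeds = [s for (s, _r, _t) in walking]

    cv = agreement.stratified_two_fold_cv(procs, speeds, _cv_analysis(config))
    total_cal = fit_total_calibration(procs, config)

    rep_ba = cv.iterations[cv.representative_subset]["MAX"]
    mc, analytic = pwb.pwb_from_agreement(
        rep_ba,
        mu_f=config.pwb_mu_pbw, sigma_f=config.pwb_sigma_pbw,
        limit=config.pwb_limit_pbw, n_draws=config.pwb_n_draws,
        seed=int(np.random.default_rng(seed + 1).integers(2 ** 31)))
    return SubjectResult(
        subject=subject, sensor_cals=sensor_cals, total_cal=total_cal, cv=cv,
        pwb_mc=mc, pwb_analytic=analytic,
        error_model=(rep_ba.slope, rep_ba.intercept, rep_ba.resid_sd))


@dataclass(frozen=True)
class PipelineResults:
    """Tidy tables summarizing a full cohort run."""

    subjects: pd.DataFrame
    sensor_calibrations: pd.DataFrame
    total_calibrations: pd.DataFrame
    cv_results: pd.DataFrame
    group_summary: pd.DataFrame
    pwb_results: pd.DataFrame
    config: RunConfig

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("subjects", "sensor_calibrations", "total_calibrations",
                     "cv_results", "group_summary", "pwb_results"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        (out / "run_log.json").write_text(json.dumps(
            {"config": self.config.to_dict()}, indent=1))


def run_pipeline(config: RunConfig = RunConfig()) -> PipelineResults:
    """Simulate the cohort and run every stage; deterministic in the seed."""
    rng = np.random.default_rng(config.seed)
    cohort = synthetic.generate_cohort(config.n_subjects,
                                       seed=int(rng.integers(2 ** 31)))
    results = [run_subject(s, config, seed=int(rng.integers(2 ** 31)))
               for s in cohort]

    subj_rows, cal_rows, tot_rows, cv_rows, pwb_rows = [], [], [], [], []
    for res in results:
        s = res.subject
        subj_rows.append({
            "subject": s.subject_id, "body_weight_n": s.body_weight,
            "foot_area_cm2": s.foot_area_cm2,
            "region_share_mid_truth": s.region_share_mid,
            "total_coeff_truth": s.true_total_coefficient,
        })
        for region, cal in res.sensor_cals.items():
            cal_rows.append({
                "subject": s.subject_id, "sensor": region,
                "a0": cal.a0, "a1": cal.a1, "a2": cal.a2, "r2": cal.fit_r2,
                "r_min_ohm": cal.r_min_ohm, "r_max_ohm": cal.r_max_ohm,
            })
        tot_rows.append({
            "subject": s.subject_id, "c_hind": res.total_cal.c_hind,
            "c_fore": res.total_cal.c_fore,
            "c_truth": s.true_total_coefficient,
            "n_rows": res.total_cal.n_rows,
        })
        for it, (ba_map, split) in enumerate(zip(res.cv.iterations, res.cv.splits)):
            for name in ASSESSMENTS:
                ba = ba_map[name]
                cv_rows.append({
                    "subject": s.subject_id, "assessment": name, "iteration": it,
                    "representative": it == res.cv.representative_subset,
                    "mod_pbw": ba.mod, "two_s_pbw": ba.two_s,
                    "p_value": ba.p_value_mod_vs_zero, "n_pairs": ba.n_pairs,
                    "slope": ba.slope, "intercept_pbw": ba.intercept,
                    "resid_sd_pbw": ba.resid_sd,
                    "foot_area_cm2": s.foot_area_cm2,
                })
        pwb_rows.append({
            "subject": s.subject_id,
            "sensitivity_mc": res.pwb_mc.sensitivity,
            "specificity_mc": res.pwb_mc.specificity,
            "sensitivity_analytic": res.pwb_analytic.sensitivity,
            "specificity_analytic": res.pwb_analytic.specificity,
            "slope": res.error_model[0], "intercept_pbw": res.error_model[1],
            "resid_sd_pbw": res.error_model[2],
        })

    cv_df = pd.DataFrame(cv_rows)
    group_rows = []
    for name in ASSESSMENTS:
        per_subject = (cv_df[cv_df.assessment == name]
                       .groupby("subject")[["mod_pbw", "two_s_pbw"]].mean())
        group_rows.append({
            "assessment": name,
            "mod_mean_pbw": per_subject.mod_pbw.mean(),
            "mod_sd_pbw": per_subject.mod_pbw.std(ddof=1),
            "two_s_mean_pbw": per_subject.two_s_pbw.mean(),
            "two_s_sd_pbw": per_subject.two_s_pbw.std(ddof=1),
            "n_subjects": len(per_subject),
        })

    return PipelineResults(
        subjects=pd.DataFrame(subj_rows),
        sensor_calibrations=pd.DataFrame(cal_rows),
        total_calibrations=pd.DataFrame(tot_rows),
        cv_results=cv_df,
        group_summary=pd.DataFrame(group_rows),
        pwb_results=pd.DataFrame(pwb_rows),
        config=config,
    )


# --------------------------------------------------------------------------
# identical-instruments self-consistency
# --------------------------------------------------------------------------

def identity_self_consistency(
    config: RunConfig | None = None,
    seed: int = 0,
) -> dict:
    """Feed the FP signal through the insole chain as both instruments.

    Generates noise-free, perfectly periodic walking trials for one
    default subject, replaces the insole channels with the FP resultant
    sampled at the insole timestamps (split into pseudo hind/fore regional
    signals), and runs resampling, filtering, total-force calibration,
    cycle pairing, peak extraction and Bland-Altman end to end.  The
    total-force calibration is fitted on one repetition and tested on the
    other *within each speed*: the binomial filter's waveform-bandwidth-
    dependent attenuation gives each speed its own (calibratable) gain, so
    within-speed calibration isolates the chain's intrinsic error budget.

    The denoising (binomial) stage is disabled by default here: a clean
    copy carries no sensor noise to remove, and heavy smoothing biases
    *every* per-cycle maximum of an asymmetric waveform upward relative to
    its value at the reference peak time — a real property of the
    measurement chain, characterized by the filter's own attenuation
    tests, not a self-consistency defect.  What remains is the resampling
    and interpolation tolerance of the chain.
    """
    if config is None:
        config = RunConfig(noise=False, clock_offset_s=0.0, ips_binomial_n=0)
    subject = synthetic.generate_subject("IDENT", seed)
    rng = np.random.default_rng(seed)
    pooled = {name: ([], []) for name in ASSESSMENTS}
    for speed in config.speeds:
        procs = []
        for rep in range(2):
            trial = synthetic.generate_walking_trial(
                subject, speed, seed=int(rng.integers(2 ** 31)),
                duration=config.trial_duration_s, noise=False, clock_offset=0.0,
                peak_cv=0.0, timing_cv=0.0)
            procs.append(_process_identity_trial(trial, config, rep))
        for cal_p, test_p in ((procs[0], procs[1]), (procs[1], procs[0])):
            total_cal = fit_total_calibration([cal_p], config)
            pairs = assessment_pairs([test_p], total_cal, config)
            for name, (ips, fp) in pairs.items():
                pooled[name][0].extend(ips)
                pooled[name][1].extend(fp)
    out = {}
    for name, (ips, fp) in pooled.items():
        ba = agreement.bland_altman(np.asarray(ips), np.asarray(fp))
        out[name] = {"mod_pbw": ba.mod, "two_s_pbw": ba.two_s}
    return out


def _process_identity_trial(trial, config: RunConfig, rep: int) -> ProcessedTrial:
    """Build a ProcessedTrial whose insole channels are the FP signal."""
    subject = trial.subject
    resultant = processing.resultant_force(trial.fp_fx, trial.fp_fy, trial.fp_fz)
    fp_force = processing.butterworth_lowpass(
        resultant, config.fp_cutoff_hz, config.fp_order,
        zero_phase=config.fp_zero_phase)

    # sample the (unfiltered) FP resultant at the insole timestamps
    t_ips = trial.ips_hind.t  # offset is zero in identity mode
    pseudo = SampledSignal(t=t_ips, values=np.interp(t_ips, resultant.t,
                                                     resultant.values), unit="N")
    # split into regional channels with the stance-phase weighting (no midfoot)
    splitter = synthetic.SubjectModel(
        subject_id=subject.subject_id, body_weight=subject.body_weight,
        foot_area_cm2=subject.foot_area_cm2, true_coverage_hind=1.0,
        true_coverage_fore=1.0, region_share_mid=0.0,
        hind_sensor=subject.hind_sensor, fore_sensor=subject.fore_sensor)
    hind_raw, _, fore_raw = synthetic.decompose_regional_forces(pseudo, splitter)

    region_force = {}
    for region, raw in (("hind", hind_raw), ("fore", fore_raw)):
        res = processing.resample_uniform(raw, config.ips_resample_hz,
                                          interpolation="spline")
        filt = processing.binomial_filter(res, config.ips_binomial_n)
        region_force[region] = _align_to_grid(filt, fp_force)

    fp_hs = _drop_stomp_events(
        events.detect_hs_fp(fp_force, config.hs_threshold_n, config.hs_debounce_s),
        trial.stomp_time_truth)
    ips_total = region_force["hind"].with_values(
        region_force["hind"].values + region_force["fore"].values)
    ips_hs = _drop_stomp_events(
        events.detect_hs_fp(ips_total, config.hs_threshold_n, config.hs_debounce_s),
        trial.stomp_time_truth)

    pairs = []
    if len(fp_hs) >= 2 and len(ips_hs) >= 2:
        fp_cycles = _drop_long_cycles(list(events.segment_cycles(fp_hs).cycles))
        ips_cycles = _drop_long_cycles(list(events.segment_cycles(ips_hs).cycles))
        pairs = _pair_cycles(fp_cycles, ips_cycles)

    return ProcessedTrial(
        subject=subject, speed=trial.speed, rep=rep,
        fp_force=fp_force, hind_force=region_force["hind"],
        fore_force=region_force["fore"], hind_resistance=region_force["hind"],
        clock_offset=0.0, paired_cycles=tuple(pairs),
        fp_hs=fp_hs, ips_hs=ips_hs, n_dropped_cycles=0)
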