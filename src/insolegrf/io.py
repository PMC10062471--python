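"""File formats and run configuration.

Signals travel as plain CSV (FP: ``t_s,fx_N,fy_N,fz_N``; IPS:
``t_s,r_hind_ohm,r_fore_ohm``), subject metadata and calibrations as JSON.
:class:`RunConfig` gathers every stage parameter with the study's printed
defaults and round-trips losslessly through YAML/JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import CalibrationTrial, SensorModel, SubjectModel, WalkingTrial
from .timeseries import SampledSignal


@dataclass(frozen=True)
class RunConfig:
    """All pipeline stage parameters, defaulting to the study protocol."""

    # cohort / synthetic conditions
    n_subjects: int = 7
    speeds: tuple = (0.5, 1.0, 1.5)   # m/s
    reps: int = 2
    trial_duration_s: float = 30.0
    noise: bool = True
    clock_offset_s: float = 0.37
    seed: int = 0
    # force plate
    fp_rate_hz: float = 2000.0
    fp_cutoff_hz: float = 20.0
    fp_order: int = 4
    fp_zero_phase: bool = True
    # insole
    ips_resample_hz: float = 2000.0
    ips_binomial_n: int = 10000
    ips_baseline_frac: float = 0.98
    ips_min_dip_s: float = 0.25
    # events
    hs_threshold_n: float = 20.0
    hs_debounce_s: float = 0.1
    sync_window_s: float = 5.0
    # peaks
    fp_peak_split_pct: float = 30.0
    ips_min_peak_width_s: float = 0.05
    # calibration
    resistance_step_ohm: float = 150.0
    # PWB simulation
    pwb_mu_pbw: float = 50.0
    pwb_sigma_pbw: float = 25.0
    pwb_limit_pbw: float = 50.0
    pwb_n_draws: int = 10_000_000

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["speeds"] = list(self.speeds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "speeds" in d:
            d["speeds"] = tuple(d["speeds"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data)


# --------------------------------------------------------------------------
# subjects
# --------------------------------------------------------------------------

def subject_to_dict(subject: SubjectModel, include_truth: bool = True) -> dict:
    d = {
        "subject_id": subject.subject_id,
        "body_weight_N": subject.body_weight,
        "foot_area_cm2": subject.foot_area_cm2,
    }
    if include_truth:
        d["truth"] = {
            "true_coverage_hind": subject.true_coverage_hind,
            "true_coverage_fore": subject.true_coverage_fore,
            "region_share_mid": subject.region_share_mid,
            "rng_seed": subject.rng_seed,
            "hind_sensor": dataclasses.asdict(subject.hind_sensor),
            "fore_sensor": dataclasses.asdict(subject.fore_sensor),
        }
    return d


#: nominal sensor used when reading subjects recorded without a truth block
_PLACEHOLDER_SENSOR = dict(baseline_resistance=2000.0, conductance_gain=8e-6,
                           conductance_curvature=5e-9, drift_rate=0.0,
                           noise_sd=0.0)


def subject_from_dict(d: dict) -> SubjectModel:
    truth = d.get("truth")
    if truth is None:
        truth = {
            "true_coverage_hind": 0.8, "true_coverage_fore": 0.8,
            "region_share_mid": 0.15, "rng_seed": 0,
            "hind_sensor": _PLACEHOLDER_SENSOR, "fore_sensor": _PLACEHOLDER_SENSOR,
        }
    return SubjectModel(
        subject_id=d["subject_id"],
        body_weight=float(d["body_weight_N"]),
        foot_area_cm2=float(d["foot_area_cm2"]),
        true_coverage_hind=truth["true_coverage_hind"],
        true_coverage_fore=truth["true_coverage_fore"],
        region_share_mid=truth["region_share_mid"],
        hind_sensor=SensorModel(**truth["hind_sensor"]),
        fore_sensor=SensorModel(**truth["fore_sensor"]),
        rng_seed=truth.get("rng_seed", 0),
    )


def write_subject(subject: SubjectModel, path: str | Path,
                  include_truth: bool = True) -> None:
    Path(path).write_text(json.dumps(subject_to_dict(subject, include_truth), indent=1))


def read_subject(path: str | Path) -> SubjectModel:
    return subject_from_dict(json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------
# trials
# --------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    for c in cols:
        if c not in df.columns:
            raise ValueError(f"{path}: missing required column {c!r}")


def _check_monotone(t: np.ndarray, path) -> None:
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        # +2: one for the header row, one for 1-based numbering
        raise ValueError(f"{path}: timestamps not strictly increasing at line {bad[0] + 3}")


def write_trial(
    trial: WalkingTrial,
    fp_csv: str | Path,
    ips_csv: str | Path,
    subject_json: str | Path | None = None,
    meta_json: str | Path | None = None,
) -> None:
    """Write a walking trial to FP/IPS CSVs (+ optional subject and truth JSON)."""
    pd.DataFrame({
        "t_s": trial.fp_fx.t, "fx_N": trial.fp_fx.values,
        "fy_N": trial.fp_fy.values, "fz_N": trial.fp_fz.values,
    }).to_csv(fp_csv, index=False, float_format="%.17g")
    pd.DataFrame({
        "t_s": trial.ips_hind.t,
        "r_hind_ohm": trial.ips_hind.values,
        "r_fore_ohm": trial.ips_fore.values,
    }).to_csv(ips_csv, index=False, float_format="%.17g")
    if subject_json is not None:
        write_subject(trial.subject, subject_json)
    if meta_json is not None:
        meta = {
            "speed_m_s": trial.speed,
            "duration_s": trial.duration,
            "stomp_time_truth_s": trial.stomp_time_truth,
            "clock_offset_truth_s": trial.clock_offset_truth,
            "hs_times_truth_s": list(trial.hs_times_truth),
            "cycle_peaks_truth_pbw": [list(p) for p in trial.cycle_peaks_truth],
        }
        Path(meta_json).write_text(json.dumps(meta, indent=1))


def read_trial(
    fp_csv: str | Path,
    ips_csv: str | Path,
    subject_json: str | Path,
    meta_json: str | Path | None = None,
) -> WalkingTrial:
    """Read and validate a walking trial from its CSV/JSON files."""
    fp = pd.read_csv(fp_csv, float_precision="round_trip")
    _require_columns(fp, ["t_s", "fx_N", "fy_N", "fz_N"], fp_csv)
    t_fp = fp["t_s"].to_numpy(float)
    _check_monotone(t_fp, fp_csv)
    dt = np.diff(t_fp)
    rate = 1.0 / float(np.mean(dt)) if len(dt) and np.allclose(dt, dt[0], rtol=1e-6) \
        else "irregular"

    ips = pd.read_csv(ips_csv, float_precision="round_trip")
    _require_columns(ips, ["t_s", "r_hind_ohm", "r_fore_ohm"], ips_csv)
    t_ips = ips["t_s"].to_numpy(float)
    _check_monotone(t_ips, ips_csv)
    for col in ("r_hind_ohm", "r_fore_ohm"):
        neg = np.flatnonzero(ips[col].to_numpy(float) <= 0)
        if neg.size:
            raise ValueError(
                f"{ips_csv}: non-positive resistance in {col!r} at line {neg[0] + 3}")

    subject = read_subject(subject_json)
    meta = {}
    if meta_json is not None and Path(meta_json).exists():
        meta = json.loads(Path(meta_json).read_text())

    def fp_sig(col):
        return SampledSignal(t=t_fp, values=fp[col].to_numpy(float),
                             unit="N", nominal_rate=rate)

    return WalkingTrial(
        fp_fx=fp_sig("fx_N"), fp_fy=fp_sig("fy_N"), fp_fz=fp_sig("fz_N"),
        ips_hind=SampledSignal(t=t_ips, values=ips["r_hind_ohm"].to_numpy(float),
                               unit="ohm"),
        ips_fore=SampledSignal(t=t_ips, values=ips["r_fore_ohm"].to_numpy(float),
                               unit="ohm"),
        speed=float(meta.get("speed_m_s", float("nan"))),
        subject=subject,
        duration=float(meta.get("duration_s", t_fp[-1] - t_fp[0])),
        stomp_time_truth=float(meta.get("stomp_time_truth_s", float("nan"))),
        clock_offset_truth=float(meta.get("clock_offset_truth_s", 0.0)),
        hs_times_truth=tuple(meta.get("hs_times_truth_s", ())),
        cycle_peaks_truth=tuple(tuple(p) for p in meta.get("cycle_peaks_truth_pbw", ())),
    )


def write_calibration_trial(trial: CalibrationTrial, fp_csv: str | Path,
                            ips_csv: str | Path) -> None:
    pd.DataFrame({"t_s": trial.fp_force.t, "f_N": trial.fp_force.values}
                 ).to_csv(fp_csv, index=False, float_format="%.17g")
    pd.DataFrame({"t_s": trial.ips_resistance.t,
                  "r_ohm": trial.ips_resistance.values}).to_csv(ips_csv, index=False, float_format="%.17g")


def read_calibration_trial(fp_csv: str | Path, ips_csv: str | Path,
                           subject: SubjectModel, region: str) -> CalibrationTrial:
    fp = pd.read_csv(fp_csv, float_precision="round_trip")
    _require_columns(fp, ["t_s", "f_N"], fp_csv)
    _check_monotone(fp["t_s"].to_numpy(float), fp_csv)
    ips = pd.read_csv(ips_csv, float_precision="round_trip")
    _require_columns(ips, ["t_s", "r_ohm"], ips_csv)
    _check_monotone(ips["t_s"].to_numpy(float), ips_csv)
    t = fp["t_s"].to_numpy(float)
    rate = 1.0 / float(np.mean(np.diff(t)))
    return CalibrationTrial(
        fp_force=SampledSignal(t=t, values=fp["f_N"].to_numpy(float),
                               unit="N", nominal_rate=rate),
        ips_resistance=SampledSignal(t=ips["t_s"].to_numpy(float),
                                     values=ips["r_ohm"].to_numpy(float), unit="ohm"),
        region=region, subject=subject)


# --------------------------------------------------------------------------
# calibrations
# --------------------------------------------------------------------------

def sensor_calibration_to_dict(cal) -> dict:
    return {"subject_id": cal.subject_id, "sensor": cal.region,
            "a0": cal.a0, "a1": cal.a1, "a2": cal.a2, "r2": cal.fit_r2,
            "r_min_ohm": cal.r_min_ohm, "r_max_ohm": cal.r_max_ohm}


def sensor_calibration_from_dict(d: dict):
    from .calibration import SensorCalibration
    return SensorCalibration(a0=d["a0"], a1=d["a1"], a2=d["a2"],
                             fit_r2=d["r2"], r_min_ohm=d["r_min_ohm"],
                             r_max_ohm=d["r_max_ohm"],
                             subject_id=d["subject_id"], region=d["sensor"])


def total_calibration_to_dict(cal) -> dict:
    return {"subject_id": cal.subject_id, "c_hind": cal.c_hind,
            "c_fore": cal.c_fore}


def total_calibration_from_dict(d: dict):
    from .calibration import TotalForceCalibration
    return TotalForceCalibration(c_hind=d["c_hind"], c_fore=d["c_fore"],
                                 subject_id=d["subject_id"])
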