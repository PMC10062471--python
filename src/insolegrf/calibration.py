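"""Two-stage insole calibration.

Stage one fits, per subject and per sensor, a second-order polynomial
relating inverse resistance (conductance G = 1/R) to force-plate force,
using the loading phases of the dedicated three-step calibration trials,
downsampled to a uniform resistance grid (every 150 ohm).

Stage two scales the two calibrated regional sensor forces to total GRF,

    F_total = C_hind * F_hind + C_fore * F_fore        (no intercept),

with C_hind, C_fore fitted by least squares on the two GRF peaks of every
gait cycle; the scaling absorbs force routed through the unsensed midfoot,
whose estimate is the total minus the raw sensor sum,

    F_mid = (C_hind - 1) * F_hind + (C_fore - 1) * F_fore.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .synthetic import CalibrationTrial
from .timeseries import SampledSignal, require_same_grid, require_same_unit

RESISTANCE_STEP_OHM = 150.0
CONTACT_FRAC_BW = 0.02
PEAK_PROMINENCE_FRAC_BW = 0.20
PLAUSIBLE_COEFF_RANGE = (0.5, 3.0)


@dataclass(frozen=True)
class SensorCalibration:
    """Quadratic map from conductance to force: F = a0 + a1*G + a2*G^2."""

    a0: float  # N
    a1: float  # N ohm
    a2: float  # N ohm^2
    fit_r2: float
    r_min_ohm: float
    r_max_ohm: float
    subject_id: str = ""
    region: str = ""

    def predict_from_conductance(self, g: np.ndarray) -> np.ndarray:
        g = np.asarray(g, dtype=float)
        return self.a0 + self.a1 * g + self.a2 * g ** 2


@dataclass(frozen=True)
class TotalForceCalibration:
    """Coefficients scaling regional sensor forces to total GRF."""

    c_hind: float
    c_fore: float
    subject_id: str = ""
    n_rows: int = 0
    resid_rms: float = float("nan")

    def __post_init__(self) -> None:
        if not (np.isfinite(self.c_hind) and np.isfinite(self.c_fore)):
            raise ValueError("total-force coefficients must be finite")
        lo, hi = PLAUSIBLE_COEFF_RANGE
        for name, c in (("c_hind", self.c_hind), ("c_fore", self.c_fore)):
            if not lo <= c <= hi:
                warnings.warn(
                    f"{name}={c:.3f} outside the plausible range [{lo}, {hi}]",
                    stacklevel=2)


def extract_loading_phases(
    fp_force: SampledSignal,
    resistance: SampledSignal,
    body_weight: float,
    n_steps: int = 3,
    contact_frac: float = CONTACT_FRAC_BW,
    prominence_frac: float = PEAK_PROMINENCE_FRAC_BW,
    baseline_frac: float = 0.98,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Paired (R, F) segments for each loading ramp of a calibration trial.

    Each segment runs from sensor contact (FP force first above 2 %BW *and*
    resistance below 98% of its trial maximum) up to the step's force peak
    (prominence above 20 %BW).  Inputs must share a time grid.
    """
    require_same_grid(fp_force, resistance)
    f = fp_force.values
    r = resistance.values
    contact_thr = contact_frac * body_weight
    r_thr = baseline_frac * np.max(r)
    peaks, _ = find_peaks(f, prominence=prominence_frac * body_weight)
    if len(peaks) < n_steps:
        raise ValueError(
            f"expected {n_steps} loading steps but found {len(peaks)} force "
            f"peaks at times {np.round(fp_force.t[peaks], 2).tolist()}")
    peaks = peaks[:n_steps]
    segments = []
    prev_peak = 0
    for p in peaks:
        pre = np.flatnonzero((f[prev_peak:p] <= contact_thr) | (r[prev_peak:p] >= r_thr))
        start = prev_peak + (int(pre[-1]) + 1 if pre.size else 0)
        segments.append((r[start:p + 1].copy(), f[start:p + 1].copy()))
        prev_peak = p
    return segments


def uniform_resistance_downsample(
    r: np.ndarray,
    f: np.ndarray,
    step: float = RESISTANCE_STEP_OHM,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample a loading segment at uniform resistance increments.

    The grid starts at the segment's initial (largest) resistance and
    descends in exact ``step`` increments as far as the segment's minimum;
    force is interpolated at each grid resistance.  A segment spanning less
    than one step falls back to its endpoints with a warning.
    """
    r = np.asarray(r, dtype=float)
    f = np.asarray(f, dtype=float)
    if len(r) != len(f) or len(r) < 2:
        raise ValueError("paired series of length >= 2 required")
    # loading: enforce monotone non-increasing resistance for interpolation
    r_mono = np.minimum.accumulate(r)
    span = r_mono[0] - r_mono[-1]
    if span < step:
        warnings.warn(
            f"resistance span {span:.1f} ohm below one {step:.0f} ohm step; "
            "falling back to segment endpoints", stacklevel=2)
        return np.array([r_mono[0], r_mono[-1]]), np.array([f[0], f[-1]])
    n_grid = int(np.floor(span / step)) + 1
    grid = r_mono[0] - step * np.arange(n_grid)
    # np.interp needs ascending abscissa
    f_grid = np.interp(grid[::-1], r_mono[::-1], f[::-1])[::-1]
    return grid, f_grid


def fit_sensor_polynomial(
    r_samples: np.ndarray,
    f_samples: np.ndarray,
    subject_id: str = "",
    region: str = "",
) -> SensorCalibration:
    """Least-squares quadratic of force on conductance G = 1/R."""
    r = np.asarray(r_samples, dtype=float)
    f = np.asarray(f_samples, dtype=float)
    if np.any(r <= 0):
        raise ValueError("resistance samples must be positive")
    g = 1.0 / r
    if len(np.unique(g)) < 3:
        raise ValueError("need at least 3 distinct conductance values for a quadratic fit")
    a2, a1, a0 = np.polyfit(g, f, 2)
    pred = a0 + a1 * g + a2 * g ** 2
    ss_res = float(np.sum((f - pred) ** 2))
    ss_tot = float(np.sum((f - np.mean(f)) ** 2))
    if ss_tot == 0.0:
        warnings.warn("degenerate fit: constant force target, r^2 undefined",
                      stacklevel=2)
        r2 = float("nan")
    else:
        r2 = 1.0 - ss_res / ss_tot
    cal = SensorCalibration(
        a0=float(a0), a1=float(a1), a2=float(a2), fit_r2=r2,
        r_min_ohm=float(np.min(r)), r_max_ohm=float(np.max(r)),
        subject_id=subject_id, region=region)
    # warn on non-monotone prediction over the fitted conductance range
    g_lo, g_hi = 1.0 / cal.r_max_ohm, 1.0 / cal.r_min_ohm
    slope_ends = (a1 + 2 * a2 * g_lo, a1 + 2 * a2 * g_hi)
    if min(slope_ends) < 0:
        warnings.warn("sensor calibration is non-monotone over its valid range",
                      stacklevel=2)
    return cal


def calibrate_sensor(
    trial: CalibrationTrial,
    fp_force: SampledSignal,
    resistance: SampledSignal,
    step: float = RESISTANCE_STEP_OHM,
) -> SensorCalibration:
    """Full stage-one calibration from a processed calibration trial."""
    segments = extract_loading_phases(
        fp_force, resistance, trial.subject.body_weight, trial.n_steps)
    rs, fs = [], []
    for r_seg, f_seg in segments:
        r_grid, f_grid = uniform_resistance_downsample(r_seg, f_seg, step)
        rs.append(r_grid)
        fs.append(f_grid)
    return fit_sensor_polynomial(
        np.concatenate(rs), np.concatenate(fs),
        subject_id=trial.subject.subject_id, region=trial.region)


def apply_sensor_calibration(
    resistance: SampledSignal,
    cal: SensorCalibration,
    subject_id: str | None = None,
) -> tuple[SampledSignal, np.ndarray]:
    """Map a resistance record to force; flag extrapolated samples.

    Returns the force signal (N) and a boolean mask marking samples whose
    resistance lies outside the calibration's fitted range (forces there
    are extrapolations beyond the 0-to-body-weight calibration ramp).
    """
    if subject_id is not None and cal.subject_id and subject_id != cal.subject_id:
        raise ValueError(
            f"calibration belongs to subject {cal.subject_id!r}, "
            f"refusing to apply it to {subject_id!r}")
    r = resistance.values
    if np.any(r <= 0):
        raise ValueError("resistance must be strictly positive")
    force = cal.predict_from_conductance(1.0 / r)
    extrapolated = (r < cal.r_min_ohm) | (r > cal.r_max_ohm)
    return resistance.with_values(force, unit="N"), extrapolated


def fit_total_force(
    f_fp: np.ndarray,
    f_hind: np.ndarray,
    f_fore: np.ndarray,
    subject_id: str = "",
) -> TotalForceCalibration:
    """Least-squares (C_hind, C_fore) with no intercept from peak rows."""
    y = np.asarray(f_fp, dtype=float)
    x = np.column_stack([np.asarray(f_hind, float), np.asarray(f_fore, float)])
    if len(y) < 2 or x.shape[0] != len(y):
        raise ValueError("need >= 2 paired peak rows")
    if np.linalg.matrix_rank(x) < 2:
        raise ValueError(
            "hindfoot and forefoot peak forces are collinear; "
            "collect more gait cycles")
    coef, res, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    return TotalForceCalibration(
        c_hind=float(coef[0]), c_fore=float(coef[1]), subject_id=subject_id,
        n_rows=len(y), resid_rms=float(np.sqrt(np.mean(resid ** 2))))


def _check_pair(f_hind: SampledSignal, f_fore: SampledSignal,
                cal: TotalForceCalibration, subject_id: str | None) -> None:
    require_same_grid(f_hind, f_fore)
    require_same_unit(f_hind, f_fore)
    if subject_id is not None and cal.subject_id and subject_id != cal.subject_id:
        raise ValueError(
            f"total-force calibration belongs to subject {cal.subject_id!r}, "
            f"refusing to apply it to {subject_id!r}")


def total_force(
    f_hind: SampledSignal,
    f_fore: SampledSignal,
    cal: TotalForceCalibration,
    subject_id: str | None = None,
) -> SampledSignal:
    """Scaled sensor sum estimating total GRF."""
    _check_pair(f_hind, f_fore, cal, subject_id)
    return f_hind.with_values(cal.c_hind * f_hind.values + cal.c_fore * f_fore.values)


def estimate_midfoot(
    f_hind: SampledSignal,
    f_fore: SampledSignal,
    cal: TotalForceCalibration,
    subject_id: str | None = None,
) -> SampledSignal:
    """Estimated unsensed midfoot force: total minus the raw sensor sum."""
    _check_pair(f_hind, f_fore, cal, subject_id)
    return f_hind.with_values((cal.c_hind - 1.0) * f_hind.values
                              + (cal.c_fore - 1.0) * f_fore.values)
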