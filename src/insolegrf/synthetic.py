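"""Synthetic gait and sensor-trial generator.

Produces force-plate (FP) and insole-pressure-sensor (IPS) recordings with
known ground truth, emulating a treadmill validation study: per-subject
calibration "step" trials (three slow loading ramps from zero to body
weight and back) and 30-s walking trials at 0.5/1.0/1.5 m/s sampled by the
FP at 2,000 Hz and by the IPS at a jittered ~28 Hz, including the stomp
transient used for clock synchronization.

The sensor is modeled with conductance affine-quadratic in applied force,

    1/R(F) = 1/R0 + g1 * F + g2 * F**2,

which is strictly monotone (resistance falls as force rises) and whose
inverse map (force as a function of conductance) is *close to* but not
exactly a quadratic polynomial — so a second-order polynomial calibration
fits well without being trivially exact.  Linear baseline drift and
additive resistance noise are optional.

Ground truth retained per trial: heel-strike times (defined as the
analytic 20-N upcrossing of the resultant GRF), the stomp time, the
injected IPS-vs-FP clock offset, and the per-cycle peak forces in %BW.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timeseries import SampledSignal, uniform

FP_RATE = 2000.0
IPS_NOMINAL_RATE = 28.0
IPS_RATE_SD = 1.2  # reported spread of the IPS sampling rate, Hz
GRAVITY = 9.81

#: stance-phase shape in fractions of stance: heel-strike, weight-acceptance
#: peak, mid-stance valley, push-off peak, toe-off
_STANCE_KNOTS = (0.0, 0.25, 0.50, 0.75, 1.0)
STANCE_FRACTION = 0.64  # stance duration as a fraction of the gait cycle
HS_THRESHOLD_N = 20.0  # force-plate heel-strike definition


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SensorModel:
    """Piezoresistive sensor: conductance affine-quadratic in force."""

    baseline_resistance: float  # R0, ohm, unloaded
    conductance_gain: float     # g1, 1/(ohm N)
    conductance_curvature: float = 0.0  # g2, 1/(ohm N^2)
    drift_rate: float = 0.0     # ohm/s additive drift on resistance
    noise_sd: float = 0.0       # ohm, additive resistance noise SD

    def __post_init__(self) -> None:
        if self.baseline_resistance <= 0:
            raise ValueError("baseline_resistance must be > 0")
        if self.conductance_gain <= 0:
            raise ValueError("conductance_gain must be > 0")
        if self.conductance_curvature < 0:
            raise ValueError("conductance_curvature must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def resistance(self, force: np.ndarray) -> np.ndarray:
        """Noise- and drift-free sensor law R(F)."""
        force = np.asarray(force, dtype=float)
        g = 1.0 / self.baseline_resistance + self.conductance_gain * force \
            + self.conductance_curvature * force ** 2
        return 1.0 / g

    def force_from_resistance(self, resistance: np.ndarray) -> np.ndarray:
        """Closed-form inverse of the noise-free law (root of the quadratic)."""
        r = np.asarray(resistance, dtype=float)
        dg = 1.0 / r - 1.0 / self.baseline_resistance
        g1, g2 = self.conductance_gain, self.conductance_curvature
        if g2 == 0:
            return dg / g1
        disc = np.maximum(g1 ** 2 + 4.0 * g2 * dg, 0.0)
        # rationalized root: stable as g2 -> 0 (no catastrophic cancellation)
        return 2.0 * dg / (g1 + np.sqrt(disc))


@dataclass(frozen=True)
class SubjectModel:
    """A synthetic subject with its two sensors and regional-force truth.

    ``true_coverage_*`` is the fraction of the regional plantar force the
    sensor captures; ``region_share_mid`` is the fraction of total stance
    force routed through the unsensed midfoot.  Because coverage applies
    identically during calibration steps and walking, the generator's
    ground-truth total-force (secondary calibration) coefficients are
    ``1 / (1 - region_share_mid)`` for both sensors.
    """

    subject_id: str
    body_weight: float            # N
    foot_area_cm2: float
    true_coverage_hind: float
    true_coverage_fore: float
    region_share_mid: float
    hind_sensor: SensorModel
    fore_sensor: SensorModel
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValueError("body_weight must be > 0")
        if self.foot_area_cm2 <= 0:
            raise ValueError("foot_area_cm2 must be > 0")
        for name in ("true_coverage_hind", "true_coverage_fore"):
            c = getattr(self, name)
            if not 0 < c <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if not 0 <= self.region_share_mid < 1:
            raise ValueError("region_share_mid must be in [0, 1)")

    def sensor(self, region: str) -> SensorModel:
        if region == "hind":
            return self.hind_sensor
        if region == "fore":
            return self.fore_sensor
        raise ValueError(f"unknown region {region!r}")

    def coverage(self, region: str) -> float:
        return {"hind": self.true_coverage_hind,
                "fore": self.true_coverage_fore}[region]

    @property
    def true_total_coefficient(self) -> float:
        """Ground-truth coefficient of the total-force calibration."""
        return 1.0 / (1.0 - self.region_share_mid)


@dataclass(frozen=True)
class CalibrationTrial:
    """One three-step loading trial for a single sensor region."""

    fp_force: SampledSignal       # resultant FP force, N, 2,000 Hz
    ips_resistance: SampledSignal  # ohm, irregular ~28 Hz
    region: str                   # "hind" | "fore"
    subject: SubjectModel
    n_steps: int = 3
    ramp_bounds_truth: tuple = ()  # (t_contact, t_peak, t_release) per step


@dataclass(frozen=True)
class WalkingTrial:
    """One 30-s walking trial recorded by both instruments."""

    fp_fx: SampledSignal
    fp_fy: SampledSignal
    fp_fz: SampledSignal
    ips_hind: SampledSignal   # ohm, irregular ~28 Hz, on the *IPS clock*
    ips_fore: SampledSignal
    speed: float              # m/s
    subject: SubjectModel
    duration: float = 30.0
    stomp_time_truth: float = float("nan")   # FP-clock time of the stomp peak
    clock_offset_truth: float = 0.0          # add to IPS timestamps to align
    hs_times_truth: tuple = ()               # FP-clock 20-N upcrossing times
    cycle_peaks_truth: tuple = ()            # (pk1, pk2) %BW per cycle

    @property
    def fp_resultant_truth(self) -> SampledSignal:
        """Noise-free resultant on the FP grid (Euclidean norm of components)."""
        v = np.sqrt(self.fp_fx.values ** 2 + self.fp_fy.values ** 2
                    + self.fp_fz.values ** 2)
        return self.fp_fx.with_values(v, unit="N")


# --------------------------------------------------------------------------
# waveform construction
# --------------------------------------------------------------------------

def _smoothstep(u: np.ndarray) -> np.ndarray:
    """Cosine ease from 0 to 1 on u in [0, 1]; flat at both ends."""
    return 0.5 * (1.0 - np.cos(np.pi * np.clip(u, 0.0, 1.0)))


def _stance_shape(u: np.ndarray, p1: float, valley: float, p2: float) -> np.ndarray:
    """Double-peaked stance waveform on stance fraction u in [0, 1].

    Two squared-cosine lobes centered at 25% and 75% of stance plus a
    valley bump; on each half the sum collapses to
    ``valley + (peak - valley) * cos^2`` so the configured peak and valley
    values are attained exactly, the waveform is monotone between its
    extrema, and the curvature around each peak is locally symmetric
    (important: symmetric peaks stay put under smoothing filters).
    """
    u = np.asarray(u, dtype=float)
    k1, k2, w = _STANCE_KNOTS[1], _STANCE_KNOTS[3], _STANCE_KNOTS[1]
    out = np.zeros_like(u)
    lob1 = np.abs(u - k1) <= w
    out[lob1] += p1 * np.cos(np.pi * (u[lob1] - k1) / (2 * w)) ** 2
    lob2 = np.abs(u - k2) <= w
    out[lob2] += p2 * np.cos(np.pi * (u[lob2] - k2) / (2 * w)) ** 2
    mid = (u >= k1) & (u <= k2)
    out[mid] += valley * np.sin(np.pi * (u[mid] - k1) / (2 * w)) ** 2
    out[(u < 0) | (u > 1)] = 0.0
    return out


def cycle_duration(speed: float) -> float:
    """Gait-cycle duration (s) as a function of treadmill speed (m/s)."""
    if speed <= 0:
        raise ValueError("speed must be > 0")
    return 1.1 / np.sqrt(speed)


def _hs_crossing_offset(p1_newton: float, stance_dur: float) -> float:
    """Analytic time after stance onset at which force first exceeds 20 N."""
    if p1_newton <= HS_THRESHOLD_N:
        raise ValueError("peak force must exceed the 20 N heel-strike threshold")
    # invert the first cosine rise segment
    s = np.arccos(1.0 - 2.0 * HS_THRESHOLD_N / p1_newton) / np.pi
    return float(s * _STANCE_KNOTS[1] * stance_dur)


def generate_grf_waveform(
    speed: float,
    n_cycles: int,
    subject: SubjectModel,
    seed: int = 0,
    peaks_pbw: tuple[float, float] = (110.0, 105.0),
    valley_pbw: float = 75.0,
    peak_cv: float = 0.015,
    timing_cv: float = 0.02,
    start_time: float = 0.0,
    rate: float = FP_RATE,
):
    """Generate the resultant walking GRF for ``n_cycles`` gait cycles.

    Returns ``(signal, hs_times, cycle_peaks)`` where ``signal`` is the
    resultant force in N on a uniform grid, ``hs_times`` are the analytic
    20-N upcrossing times (one per cycle) and ``cycle_peaks`` the realized
    per-cycle (pk1, pk2) in %BW.  Peak heights and cycle durations vary
    cycle-to-cycle by the given coefficients of variation; with both set
    to zero the configured peaks are attained exactly.
    """
    if n_cycles < 0:
        raise ValueError("n_cycles must be >= 0")
    if speed <= 0:
        raise ValueError("speed must be > 0")
    rng = np.random.default_rng(seed)
    base_cycle = cycle_duration(speed)

    if n_cycles == 0:
        empty = uniform(np.zeros(0), rate, "N", t0=start_time)
        return empty, [], []

    durations = base_cycle * (1.0 + timing_cv * rng.standard_normal(n_cycles))
    durations = np.maximum(durations, 0.5 * base_cycle)
    p1s = peaks_pbw[0] * (1.0 + peak_cv * rng.standard_normal(n_cycles))
    p2s = peaks_pbw[1] * (1.0 + peak_cv * rng.standard_normal(n_cycles))
    valleys = valley_pbw * (1.0 + peak_cv * rng.standard_normal(n_cycles))
    # keep the valley strictly below both peaks so cycles stay double-peaked
    valleys = np.minimum(valleys, 0.9 * np.minimum(p1s, p2s))

    total = float(np.sum(durations))
    n = int(np.floor(total * rate))
    t = start_time + np.arange(n) / rate
    force = np.zeros(n)
    hs_times: list[float] = []
    peaks: list[tuple[float, float]] = []

    bw = subject.body_weight
    t0 = start_time
    for i in range(n_cycles):
        stance = STANCE_FRACTION * durations[i]
        m = (t >= t0) & (t < t0 + stance)
        u = (t[m] - t0) / stance
        force[m] = _stance_shape(u, p1s[i] / 100 * bw, valleys[i] / 100 * bw,
                                 p2s[i] / 100 * bw)
        hs_times.append(t0 + _hs_crossing_offset(p1s[i] / 100 * bw, stance))
        peaks.append((float(p1s[i]), float(p2s[i])))
        t0 += durations[i]

    return uniform(force, rate, "N", t0=start_time), hs_times, peaks


#: hindfoot carries the full sensed load until this fraction of the loaded
#: span, then hands over to the forefoot (cosine transition) by the second;
#: the transition stays clear of both GRF peaks (25% / 75% of stance) so
#: each sensed channel is locally symmetric around its own peak
HIND_PLATEAU_FRAC = 0.40
FORE_PLATEAU_FRAC = 0.60


def _hind_weight(tau: np.ndarray) -> np.ndarray:
    """Hindfoot share of the sensed load across a loaded span (1 -> 0)."""
    u = (tau - HIND_PLATEAU_FRAC) / (FORE_PLATEAU_FRAC - HIND_PLATEAU_FRAC)
    return 0.5 * (1.0 + np.cos(np.pi * np.clip(u, 0.0, 1.0)))


def decompose_regional_forces(grf: SampledSignal, subject: SubjectModel):
    """Split total GRF into (hind, mid, fore) regional forces.

    Within each contiguous loaded span the hindfoot carries the full
    sensed share ``1 - region_share_mid`` through weight acceptance, hands
    over to the forefoot across mid-stance (cosine transition), and the
    forefoot carries the full sensed share through push-off; the midfoot
    takes a constant share.  The three outputs sum to the input at every
    sample.
    """
    f = grf.values
    if np.any(f < 0):
        raise ValueError("GRF must be non-negative for regional decomposition")
    m_share = subject.region_share_mid
    hind = np.zeros_like(f)
    fore = np.zeros_like(f)
    mid = np.zeros_like(f)

    # contiguous loaded spans
    idx = np.flatnonzero(f > 0)
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        span_starts = np.concatenate(([idx[0]], idx[breaks + 1]))
        span_ends = np.concatenate((idx[breaks], [idx[-1]]))  # inclusive
        for s, e in zip(span_starts, span_ends):
            n = e - s + 1
            tau = np.arange(n) / max(n - 1, 1)
            c = _hind_weight(tau)
            seg = f[s:e + 1]
            hind[s:e + 1] = (1.0 - m_share) * c * seg
            fore[s:e + 1] = (1.0 - m_share) * (1.0 - c) * seg
            mid[s:e + 1] = m_share * seg
    return (grf.with_values(hind), grf.with_values(mid), grf.with_values(fore))


def force_to_resistance(
    force: SampledSignal,
    sensor: SensorModel,
    seed: int = 0,
    noise: bool = True,
) -> SampledSignal:
    """Apply the sensor law (plus drift and optional noise) to a sensed force.

    ``force`` is the force actually seen by the sensor, i.e. the regional
    force already scaled by the coverage fraction.  Drift accumulates as
    ``drift_rate * (t - t[0])``.
    """
    f = force.values
    if not np.all(np.isfinite(f)):
        raise ValueError("force contains non-finite samples")
    if np.any(f < 0):
        raise ValueError("sensed force must be non-negative")
    r = sensor.resistance(f)
    if len(force):
        r = r + sensor.drift_rate * (force.t - force.t[0])
    if noise and sensor.noise_sd > 0:
        rng = np.random.default_rng(seed)
        r = r + sensor.noise_sd * rng.standard_normal(len(r))
    return force.with_values(r, unit="ohm")


# --------------------------------------------------------------------------
# trial generators
# --------------------------------------------------------------------------

def _ips_timestamps(duration: float, rng: np.random.Generator,
                    jitter: float = 0.10) -> np.ndarray:
    """Strictly increasing ~28 Hz timestamps with uniform +/-10% period jitter."""
    period = 1.0 / IPS_NOMINAL_RATE
    n_max = int(np.ceil(duration / (period * (1 - jitter)))) + 2
    dts = period * (1.0 + jitter * rng.uniform(-1.0, 1.0, size=n_max))
    t = np.concatenate(([0.0], np.cumsum(dts)))
    return t[t <= duration]


def generate_calibration_trial(
    subject: SubjectModel,
    region: str,
    seed: int = 0,
    noise: bool = True,
    n_steps: int = 3,
    ramp_up: float = 3.0,
    ramp_down: float = 3.0,
    rest: float = 2.0,
) -> CalibrationTrial:
    """Three slow loading "steps" of one sensor from 0 to body weight and back.

    The FP sees the full applied force; the sensor sees it scaled by the
    region's coverage fraction, so the minimum resistance over the trial is
    ``R(body_weight * coverage)`` up to noise.
    """
    if region not in ("hind", "fore"):
        raise ValueError(f"region must be 'hind' or 'fore', got {region!r}")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    bw = subject.body_weight
    step = ramp_up + ramp_down + rest
    duration = rest + n_steps * step
    n = int(duration * FP_RATE)
    t = np.arange(n) / FP_RATE
    force = np.zeros(n)
    bounds = []
    for k in range(n_steps):
        t_on = rest + k * step
        up = (t >= t_on) & (t < t_on + ramp_up)
        force[up] = bw * _smoothstep((t[up] - t_on) / ramp_up)
        down = (t >= t_on + ramp_up) & (t < t_on + ramp_up + ramp_down)
        force[down] = bw * _smoothstep(1.0 - (t[down] - t_on - ramp_up) / ramp_down)
        bounds.append((t_on, t_on + ramp_up, t_on + ramp_up + ramp_down))

    fp = uniform(force, FP_RATE, "N")
    t_ips = _ips_timestamps(duration, rng)
    sensed = np.interp(t_ips, t, force) * subject.coverage(region)
    sensed_sig = SampledSignal(t=t_ips, values=sensed, unit="N")
    resistance = force_to_resistance(
        sensed_sig, subject.sensor(region),
        seed=int(rng.integers(2 ** 31)), noise=noise)
    return CalibrationTrial(
        fp_force=fp, ips_resistance=resistance, region=region,
        subject=subject, n_steps=n_steps, ramp_bounds_truth=tuple(bounds))


def generate_walking_trial(
    subject: SubjectModel,
    speed: float,
    seed: int = 0,
    duration: float = 30.0,
    noise: bool = True,
    clock_offset: float = 0.0,
    stomp_peak_pbw: float = 300.0,
    stomp_time: float = 1.0,
    stomp_width: float = 0.2,
    walk_start: float = 3.0,
    peak_cv: float = 0.015,
    timing_cv: float = 0.02,
) -> WalkingTrial:
    """One treadmill walking trial with a synchronization stomp.

    The FP record is ``duration * 2,000`` samples on [0, duration).  The
    stomp is a raised-cosine transient centered at ``stomp_time`` whose
    peak exceeds every walking peak.  IPS resistance is sampled at a
    jittered ~28 Hz on its own clock: adding ``clock_offset_truth`` (=
    ``clock_offset``) to the IPS timestamps aligns them with the FP clock.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    bw = subject.body_weight

    base_cycle = cycle_duration(speed)
    n_cycles = int(np.floor((duration - walk_start - 0.2) / base_cycle))
    walk, hs_times, peaks = generate_grf_waveform(
        speed, n_cycles, subject, seed=int(rng.integers(2 ** 31)),
        peak_cv=peak_cv, timing_cv=timing_cv, start_time=walk_start)

    n = int(round(duration * FP_RATE))
    t = np.arange(n) / FP_RATE
    force = np.zeros(n)
    iw = np.searchsorted(t, walk_start)
    force[iw:iw + len(walk)] = walk.values[: n - iw]

    walking_only = uniform(force.copy(), FP_RATE, "N")
    hind, _, fore = decompose_regional_forces(walking_only, subject)
    hind_v, fore_v = hind.values.copy(), fore.values.copy()

    # stomp transient: flat-footed, constant regional split (time-symmetric
    # in every channel so it anchors clock synchronization without skew)
    if stomp_peak_pbw > 0:
        in_pulse = np.abs(t - stomp_time) < stomp_width / 2
        u = (t[in_pulse] - (stomp_time - stomp_width / 2)) / stomp_width
        pulse = stomp_peak_pbw / 100 * bw * 0.5 * (1 - np.cos(2 * np.pi * u))
        force[in_pulse] += pulse
        sensed_share = 1.0 - subject.region_share_mid
        hind_v[in_pulse] += 0.6 * sensed_share * pulse
        fore_v[in_pulse] += 0.4 * sensed_share * pulse

    resultant = uniform(force, FP_RATE, "N")
    # fixed shoe/foot orientation: vertical-dominant force direction
    dz, dx = 0.995, 0.05
    dy = float(np.sqrt(1.0 - dz ** 2 - dx ** 2))
    fp_fx = resultant.with_values(dx * force)
    fp_fy = resultant.with_values(dy * force)
    fp_fz = resultant.with_values(dz * force)

    hind = hind.with_values(hind_v)
    fore = fore.with_values(fore_v)

    t_ips = _ips_timestamps(duration, rng)
    signals = {}
    for region, regional in (("hind", hind), ("fore", fore)):
        sensed = np.interp(t_ips, t, regional.values) * subject.coverage(region)
        sensed_sig = SampledSignal(t=t_ips, values=sensed, unit="N")
        r = force_to_resistance(sensed_sig, subject.sensor(region),
                                seed=int(rng.integers(2 ** 31)), noise=noise)
        # move onto the IPS clock: true time = ips time + clock_offset
        signals[region] = r.with_time(t_ips - clock_offset)

    return WalkingTrial(
        fp_fx=fp_fx, fp_fy=fp_fy, fp_fz=fp_fz,
        ips_hind=signals["hind"], ips_fore=signals["fore"],
        speed=speed, subject=subject, duration=duration,
        stomp_time_truth=stomp_time, clock_offset_truth=clock_offset,
        hs_times_truth=tuple(hs_times), cycle_peaks_truth=tuple(peaks))


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------

#: study cohort body mass, kg (mean, SD)
BODY_MASS_KG = (75.2, 18.2)


def generate_subject(subject_id: str, seed: int) -> SubjectModel:
    """Draw one subject from the cohort distribution."""
    rng = np.random.default_rng(seed)
    mass = float(np.clip(rng.normal(*BODY_MASS_KG), 45.0, 120.0))
    foot_area = float(np.clip(rng.normal(36.0, 5.0), 22.0, 55.0))

    def sensor() -> SensorModel:
        return SensorModel(
            baseline_resistance=float(rng.uniform(1500.0, 2500.0)),
            conductance_gain=float(rng.uniform(6e-6, 1.2e-5)),
            conductance_curvature=float(rng.uniform(5e-10, 2.5e-9)),
            drift_rate=0.5,
            noise_sd=2.5,
        )

    return SubjectModel(
        subject_id=subject_id,
        body_weight=mass * GRAVITY,
        foot_area_cm2=foot_area,
        true_coverage_hind=float(rng.uniform(0.65, 0.95)),
        true_coverage_fore=float(rng.uniform(0.65, 0.95)),
        region_share_mid=float(rng.uniform(0.05, 0.18)),
        hind_sensor=sensor(),
        fore_sensor=sensor(),
        rng_seed=seed,
    )


def generate_cohort(n_subjects: int = 7, seed: int = 0) -> list[SubjectModel]:
    """The default synthetic cohort (7 analyzable subjects)."""
    root = np.random.default_rng(seed)
    seeds = root.integers(2 ** 31, size=n_subjects)
    return [generate_subject(f"S{i + 1:02d}", int(s))
            for i, s in enumerate(seeds)]
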