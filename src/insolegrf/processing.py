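"""Filtering, resampling, zeroing, and body-weight normalization.

Force-plate (FP) processing: resolve 3-axis force into the resultant and
low-pass it at 20 Hz with a fourth-order Butterworth filter (zero-phase by
default so peak timings are not lagged).

Insole (IPS) processing: resample the irregular ~28 Hz resistance record to
2,000 Hz, smooth with a binomial filter of n = 10,000 convolutions
(equivalent to a Gaussian of variance n/2 samples^2), zero per-trial
baselines measured while the sensor is unloaded, and clamp swing-phase
noise to zero.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline, PchipInterpolator
from scipy.stats import binom

from .timeseries import SampledSignal, require_same_grid, require_same_unit


def resultant_force(fx: SampledSignal, fy: SampledSignal, fz: SampledSignal) -> SampledSignal:
    """Elementwise Euclidean norm of the three force components."""
    require_same_grid(fx, fy, fz)
    require_same_unit(fx, fy, fz)
    v = np.sqrt(fx.values ** 2 + fy.values ** 2 + fz.values ** 2)
    return fx.with_values(v)


def butterworth_lowpass(
    sig: SampledSignal,
    cutoff_hz: float = 20.0,
    order: int = 4,
    zero_phase: bool = True,
) -> SampledSignal:
    """Low-pass Butterworth filter on a uniformly sampled signal.

    ``zero_phase=True`` applies the filter forward and backward
    (squaring the magnitude response); ``False`` gives the textbook
    single-pass response.
    """
    if not sig.is_uniform:
        raise ValueError("Butterworth filtering requires uniform sampling; resample first")
    rate = float(sig.nominal_rate)
    if cutoff_hz >= rate / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist {rate / 2} Hz")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=rate, output="sos")
    if zero_phase:
        out = sps.sosfiltfilt(sos, sig.values)
    else:
        zi = sps.sosfilt_zi(sos) * (sig.values[0] if len(sig) else 0.0)
        out, _ = sps.sosfilt(sos, sig.values, zi=zi)
    return sig.with_values(out)


def resample_uniform(sig: SampledSignal, target_hz: float = 2000.0,
                     interpolation: str = "monotone") -> SampledSignal:
    """Resample onto a uniform grid at ``target_hz`` spanning the input range.

    Uniformly sampled inputs go through polyphase band-limited resampling
    (Kaiser-windowed FIR anti-aliasing, edge padding by line extension);
    irregularly timestamped inputs are interpolated with a monotone
    (PCHIP) cubic, which cannot overshoot at sharp loading transients —
    the right choice for saturating resistance records.  For smooth force
    records ``interpolation="spline"`` selects a C2 cubic spline with an
    order of magnitude less flattening at waveform peaks.
    The output grid is ``t0 + k / target_hz`` for
    ``k = 0 .. floor(duration * target_hz)``.
    """
    if len(sig) < 2:
        raise ValueError("resampling requires at least 2 samples")
    t0 = float(sig.t[0])
    n_out = int(np.floor(sig.duration * target_hz)) + 1
    t_out = t0 + np.arange(n_out) / target_hz

    dt = np.diff(sig.t)
    uniform_input = np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12)
    if uniform_input:
        rate_in = 1.0 / float(np.mean(dt))
        frac = Fraction(target_hz / rate_in).limit_denominator(10000)
        up, down = frac.numerator, frac.denominator
        if up == down:
            out = sig.values[:n_out].copy()
        else:
            y = sps.resample_poly(sig.values, up, down, padtype="line")
            out = y[:n_out]
            if len(out) < n_out:  # polyphase output one short of the grid
                out = np.concatenate([out, np.repeat(out[-1], n_out - len(out))])
    else:
        if interpolation == "monotone":
            interp = PchipInterpolator(sig.t, sig.values)
        elif interpolation == "spline":
            interp = CubicSpline(sig.t, sig.values)
        else:
            raise ValueError(f"unknown interpolation {interpolation!r}")
        out = interp(np.clip(t_out, sig.t[0], sig.t[-1]))
    return SampledSignal(t=t_out, values=out, unit=sig.unit,
                         nominal_rate=float(target_hz))


def binomial_kernel(n_convolutions: int) -> np.ndarray:
    """Impulse response of n successive (1, 2, 1)/4 convolutions.

    The exact kernel is the binomial(2n, 1/2) pmf (2n + 1 taps), which for
    large n approaches a Gaussian with variance n/2 samples^2.
    """
    if n_convolutions < 0:
        raise ValueError("n_convolutions must be >= 0")
    if n_convolutions == 0:
        return np.array([1.0])
    k = np.arange(2 * n_convolutions + 1)
    kern = binom.pmf(k, 2 * n_convolutions, 0.5)
    return kern / kern.sum()  # unit DC gain to the last bit


def binomial_filter(
    sig: SampledSignal,
    n_convolutions: int = 10000,
    method: str = "exact",
) -> SampledSignal:
    """Binomial (approximately Gaussian) smoothing filter.

    ``method="exact"`` convolves once with the exact 2n+1-tap binomial
    kernel (FFT convolution, edge padding with the edge values);
    ``method="naive"`` applies the (1, 2, 1)/4 kernel n times and is the
    slow reference used in tests on short signals.
    """
    if not sig.is_uniform:
        raise ValueError("binomial filtering requires uniform sampling")
    if n_convolutions < 0:
        raise ValueError("n_convolutions must be >= 0")
    if n_convolutions == 0 or len(sig) == 0:
        return sig.with_values(sig.values.copy())
    x = sig.values
    if method == "exact":
        kern = binomial_kernel(n_convolutions)
        half = n_convolutions
        padded = np.concatenate([np.repeat(x[0], half), x, np.repeat(x[-1], half)])
        out = sps.fftconvolve(padded, kern, mode="valid")
    elif method == "naive":
        out = x.copy()
        for _ in range(n_convolutions):
            padded = np.concatenate([out[:1], out, out[-1:]])
            out = np.convolve(padded, [0.25, 0.5, 0.25], mode="valid")
    else:
        raise ValueError(f"unknown method {method!r}")
    return sig.with_values(out)


def detect_unloaded(resistance: SampledSignal, baseline_frac: float = 0.98) -> np.ndarray:
    """Boolean mask of samples where the sensor is unloaded.

    Unloaded = resistance within (1 - baseline_frac) of the trial maximum,
    i.e. ``R >= baseline_frac * max(R)`` — the mirror of the 98 %-of-baseline
    heel-strike rule.
    """
    r = resistance.values
    if len(r) == 0:
        return np.zeros(0, dtype=bool)
    return r >= baseline_frac * np.max(r)


def zero_baseline(
    sig: SampledSignal,
    baseline_regions: list[tuple[float, float]] | None = None,
    resistance: SampledSignal | None = None,
    baseline_frac: float = 0.98,
    trial_label: str = "",
) -> tuple[SampledSignal, float]:
    """Subtract the mean signal level over unloaded (baseline) spans.

    Baseline spans may be given explicitly as time windows, or detected
    from a paired resistance record (samples within 2% of the trial's
    maximum resistance).  Returns the zeroed signal and the subtracted
    baseline value.
    """
    if baseline_regions is not None:
        mask = np.zeros(len(sig), dtype=bool)
        for t0, t1 in baseline_regions:
            mask |= (sig.t >= t0) & (sig.t <= t1)
    elif resistance is not None:
        require_same_grid(sig, resistance)
        mask = detect_unloaded(resistance, baseline_frac)
    else:
        raise ValueError("provide baseline_regions or a resistance record")
    if not mask.any():
        label = f" in trial {trial_label}" if trial_label else ""
        raise ValueError(f"no unloaded baseline span found{label}")
    baseline = float(np.mean(sig.values[mask]))
    return sig.with_values(sig.values - baseline), baseline


def normalize_bw(force: SampledSignal, body_weight: float) -> SampledSignal:
    """Newtons to percent body weight."""
    if body_weight <= 0:
        raise ValueError("body_weight must be > 0")
    if force.unit != "N":
        raise ValueError(f"expected a force in N, got unit {force.unit!r}")
    return force.with_values(force.values * 100.0 / body_weight, unit="%BW")


def denormalize_bw(force: SampledSignal, body_weight: float) -> SampledSignal:
    """Percent body weight back to newtons."""
    if body_weight <= 0:
        raise ValueError("body_weight must be > 0")
    if force.unit != "%BW":
        raise ValueError(f"expected a force in %BW, got unit {force.unit!r}")
    return force.with_values(force.values * body_weight / 100.0, unit="N")


def clamp_swing(force: SampledSignal, unloaded_mask: np.ndarray) -> SampledSignal:
    """Zero the force wherever the sensor is detected unloaded."""
    unloaded_mask = np.asarray(unloaded_mask, dtype=bool)
    if len(unloaded_mask) != len(force):
        raise ValueError("mask length does not match the signal")
    out = force.values.copy()
    out[unloaded_mask] = 0.0
    return force.with_values(out)
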