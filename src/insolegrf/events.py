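"""Stomp synchronization, heel-strike detection, and gait-cycle segmentation.

Heel strikes (HS) are detected independently in the two instruments: the
force plate fires on the first upward crossing of 20 N after an unloaded
span, the insole on the first sample of any span where resistance stays
below 98% of the unloaded baseline for at least 0.25 s.  The stomp — a
deliberate high-force transient near the start of every trial — appears in
both records and anchors the clock alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timeseries import SampledSignal

HS_THRESHOLD_N = 20.0
HS_DEBOUNCE_S = 0.1
IPS_BASELINE_FRAC = 0.98
IPS_MIN_DIP_S = 0.25


@dataclass(frozen=True)
class GaitCycleSet:
    """Heel-strike times and the half-open cycles they delimit."""

    hs_times: np.ndarray
    cycles: tuple  # ((start, end), ...) half-open [HS_i, HS_{i+1})

    def __post_init__(self) -> None:
        hs = np.asarray(self.hs_times, dtype=float)
        object.__setattr__(self, "hs_times", hs)
        if len(self.cycles) != len(hs) - 1:
            raise ValueError("cycle count must equal HS count - 1")

    def __len__(self) -> int:
        return len(self.cycles)

    def percent_of_cycle(self, time: float | np.ndarray) -> np.ndarray:
        """Map times to [0, 100) within their containing cycle (NaN outside)."""
        time = np.atleast_1d(np.asarray(time, dtype=float))
        out = np.full_like(time, np.nan)
        for t0, t1 in self.cycles:
            m = (time >= t0) & (time < t1)
            out[m] = 100.0 * (time[m] - t0) / (t1 - t0)
        return out


def stomp_event_time(
    sig: SampledSignal,
    kind: str,
    window_s: float = 5.0,
    min_peak_ratio: float = 1.5,
) -> float:
    """Locate the stomp in one instrument, on that instrument's own clock.

    For a force record the stomp is the force maximum within the opening
    window; for a resistance record it is the resistance minimum (deepest
    loading).  The force maximum must exceed ``min_peak_ratio`` times the
    median level of the rest of the record's loaded peaks, otherwise no
    stomp is deemed present.
    """
    if len(sig) == 0:
        raise ValueError("empty signal")
    t0 = sig.t[0]
    m = sig.t <= t0 + window_s
    if not m.any():
        raise ValueError("synchronization window contains no samples")
    if kind == "force":
        i = int(np.argmax(sig.values[m]))
        peak = sig.values[m][i]
        later = sig.values[~m]
        if later.size:
            from scipy.signal import find_peaks
            ref = float(np.max(later))
            locs, _ = find_peaks(later, prominence=0.3 * ref) if ref > 0 else ([], None)
            median_walk_peak = float(np.median(later[locs])) if len(locs) else ref
            if median_walk_peak > 0 and peak < min_peak_ratio * median_walk_peak:
                raise ValueError(
                    "no stomp transient found in the force record; "
                    "pass a manual clock offset")
        return float(sig.t[m][i])
    if kind == "resistance":
        t_w = sig.t[m]
        g = 1.0 / sig.values[m]  # conductance: linear-plus in applied force
        i = int(np.argmax(g))
        g_base = float(np.median(g))
        thr = g_base + 0.5 * (g[i] - g_base)
        if g[i] <= g_base:
            raise ValueError(
                "no stomp transient found in the resistance record; "
                "pass a manual clock offset")
        # contiguous super-threshold run around the deepest loading
        above = g >= thr
        lo = i
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = i
        while hi < len(g) - 1 and above[hi + 1]:
            hi += 1
        w = g[lo:hi + 1] - thr
        return float(np.sum(t_w[lo:hi + 1] * w) / np.sum(w))


def synchronize_stomp(
    ips_resistance: SampledSignal,
    fp_force: SampledSignal,
    window_s: float = 5.0,
    refine_s: float = 0.06,
) -> float:
    """Clock offset to *add* to IPS timestamps to align them with the FP.

    Coarse alignment matches the FP stomp force peak with the
    conductance-weighted centroid of the IPS stomp dip; the offset is then
    refined by cross-correlating the two stomp pulses (force against
    conductance, both symmetric about the stomp center) over a
    +/- ``refine_s`` lag window.  Swapping which stream is treated as the
    reference negates the offset.
    """
    t_fp = stomp_event_time(fp_force, "force", window_s)
    t_ips = stomp_event_time(ips_resistance, "resistance", window_s)
    coarse = t_fp - t_ips

    # cross-correlation refinement around the stomp
    rate = 2000.0
    half = 0.45
    tt = np.arange(-half, half, 1.0 / rate)
    f_win = np.interp(t_fp + tt, fp_force.t, fp_force.values)
    f_win = f_win - np.mean(f_win)
    te = np.arange(-half - refine_s, half + refine_s, 1.0 / rate)
    g_ext = np.interp(t_ips + te, ips_resistance.t, 1.0 / ips_resistance.values)
    g_ext = g_ext - np.mean(g_ext)
    corr = np.correlate(g_ext, f_win, mode="valid")
    if len(corr) == 0 or not np.any(corr > 0):
        return coarse
    k = int(np.argmax(corr))
    return coarse + refine_s - k / rate


def detect_hs_fp(
    force: SampledSignal,
    threshold: float = HS_THRESHOLD_N,
    debounce_s: float = HS_DEBOUNCE_S,
) -> np.ndarray:
    """Force-plate heel strikes: upward threshold crossings after an
    unloaded span of at least ``debounce_s``."""
    if not force.is_uniform:
        raise ValueError("FP heel-strike detection requires uniform sampling")
    f = force.values
    if len(f) < 2:
        return np.zeros(0)
    rate = float(force.nominal_rate)
    n_deb = max(int(round(debounce_s * rate)), 1)
    above = f >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    times = []
    for i in crossings:
        lo = max(i - n_deb, 0)
        if i - lo >= n_deb and np.all(f[lo:i] < threshold):
            times.append(force.t[i])
    return np.asarray(times)


def detect_hs_ips(
    resistance: SampledSignal,
    baseline: float,
    baseline_frac: float = IPS_BASELINE_FRAC,
    min_duration_s: float = IPS_MIN_DIP_S,
) -> np.ndarray:
    """Insole heel strikes: first sample of each span where resistance stays
    below ``baseline_frac * baseline`` for at least ``min_duration_s``."""
    if baseline <= 0:
        raise ValueError("baseline resistance must be > 0")
    below = resistance.values < baseline_frac * baseline
    idx = np.flatnonzero(below)
    if idx.size == 0:
        return np.zeros(0)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    times = []
    for s, e in zip(starts, ends):
        if resistance.t[e] - resistance.t[s] >= min_duration_s:
            times.append(resistance.t[s])
    return np.asarray(times)


def segment_cycles(hs_times: np.ndarray) -> GaitCycleSet:
    """k heel strikes delimit k - 1 contiguous half-open gait cycles."""
    hs = np.asarray(hs_times, dtype=float)
    if len(hs) < 2:
        raise ValueError("at least 2 heel strikes are required to segment cycles")
    cycles = tuple((float(a), float(b)) for a, b in zip(hs[:-1], hs[1:]))
    return GaitCycleSet(hs_times=hs, cycles=cycles)
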