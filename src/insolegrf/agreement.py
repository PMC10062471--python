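"""Per-cycle peak extraction and Bland-Altman agreement analysis.

Two assessments compare insole (IPS) and force-plate (FP) force per gait
cycle: 2PK pairs the weight-acceptance and push-off peaks, MAX pairs the
single per-cycle maxima.  FP peaks use the percent-of-cycle rule (maximum
in the first 30% of the cycle, then the maximum after 30%); IPS peaks are
the two largest local maxima wider than 0.05 s (width at half prominence).

Agreement is summarized Bland-Altman style: differences d = IPS - FP, mean
of differences (MoD, the bias), 2S = 1.96 sample SDs of d (the half-width
from MoD to each limit of agreement), a one-sample t-test of MoD against
zero, and a least-squares regression of d on the pair mean quantifying how
bias grows with force magnitude.  Calibration performance per subject is
evaluated with stratified two-fold cross-validation: each fold holds one
trial of each walking speed, giving exactly 2^3 = 8 distinct splits.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from scipy.signal import find_peaks

from .timeseries import SampledSignal

FP_PEAK_SPLIT_PCT = 30.0
IPS_MIN_PEAK_WIDTH_S = 0.05
LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class CyclePeaks:
    """Peaks of one instrument within one gait cycle (values in the
    signal's unit, times on the FP clock)."""

    pk1: float
    pk2: float
    t1: float
    t2: float
    max_value: float

    def __post_init__(self) -> None:
        if not self.t1 < self.t2:
            raise ValueError("weight-acceptance peak must precede push-off peak")


def extract_2pk(
    cycle_force: SampledSignal,
    instrument: str,
    cycle_start: float | None = None,
    cycle_end: float | None = None,
    min_width_s: float = IPS_MIN_PEAK_WIDTH_S,
) -> CyclePeaks | None:
    """Weight-acceptance and push-off peaks of one cycle.

    ``instrument="fp"`` applies the 30 %-of-cycle split rule;
    ``instrument="ips"`` takes the two largest local maxima with width at
    half prominence above ``min_width_s``, ordered by time, and returns
    ``None`` when fewer than two qualify (the cycle is then excluded from
    the 2PK assessment but not from MAX).
    """
    if len(cycle_force) == 0:
        raise ValueError("empty cycle")
    t = cycle_force.t
    f = cycle_force.values
    t0 = t[0] if cycle_start is None else cycle_start
    t1 = t[-1] if cycle_end is None else cycle_end

    if instrument == "fp":
        split = t0 + (t1 - t0) * FP_PEAK_SPLIT_PCT / 100.0
        early = t < split
        if not early.any() or early.all():
            return None
        i1 = int(np.argmax(f[early]))
        late = ~early
        i2 = int(np.argmax(f[late])) + int(np.count_nonzero(early))
        return CyclePeaks(pk1=float(f[i1]), pk2=float(f[i2]),
                          t1=float(t[i1]), t2=float(t[i2]),
                          max_value=float(np.max(f)))
    if instrument == "ips":
        if len(t) < 3:
            return None
        rate = 1.0 / float(np.median(np.diff(t)))
        locs, props = find_peaks(f, width=min_width_s * rate, rel_height=0.5)
        if len(locs) < 2:
            return None
        top2 = locs[np.argsort(f[locs])[-2:]]
        top2.sort()
        return CyclePeaks(pk1=float(f[top2[0]]), pk2=float(f[top2[1]]),
                          t1=float(t[top2[0]]), t2=float(t[top2[1]]),
                          max_value=float(np.max(f)))
    raise ValueError(f"instrument must be 'fp' or 'ips', got {instrument!r}")


def extract_max(cycle_force: SampledSignal) -> float:
    """Absolute maximum force within a gait cycle."""
    if len(cycle_force) == 0:
        raise ValueError("empty cycle")
    return float(np.max(cycle_force.values))


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bland-Altman agreement summary for paired IPS/FP measurements."""

    mod: float          # mean of differences (IPS - FP), %BW
    sd_diff: float      # sample SD of differences, %BW
    two_s: float        # 1.96 * sd_diff
    loa_low: float
    loa_high: float
    p_value_mod_vs_zero: float
    n_pairs: int
    slope: float        # regression of d on pair mean
    intercept: float    # %BW
    resid_sd: float     # SD about the regression line, %BW


def bland_altman(ips: np.ndarray, fp: np.ndarray) -> BlandAltmanResult:
    """Bland-Altman statistics on paired measurements (same unit, %BW)."""
    ips = np.asarray(ips, dtype=float)
    fp = np.asarray(fp, dtype=float)
    if ips.shape != fp.shape or ips.ndim != 1:
        raise ValueError("ips and fp must be paired 1-D arrays")
    n = len(ips)
    if n < 3:
        raise ValueError("Bland-Altman needs at least 3 pairs")
    d = ips - fp
    mod = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    two_s = LOA_MULTIPLIER * sd
    if sd > 0:
        p = float(stats.ttest_1samp(d, 0.0).pvalue)
    else:
        p = 1.0 if mod == 0 else 0.0
    mean_pair = (ips + fp) / 2.0
    if np.ptp(mean_pair) > 0:
        reg = stats.linregress(mean_pair, d)
        slope, intercept = float(reg.slope), float(reg.intercept)
        resid = d - (slope * mean_pair + intercept)
        resid_sd = float(np.std(resid, ddof=2)) if n > 2 else float("nan")
    else:
        slope, intercept, resid_sd = 0.0, mod, sd
    return BlandAltmanResult(
        mod=mod, sd_diff=sd, two_s=two_s,
        loa_low=mod - two_s, loa_high=mod + two_s,
        p_value_mod_vs_zero=p, n_pairs=n,
        slope=slope, intercept=intercept, resid_sd=resid_sd)


@dataclass(frozen=True)
class CrossValidationResult:
    """Per-iteration Bland-Altman results and their aggregate."""

    iterations: tuple  # of dict: assessment -> BlandAltmanResult
    splits: tuple      # of (calibration trial indices, test trial indices)
    representative_subset: int = -1

    def __post_init__(self) -> None:
        if len(self.iterations) != len(self.splits):
            raise ValueError("one split per iteration required")

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)

    def summary(self, assessment: str) -> dict:
        """Mean +/- SD of MoD and 2S across iterations."""
        mods = np.array([it[assessment].mod for it in self.iterations])
        twos = np.array([it[assessment].two_s for it in self.iterations])
        return {
            "mod_mean": float(np.mean(mods)),
            "mod_sd": float(np.std(mods, ddof=1)),
            "two_s_mean": float(np.mean(twos)),
            "two_s_sd": float(np.std(twos, ddof=1)),
        }


def enumerate_stratified_splits(speeds: Sequence[float]) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All fold assignments with one trial per speed in each fold.

    ``speeds`` lists each trial's walking speed; exactly two trials per
    speed are required.  With three speeds this yields the 2^3 = 8
    distinct calibration/test splits.
    """
    speeds = list(speeds)
    by_speed: dict[float, list[int]] = {}
    for i, s in enumerate(speeds):
        by_speed.setdefault(s, []).append(i)
    for s, idxs in by_speed.items():
        if len(idxs) != 2:
            raise ValueError(
                f"stratification requires exactly 2 trials per speed; "
                f"speed {s} has {len(idxs)}")
    keys = sorted(by_speed)
    splits = []
    for choice in itertools.product((0, 1), repeat=len(keys)):
        cal = tuple(by_speed[k][c] for k, c in zip(keys, choice))
        test = tuple(by_speed[k][1 - c] for k, c in zip(keys, choice))
        splits.append((cal, test))
    return splits


def stratified_two_fold_cv(
    trials: Sequence,
    speeds: Sequence[float],
    analysis: Callable[[Sequence, Sequence], dict],
) -> CrossValidationResult:
    """Run ``analysis(calibration_trials, test_trials)`` over every
    stratified split and collect the per-iteration results.

    ``analysis`` must return a mapping from assessment name (e.g. "2PK",
    "MAX") to :class:`BlandAltmanResult`.
    """
    if len(trials) != len(speeds):
        raise ValueError("one speed per trial required")
    splits = enumerate_stratified_splits(speeds)
    iterations = []
    for cal_idx, test_idx in splits:
        res = analysis([trials[i] for i in cal_idx], [trials[i] for i in test_idx])
        iterations.append(dict(res))
    cv = CrossValidationResult(iterations=tuple(iterations), splits=tuple(splits))
    rep = select_representative_subset(cv)
    return CrossValidationResult(iterations=cv.iterations, splits=cv.splits,
                                 representative_subset=rep)


def _normal_overlap(m1: float, s1: float, m2: float, s2: float) -> float:
    """Overlap coefficient of two normal densities (integral of their min)."""
    eps = 1e-12
    s1, s2 = max(s1, eps), max(s2, eps)
    if abs(s1 - s2) < eps:
        return float(2 * stats.norm.cdf(-abs(m1 - m2) / (2 * s1)))
    # densities cross where the log-pdfs are equal: quadratic in x
    a = 1 / (2 * s2 ** 2) - 1 / (2 * s1 ** 2)
    b = m1 / s1 ** 2 - m2 / s2 ** 2
    c = m2 ** 2 / (2 * s2 ** 2) - m1 ** 2 / (2 * s1 ** 2) + np.log(s2 / s1)
    disc = b ** 2 - 4 * a * c
    if disc <= 0:
        return 1.0
    x1, x2 = sorted(((-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)))
    n1, n2 = stats.norm(m1, s1), stats.norm(m2, s2)
    # integrate min(pdf1, pdf2) over the three regions
    total = 0.0
    mids = [x1 - 1.0, (x1 + x2) / 2, x2 + 1.0]
    bounds = [(-np.inf, x1), (x1, x2), (x2, np.inf)]
    for mid, (lo, hi) in zip(mids, bounds):
        lower = n1 if n1.pdf(mid) <= n2.pdf(mid) else n2
        total += lower.cdf(hi) - lower.cdf(lo)
    return float(min(total, 1.0))


def select_representative_subset(
    cv: CrossValidationResult,
    assessment: str = "MAX",
) -> int:
    """Iteration whose (MoD, 2S) normal distribution overlaps the mean
    cross-validation distribution the most (ties -> lowest index)."""
    summ = cv.summary(assessment)
    mean_mod = summ["mod_mean"]
    mean_sd = summ["two_s_mean"] / LOA_MULTIPLIER
    best_idx, best_ovl = 0, -1.0
    for i, it in enumerate(cv.iterations):
        ba = it[assessment]
        ovl = _normal_overlap(ba.mod, ba.two_s / LOA_MULTIPLIER, mean_mod, mean_sd)
        if ovl > best_ovl + 1e-15:
            best_idx, best_ovl = i, ovl
    return best_idx
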