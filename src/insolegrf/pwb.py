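"""Partial-weight-bearing (PWB) overload-detection simulation.

Maximum per-cycle forces under a 50 %BW PWB instruction are modeled as
F ~ Normal(50, 25^2) %BW.  The sensor's error for a given true force is
drawn from the Bland-Altman difference-versus-magnitude regression line,
D | F ~ Normal(s*F + b, sigma_e^2), and the sensor measurement is
M = F + D.  Both F and M are classified against the 50 %BW limit;
sensitivity is the fraction of truly-below-limit forces the sensor also
reads as below, specificity the same for above.

Because (F, M) is jointly bivariate normal, both rates have a closed form
through the bivariate normal CDF; :func:`analytic_pwb` is the exact oracle
against which the Monte-Carlo engine is checked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

_CHUNK = 2_000_000  # draws per Monte-Carlo block


@dataclass(frozen=True)
class PWBConfig:
    """Configuration of one PWB overload-detection simulation."""

    mu_f: float = 50.0       # mean maximum force, %BW
    sigma_f: float = 25.0    # SD of maximum force, %BW
    limit: float = 50.0      # PWB prescription limit, %BW
    n_draws: int = 10_000_000
    slope: float = 0.0       # s: error-model slope vs true force
    intercept: float = 0.0   # b, %BW
    resid_sd: float = 0.0    # sigma_e, %BW
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_f <= 0:
            raise ValueError("sigma_f must be > 0")
        if self.resid_sd < 0:
            raise ValueError("resid_sd must be >= 0")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


@dataclass(frozen=True)
class PWBResult:
    """Sensitivity/specificity of overload classification.

    For the Monte-Carlo engine the 2x2 table counts are integers summing
    to ``n_draws`` and the rates reproduce exactly from them; the analytic
    oracle reports zero standard errors and no counts.
    """

    sensitivity: float
    specificity: float
    se_sensitivity: float
    se_specificity: float
    n_true_below: int
    n_true_above: int
    n_below_correct: int
    n_above_correct: int

    @property
    def counts(self) -> tuple[int, int, int, int]:
        """(below&correct, below&missed, above&correct, above&missed)."""
        return (self.n_below_correct, self.n_true_below - self.n_below_correct,
                self.n_above_correct, self.n_true_above - self.n_above_correct)


def simulate_pwb(cfg: PWBConfig) -> PWBResult:
    """Monte-Carlo simulation of the PWB classifier.

    Ties at exactly the limit are classified as "above" (a measure-zero
    convention fixed for bit-reproducibility).  Deterministic given the
    config seed.
    """
    rng = np.random.default_rng(cfg.seed)
    n_tb = n_ta = n_bc = n_ac = 0
    remaining = cfg.n_draws
    while remaining > 0:
        n = min(remaining, _CHUNK)
        f = rng.normal(cfg.mu_f, cfg.sigma_f, n)
        d = cfg.slope * f + cfg.intercept
        if cfg.resid_sd > 0:
            d = d + rng.normal(0.0, cfg.resid_sd, n)
        m = f + d
        true_below = f < cfg.limit
        meas_below = m < cfg.limit
        n_tb += int(np.count_nonzero(true_below))
        n_ta += int(np.count_nonzero(~true_below))
        n_bc += int(np.count_nonzero(true_below & meas_below))
        n_ac += int(np.count_nonzero(~true_below & ~meas_below))
        remaining -= n
    sens = n_bc / n_tb if n_tb else float("nan")
    spec = n_ac / n_ta if n_ta else float("nan")
    se_sens = float(np.sqrt(sens * (1 - sens) / n_tb)) if n_tb else float("nan")
    se_spec = float(np.sqrt(spec * (1 - spec) / n_ta)) if n_ta else float("nan")
    return PWBResult(sensitivity=float(sens), specificity=float(spec),
                     se_sensitivity=se_sens, se_specificity=se_spec,
                     n_true_below=n_tb, n_true_above=n_ta,
                     n_below_correct=n_bc, n_above_correct=n_ac)


def analytic_pwb(cfg: PWBConfig) -> PWBResult:
    """Closed-form sensitivity/specificity via the bivariate normal CDF.

    With M = (1 + s) F + b + eps, (F, M) is bivariate normal with means
    (mu, (1+s) mu + b), variances (sf^2, (1+s)^2 sf^2 + se^2) and
    covariance (1+s) sf^2; the rates are conditional orthant
    probabilities.  Degenerate (zero-residual) error models reduce to
    one-dimensional threshold formulas.
    """
    mu, sf, L = cfg.mu_f, cfg.sigma_f, cfg.limit
    s1 = 1.0 + cfg.slope
    b, se = cfg.intercept, cfg.resid_sd
    p_below = float(stats.norm.cdf(L, mu, sf))
    p_above = 1.0 - p_below

    if se <= 1e-6 * sf:  # (near-)deterministic error model
        # M is a deterministic affine function of F
        if s1 > 0:
            thr = (L - b) / s1  # M < L  <=>  F < thr
            p_bb = float(stats.norm.cdf(min(L, thr), mu, sf))
            p_aa = 1.0 - float(stats.norm.cdf(max(L, thr), mu, sf))
        elif s1 < 0:
            thr = (L - b) / s1  # M < L  <=>  F > thr
            p_bb = max(p_below - float(stats.norm.cdf(thr, mu, sf)), 0.0)
            p_aa = max(float(stats.norm.cdf(thr, mu, sf)) - p_below, 0.0)
        else:  # M = b constant; ties at b == L count as "above"
            p_bb = p_below if b < L else 0.0
            p_aa = p_above if b >= L else 0.0
    else:
        mean = np.array([mu, s1 * mu + b])
        cov = np.array([[sf ** 2, s1 * sf ** 2],
                        [s1 * sf ** 2, s1 ** 2 * sf ** 2 + se ** 2]])
        p_bb = float(stats.multivariate_normal(
            mean=mean, cov=cov, allow_singular=True).cdf([L, L]))
        p_m_below = float(stats.norm.cdf(L, mean[1], np.sqrt(cov[1, 1])))
        p_aa = 1.0 - p_below - p_m_below + p_bb

    sens = p_bb / p_below if p_below > 0 else float("nan")
    spec = p_aa / p_above if p_above > 0 else float("nan")
    return PWBResult(sensitivity=float(np.clip(sens, 0, 1)),
                     specificity=float(np.clip(spec, 0, 1)),
                     se_sensitivity=0.0, se_specificity=0.0,
                     n_true_below=0, n_true_above=0,
                     n_below_correct=0, n_above_correct=0)


def pwb_from_agreement(ba, **overrides) -> tuple[PWBResult, PWBResult]:
    """Run both PWB engines from a fitted Bland-Altman error model.

    ``ba`` must carry the difference-versus-magnitude regression fields
    (slope, intercept, resid_sd).  Keyword overrides update any
    :class:`PWBConfig` field.  Returns (monte_carlo, analytic).
    """
    for name in ("slope", "intercept", "resid_sd"):
        v = getattr(ba, name, None)
        if v is None or not np.isfinite(v):
            raise ValueError(f"agreement result lacks a finite {name!r}")
    kwargs = dict(slope=ba.slope, intercept=ba.intercept, resid_sd=ba.resid_sd)
    kwargs.update(overrides)
    cfg = PWBConfig(**kwargs)
    return simulate_pwb(cfg), analytic_pwb(cfg)
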