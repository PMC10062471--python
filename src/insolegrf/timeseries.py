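"""Timestamped scalar series with unit tags.

Every stage of the pipeline passes force (N or %BW) and resistance (ohm)
records around as :class:`SampledSignal`.  The container enforces strictly
increasing timestamps and carries a unit tag so that stages cannot silently
mix newtons with body-weight-normalized force.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: recognised unit tags
UNITS = ("N", "%BW", "ohm", "dimensionless")

IRREGULAR = "irregular"


@dataclass(frozen=True)
class SampledSignal:
    """A scalar time series.

    Parameters
    ----------
    t:
        Timestamps in seconds, strictly increasing.
    values:
        Sample values, same length as ``t``.
    unit:
        One of ``"N"``, ``"%BW"``, ``"ohm"``, ``"dimensionless"``.
    nominal_rate:
        Sampling rate in Hz for uniformly sampled records, or the string
        ``"irregular"``.
    """

    t: np.ndarray
    values: np.ndarray
    unit: str
    nominal_rate: float | str = IRREGULAR

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.ndim != 1:
            raise ValueError("timestamps and values must be 1-D")
        if len(t) != len(v):
            raise ValueError(
                f"length mismatch: {len(t)} timestamps vs {len(v)} values"
            )
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise ValueError(f"timestamps not strictly increasing at index {bad}")
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Time spanned by the record, in seconds."""
        if len(self.t) < 2:
            return 0.0
        return float(self.t[-1] - self.t[0])

    @property
    def is_uniform(self) -> bool:
        return self.nominal_rate != IRREGULAR

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "SampledSignal":
        """Copy of this signal with new values (same time base)."""
        return replace(self, values=np.asarray(values, float),
                       unit=self.unit if unit is None else unit)

    def with_time(self, t: np.ndarray, nominal_rate: float | str | None = None) -> "SampledSignal":
        rate = self.nominal_rate if nominal_rate is None else nominal_rate
        return replace(self, t=np.asarray(t, float), nominal_rate=rate)

    def crop(self, t0: float, t1: float) -> "SampledSignal":
        """Samples with t0 <= t < t1."""
        m = (self.t >= t0) & (self.t < t1)
        return replace(self, t=self.t[m], values=self.values[m])


def uniform(values: np.ndarray, rate: float, unit: str, t0: float = 0.0) -> SampledSignal:
    """Build a uniformly sampled signal starting at ``t0``."""
    values = np.asarray(values, dtype=float)
    t = t0 + np.arange(len(values)) / float(rate)
    return SampledSignal(t=t, values=values, unit=unit, nominal_rate=float(rate))


def require_same_grid(*signals: SampledSignal) -> None:
    """Raise if the signals are not sampled on the same time grid."""
    ref = signals[0]
    for s in signals[1:]:
        if len(s) != len(ref) or not np.allclose(s.t, ref.t, rtol=0, atol=1e-9):
            raise ValueError("signals are not on a common time grid")


def require_same_unit(*signals: SampledSignal) -> str:
    units = {s.unit for s in signals}
    if len(units) != 1:
        raise ValueError(f"mixed units {sorted(units)} are not allowed here")
    return signals[0].unit
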