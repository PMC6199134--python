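"""Interval-variability descriptors for interbreath/interbeat series.

The Poincare "major and minor axes" are mapped to the standard SD2/SD1
dispersions parallel/perpendicular to the identity line of the first-return
plot, and the "estimated area" to the fitted ellipse area pi*SD1*SD2.  Both
the axis pair and the product are emitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import InsufficientDataError

__all__ = ["IntervalSeries", "VariabilityDescriptors", "descriptors",
           "intervals_from_times"]


@dataclass(frozen=True)
class IntervalSeries:
    intervals: np.ndarray  # seconds, successive differences of event times
    source: str = "breath"  # {"breath", "beat"}

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals",
                           np.asarray(self.intervals, dtype=float))
        if self.intervals.size and np.any(self.intervals <= 0):
            raise ValueError("all intervals must be strictly positive")

    def __len__(self) -> int:
        return int(self.intervals.size)


def intervals_from_times(times: np.ndarray, source: str = "breath") -> IntervalSeries:
    return IntervalSeries(np.diff(np.asarray(times, dtype=float)), source)


@dataclass(frozen=True)
class VariabilityDescriptors:
    sd: float  # s, sample SD (n-1)
    rmssd: float  # s
    cv: float  # unitless
    sd1: float  # s, short-axis dispersion = rmssd/sqrt(2)
    sd2: float  # s, long-axis dispersion
    sd_product: float  # s^2, SD1*SD2 ("SDxSD")
    poincare_area: float  # s^2, pi*SD1*SD2

    def as_dict(self, prefix: str = "") -> dict:
        return {prefix + k: getattr(self, k) for k in
                ("sd", "rmssd", "cv", "sd1", "sd2", "sd_product",
                 "poincare_area")}


def descriptors(series: IntervalSeries) -> VariabilityDescriptors:
    """Time-domain variability of an interval series (length >= 3).

    sd is the n-1 sample standard deviation, cv = sd/mean, rmssd the root
    mean square of successive interval differences, sd1 = rmssd/sqrt(2),
    sd2 = sqrt(max(0, 2 sd^2 - sd1^2)).
    """
    x = series.intervals
    if x.size < 3:
        raise InsufficientDataError(
            f"need >= 3 intervals, got {x.size}")
    sd = float(np.std(x, ddof=1))
    mean = float(np.mean(x))
    cv = sd / mean
    rmssd = float(np.sqrt(np.mean(np.diff(x) ** 2)))
    sd1 = rmssd / math.sqrt(2.0)
    sd2 = math.sqrt(max(0.0, 2.0 * sd * sd - sd1 * sd1))
    return VariabilityDescriptors(
        sd=sd, rmssd=rmssd, cv=cv, sd1=sd1, sd2=sd2,
        sd_product=sd1 * sd2, poincare_area=math.pi * sd1 * sd2)
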