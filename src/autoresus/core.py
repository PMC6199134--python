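"""Shared domain types for the autoresuscitation pipeline.

Time is expressed in seconds from record start throughout; windows are
closed-open ``[start, end)``.  Volumes carry the instrument-sheet unit
("printed" microlitre-scale numbers); see :mod:`autoresus.synth` for the
printed-to-physical conversion factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AnalysisError",
    "InsufficientDataError",
    "UndefinedResultError",
    "NoApneaError",
    "SeparationError",
    "AssayTimeline",
    "EventSeries",
    "TraceBundle",
]


class AnalysisError(ValueError):
    """Base class for recoverable analysis failures."""


class InsufficientDataError(AnalysisError):
    """Raised when fewer observations are available than a method requires."""


class UndefinedResultError(AnalysisError):
    """Raised when a quantity is undefined for the given input (e.g. empty
    event series, zero denominator)."""


class NoApneaError(AnalysisError):
    """Raised when breathing never ceases inside an asphyxia window."""


class SeparationError(AnalysisError):
    """Raised when a logistic fit is degenerate (complete separation)."""


@dataclass(frozen=True)
class AssayTimeline:
    """Annotation of the repeated-asphyxia assay for one recording.

    The record starts with an acclimation period in room air, followed by an
    injection at ``cno_time``, a post-injection settling period, and then
    ``n_bouts`` asphyxia bouts.  Each bout consists of a pre-bout baseline
    search window, an asphyxia window, and a fixed-length recovery window
    starting at the end of asphyxia.
    """

    acclimation_window: tuple[float, float]
    cno_time: float
    pre_cno_baseline_window: tuple[float, float]
    pre_bout_baseline_windows: tuple[tuple[float, float], ...]
    asphyxia_windows: tuple[tuple[float, float], ...]
    recovery_window_duration: float = 330.0

    def __post_init__(self) -> None:
        if self.recovery_window_duration <= 0:
            raise ValueError("recovery_window_duration must be positive")
        if len(self.pre_bout_baseline_windows) != len(self.asphyxia_windows):
            raise ValueError("one pre-bout baseline window required per bout")
        for w in self._all_windows():
            if not w[1] > w[0]:
                raise ValueError(f"degenerate window {w}")
        ordered = self._all_windows()
        for prev, nxt in zip(ordered, ordered[1:]):
            if nxt[0] < prev[1] - 1e-9:
                raise ValueError("timeline windows overlap or are unordered")

    def _all_windows(self) -> list[tuple[float, float]]:
        wins = [self.acclimation_window]
        for base, asp in zip(self.pre_bout_baseline_windows, self.asphyxia_windows):
            wins.append(base)
            wins.append(asp)
            wins.append((asp[1], asp[1] + self.recovery_window_duration))
        return wins

    @property
    def n_bouts(self) -> int:
        return len(self.asphyxia_windows)

    @property
    def recovery_windows(self) -> tuple[tuple[float, float], ...]:
        return tuple(
            (a[1], a[1] + self.recovery_window_duration) for a in self.asphyxia_windows
        )

    @property
    def duration(self) -> float:
        return self.recovery_windows[-1][1] if self.asphyxia_windows else self.acclimation_window[1]

    def to_dict(self) -> dict:
        return {
            "acclimation_window": list(self.acclimation_window),
            "cno_time": self.cno_time,
            "pre_cno_baseline_window": list(self.pre_cno_baseline_window),
            "pre_bout_baseline_windows": [list(w) for w in self.pre_bout_baseline_windows],
            "asphyxia_windows": [list(w) for w in self.asphyxia_windows],
            "recovery_window_duration": self.recovery_window_duration,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AssayTimeline":
        return cls(
            acclimation_window=tuple(d["acclimation_window"]),
            cno_time=float(d["cno_time"]),
            pre_cno_baseline_window=tuple(d["pre_cno_baseline_window"]),
            pre_bout_baseline_windows=tuple(tuple(w) for w in d["pre_bout_baseline_windows"]),
            asphyxia_windows=tuple(tuple(w) for w in d["asphyxia_windows"]),
            recovery_window_duration=float(d["recovery_window_duration"]),
        )


@dataclass
class EventSeries:
    """Detected point events (breaths, beats, or gasps) on one channel.

    ``integrals`` is the signed area of the deflection lobe for breaths and
    gasps; it is empty for beats.
    """

    kind: str  # {"breath", "beat", "gasp"}
    times: np.ndarray
    amplitudes: np.ndarray
    integrals: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.integrals = np.asarray(self.integrals, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if self.amplitudes.size not in (0, self.times.size):
            raise ValueError("amplitudes length mismatch")
        if self.integrals.size not in (0, self.times.size):
            raise ValueError("integrals length mismatch")

    def __len__(self) -> int:
        return int(self.times.size)

    @classmethod
    def empty(cls, kind: str) -> "EventSeries":
        z = np.empty(0)
        return cls(kind, z, z.copy(), z.copy())

    def restrict(self, window: Sequence[float]) -> "EventSeries":
        """Events with ``start <= t < end``."""
        start, end = window
        m = (self.times >= start) & (self.times < end)
        amps = self.amplitudes[m] if self.amplitudes.size else self.amplitudes
        ints = self.integrals[m] if self.integrals.size else self.integrals
        return EventSeries(self.kind, self.times[m], amps, ints)

    @property
    def intervals(self) -> np.ndarray:
        return np.diff(self.times)


@dataclass
class TraceBundle:
    """Multichannel uniformly sampled physiological record for one pup.

    Channels: respiratory ``pressure`` (transducer units), ``beat_marker``
    impulse train, chamber ``o2_fraction`` (0-1, mixed expired side), and gas
    ``flow`` (ml/min).
    """

    sampling_rate: float
    pressure: np.ndarray
    beat_marker: np.ndarray
    o2_fraction: np.ndarray
    flow: np.ndarray
    timeline: AssayTimeline
    body_weight: float
    calibration: float = 0.01  # ml of air per unit*s of integrated pressure
    f_io2: float = 0.21
    t_a: float = 35.5  # chamber ambient temperature, deg C (held constant)
    t_b: float = 35.5
    pup_id: str = "pup"
    genotype: str = "experimental"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.body_weight <= 0:
            raise ValueError("body_weight must be positive")
        n = len(self.pressure)
        for name in ("beat_marker", "o2_fraction", "flow"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name} length differs from pressure")

    @property
    def n_samples(self) -> int:
        return int(len(self.pressure))

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def sample_slice(self, window: Sequence[float]) -> slice:
        """Index slice covering ``[start, end)`` in seconds."""
        start, end = window
        i0 = max(0, int(np.ceil(start * self.sampling_rate - 1e-9)))
        i1 = min(self.n_samples, int(np.ceil(end * self.sampling_rate - 1e-9)))
        return slice(i0, max(i0, i1))
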