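"""Event detection and baseline cardiorespiratory measures.

Breath and beat detection use prominence-thresholded local-maximum search
with a refractory period, thresholds expressed relative to a robust noise
scale so detection is invariant to uniform amplitude scaling of the channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .core import EventSeries, TraceBundle, UndefinedResultError

__all__ = [
    "BaselineMeasures",
    "robust_noise_sd",
    "detect_breaths",
    "detect_beats",
    "tidal_volume",
    "minute_ventilation",
    "oxygen_consumption",
    "select_stable_window",
    "baseline_measures",
    "mean_rate",
]


def robust_noise_sd(x: np.ndarray) -> float:
    """Noise scale via the median absolute deviation (Gaussian-consistent)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def _lobe_integral(x: np.ndarray, peak: int, dt: float) -> float:
    """Signed area of the deflection lobe around ``peak`` above baseline
    (zero after median subtraction), bounded by the nearest non-positive
    samples on each side."""
    left = peak
    while left > 0 and x[left - 1] > 0:
        left -= 1
    right = peak
    n = len(x)
    while right < n - 1 and x[right + 1] > 0:
        right += 1
    return float(np.trapezoid(x[left:right + 1], dx=dt))


def _subsample_offsets(x: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """Parabolic-vertex refinement of peak positions (fraction of a sample).

    Event timing at the recovery threshold is ill-conditioned (interval
    decrements per event are far below one sample period), so grid-snapped
    peak times are not good enough; the three-point vertex restores
    sub-sample accuracy on smooth deflections.
    """
    offsets = np.zeros(peaks.size)
    inner = (peaks > 0) & (peaks < x.size - 1)
    p = peaks[inner]
    denom = x[p - 1] - 2.0 * x[p] + x[p + 1]
    good = denom < 0
    delta = np.zeros(p.size)
    delta[good] = 0.5 * (x[p - 1] - x[p + 1])[good] / denom[good]
    offsets[inner] = np.clip(delta, -0.5, 0.5)
    return offsets


def _detect_peaks(trace: TraceBundle, channel: np.ndarray, window,
                  height: float, prominence: float,
                  refractory_fraction: float = 0.25,
                  with_integrals: bool = True) -> EventSeries:
    sl = trace.sample_slice(window)
    x = channel[sl]
    kind = "breath" if with_integrals else "beat"
    if x.size < 3:
        return EventSeries.empty(kind)
    x = x - np.median(x)
    dt = 1.0 / trace.sampling_rate

    peaks, _ = find_peaks(x, height=height, prominence=prominence)
    if peaks.size == 0:
        return EventSeries.empty(kind)
    if peaks.size > 1:
        # refractory pass: 0.25x the typical inter-event interval
        distance = max(1, int(refractory_fraction * np.median(np.diff(peaks))))
        peaks, _ = find_peaks(x, height=height, prominence=prominence,
                              distance=distance)
    times = (sl.start + peaks + _subsample_offsets(x, peaks)) * dt
    amps = x[peaks]
    if with_integrals:
        integrals = np.array([_lobe_integral(x, p, dt) for p in peaks])
    else:
        integrals = np.empty(0)
    return EventSeries(kind, times, amps, integrals)


def detect_breaths(trace: TraceBundle, window, prominence_factor: float = 4.0,
                   refractory_fraction: float = 0.25) -> EventSeries:
    """One event per pressure deflection whose height and prominence exceed
    ``prominence_factor`` times the robust noise SD of the window.

    An empty or flat window yields an empty series.
    """
    sl = trace.sample_slice(window)
    x = trace.pressure[sl]
    if x.size < 3:
        return EventSeries.empty("breath")
    thr = max(prominence_factor * robust_noise_sd(x), 1e-12)
    return _detect_peaks(trace, trace.pressure, window, height=thr,
                         prominence=thr, refractory_fraction=refractory_fraction)


def detect_beats(trace: TraceBundle, window,
                 refractory_fraction: float = 0.25) -> EventSeries:
    """Impulse detection on the cardiac marker channel; threshold is half the
    record-wide impulse amplitude, so a window of programmed asystole yields
    an empty series."""
    amp = float(np.max(trace.beat_marker)) if trace.beat_marker.size else 0.0
    if amp <= 0:
        return EventSeries.empty("beat")
    thr = amp / 2.0
    series = _detect_peaks(trace, trace.beat_marker, window, height=thr,
                           prominence=thr / 2.0,
                           refractory_fraction=refractory_fraction,
                           with_integrals=False)
    series.kind = "beat"
    return series


def tidal_volume(breaths: EventSeries, calibration: float,
                 body_weight: float) -> float:
    """Mass-normalized tidal volume (ml/g): mean per-breath integral times
    the pressure calibration (ml per unit*s), divided by body weight."""
    if calibration <= 0:
        raise ValueError("calibration must be positive")
    if body_weight <= 0:
        raise ValueError("body_weight must be positive")
    if len(breaths) == 0 or breaths.integrals.size == 0:
        raise UndefinedResultError("tidal volume undefined for empty breath series")
    return float(np.mean(breaths.integrals)) * calibration / body_weight


def minute_ventilation(f: float, v_t: float) -> float:
    """VE = f * V_T."""
    if f < 0 or v_t < 0:
        raise ValueError("rate and tidal volume must be non-negative")
    return f * v_t


def oxygen_consumption(flow: float, f_io2: float, f_eo2: float,
                       body_weight: float) -> float:
    """VO2 = flow * (F_IO2 - F_EO2) / body weight."""
    if not (0.0 <= f_io2 <= 1.0):
        raise ValueError("f_io2 must be a fraction in [0, 1]")
    if f_eo2 < 0 or f_eo2 > f_io2:
        raise UndefinedResultError(
            f"invalid measurement: F_EO2={f_eo2} outside [0, F_IO2={f_io2}]")
    if body_weight <= 0:
        raise ValueError("body_weight must be positive")
    return flow * (f_io2 - f_eo2) / body_weight


def select_stable_window(trace: TraceBundle, search_window,
                         duration: float = 30.0,
                         artifact_factor: float = 8.0,
                         scale_percentile: float = 95.0,
                         score_threshold: float = 0.0,
                         step: float = 1.0) -> tuple[tuple[float, float], bool]:
    """Earliest ``duration``-second sub-window whose movement-artifact score
    does not exceed ``score_threshold``.

    The artifact score of a sub-window is the fraction of samples whose
    deviation from the search-window median exceeds ``artifact_factor`` times
    a robust full-signal scale (the ``scale_percentile`` of absolute
    deviations, which tracks the eupneic deflection envelope rather than the
    noise floor, so ordinary breaths do not count as artifacts).  If no
    sub-window passes, the minimum-score window is returned with a warning
    flag (second element True).
    """
    start, end = search_window
    if end - start < duration:
        raise ValueError("search window shorter than requested duration")
    sl = trace.sample_slice(search_window)
    x = trace.pressure[sl]
    dev = np.abs(x - np.median(x))
    scale = float(np.percentile(dev, scale_percentile))
    mask = dev > artifact_factor * max(scale, 1e-12)

    fs = trace.sampling_rate
    w = int(round(duration * fs))
    stride = max(1, int(round(step * fs)))
    csum = np.concatenate([[0], np.cumsum(mask)])
    best_i, best_score = 0, np.inf
    for i in range(0, x.size - w + 1, stride):
        score = (csum[i + w] - csum[i]) / w
        if score <= score_threshold:
            t0 = start + i / fs
            return (t0, t0 + duration), False
        if score < best_score:
            best_i, best_score = i, score
    t0 = start + best_i / fs
    return (t0, t0 + duration), True


def mean_rate(events: EventSeries) -> float:
    """Mean event rate over the series span, per minute."""
    if len(events) < 2:
        raise UndefinedResultError("rate undefined for fewer than 2 events")
    span = events.times[-1] - events.times[0]
    return 60.0 * (len(events) - 1) / span


@dataclass(frozen=True)
class BaselineMeasures:
    """Baseline cardiorespiratory measures over one window.

    Volumes are in physical ml (per g where mass-normalized); VE == f * V_T
    by construction.
    """

    f: float  # breaths/min
    V_T: float  # ml/g
    VE: float  # ml/min/g
    HR: float  # beats/min
    VO2: float  # ml/min/g
    VEVO2: float
    window: tuple[float, float]
    n_breaths: int = 0
    n_beats: int = 0

    def as_dict(self) -> dict:
        return {
            "f": self.f, "V_T": self.V_T, "VE": self.VE, "HR": self.HR,
            "VO2": self.VO2, "VEVO2": self.VEVO2,
            "window_start": self.window[0], "window_end": self.window[1],
        }


def baseline_measures(trace: TraceBundle, window) -> BaselineMeasures:
    """Compose detection and the rate/volume formulas over one window."""
    breaths = detect_breaths(trace, window)
    if len(breaths) < 2:
        raise UndefinedResultError("too few breaths in baseline window")
    beats = detect_beats(trace, window)
    if len(beats) < 2:
        raise UndefinedResultError("too few beats in baseline window")
    f = mean_rate(breaths)
    v_t = tidal_volume(breaths, trace.calibration, trace.body_weight)
    ve = minute_ventilation(f, v_t)
    hr = mean_rate(beats)
    sl = trace.sample_slice(window)
    f_eo2 = float(np.mean(trace.o2_fraction[sl]))
    flow = float(np.mean(trace.flow[sl]))
    vo2 = oxygen_consumption(flow, trace.f_io2, f_eo2, trace.body_weight)
    if vo2 <= 0:
        raise UndefinedResultError("non-positive oxygen consumption")
    return BaselineMeasures(f=f, V_T=v_t, VE=ve, HR=hr, VO2=vo2,
                            VEVO2=ve / vo2, window=tuple(window),
                            n_breaths=len(breaths), n_beats=len(beats))
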