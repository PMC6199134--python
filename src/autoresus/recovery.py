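"""Per-bout apnea, recovery-latency, and gasp analysis.

tau (for breathing frequency or heart rate) is the time from the end of
asphyxia until the instantaneous rate is sustained for at least ``sustain``
seconds at or above ``fraction`` of the pre-bout baseline; a breathing tau
not achieved within the recording window is censored at ``max_time + 1``
(331 s by default), while an unachieved heart-rate tau is reported as
unrecovered rather than censored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .core import (AssayTimeline, EventSeries, NoApneaError, TraceBundle,
                   UndefinedResultError)
from .signals import _detect_peaks, _lobe_integral, robust_noise_sd

__all__ = [
    "BoutRecovery",
    "GaspProfile",
    "apnea_onset",
    "recovery_latency",
    "detect_gasps",
    "gasp_profile",
    "detect_death",
    "analyze_bout",
]

CENSOR_TAU = 331.0


@dataclass
class BoutRecovery:
    """Recovery metrics for one asphyxia bout of one pup."""

    bout_index: int
    pre_bout_baseline_f: float
    pre_bout_baseline_HR: float
    apnea_latency: float | None
    tau_f: float | None  # s; == CENSOR_TAU when censored
    tau_f_censored: bool
    tau_HR: float | None  # s; None when unrecovered
    tau_HR_unrecovered: bool
    died_this_bout: bool
    transient_HR_recovery_in_fatal_bout: bool = False

    def __post_init__(self) -> None:
        if self.tau_f is not None and self.tau_f < 0.0:
            raise ValueError("tau_f must be non-negative")
        if self.tau_f_censored and self.tau_f is None:
            raise ValueError("a censored tau_f must carry the censor value")


@dataclass
class GaspProfile:
    """First-gasp latency/size and inter-gasp structure for one bout.

    Missing quantities (too few gasps, no beats inside a gap) are left as
    None, never imputed.
    """

    n_gasps: int
    first_gasp_latency: float | None  # s from apnea onset
    first_gasp_size: float | None  # integral / body weight
    inter_gasp_intervals: list[float] = field(default_factory=list)  # I..IV
    mean_hr_between_gasps: list[float | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.first_gasp_latency is not None and self.first_gasp_latency <= 0:
            raise ValueError("first-gasp latency must be positive")
        if len(self.inter_gasp_intervals) > 4:
            raise ValueError("at most four inter-gasp intervals are reported")


def apnea_onset(breaths: EventSeries, asphyxia_window,
                baseline_median_ibi: float | None = None,
                gap_factor: float = 3.0,
                search_extension: float = 60.0) -> float:
    """Time of the last breath after asphyxia onset that is followed by a
    breathing-free gap of at least ``gap_factor`` times the pre-bout median
    interbreath interval.

    Returns the asphyxia start time when no breath at all falls inside the
    search span; raises :class:`NoApneaError` when breathing never ceases.
    """
    a0, a1 = asphyxia_window
    if baseline_median_ibi is None:
        pre = breaths.restrict((a0 - 30.0, a0))
        if len(pre) < 2:
            raise UndefinedResultError("cannot estimate pre-bout interbreath interval")
        baseline_median_ibi = float(np.median(pre.intervals))
    span_end = a1 + search_extension
    t = breaths.times[(breaths.times >= a0) & (breaths.times < span_end)]
    if t.size == 0:
        return float(a0)
    gaps = np.diff(np.concatenate([t, [span_end]]))
    qualifying = np.nonzero(gaps >= gap_factor * baseline_median_ibi)[0]
    if qualifying.size == 0:
        raise NoApneaError("breathing never ceased inside the asphyxia window")
    return float(t[qualifying[0]])


def recovery_latency(events: EventSeries, baseline_rate: float,
                     asphyxia_end: float, fraction: float = 0.63,
                     sustain: float = 3.0, max_time: float = 330.0,
                     censor_value: float | None = None) -> float | None:
    """tau: start of the earliest maximal run of consecutive inter-event
    intervals with instantaneous rate >= ``fraction * baseline_rate`` whose
    span is at least ``sustain`` seconds, measured from ``asphyxia_end``.

    A run already in progress at ``asphyxia_end`` gives tau = 0.  If no
    qualifying run starts within ``max_time``, returns ``censor_value``
    (which may be None for the unrecovered/heart-rate convention).
    """
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    t = events.times
    if t.size < 2:
        return censor_value
    max_interval = 60.0 / (fraction * baseline_rate)
    ok = np.diff(t) <= max_interval

    i = 0
    n = ok.size
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and ok[j + 1]:
            j += 1
        run_start, run_end = t[i], t[j + 1]
        if (run_end > asphyxia_end
                and run_end - run_start >= sustain
                and run_start - asphyxia_end <= max_time):
            return max(0.0, float(run_start - asphyxia_end))
        i = j + 1
    return censor_value


def _rising_o2_start(trace: TraceBundle, from_time: float, until: float,
                     smooth: float = 0.5, sustain: float = 1.0) -> float | None:
    """First time >= from_time at which the smoothed O2 channel rises for at
    least ``sustain`` seconds (asphyxic gas off, chamber refilling)."""
    fs = trace.sampling_rate
    sl = trace.sample_slice((from_time, until))
    x = trace.o2_fraction[sl]
    if x.size < 3:
        return None
    k = max(1, int(smooth * fs))
    kernel = np.ones(k) / k
    xs = np.convolve(x, kernel, mode="same")
    rising = np.diff(xs) > 0
    need = max(1, int(sustain * fs))
    csum = np.concatenate([[0], np.cumsum(rising)])
    for i in range(rising.size - need + 1):
        if csum[i + need] - csum[i] == need:
            return from_time + i / fs
    return None


def detect_gasps(trace: TraceBundle, apnea_onset_time: float,
                 search_end: float | None = None,
                 voltage_threshold: float = 0.002,
                 baseline_amplitude: float | None = None,
                 min_separation: float = 0.3) -> EventSeries:
    """Steeple-like pressure deflections after apnea onset, counted only once
    the O2 channel is rising.

    Amplitude must exceed ``voltage_threshold`` (calibrated transducer
    units); when ``baseline_amplitude`` (typical eupneic deflection height)
    is supplied, gasps must additionally reach twice that height, which
    separates the gasp train from resumed eupneic breaths.  An empty series
    means the pup never gasped (death in primary apnea).
    """
    timeline = trace.timeline
    if search_end is None:
        search_end = trace.duration
        for a0, a1 in timeline.asphyxia_windows:
            if a0 <= apnea_onset_time <= a1:
                search_end = a1 + timeline.recovery_window_duration
                break
    start = _rising_o2_start(trace, apnea_onset_time, search_end)
    if start is None:
        return EventSeries.empty("gasp")

    fs = trace.sampling_rate
    sl = trace.sample_slice((start, search_end))
    x = trace.pressure[sl] - np.median(trace.pressure[sl])
    height = float(voltage_threshold)
    if baseline_amplitude is not None:
        height = max(height, 2.0 * float(baseline_amplitude))
    noise_floor = 4.0 * robust_noise_sd(x)
    height = max(height, noise_floor)
    peaks, _ = find_peaks(x, height=height, prominence=height / 2.0,
                          distance=max(1, int(min_separation * fs)))
    if peaks.size == 0:
        return EventSeries.empty("gasp")
    dt = 1.0 / fs
    times = (sl.start + peaks) * dt
    amps = x[peaks]
    integrals = np.array([_lobe_integral(x, p, dt) for p in peaks])
    return EventSeries("gasp", times, amps, integrals)


def gasp_profile(gasps: EventSeries, beats: EventSeries,
                 apnea_onset_time: float, body_weight: float,
                 max_intervals: int = 4) -> GaspProfile:
    """First-gasp latency and size, inter-gasp intervals I-IV (gaps between
    gasps 1-2 ... 4-5), and the mean heart rate inside each gap."""
    if body_weight <= 0:
        raise ValueError("body_weight must be positive")
    n = len(gasps)
    if n == 0:
        return GaspProfile(n_gasps=0, first_gasp_latency=None,
                           first_gasp_size=None)
    latency = float(gasps.times[0] - apnea_onset_time)
    size = float(gasps.integrals[0]) / body_weight if gasps.integrals.size else None

    intervals: list[float] = []
    hr_between: list[float | None] = []
    for i in range(min(n - 1, max_intervals)):
        g0, g1 = gasps.times[i], gasps.times[i + 1]
        intervals.append(float(g1 - g0))
        bt = beats.times[(beats.times > g0) & (beats.times < g1)]
        if bt.size >= 2:
            hr_between.append(60.0 / float(np.mean(np.diff(bt))))
        else:
            hr_between.append(None)
    return GaspProfile(n_gasps=n, first_gasp_latency=latency,
                       first_gasp_size=size,
                       inter_gasp_intervals=intervals,
                       mean_hr_between_gasps=hr_between)


def detect_death(breaths: EventSeries, beats: EventSeries,
                 timeline: AssayTimeline, record_duration: float,
                 quiet_margin: float = 30.0) -> int | None:
    """Bout index during which all activity permanently ceased, or None.

    A pup is scored as having died when its last breath and last beat both
    precede the end of the record by more than ``quiet_margin`` seconds; the
    fatal bout is the one whose asphyxia-plus-recovery span contains that
    last event.
    """
    last = 0.0
    if len(breaths):
        last = max(last, float(breaths.times[-1]))
    if len(beats):
        last = max(last, float(beats.times[-1]))
    if last >= record_duration - quiet_margin:
        return None
    for k, ((a0, _), (_, rec_end)) in enumerate(
            zip(timeline.asphyxia_windows, timeline.recovery_windows), start=1):
        if a0 <= last <= rec_end:
            return k
    # ceased outside any bout span: attribute to the preceding bout
    for k in range(timeline.n_bouts, 0, -1):
        if last >= timeline.asphyxia_windows[k - 1][0]:
            return k
    return None


def analyze_bout(breaths: EventSeries, beats: EventSeries,
                 timeline: AssayTimeline, bout_index: int,
                 pre_bout_f: float, pre_bout_hr: float,
                 died_this_bout: bool = False,
                 fraction: float = 0.63, sustain: float = 3.0,
                 max_time: float | None = None,
                 gap_factor: float = 3.0) -> BoutRecovery:
    """Assemble per-bout recovery metrics from detected event series."""
    a0, a1 = timeline.asphyxia_windows[bout_index - 1]
    if max_time is None:
        max_time = timeline.recovery_window_duration
    try:
        onset = apnea_onset(breaths, (a0, a1), gap_factor=gap_factor)
        latency = onset - a0
    except (NoApneaError, UndefinedResultError):
        latency = None

    tau_f = recovery_latency(breaths, pre_bout_f, a1, fraction=fraction,
                             sustain=sustain, max_time=max_time,
                             censor_value=None)
    tau_hr = recovery_latency(beats, pre_bout_hr, a1, fraction=fraction,
                              sustain=sustain, max_time=max_time,
                              censor_value=None)
    censored = tau_f is None and not died_this_bout
    # fatal bouts never meet the breathing criterion; keep tau_f undefined
    if died_this_bout:
        tau_f = None
        censored = False
    elif censored:
        tau_f = max_time + 1.0
    return BoutRecovery(
        bout_index=bout_index,
        pre_bout_baseline_f=pre_bout_f,
        pre_bout_baseline_HR=pre_bout_hr,
        apnea_latency=latency,
        tau_f=tau_f,
        tau_f_censored=censored,
        tau_HR=tau_hr,
        tau_HR_unrecovered=tau_hr is None,
        died_this_bout=died_this_bout,
        transient_HR_recovery_in_fatal_bout=bool(died_this_bout
                                                 and tau_hr is not None),
    )
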