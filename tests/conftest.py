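import numpy as np
import pytest

from autoresus.core import AssayTimeline, EventSeries, TraceBundle
from autoresus.synth import (CohortConfig, build_timeline, sample_cohort,
                             synthesize_trace)


@pytest.fixture(scope="session")
def noiseless_config() -> CohortConfig:
    return CohortConfig.compact(
        n_experimental=3, n_control=2, seed=42, n_bouts=2,
        noise_sd=0.0, o2_noise_sd=0.0,
        recovery_window_duration=150.0, terminal_delay=40.0)


@pytest.fixture(scope="session")
def timeline(noiseless_config):
    return build_timeline(noiseless_config)


@pytest.fixture(scope="session")
def cohort(noiseless_config):
    return sample_cohort(noiseless_config)


@pytest.fixture(scope="session")
def traces(noiseless_config, timeline, cohort):
    """(pup, trace, truth) triples for the small noiseless cohort."""
    out = []
    for i, pup in enumerate(cohort):
        trace, truth = synthesize_trace(pup, timeline, noiseless_config,
                                        seed=1000 + i)
        out.append((pup, trace, truth))
    return out


@pytest.fixture(scope="session")
def surviving(traces):
    for pup, trace, truth in traces:
        if truth.survived:
            return pup, trace, truth
    raise RuntimeError("fixture cohort has no survivor")


@pytest.fixture(scope="session")
def fatal(traces):
    for pup, trace, truth in traces:
        if not truth.survived:
            return pup, trace, truth
    raise RuntimeError("fixture cohort has no fatality")


def toy_timeline(duration: float = 60.0, asphyxia=(10.0, 30.0),
                 recovery: float = 25.0) -> AssayTimeline:
    """Minimal single-bout timeline for hand-constructed traces."""
    a0, a1 = asphyxia
    return AssayTimeline(
        acclimation_window=(0.0, a0 - 5.0),
        cno_time=a0 - 5.0,
        pre_cno_baseline_window=(0.0, a0 - 5.0),
        pre_bout_baseline_windows=((a0 - 5.0, a0),),
        asphyxia_windows=((a0, a1),),
        recovery_window_duration=recovery,
    )


def manual_trace(fs: float = 200.0, duration: float = 60.0,
                 pressure=None, beat=None, o2=None,
                 timeline: AssayTimeline | None = None,
                 body_weight: float = 5.0, **kwargs) -> TraceBundle:
    n = int(round(duration * fs))

    def _chan(x):
        return np.zeros(n) if x is None else np.asarray(x, dtype=float)

    return TraceBundle(
        sampling_rate=fs,
        pressure=_chan(pressure),
        beat_marker=_chan(beat),
        o2_fraction=_chan(o2) if o2 is not None else np.full(n, 0.2),
        flow=np.full(n, 140.0),
        timeline=timeline or toy_timeline(duration),
        body_weight=body_weight,
        **kwargs,
    )


def add_pulses(x: np.ndarray, fs: float, times, amp: float,
               width: float) -> np.ndarray:
    """Raised-cosine pulses, same kernel family as the generator."""
    for c in np.atleast_1d(times):
        i0 = max(0, int(np.ceil((c - width / 2) * fs)))
        i1 = min(len(x) - 1, int(np.floor((c + width / 2) * fs)))
        tt = np.arange(i0, i1 + 1) / fs - c
        x[i0:i1 + 1] += amp * 0.5 * (1 + np.cos(2 * np.pi * tt / width))
    return x


def events(times, kind: str = "breath", amplitudes=None, integrals=None):
    times = np.asarray(times, dtype=float)
    return EventSeries(
        kind, times,
        np.ones_like(times) if amplitudes is None else np.asarray(amplitudes, float),
        np.ones_like(times) if integrals is None else np.asarray(integrals, float))
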