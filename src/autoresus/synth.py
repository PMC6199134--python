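"""Synthetic cohort and trace generation for the repeated-asphyxia assay.

The generator emits, for each simulated pup, a multichannel
:class:`~autoresus.core.TraceBundle` (respiratory pressure, cardiac impulse
train, mixed-expired O2 fraction, gas flow) together with a
:class:`GroundTruth` record of every programmed event, so the detection and
recovery estimators can be validated by parameter recovery.

Baseline cardiorespiratory values are drawn from per-genotype normal
distributions whose default means/SDs are the instrument-sheet ("printed")
numbers; volumes are converted to physical millilitres for waveform synthesis
with :data:`PRINTED_VOLUME_SCALE` and never silently rescaled in the stored
profile.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AssayTimeline, TraceBundle

__all__ = [
    "PRINTED_VOLUME_SCALE",
    "BASELINE_DISTRIBUTIONS",
    "DEFAULT_MORTALITY_MODEL",
    "PupProfile",
    "CohortConfig",
    "GroundTruth",
    "build_timeline",
    "sample_cohort",
    "synthesize_trace",
    "write_bundle",
    "read_bundle",
]

# Printed volume figures (tidal volume ~4.5 "ml/g", oxygen consumption
# ~77 "ml/min/g") are microlitre-scale for a 5 g pup; one printed unit is
# taken as 1e-3 ml when building physical waveforms.  The stored profile
# keeps the printed numbers untouched.
PRINTED_VOLUME_SCALE = 1e-3

# Per-genotype (mean, sd) of baseline characteristics used by sample_cohort.
BASELINE_DISTRIBUTIONS: dict[str, dict[str, tuple[float, float]]] = {
    "control": {
        "body_weight": (5.503, 1.115),
        "baseline_f": (241.6, 26.87),
        "baseline_VT": (4.51, 1.034),
        "baseline_HR": (634.6, 40.88),
        "baseline_VEVO2": (14.33, 2.989),
        "apnea_latency": (23.4, 4.9),
    },
    "experimental": {
        "body_weight": (5.04, 1.275),
        "baseline_f": (246.3, 30.93),
        "baseline_VT": (4.757, 1.784),
        "baseline_HR": (612.8, 42.01),
        "baseline_VEVO2": (16.13, 3.741),
        "apnea_latency": (23.4, 4.1),
    },
}

# Log-odds mortality model: intercept + coef*VEVO2 + genotype_term*[experimental].
# Defaults reproduce ~30% experimental and ~4-7% control mortality at the
# genotype VEVO2 means, with a per-unit ventilatory-equivalents odds ratio of
# 1.399 and a genotype odds ratio of 6.53.
DEFAULT_MORTALITY_MODEL: dict[str, float] = {
    "intercept": -8.14,
    "coef_per_unit_VEVO2": math.log(1.399),
    "genotype_term": math.log((7 / 1) / (15 / 14)),
}

_C63 = -math.log(1.0 - 0.63)  # rate profile reaches 63% of baseline at t = tau


@dataclass
class PupProfile:
    """Programmed per-pup parameters (printed units for volumes)."""

    pup_id: str
    genotype: str  # {"experimental", "control"}
    body_weight: float  # g
    baseline_f: float  # breaths/min
    baseline_VT: float  # printed volume units per g
    baseline_HR: float  # beats/min
    baseline_VO2: float  # printed volume units /min/g
    apnea_latency: float  # s from asphyxia onset
    gasp_params: dict = field(default_factory=dict)
    recovery_tau_f_true: float = 45.0  # s
    recovery_tau_HR_true: float = 25.0  # s
    mortality_bout: int | None = None
    transient_hr_recovery: bool = False

    def __post_init__(self) -> None:
        if self.genotype not in ("experimental", "control"):
            raise ValueError(f"unknown genotype {self.genotype!r}")
        for name in ("body_weight", "baseline_f", "baseline_VT", "baseline_HR",
                     "baseline_VO2", "apnea_latency",
                     "recovery_tau_f_true", "recovery_tau_HR_true"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        gp = self.gasp_params
        if gp:
            if not len(gp.get("gasp_sizes", [])) >= 1:
                raise ValueError("gasp_sizes must have length >= 1")
            if len(gp.get("inter_gasp_intervals", [])) != len(gp["gasp_sizes"]) - 1:
                raise ValueError("need one inter-gasp interval per gasp gap")
        if self.mortality_bout is not None and self.mortality_bout < 1:
            raise ValueError("mortality_bout must be >= 1 or None")

    @property
    def baseline_VE(self) -> float:
        """Minute ventilation, printed units/min/g (f * V_T)."""
        return self.baseline_f * self.baseline_VT

    @property
    def baseline_VEVO2(self) -> float:
        return self.baseline_VE / self.baseline_VO2

    def to_dict(self) -> dict:
        d = asdict(self)
        gp = d["gasp_params"]
        for k in ("gasp_sizes", "inter_gasp_intervals"):
            if k in gp:
                gp[k] = [float(x) for x in gp[k]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PupProfile":
        return cls(**d)


@dataclass
class CohortConfig:
    """Cohort composition, assay timing, and trace-synthesis parameters."""

    n_experimental: int = 22
    n_control: int = 15
    seed: int = 0
    mortality_model: dict = field(default_factory=lambda: dict(DEFAULT_MORTALITY_MODEL))

    # timeline (seconds)
    acclimation_duration: float = 1200.0
    post_cno_duration: float = 600.0
    baseline_window_duration: float = 180.0
    asphyxia_duration: float = 30.0
    recovery_window_duration: float = 330.0
    n_bouts: int = 4

    # trace synthesis
    sampling_rate: float = 1000.0  # Hz
    noise_sd: float = 0.5  # pressure channel, transducer units
    beat_noise_sd: float = 0.0
    o2_noise_sd: float = 5e-4
    flow_ml_min: float = 140.0
    f_io2: float = 0.21
    calibration: float = 0.01  # ml per pressure-unit*s
    breath_width: float = 0.10  # s, single-lobe raised-cosine kernel
    gasp_width: float = 0.06  # s, narrower "steeple" kernel
    bradycardia_depth: float = 0.40  # fraction of baseline HR during apnea
    brady_ramp: float = 3.0  # s to reach bradycardia floor
    gasp_hr_bump: float = 0.0  # additive HR bump per gasp, fraction of baseline
    terminal_delay: float = 45.0  # s after asphyxia end at which a fatal bout ends
    artifact_rate_per_min: float = 0.0
    artifact_amplitude_factor: float = 12.0  # x eupneic breath amplitude
    artifact_duration: float = 1.5  # s
    n_gasps: int = 5
    baseline_overrides: dict | None = None  # genotype -> {field: (mean, sd)}

    def __post_init__(self) -> None:
        if self.n_experimental < 0 or self.n_control < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.n_experimental + self.n_control < 1:
            raise ValueError("cohort must contain at least one pup")
        if self.sampling_rate < 100:
            raise ValueError("sampling_rate must be >= 100 Hz")
        if not 0 < self.f_io2 <= 1:
            raise ValueError("f_io2 must be in (0, 1]")
        for name in ("acclimation_duration", "post_cno_duration",
                     "baseline_window_duration", "asphyxia_duration",
                     "recovery_window_duration"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.n_bouts < 1:
            raise ValueError("n_bouts must be >= 1")
        if self.baseline_window_duration > self.post_cno_duration:
            raise ValueError("baseline window must fit inside the post-injection period")
        if self.terminal_delay >= self.recovery_window_duration:
            raise ValueError("terminal_delay must fall inside the recovery window")
        if self.baseline_overrides:
            for dists in self.baseline_overrides.values():
                for key, (mean, sd) in dists.items():
                    if sd < 0:
                        raise ValueError(f"negative SD for {key}")

    @classmethod
    def compact(cls, **kwargs) -> "CohortConfig":
        """Short-timeline, 200 Hz configuration for tests and demos."""
        defaults = dict(
            sampling_rate=200.0,
            acclimation_duration=60.0,
            post_cno_duration=60.0,
            baseline_window_duration=40.0,
        )
        defaults.update(kwargs)
        return cls(**defaults)

    def distributions(self, genotype: str) -> dict[str, tuple[float, float]]:
        dists = dict(BASELINE_DISTRIBUTIONS[genotype])
        if self.baseline_overrides and genotype in self.baseline_overrides:
            dists.update(self.baseline_overrides[genotype])
        return dists


@dataclass
class GroundTruth:
    """Programmed events and parameters backing one emitted trace."""

    breath_times: np.ndarray
    beat_times: np.ndarray
    bouts: list[dict]  # per bout: onset, gasp times/sizes, taus, baselines
    died_bout: int | None
    terminal_time: float | None
    artifact_times: list[float]
    pre_cno: dict  # programmed baseline measures (printed units)

    @property
    def survived(self) -> bool:
        return self.died_bout is None

    def to_dict(self) -> dict:
        return {
            "breath_times": [float(x) for x in self.breath_times],
            "beat_times": [float(x) for x in self.beat_times],
            "bouts": self.bouts,
            "died_bout": self.died_bout,
            "terminal_time": self.terminal_time,
            "artifact_times": list(self.artifact_times),
            "pre_cno": self.pre_cno,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            breath_times=np.asarray(d["breath_times"], dtype=float),
            beat_times=np.asarray(d["beat_times"], dtype=float),
            bouts=d["bouts"],
            died_bout=d["died_bout"],
            terminal_time=d["terminal_time"],
            artifact_times=list(d["artifact_times"]),
            pre_cno=d["pre_cno"],
        )


def build_timeline(config: CohortConfig) -> AssayTimeline:
    """Assay timeline: acclimation, injection, settling, then n_bouts cycles
    of (pre-bout baseline window, asphyxia, fixed recovery window)."""
    acc = config.acclimation_duration
    bw = config.baseline_window_duration
    asp = config.asphyxia_duration
    rec = config.recovery_window_duration

    baselines = []
    asphyxias = []
    t = acc + config.post_cno_duration
    for _ in range(config.n_bouts):
        baselines.append((t - bw, t))
        asphyxias.append((t, t + asp))
        t = t + asp + rec + bw
    return AssayTimeline(
        acclimation_window=(0.0, acc),
        cno_time=acc,
        pre_cno_baseline_window=(acc - min(bw, acc), acc),
        pre_bout_baseline_windows=tuple(baselines),
        asphyxia_windows=tuple(asphyxias),
        recovery_window_duration=rec,
    )


def _draw(rng: np.random.Generator, mean: float, sd: float,
          lo: float, hi: float | None = None) -> float:
    x = float(rng.normal(mean, sd))
    if hi is not None:
        x = min(x, hi)
    return max(x, lo)


def sample_cohort(config: CohortConfig) -> list[PupProfile]:
    """Draw per-pup profiles; mortality follows the configured logistic model
    on baseline ventilatory equivalents.

    Ventilatory equivalents are drawn directly from their per-genotype normal
    distribution and oxygen consumption derived as VE/VEVO2, keeping the
    mortality predictor on exactly the programmed distribution.
    """
    rng = np.random.default_rng(config.seed)
    model = config.mortality_model
    intercept = float(model.get("intercept", DEFAULT_MORTALITY_MODEL["intercept"]))
    coef = float(model.get("coef_per_unit_VEVO2", 0.0))
    genotype_term = model.get("genotype_term", None)

    max_latency = config.asphyxia_duration - 2.0
    pups: list[PupProfile] = []
    groups = [("experimental", config.n_experimental), ("control", config.n_control)]
    for genotype, n in groups:
        dists = config.distributions(genotype)
        for i in range(n):
            bw = _draw(rng, *dists["body_weight"], lo=1.0)
            f = _draw(rng, *dists["baseline_f"], lo=60.0)
            vt = _draw(rng, *dists["baseline_VT"], lo=0.5)
            hr = _draw(rng, *dists["baseline_HR"], lo=200.0)
            vevo2 = _draw(rng, *dists["baseline_VEVO2"], lo=2.0)
            vo2 = f * vt / vevo2
            latency = _draw(rng, *dists["apnea_latency"], lo=8.0, hi=max_latency)

            # gasp train: first-gasp latency must land after the asphyxic gas
            # is switched off (O2 rising), i.e. beyond the remaining window
            min_fgl = (config.asphyxia_duration - latency) + 1.0
            fgl = _draw(rng, 9.0, 2.0, lo=min_fgl)
            # gasp integrals scale with the pup's eupneic breath integral so
            # the steeple-vs-breath amplitude contrast is preserved per pup
            breath_integral = vt * PRINTED_VOLUME_SCALE * bw / config.calibration
            sizes = [breath_integral * _draw(rng, 3.0, 0.5, lo=2.0)
                     for _ in range(config.n_gasps)]
            igis = [_draw(rng, 5.0, 1.0, lo=2.0) for _ in range(config.n_gasps - 1)]

            tau_f = _draw(rng, 45.0, 15.0, lo=8.0, hi=65.0)
            tau_hr = _draw(rng, 25.0, 8.0, lo=5.0, hi=35.0)

            # mortality: logistic in VEVO2; control pups are exempt unless a
            # genotype term extends the model to both genotypes
            if genotype == "experimental":
                eta = intercept + coef * vevo2
                eta += float(genotype_term) if genotype_term is not None else 0.0
                p_death = 1.0 / (1.0 + math.exp(-eta))
            elif genotype_term is not None:
                eta = intercept + coef * vevo2
                p_death = 1.0 / (1.0 + math.exp(-eta))
            else:
                p_death = 0.0
            dies = bool(rng.random() < p_death)
            mortality_bout = int(rng.integers(1, config.n_bouts + 1)) if dies else None
            transient = bool(dies and rng.random() < 3 / 7)

            pups.append(PupProfile(
                pup_id=f"{genotype[:4]}{i:03d}",
                genotype=genotype,
                body_weight=bw,
                baseline_f=f,
                baseline_VT=vt,
                baseline_HR=hr,
                baseline_VO2=vo2,
                apnea_latency=latency,
                gasp_params={
                    "first_gasp_latency": fgl,
                    "gasp_sizes": sizes,
                    "inter_gasp_intervals": igis,
                },
                recovery_tau_f_true=tau_f,
                recovery_tau_HR_true=tau_hr,
                mortality_bout=mortality_bout,
                transient_hr_recovery=transient,
            ))
    return pups


def _events_from_rate(t: np.ndarray, rate_hz: np.ndarray, dt: float) -> np.ndarray:
    """Event times where the cumulative rate integral crosses successive
    integers (phase accumulator)."""
    # trapezoidal phase integral: O(dt^2) accuracy keeps event spacing smooth
    # near the recovery threshold, where timing is ill-conditioned
    cum = np.empty_like(rate_hz)
    if cum.size:
        cum[0] = 0.0
        np.cumsum((rate_hz[1:] + rate_hz[:-1]) * (0.5 * dt), out=cum[1:])
    total = cum[-1] if cum.size else 0.0
    if total < 1.0:
        return np.empty(0)
    targets = np.arange(1.0, math.floor(total) + 0.5)
    return np.interp(targets, cum, t)


def _add_kernel(signal: np.ndarray, fs: float, center: float, amp: float,
                width: float) -> None:
    """Add a single-lobe raised-cosine pulse in place."""
    i0 = max(0, int(math.ceil((center - width / 2) * fs)))
    i1 = min(len(signal) - 1, int(math.floor((center + width / 2) * fs)))
    if i1 < i0:
        return
    tt = np.arange(i0, i1 + 1) / fs - center
    signal[i0:i1 + 1] += amp * 0.5 * (1.0 + np.cos(2.0 * np.pi * tt / width))


def _exp_recovery(tseg: np.ndarray, t0: float, base: float, tau: float,
                  floor_frac: float) -> np.ndarray:
    """Rate profile rising from ``floor_frac*base`` toward ``base`` and
    crossing 63% of base exactly at ``t0 + tau``."""
    if floor_frac >= 0.63:
        raise ValueError("recovery floor must start below the 63% criterion")
    theta = tau / math.log((1.0 - floor_frac) / (1.0 - 0.63))
    x = floor_frac + (1.0 - floor_frac) * (1.0 - np.exp(-(tseg - t0) / theta))
    return base * np.minimum(x, 1.0)


def synthesize_trace(pup: PupProfile, timeline: AssayTimeline,
                     config: CohortConfig | None = None,
                     seed: int = 0) -> tuple[TraceBundle, GroundTruth]:
    """Render one pup's multichannel record plus its ground-truth event list.

    Pressure is a sum of per-breath raised-cosine kernels (area set by the
    programmed tidal volume through the pressure calibration), silenced from
    apnea onset, followed by steeple-like gasp kernels and an
    exponential-approach resumption of eupnea whose instantaneous rate crosses
    63% of the pre-bout baseline exactly at the programmed tau.  The cardiac
    channel is an impulse train with bradycardia during apnea and an analogous
    exponential heart-rate recovery.
    """
    if config is None:
        config = CohortConfig()
    fs = config.sampling_rate
    dt = 1.0 / fs
    n = int(round(timeline.duration * fs))
    t = np.arange(n) * dt
    rng = np.random.default_rng(seed)

    f_hz = pup.baseline_f / 60.0
    hr_hz = pup.baseline_HR / 60.0
    depth = config.bradycardia_depth

    breath_rate = np.full(n, f_hz)
    beat_rate = np.full(n, hr_hz)

    died_bout = pup.mortality_bout
    terminal_time: float | None = None
    bouts: list[dict] = []
    gasp_events: list[tuple[float, float]] = []  # (time, size integral)

    gp = pup.gasp_params or {
        "first_gasp_latency": max(config.asphyxia_duration - pup.apnea_latency + 2.0, 3.0),
        "gasp_sizes": [6.0] * config.n_gasps,
        "inter_gasp_intervals": [5.0] * (config.n_gasps - 1),
    }

    for k, (a0, a1) in enumerate(timeline.asphyxia_windows, start=1):
        if died_bout is not None and k > died_bout:
            break
        rec_end = a1 + timeline.recovery_window_duration
        onset = min(a0 + pup.apnea_latency, a1 - dt)
        fatal = died_bout == k

        i_on, i_a1 = int(onset * fs), int(a1 * fs)
        i_rec = min(n, int(rec_end * fs))

        # gasp train for this bout
        fgl = float(gp["first_gasp_latency"])
        g_times = onset + fgl + np.concatenate(
            [[0.0], np.cumsum(np.asarray(gp["inter_gasp_intervals"], dtype=float))])
        if g_times.size and g_times[-1] > rec_end:
            raise ValueError(
                f"gasp train extends past the recovery window of bout {k}")

        bout_info: dict = {
            "bout": k,
            "asphyxia_window": [a0, a1],
            "apnea_onset": onset,
            "apnea_latency": onset - a0,
            "pre_bout_f": pup.baseline_f,
            "pre_bout_HR": pup.baseline_HR,
            "died_this_bout": fatal,
        }

        if fatal:
            terminal_time = a1 + config.terminal_delay
            if pup.transient_hr_recovery:
                terminal_time = min(a1 + pup.recovery_tau_HR_true + 14.0,
                                    rec_end - 1.0)
            g_times = g_times[g_times <= terminal_time]
            breath_rate[i_on:] = 0.0
            i_term = int(terminal_time * fs)
            # bradycardia, then either a short transient recovery or decline
            _ramp_down(beat_rate, t, i_on, hr_hz, depth, config.brady_ramp, fs)
            if pup.transient_hr_recovery:
                seg = slice(i_a1, i_term)
                beat_rate[seg] = _exp_recovery(
                    t[seg], a1, hr_hz, pup.recovery_tau_HR_true, depth)
                i_fall = int((terminal_time - 8.0) * fs)
                _linear_to_zero(beat_rate, i_fall, i_term)
                bout_info["tau_HR_true"] = pup.recovery_tau_HR_true
                bout_info["transient_hr_recovery"] = True
            else:
                i_fall = int((a1 + 10.0) * fs)
                beat_rate[i_a1:i_fall] = depth * hr_hz
                _linear_to_zero(beat_rate, i_fall, i_term)
                bout_info["tau_HR_true"] = None
                bout_info["transient_hr_recovery"] = False
            beat_rate[i_term:] = 0.0
            bout_info["tau_f_true"] = None
        else:
            breath_rate[i_on:i_a1] = 0.0
            seg = slice(i_a1, i_rec)
            breath_rate[seg] = np.minimum(
                f_hz * (1.0 - np.exp(-(t[seg] - a1) * _C63 / pup.recovery_tau_f_true)),
                f_hz)
            breath_rate[i_rec:] = f_hz

            _ramp_down(beat_rate, t, i_on, hr_hz, depth, config.brady_ramp, fs)
            beat_rate[seg] = _exp_recovery(
                t[seg], a1, hr_hz, pup.recovery_tau_HR_true, depth)
            beat_rate[i_rec:] = hr_hz
            bout_info["tau_f_true"] = pup.recovery_tau_f_true
            bout_info["tau_HR_true"] = pup.recovery_tau_HR_true
            bout_info["transient_hr_recovery"] = False

        sizes = list(gp["gasp_sizes"])[:len(g_times)]
        bout_info["gasp_times"] = [float(x) for x in g_times]
        bout_info["gasp_sizes"] = [float(x) for x in sizes]
        gasp_events.extend(zip(g_times, sizes))
        bouts.append(bout_info)

    # optional gasp-driven heart-rate bumps (disordered-gasp phenotype)
    if config.gasp_hr_bump > 0:
        for g_time, _ in gasp_events:
            mask = t >= g_time
            beat_rate[mask] += (config.gasp_hr_bump * hr_hz
                                * np.exp(-(t[mask] - g_time) / 1.0))

    breath_times = _events_from_rate(t, breath_rate, dt)
    beat_times = _events_from_rate(t, beat_rate, dt)

    # --- waveforms -------------------------------------------------------
    vol_per_breath_ml = pup.baseline_VT * PRINTED_VOLUME_SCALE * pup.body_weight
    breath_integral = vol_per_breath_ml / config.calibration  # unit*s
    breath_amp = 2.0 * breath_integral / config.breath_width

    pressure = np.zeros(n)
    for bt in breath_times:
        _add_kernel(pressure, fs, bt, breath_amp, config.breath_width)
    for g_time, g_size in gasp_events:
        _add_kernel(pressure, fs, g_time, 2.0 * g_size / config.gasp_width,
                    config.gasp_width)

    # 7-sample cardiac pulse: wide enough for sub-sample peak interpolation
    beat_marker = np.zeros(n)
    for bt in beat_times:
        _add_kernel(beat_marker, fs, bt, 1.0, 7.0 * dt)

    # O2 channel: mixed-expired fraction at baseline, near-zero during
    # asphyxia, exponential return afterwards (to room-air F_IO2 once a pup
    # has died and stops consuming oxygen)
    vo2_ml = pup.baseline_VO2 * PRINTED_VOLUME_SCALE  # ml/min/g
    f_eo2 = config.f_io2 - vo2_ml * pup.body_weight / config.flow_ml_min
    if not 0.0 <= f_eo2 <= config.f_io2:
        raise ValueError("programmed VO2 incompatible with flow and F_IO2")
    o2 = np.full(n, f_eo2)
    low = 0.005
    for k, (a0, a1) in enumerate(timeline.asphyxia_windows, start=1):
        if died_bout is not None and k > died_bout:
            break
        i0, i1 = int(a0 * fs), min(n, int(a1 * fs))
        o2[i0:i1] = low + (f_eo2 - low) * np.exp(-(t[i0:i1] - a0) / 1.5)
        target = config.f_io2 if died_bout == k else f_eo2
        o2[i1:] = target + (o2[i1 - 1] - target) * np.exp(-(t[i1:] - a1) / 2.0)

    # movement artifacts
    artifact_times: list[float] = []
    if config.artifact_rate_per_min > 0:
        n_art = rng.poisson(config.artifact_rate_per_min * timeline.duration / 60.0)
        for _ in range(n_art):
            c = float(rng.uniform(0, timeline.duration))
            amp = config.artifact_amplitude_factor * breath_amp * rng.choice([-1, 1])
            _add_kernel(pressure, fs, c, amp, config.artifact_duration)
            artifact_times.append(c)

    if config.noise_sd > 0:
        pressure += rng.normal(0.0, config.noise_sd, n)
    if config.beat_noise_sd > 0:
        beat_marker += rng.normal(0.0, config.beat_noise_sd, n)
    if config.o2_noise_sd > 0:
        o2 += rng.normal(0.0, config.o2_noise_sd, n)

    trace = TraceBundle(
        sampling_rate=fs,
        pressure=pressure,
        beat_marker=beat_marker,
        o2_fraction=o2,
        flow=np.full(n, config.flow_ml_min),
        timeline=timeline,
        body_weight=pup.body_weight,
        calibration=config.calibration,
        f_io2=config.f_io2,
        pup_id=pup.pup_id,
        genotype=pup.genotype,
    )
    truth = GroundTruth(
        breath_times=breath_times,
        beat_times=beat_times,
        bouts=bouts,
        died_bout=died_bout,
        terminal_time=terminal_time,
        artifact_times=artifact_times,
        pre_cno={
            "f": pup.baseline_f,
            "V_T": pup.baseline_VT,
            "VE": pup.baseline_VE,
            "HR": pup.baseline_HR,
            "VO2": pup.baseline_VO2,
            "VEVO2": pup.baseline_VEVO2,
            "F_EO2": f_eo2,
        },
    )
    return trace, truth


def _ramp_down(rate: np.ndarray, t: np.ndarray, i_on: int, base_hz: float,
               depth: float, ramp_s: float, fs: float) -> None:
    """Linear bradycardia ramp from baseline to ``depth*base`` in place."""
    i_end = min(len(rate), i_on + int(ramp_s * fs))
    k = i_end - i_on
    if k > 0:
        rate[i_on:i_end] = base_hz * (1.0 - (1.0 - depth) * np.arange(k) / k)
    rate[i_end:] = depth * base_hz


def _linear_to_zero(rate: np.ndarray, i0: int, i1: int) -> None:
    i0 = max(0, i0)
    i1 = min(len(rate), max(i1, i0 + 1))
    start = rate[i0 - 1] if i0 > 0 else rate[0]
    rate[i0:i1] = start * np.linspace(1.0, 0.0, i1 - i0, endpoint=False)
    rate[i1:] = 0.0


# --- bundle directory I/O ------------------------------------------------

def write_bundle(directory: str | Path, trace: TraceBundle, truth: GroundTruth,
                 pup: PupProfile) -> Path:
    """Write one pup's bundle: trace.csv, timeline.json, ground_truth.json,
    pup.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({
        "time_s": trace.time,
        "pressure": trace.pressure,
        "beat_marker": trace.beat_marker,
        "o2_fraction": trace.o2_fraction,
        "flow_ml_min": trace.flow,
    })
    df.to_csv(directory / "trace.csv", index=False)
    (directory / "timeline.json").write_text(
        json.dumps(trace.timeline.to_dict(), indent=1))
    (directory / "ground_truth.json").write_text(
        json.dumps(truth.to_dict(), indent=1))
    meta = pup.to_dict()
    meta.update({"sampling_rate": trace.sampling_rate,
                 "calibration": trace.calibration, "f_io2": trace.f_io2})
    (directory / "pup.json").write_text(json.dumps(meta, indent=1))
    return directory


def read_bundle(directory: str | Path) -> tuple[TraceBundle, GroundTruth, PupProfile]:
    """Read a bundle directory written by :func:`write_bundle`."""
    directory = Path(directory)
    df = pd.read_csv(directory / "trace.csv")
    timeline = AssayTimeline.from_dict(
        json.loads((directory / "timeline.json").read_text()))
    truth = GroundTruth.from_dict(
        json.loads((directory / "ground_truth.json").read_text()))
    meta = json.loads((directory / "pup.json").read_text())
    fs = float(meta.pop("sampling_rate"))
    calibration = float(meta.pop("calibration"))
    f_io2 = float(meta.pop("f_io2"))
    pup = PupProfile.from_dict(meta)
    trace = TraceBundle(
        sampling_rate=fs,
        pressure=df["pressure"].to_numpy(),
        beat_marker=df["beat_marker"].to_numpy(),
        o2_fraction=df["o2_fraction"].to_numpy(),
        flow=df["flow_ml_min"].to_numpy(),
        timeline=timeline,
        body_weight=pup.body_weight,
        calibration=calibration,
        f_io2=f_io2,
        pup_id=pup.pup_id,
        genotype=pup.genotype,
    )
    return trace, truth, pup
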