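"""End-to-end orchestration: generate or load trace bundles, extract per-pup
features, assemble the cohort table, and run the cohort statistics.

All outputs are plain CSV/JSON; the pipeline is pure given (config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import recovery as rec
from . import signals as sig
from . import stats as st
from . import variability as vb
from .core import AnalysisError, TraceBundle, UndefinedResultError
from .synth import (PRINTED_VOLUME_SCALE, CohortConfig, GroundTruth,
                    PupProfile, build_timeline, read_bundle, sample_cohort,
                    synthesize_trace, write_bundle)

__all__ = ["RunConfig", "extract_pup_features", "analyze_cohort", "run"]

log = logging.getLogger("autoresus")


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Exactly one input source: either ``generate=True`` (cohort simulated
    from ``cohort``) or ``trace_dir`` pointing at bundle directories.
    """

    generate: bool = True
    trace_dir: str | None = None
    out_dir: str = "autoresus_out"
    cohort: CohortConfig = field(default_factory=CohortConfig.compact)
    fraction: float = 0.63
    sustain: float = 3.0
    max_time: float | None = None  # defaults to the recovery window length
    gasp_voltage_threshold: float = 0.002
    stable_duration: float = 30.0
    write_bundles: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.generate == (self.trace_dir is not None):
            raise ValueError("exactly one input source: generate or trace_dir")
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must be in (0, 1]")


def _stable_baseline(trace: TraceBundle, window, duration: float):
    win, flagged = sig.select_stable_window(trace, window, duration=duration)
    measures = sig.baseline_measures(trace, win)
    return measures, flagged


def _variability_row(trace: TraceBundle, window, prefix: str) -> dict:
    out: dict = {}
    breaths = sig.detect_breaths(trace, window)
    beats = sig.detect_beats(trace, window)
    for events, src in ((breaths, "ibi_breath"), (beats, "ibi_beat")):
        try:
            desc = vb.descriptors(vb.intervals_from_times(events.times))
            out.update(desc.as_dict(prefix=f"{prefix}_{src}_"))
        except AnalysisError:
            pass
    return out


def extract_pup_features(trace: TraceBundle, run_config: RunConfig | None = None
                         ) -> tuple[dict, list[dict]]:
    """Per-pup feature extraction from one trace bundle.

    Returns (pup_row, bout_rows): the wide cohort-table row and one row per
    analyzed bout (up to and including a fatal bout).
    """
    cfg = run_config or RunConfig()
    timeline = trace.timeline
    duration = trace.duration
    max_time = cfg.max_time or timeline.recovery_window_duration
    stable = min(cfg.stable_duration,
                 timeline.pre_bout_baseline_windows[0][1]
                 - timeline.pre_bout_baseline_windows[0][0])

    breaths = sig.detect_breaths(trace, (0.0, duration))
    beats = sig.detect_beats(trace, (0.0, duration))
    died_bout = rec.detect_death(breaths, beats, timeline, duration)

    row: dict = {
        "pup_id": trace.pup_id,
        "genotype": trace.genotype,
        "body_weight": trace.body_weight,
        "died": died_bout is not None,
        "died_bout": died_bout,
        "survived": died_bout is None,
    }

    # baseline a (pre-injection) and b' (first pre-bout) windows
    for prefix, window in (("pre", timeline.pre_cno_baseline_window),
                           ("cno", timeline.pre_bout_baseline_windows[0])):
        try:
            measures, flagged = _stable_baseline(trace, window, stable)
            d = measures.as_dict()
            # report volumes on the printed (instrument-sheet) scale
            for key in ("V_T", "VE", "VO2"):
                d[key] = d[key] / PRINTED_VOLUME_SCALE
            row.update({f"{prefix}_{k}": v for k, v in d.items()})
            row[f"{prefix}_window_flagged"] = flagged
            row.update(_variability_row(trace, (d["window_start"],
                                                d["window_end"]), prefix))
        except AnalysisError as exc:
            log.warning("pup %s: baseline %s failed: %s", trace.pup_id, prefix, exc)
            row[f"{prefix}_failed"] = str(exc)

    bout_rows: list[dict] = []
    last_k = died_bout if died_bout is not None else timeline.n_bouts
    for k in range(1, last_k + 1):
        base_win = timeline.pre_bout_baseline_windows[k - 1]
        try:
            base, _ = _stable_baseline(trace, base_win, stable)
        except AnalysisError as exc:
            log.warning("pup %s bout %d: baseline failed: %s", trace.pup_id, k, exc)
            continue
        bout = rec.analyze_bout(
            breaths, beats, timeline, k, base.f, base.HR,
            died_this_bout=(died_bout == k),
            fraction=cfg.fraction, sustain=cfg.sustain, max_time=max_time)
        r = {
            "pup_id": trace.pup_id,
            "genotype": trace.genotype,
            "bout": k,
            "baseline_f": bout.pre_bout_baseline_f,
            "baseline_HR": bout.pre_bout_baseline_HR,
            "apnea_latency": bout.apnea_latency,
            "tau_f": bout.tau_f,
            "tau_f_censored": bout.tau_f_censored,
            "tau_HR": bout.tau_HR,
            "tau_HR_unrecovered": bout.tau_HR_unrecovered,
            "died_this_bout": bout.died_this_bout,
            "transient_HR_recovery": bout.transient_HR_recovery_in_fatal_bout,
        }

        # gasp profile (reported for every analyzed bout; bout 1 feeds the
        # cohort-level gasp columns)
        a0, a1 = timeline.asphyxia_windows[k - 1]
        try:
            onset = rec.apnea_onset(breaths, (a0, a1))
        except AnalysisError:
            onset = None
        if onset is not None:
            pre_breaths = breaths.restrict(base_win)
            base_amp = (float(np.median(pre_breaths.amplitudes))
                        if len(pre_breaths) else None)
            gasps = rec.detect_gasps(
                trace, onset, voltage_threshold=cfg.gasp_voltage_threshold,
                baseline_amplitude=base_amp)
            profile = rec.gasp_profile(gasps, beats, onset, trace.body_weight)
            r.update(_gasp_columns(profile))
            if k == 1:
                row.update({f"gasp_{kk}": v
                            for kk, v in _gasp_columns(profile).items()})
        bout_rows.append(r)

    for r in bout_rows:
        k = r["bout"]
        for key in ("tau_f", "tau_f_censored", "tau_HR", "tau_HR_unrecovered",
                    "apnea_latency", "died_this_bout"):
            row[f"bout{k}_{key}"] = r[key]
    return row, bout_rows


def _gasp_columns(profile: rec.GaspProfile) -> dict:
    out = {
        "n_gasps": profile.n_gasps,
        "first_gasp_latency": profile.first_gasp_latency,
        "first_gasp_size": profile.first_gasp_size,
    }
    for i in range(4):
        label = "I II III IV".split()[i]
        igi = (profile.inter_gasp_intervals[i]
               if i < len(profile.inter_gasp_intervals) else None)
        hr = (profile.mean_hr_between_gasps[i]
              if i < len(profile.mean_hr_between_gasps) else None)
        out[f"interval_{label}"] = igi
        out[f"interval_{label}_missing"] = igi is None
        out[f"hr_interval_{label}"] = hr
        out[f"hr_interval_{label}_missing"] = hr is None
    return out


def analyze_cohort(cohort_df: pd.DataFrame, bouts_df: pd.DataFrame) -> dict:
    """Cohort statistics report: mortality (table, OR, mid-P), logistic
    mortality models, coupling regressions, VEVO2 variance test."""
    report: dict = {}

    exp = cohort_df[cohort_df.genotype == "experimental"]
    ctl = cohort_df[cohort_df.genotype == "control"]
    a = int(exp.died.sum())
    b = int((~exp.died.astype(bool)).sum())
    c = int(ctl.died.sum())
    d = int((~ctl.died.astype(bool)).sum())
    table = st.ContingencyTable(a, b, c, d)
    mortality: dict = {"table": table.as_dict()}
    mortality["percent_experimental"] = 100.0 * a / max(a + b, 1)
    mortality["percent_control"] = 100.0 * c / max(c + d, 1)
    try:
        mortality["odds_ratio"] = st.odds_ratio(table)
    except AnalysisError as exc:
        mortality["odds_ratio"] = None
        mortality["odds_ratio_note"] = str(exc)
    if min(a + b, c + d) > 0:
        mortality["midp"] = st.fisher_midp_one_tailed(table)
    report["mortality"] = mortality

    logistic = []
    for predictor in ("pre_HR", "pre_VE", "pre_VO2", "pre_VEVO2"):
        if predictor not in cohort_df:
            continue
        sub = cohort_df.dropna(subset=[predictor])
        entry: dict = {"predictor": predictor, "n": int(len(sub))}
        try:
            res = st.logistic_mortality(sub, predictor)
            entry.update({
                "odds_ratio": res.odds_ratios[predictor],
                "conf_int": list(res.conf_int[predictor]),
                "p_value": res.p_values[predictor],
                "converged": res.converged,
            })
        except (AnalysisError, ValueError) as exc:
            entry["error"] = str(exc)
        logistic.append(entry)
    report["logistic"] = logistic

    def _pairs(df: pd.DataFrame):
        ok = (~df.tau_f_censored.astype(bool)) & (~df.tau_HR_unrecovered.astype(bool))
        ok &= df.tau_f.notna() & df.tau_HR.notna()
        sub = df[ok]
        return sub.tau_f.to_numpy(float), sub.tau_HR.to_numpy(float)

    coupling: dict = {}
    for genotype in ("experimental", "control"):
        gdf = bouts_df[bouts_df.genotype == genotype]
        tf, th = _pairs(gdf)
        entry = {"n": int(tf.size)}
        try:
            r = st.coupling_regression(tf, th)
            entry.update({"slope": r.slope, "intercept": r.intercept,
                          "r_squared": r.r_squared,
                          "p_nonzero_slope": r.p_nonzero_slope,
                          "runs_test_p": r.runs_test_p})
        except AnalysisError as exc:
            entry["error"] = str(exc)
        coupling[genotype] = entry
    tf_e, th_e = _pairs(bouts_df[bouts_df.genotype == "experimental"])
    tf_c, th_c = _pairs(bouts_df[bouts_df.genotype == "control"])
    if tf_e.size >= 3 and tf_c.size >= 3:
        try:
            coupling["slope_difference_p"] = st.compare_slopes(
                th_e, tf_e, th_c, tf_c)
        except AnalysisError as exc:
            coupling["slope_difference_note"] = str(exc)
    report["coupling"] = coupling

    if "pre_VEVO2" in cohort_df:
        ve = exp.pre_VEVO2.dropna().to_numpy(float)
        vc = ctl.pre_VEVO2.dropna().to_numpy(float)
        if ve.size >= 2 and vc.size >= 2:
            report["vevo2_variance_f_p"] = st.variance_f_test(ve, vc)
    return report


def run(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Execute the pipeline and write cohort.csv, bouts.csv, stats.json."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("run config: %s", {k: v for k, v in asdict(config).items()
                                if k != "cohort"})

    traces: list[TraceBundle] = []
    if config.generate:
        cc = config.cohort
        log.info("generating cohort: %d experimental + %d control, seed %d",
                 cc.n_experimental, cc.n_control, cc.seed)
        timeline = build_timeline(cc)
        pups = sample_cohort(cc)
        for i, pup in enumerate(pups):
            trace, truth = synthesize_trace(pup, timeline, cc,
                                            seed=cc.seed * 100003 + i)
            if config.write_bundles:
                write_bundle(out / "bundles" / pup.pup_id, trace, truth, pup)
            traces.append(trace)
    else:
        root = Path(config.trace_dir)
        if not root.is_dir():
            raise FileNotFoundError(f"trace directory {root} not readable")
        for sub in sorted(p for p in root.iterdir() if p.is_dir()):
            trace, _, _ = read_bundle(sub)
            traces.append(trace)
        if not traces:
            raise FileNotFoundError(f"no bundle directories under {root}")

    rows, bout_rows = [], []
    for trace in traces:
        row, bouts = extract_pup_features(trace, config)
        rows.append(row)
        bout_rows.extend(bouts)
    cohort_df = pd.DataFrame(rows)
    bouts_df = pd.DataFrame(bout_rows)
    if cohort_df["pup_id"].duplicated().any():
        raise ValueError("duplicate pup ids in cohort")

    report = analyze_cohort(cohort_df, bouts_df)
    cohort_df.to_csv(out / "cohort.csv", index=False)
    bouts_df.to_csv(out / "bouts.csv", index=False)
    (out / "stats.json").write_text(json.dumps(report, indent=1, default=float))
    log.info("wrote %s", out)
    return cohort_df, bouts_df, report
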