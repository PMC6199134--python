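# autoresus

Analysis pipeline for neonatal autoresuscitation assays: from multichannel
plethysmograph/ECG-style traces to per-pup recovery metrics and cohort
statistics, with a synthetic-trace generator standing in for raw recordings.

The package covers:

- **`autoresus.synth`** — cohorts of annotated synthetic trace bundles
  (respiratory pressure, cardiac impulse train, mixed-expired O2 fraction,
  gas flow) over a repeated-asphyxia assay timeline, with ground truth for
  every programmed event: apnea latency, gasp train, exponential-approach
  breathing/heart-rate recovery, logistic-model mortality.
- **`autoresus.signals`** — breath/beat detection (robust-SD-relative
  prominence thresholds, sub-sample peak timing), tidal volume from
  calibrated pressure integrals, minute ventilation (f x V_T), oxygen
  consumption (flow x (F_IO2 - F_EO2) / BW), stable 30-s baseline window
  selection, composed baseline measures.
- **`autoresus.variability`** — interval-variability descriptors: SD, CV,
  RMSSD, Poincare SD1/SD2 and ellipse area.
- **`autoresus.recovery`** — apnea onset, recovery latency tau (time from
  end of asphyxia to >= 3 s sustained at >= 63% of the pre-bout baseline
  rate; 331-s censoring for breathing, unrecovered convention for heart
  rate), gasp detection gated on rising O2, gasp profiles (first-gasp
  latency/size, inter-gasp intervals I-IV, mean HR per interval).
- **`autoresus.stats`** — (A/C)/(B/D) odds ratio, one-tailed Fisher exact
  test with Lancaster mid-P correction by hypergeometric enumeration,
  logistic regression by IRLS with Wald intervals and separation detection,
  coupling regression with a Wald-Wolfowitz runs test on residual signs
  (exact for n <= 20), slope-difference test, variance F test.
- **`autoresus.pipeline`** — orchestration, CSV/JSON I/O, CLI.

## CLI

```sh
autoresus demo --seed 7 --out demo_out            # small end-to-end run
autoresus simulate --seed 3 --n-exp 22 --n-ctrl 15 --out sim_out
autoresus extract sim_out/bundles --out features
autoresus analyze features/cohort.csv features/bouts.csv --out stats.json
autoresus report stats.json
```

`simulate` writes one bundle directory per pup (`trace.csv`,
`timeline.json`, `ground_truth.json`, `pup.json`). `--compact` (default)
uses a shortened 200 Hz assay timeline; `--full` uses the full-length
1 kHz protocol (20 min acclimation, injection, four asphyxia bouts with
330-s recovery windows). Extraction outputs `cohort.csv` (one row per pup),
`bouts.csv` (one row per pup x analyzed bout) and `stats.json`.

## Library use

```python
from autoresus import CohortConfig, RunConfig, run

cohort = CohortConfig.compact(n_experimental=22, n_control=15, seed=7)
cohort_df, bouts_df, report = run(RunConfig(generate=True, cohort=cohort,
                                            out_dir="out"))
print(report["mortality"])
```

## Notes on units

Volume figures follow the instrument-sheet ("printed") convention in which
tidal volume is ~4.5 units/g; one printed unit corresponds to 1e-3 ml in
the physical waveform synthesis (`autoresus.synth.PRINTED_VOLUME_SCALE`).
Ratios such as VE/VO2 are scale-invariant. Time is seconds from record
start; windows are closed-open.
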