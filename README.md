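# carotidflow

Analysis pipeline for exercise-induced carotid blood-flow patterns: it
estimates endothelial shear stress (ESS) from pulsatile centerline velocity
waveforms via the analytical oscillatory-flow (Womersley) solution,
classifies flow by Reynolds number, and runs a repeated-measures statistical
analysis (random-intercept mixed model with Type-III Satterthwaite F tests,
Holm-corrected paired post-hocs with Hedges' g, bootstrap CV reliability,
Reynolds confidence intervals).  A seeded synthetic-waveform generator
produces participant-structured studies calibrated to published
condition-level ESS distributions, so the full pipeline can be exercised and
validated without the original ultrasound recordings.

## Modules

- `carotidflow.hemodynamics` — waveform/geometry/blood types, Fourier
  decomposition, per-harmonic Womersley wall-shear transfer (complex Bessel
  functions), ESS time series in dyn/cm², Reynolds number and flow-regime
  classification (undisturbed < 200, disturbed 200–1800, indeterminate
  1800–2000, turbulent > 2000).
- `carotidflow.synthetic` — canonical 8-harmonic carotid-like cycle,
  ESS-target calibration by linear scaling, and `generate_study` (participant
  random intercepts with a configurable ICC, truncated-normal draws,
  per-participant seed substreams).
- `carotidflow.mixedmodel` — from-scratch REML random-intercept fit
  (profiled variance ratio, closed-form per-group GLS) with Satterthwaite or
  containment denominator df.
- `carotidflow.statistics` — pairwise families, Holm adjustment, paired
  Hedges' g with magnitude bands, summary-statistics t tests, CV with
  percentile-bootstrap CI, Shapiro–Wilk check, per-condition Reynolds CIs.
- `carotidflow.io`, `carotidflow.config`, `carotidflow.cli` — CSV schemas,
  YAML config, click CLI.

## CLI

```bash
carotidflow simulate    --seed 1 --outdir run      # waveforms.csv, truth.csv
carotidflow compute-ess run/waveforms.csv --outdir run   # results.csv
carotidflow analyze     run/results.csv --outdir run     # anova.csv, pairwise_*.csv,
                                                         # reliability.csv, re_summary.csv, report.md
carotidflow report      --seed 1 --outdir run      # all of the above in one go
```

All commands accept `--config config.yaml` (keys: `seed`, `n_participants`,
`icc`, `n_harmonics`, `samples`, `n_boot`, `df_method`, `heart_rates`,
`ess_targets`, `outdir`); `--seed`/`--outdir` flags override the file.

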