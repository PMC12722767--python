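# respmon

Continuous respiratory-state monitoring for ICU time series, end to end:

- **Gridding & imputation** — long-format observations (patient id, timestamp,
  variable id, value) are resampled onto a 5-minute grid anchored at the first
  heart-rate measurement (capped at 28 days), with per-variable forward-fill
  policies (indefinite, fixed-horizon, data-adaptive `2·median + IQR`, or
  exact-grid-point) in two modes: *dense* (every value finite, for annotation)
  and *feature* (missingness preserved, for modelling).
- **Oxygenation** — continuous PaO2 estimation from pulse oximetry via the
  closed-form Severinghaus/Ellis dissociation-curve inversion, refined by two
  nested robust (Huber-loss, L2-penalised) regressions on degree-3 polynomial
  context features and the model's own prior signed errors; FIO2 rule cascade
  (ventilator / supplemental / high-flow / ambient air); Nadaraya–Watson
  smoothed P/F ratio.
- **Endpoints** — respiratory-failure severity (forward 1-h two-thirds rule,
  right-edge correction, sandwich post-processing), ventilation status (point
  voting plus gap/short-event clean-up) and readiness-to-extubate (13-criterion
  violation score, trailing 1-h two-thirds rule).
- **Labels** — the four prediction tasks: failure onset, ventilation onset,
  readiness onset (24-h horizons) and extubation failure (48-h re-intubation,
  30-min augmentation, death-censoring, tracheostomy and off-unit rules).
- **Features** — current values, multi-resolution summaries (10/26/63/156 h;
  median/IQR/trend), measurement intensity, instability history, statics.
- **Models & evaluation** — gradient-boosted tree models with AUPRC-guided
  early stopping, exact TreeSHAP attributions (own implementation), greedy
  forward variable selection by mean reciprocal rank, calibration reports,
  clinical baselines (decision tree, SpO2/FIO2 threshold, readiness score),
  alarm generation with 4-h silencing and 30-min post-recovery re-arm,
  event-based precision/recall, earliness, detectable-prevalence floors,
  prevalence correction and bootstrap subgroup analyses.
- **Resource planning** — hourly unit census, per-patient ventilation
  probabilities summed with an admissions regressor to forecast ventilator
  demand over 4–24 h windows, against a persistence baseline.
- **Synthetic cohort** — a seeded latent-state ICU simulator (`respmon.simulate`)
  with known ground truth emits HiRID-like long-format tables, so the whole
  pipeline runs and is tested without any external data.

## CLI

```bash
respmon simulate --n-stays 100 --seed 1 --out-dir sim/
respmon annotate --obs sim/observations.csv --statics sim/statics.csv --out-dir annotated/
respmon train    --obs sim/observations.csv --statics sim/statics.csv --task RF --out report.json
respmon evaluate --obs sim/observations.csv --statics sim/statics.csv --out eval.json
respmon plan     --obs sim/observations.csv --statics sim/statics.csv --horizon 8-16 --out plan.csv
```

The variable schema (kinds, units, imputation modes, normal values, severity
thresholds) ships as `respmon.schema.default_schema()` and round-trips through
YAML (`--schema-yaml`).

## Layout

| module | contents |
| --- | --- |
| `respmon.schema` | variable specs, stay records, constants |
| `respmon.gridding` | 5-min gridding, adaptive horizons, imputation, training stats |
| `respmon.oxygenation` | Severinghaus/Ellis, SpO2 smoothing, PaO2/FIO2/P-F tracks |
| `respmon.endpoints` | failure / ventilation / readiness annotators |
| `respmon.labels` | task label construction |
| `respmon.features` | feature-matrix assembly |
| `respmon.treeshap` | exact path-dependent SHAP for tree ensembles |
| `respmon.modeling` | splits, task models, selection, calibration, baselines |
| `respmon.alarms` | alarm policy, event-based metrics, prevalence correction, fairness |
| `respmon.resource` | census, demand forecasting, persistence baseline |
| `respmon.simulate` / `respmon.fixtures` | synthetic cohort + golden rule fixtures |
| `respmon.pipeline` / `respmon.experiments` | orchestration and seeded experiments |
| `respmon.io` / `respmon.cli` | long-format IO and the `respmon` CLI |
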