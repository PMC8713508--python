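# sidkit

Statistics and prediction models for bedside **signs of impending death**
(SID) in longitudinal dying-phase cohorts:

- **Cohort model & I/O** (`sidkit.core_cohort`) — patients with a single
  terminal status (death or one of six discontinuation reasons),
  ~12-hourly observations of 11 physical signs (ternary flags) and six
  vitals, CSV round-tripping, first-event derivation, and the
  observation-discontinuation rules (meal intake for 2+ days, 60-day limit).
- **Shock index** (`sidkit.vitals_features`) — SI = HR / SBP, the derived
  "SI > 1.0" predictor event (strict inequality), and backward-binned
  vitals trajectories over the final 7 days before death.
- **Per-sign statistics** (`sidkit.sign_statistics`) — prevalence within
  72 h of death, mortality within 72 h / 24 h of first appearance, and the
  backward Kaplan–Meier median onset (days before death) with a
  Brookmeyer–Crowley (log(−log)) 95% CI.
- **OR-rule search** (`sidkit.rule_search`) — the prediction probability of
  a subset of the 12 predictors at a horizon (7 d / 72 h / 24 h), exhaustive
  best-subset search over all C(12, m) combinations for every m = 1…12, and
  seeded 10-fold cross-validation with per-fold subset re-selection
  (micro-averaged by default).
- **Synthetic cohorts** (`sidkit.synthetic_cohort`) — a seeded generator
  whose per-sign occurrence probabilities and median onset leads default to
  the packaged reference count table, with vitals drifting so the shock
  index crosses 1.0 near death, plus a calibration report.
- **CLI** (`sid`) — `generate`, `stats`, `search`, `report`.

The rule semantics: a decedent is a *success* for subset S at horizon h iff
at least one member of S occurs before death and death follows within h of
the **earliest** member event. The denominator is all decedents; censored
patients are excluded with a warning.

## CLI

```sh
sid generate --n 50 --seed 7 --out-dir out/            # synthetic cohort CSVs
sid stats  --patients out/patients.csv --observations out/observations.csv \
           --out out/sign_summary.csv                  # per-sign summary table
sid search --patients out/patients.csv --observations out/observations.csv \
           --horizon 7d --m 1..12 --k 10 --seed 7 --out out/models_7d.csv
sid report --patients out/patients.csv --observations out/observations.csv \
           --out-dir out/report --seed 7               # summary + all horizons + manifest
```

Outputs are deterministic given the seed (byte-identical CSVs on re-run)
and re-parseable by `sidkit.core_cohort.read_cohort` /
`pandas.read_csv`. Report percentages are printed to one decimal with
full-precision companion columns.

## Data layout

Patient CSV: `patient_id, age, sex, diagnosis, charlson, obs_start_h,
terminal_h, terminal_status, censor_reason`. Observation CSV:
`patient_id, time_h, <11 sign columns 0/1/empty>, sbp, dbp, hr, temp, rr,
spo2` (empty cell = missing). Time is in hours from the cohort origin. The
mapping from sign column identifiers to display names ships as
`sidkit/data/sign_names.json`.
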