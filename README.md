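# oculopd

Analysis pipeline for VR eye-tracking recordings from a lateralised
pro-/anti-saccade protocol, aimed at screening for early-stage Parkinson's
disease. The package covers the full chain:

1. **protocol** — task structure (1 s fixation, 1.2 s lateral stimulus, 2 s
   rest; 40 trials per task, 20 per side), domain types, and CSV
   interchange formats for recordings and event logs.
2. **synthdata** — synthetic cohorts with known generating truth:
   minimum-jerk saccades, behavioural rules for pro/anti trials (direction
   errors, corrective saccades), band-structured pupil oscillations,
   blinks. Group profiles are centred on published group-level summary
   scales and are illustrative, not a claim of fidelity.
3. **preprocess** — blink/artifact detection (validity flags, pupil bounds,
   slew limit), short-gap interpolation of pupil channels, per-trial
   exclusion. Gaze channels are never interpolated.
4. **saccades** — velocity-hysteresis saccade detection (spline-refined
   peak velocity), trial scoring (latency, accuracy, direction errors,
   corrections, time-to-complete), and the 14-parameter per-subject
   summary.
5. **pupilspec** — single-sided amplitude spectra (`2/N |DFT|`) of pupil
   traces on a 0.1 Hz grid up to 19 Hz (191 bins), averaged over
   consecutive 10 s windows; band labels low (0–6 Hz), medium (7–12 Hz),
   high (13–19 Hz).
6. **stats** — Shapiro–Wilk-gated two-group comparison (pooled t vs
   Mann–Whitney U, alpha = 0.05, uncorrected), summary-statistic pooled t,
   per-band significant-bin counting with both-eye totals, and report
   tables.
7. **diagnose** — feature matrices for six feature-set configurations
   (basic / freq-pro / freq-anti / combinations / all), significance-based
   feature selection *inside* each training fold, repeated stratified
   k-fold Random-Forest evaluation, and the end-to-end pipeline with CSV
   tables, figures, and a JSON run log.

Note: per-frequency significance is reported at uncorrected alpha = 0.05
across 191 bins by design; treat band counts as descriptive.

## CLI

```bash
oculopd report --out out/ --seed 1           # default synthetic end-to-end run
oculopd report --dump-config --out out/      # print effective config (YAML)
oculopd simulate --config cfg.yaml --out data/
oculopd analyze --recordings data/ --out out/ --tasks pro,anti
```

`analyze` expects a `subjects.csv` manifest (subject_id, group) plus
`<subject>_<task>_recording.csv` / `<subject>_<task>_events.csv` files in
the formats written by `simulate`.

## Library usage

```python
from oculopd import CohortConfig, simulate_cohort
from oculopd.diagnose import extract_cohort_features, cohort_tables, build_feature_matrix, evaluate

cohort = simulate_cohort(CohortConfig(n_pd=43, n_control=25, seed=1))
summaries, features = extract_cohort_features(cohort)
tables = cohort_tables(summaries, features)          # comparison + band counts
report = evaluate(build_feature_matrix(summaries, features, "all"), seed=1)
print(report.accuracy)
```
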