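# apnealab

Detection and paired analysis of cardiorespiratory events in premature
infants: breathing pauses (apnea of prematurity), intermittent-hypoxia (IH)
episodes and bradycardia episodes, scored from bedside-monitor recordings and
compared within subject between 6-hour stimulation ON/OFF blocks.

The package is written for researchers analysing neonatal crossover studies in
which an intervention (here, mild limb vibration) alternates ON and OFF over a
24-h monitoring window and the question is whether event burden falls during
the ON periods.  It also ships a synthetic-data generator that produces
labelled recordings and 15-subject cohort tables with the same statistical
structure, so the entire pipeline is testable without clinical data.

## Event definitions

All thresholds are configurable; defaults follow standard neonatal practice:

| outcome | definition |
|---|---|
| short breathing pause | silent time `d` in the effort signal with 3 s < `d` ≤ 5 s |
| long breathing pause | silent time `d` > 5 s |
| IH episode | SpO2 strictly below 90 / 88 / 85 % for ≥ 5 s (per threshold) |
| mild / moderate bradycardia | heart rate strictly below 110 / 100 bpm (≥ 1 s) |

A pause is the inter-breath interval minus one median breath period (clipped
at zero): the silent time beyond one expected cycle, so slow but regular
breathing is not scored as apnea.  SpO2 is evaluated on the oximeter-averaged
trace (trailing 8-s moving average, the averaging time of the study
oximeters).  Episodes are assigned to the 6-h block containing their onset and
never split across boundaries.

## Statistics

For each of 14 outcomes (7 counts + 7 total durations), per-subject totals in
the 12 h OFF vs the 12 h ON are compared with a **paired t-test on
ln(x+1)-transformed values** (the transform that normalises right-skewed event
counts); raw-scale means ± SE and the mean difference MD = OFF − ON are
reported for interpretability, so a positive MD is a reduction under
stimulation.  Normality of the transformed differences is screened with
Shapiro–Wilk and Lilliefors-corrected Kolmogorov–Smirnov tests (reported, not
enforced); p values are two-sided with no multiplicity correction.  The
per-subject percent-change table uses 100·(ON − OFF)/OFF, so there a negative
value is a reduction.

## Worked example

```python
import apnealab as al

cohort = al.generate_cohort(n_subjects=15, seed=42)        # synthetic cohort
report = al.cohort_report(cohort, transform_kind="lnp1")
print(al.format_report(report))
```

prints (first rows):

```
| outcome           | OFF mean±SE   | ON mean±SE   | MD    | %change | t     | df | p          |
| pause_long_count  | 174.3±27.1    | 107.3±13.5   | 67.1  | 38%     | 4.586 | 14 | 0.000424 * |
| pause_long_dur    | 1342.1±201.2  | 807.1±103.2  | 535.0 | 40%     | 4.575 | 14 | 0.000432 * |
| desat_lt90_count  | 110.1±15.9    | 80.5±12.7    | 29.5  | 27%     | 3.919 | 14 | 0.00154  * |
```

i.e. this simulated cohort shows a 38 % reduction in long-pause counts under
stimulation (MD ≈ 67 pauses per 12 h), significant on the transformed scale at
t(14) = 4.59.  Signal-level detection works the same way:

```python
params = al.SimParams(duration_h=2.0, sample_rate=50.0, spo2_rate=5.0,
                      hr_rate=5.0, seed=1)
schedule = al.StimulationSchedule.standard("off_first", block_hours=0.5)
recording, truth = al.generate_recording(params, schedule)
events = al.assign_events(al.detect_events(recording), schedule)
```

See `examples/` for narrative scripts (`detect_events.py`,
`cohort_statistics.py`, `score_detectors.py`), each printing the numbers it
computes and what they mean.  A thin CLI wraps the same functions:

```sh
apnealab simulate --n-subjects 15 --seed 1 --out sim/
apnealab stats --cohort sim/cohort.csv --out results/
apnealab detect --input rec.edf --schedule off-first --out out/
```

## File formats

* **Recordings**: EDF (read via mne; a minimal 16-bit writer is included), or
  a *CSV bundle* — one `time_s,value[,valid]` CSV per channel plus a
  `manifest.yaml` mapping channel roles (`resp`, `ecg`, `hr`, `spo2`) to files
  and rates.  Physically impossible samples (SpO2 outside [0, 100],
  non-positive HR) are masked invalid, never imputed or dropped.
* **Events**: CSV with columns `subject_id, type, threshold_label, onset_s,
  duration_s, condition`, sorted by onset.
* **Cohort tables**: CSV or XLSX, one row per subject, columns
  `<outcome>_<count|dur>_<off|on>` for each outcome stem (`pause_short`,
  `pause_long`, `desat_lt90`, `desat_lt88`, `desat_lt85`, `brady_lt110`,
  `brady_lt100`) plus `subject_id`, `order`, `valid_time_off/on`.
  `read_cohort_table(path, column_map=...)` renames foreign headers.  A
  per-participant spreadsheet of a real study, converted to these columns and
  placed at `data/participant_dataset.xlsx`, is analysed by the same
  `cohort_report` call (see `tests/test_acceptance.py`).

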