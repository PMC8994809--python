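# moodews

Early warning signals (EWS) for manic and depressive transitions in
ecological momentary assessment (EMA) time series.

## The problem

Patients with bipolar disorder can shift abruptly between mood states.
Complex-dynamical-systems theory predicts that, when such a shift is a
critical transition, the system shows *critical slowing down* as it
approaches the tipping point: perturbations linger longer and
fluctuations grow.  In intensive longitudinal self-report data this
manifests as rising **lag-1 autocorrelation** and rising **standard
deviation** of momentary affect/symptom states — generic early warning
signals that could, in principle, power personalized relapse alerts.

`moodews` implements the full idiographic analysis for this design:

* **Weekly scales.** Manic symptoms on the Altman Self-Rating Mania
  Scale (ASRM, 0–20) and depressive symptoms on the Quick Inventory of
  Depressive Symptomatology (QIDS-SR, 0–48).  A *transition* is an
  abrupt (within one week) rise of ≥ 6 points with no comparable rise
  in the two preceding weeks.
* **EMA states.** 17 momentary states (cheerful, worry, agitated, full
  of ideas, ...) on continuous 0–100 sliders, five scheduled beeps per
  day with realistic (~24%) missingness.
* **Moving-window indicators.** Each pre-transition segment is
  winsorized (P5/P95) and detrended with a Gaussian-kernel smoother
  (a linear within-window variant is available); AR(1) — the
  least-squares slope of x_t on x_(t−1) over same-day pairs, overnight
  lags excluded — and SD are estimated in 70-slot (two-week) windows
  sliding one slot at a time.
* **Trend testing.** Mann–Kendall's S and τ over the indicator values
  of the final two pre-transition weeks, with the Hamed–Rao variance
  correction for the strong serial dependence that overlapping windows
  induce, then Benjamini–Hochberg FDR (q = .05) across all tests of a
  patient.  Only significant *rises* (τ > 0) count as EWS.
* **Predictive value.** Sensitivity over transition segments,
  specificity over ~245-beep stable control segments of
  non-transitioning patients, and

      PPV = sens·prev / (sens·prev + (1 − spec)(1 − prev))
      NPV = spec·(1 − prev) / ((1 − sens)·prev + spec·(1 − prev))

  against the transition prevalence, per momentary state and averaged
  ("alarm in at least one state").

Because raw patient data of this kind are not publicly deposited, the
package ships a first-class synthetic-data generator
(`moodews.synthetic`) that emulates both data streams with known ground
truth: latent AR(1) momentary states whose coefficient and/or
innovation SD ramp up linearly before a programmed transition, bounded
0–100 responses, independent overnight innovations, MCAR missingness,
and weekly scales with programmable jumps.  Every downstream stage is
therefore testable end to end.

## Worked example

Run the full pipeline on a 20-patient synthetic cohort shaped like a
typical monitoring study — 11 transitioning patients (four with two
transitions: 7 manic + 8 depressive in total) and 9 non-transitioning
patients of whom 7 yield stable control segments, with AR ramps
(0.2 → 0.7 over the final fortnight) planted in three states per
transition:

```python
from moodews import PipelineConfig, run_pipeline
from moodews.experiments import paper_like_cohort_config

config = PipelineConfig(
    outdir="ews_run",
    sim=paper_like_cohort_config(seed=7),
    seed=7,
)
report = run_pipeline(config)
print(f"patients: {report['n_patients']}, transitions: {report['n_transitions']}, "
      f"segments: {report['n_segments']}")
print("prevalence:", {k: round(v, 3) for k, v in report["prevalence"].items()})
print("mean EWS per segment:", report["mean_ews_per_segment"]["ar1"])
```

prints

```
patients: 20, transitions: 15, segments: 22
prevalence: {'manic': 0.318, 'depressive': 0.364}
mean EWS per segment: {'manic': 0.8571428571428571, 'depressive': 0.75, 'control': 0.14285714285714285}
```

The 22 analysis segments (15 pre-transition + 7 control) give manic and
depressive transition prevalences of 32% and 36% — the baselines any
useful alarm must beat.  On average ~0.8 states show a significant
autocorrelation EWS before a transition versus ~0.14 in stable
controls.  The averaged rows of the evaluation table:

```python
import pandas as pd
table = pd.read_csv("ews_run/evaluation.csv")
avg = table[table.state == "__any_state__"][
    ["indicator", "transition_kind", "sensitivity", "specificity", "ppv", "npv"]
]
print(avg.round(2).to_string(index=False))
```

```
indicator transition_kind  sensitivity  specificity  ppv  npv
      ar1           manic         0.43         0.86 0.58 0.76
      ar1      depressive         0.25         0.86 0.50 0.67
       sd           manic         0.43         1.00 1.00 0.79
       sd      depressive         0.50         1.00 1.00 0.78
```

Reading the first row: when at least one momentary state showed a
significant autocorrelation rise, the probability of an impending manic
transition was 58%, up from the 32% base rate; the absence of any alarm
raised the probability of *no* manic transition from 68% to 76%.  Note
the many missed transitions (sensitivity ≤ 0.5): with two weeks of
heavily overlapping windows the corrected trend test is conservative,
so absent alarms are weak evidence of stability — the central caveat
for clinical use.

The same pipeline runs from the shell (`moodews simulate`,
`detect-transitions`, `preprocess`, `ews`, `test`, `evaluate`,
`run-all`), reading and writing plain CSV/JSON artifacts plus the
resolved YAML configuration, and accepts user-supplied EMA/weekly CSVs
in place of simulation (`PipelineConfig(simulate=False, ema_path=...,
weekly_path=...)`).

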