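# pedaki

Early prediction of acute kidney injury (AKI) in pediatric critical care.

AKI affects a substantial fraction of PICU patients and is diagnosed, per the
KDIGO guidelines, only after serum creatinine has already risen — too late
for prevention. `pedaki` implements a complete retrospective toolchain for a
creatinine-based pediatric AKI early-warning system: KDIGO serum-creatinine
cohort labeling, 6-hourly windowed EHR feature engineering, an
age-conditioned additive ensemble of lookup-table weak classifiers that
predicts moderate-to-severe (stage 2/3) AKI up to 48 h before onset with a
per-prediction explanation, a renal-angina-index (RAI) comparator, and an
episode-level evaluation protocol. Because real pediatric ICU records cannot
be redistributed, the package ships a seeded synthetic EHR generator with
exact ground truth, so every stage is testable offline.

It is intended for clinical-informatics researchers and data scientists who
want a transparent, reproducible reference implementation of this class of
alerting model — not a bedside device.

## The model

KDIGO serum-creatinine staging, with baseline `SCr_base` the age/sex normal
mean and `rise48` the rise over the prior 48 h:

| stage | criterion |
|---|---|
| 3 | SCr ≥ 3.0 × baseline, or SCr ≥ 4.0 mg/dL, or renal replacement therapy |
| 2 | SCr ≥ 2.0 × baseline |
| 1 | SCr ≥ 1.5 × baseline, or rise48 ≥ 0.3 mg/dL |

The risk model is additive in probability space:

```
risk(t) = clip( b0 + Σ_j C_j(age, x_j(t)), 0, 1 )
```

where each weak classifier `C_j` is a lookup table over (age bin, value bin)
for one windowed predictor `x_j` — e.g. the maximum shock index over the past
30 h, the least-squares creatinine slope over the past 48 h (CRoC), or the
number of high-nephrotoxic-potential drug administrations in the past week —
with a dedicated cell for missing values, so no imputation is ever needed.
`b0` is the training prevalence. Because the prediction is a plain sum, the
contribution of every predictor can be separated, ranked, and shown to the
clinician next to the alert ("CRoC contributes +0.60; patient on
aminoglycosides — check level and review dose and indication").

Fitting is squared-loss cyclic boosting over the cell tables with
count-shrunk updates, and predictors enter by greedy forward selection
scored on validation AUROC. Models are evaluated per *episode* (one labeled
encounter): sensitivity and PPV of alerts in the 6–48 h pre-onset window,
lead-time distribution, AUROC resolved by lead time, and the same harness
applied to the RAI comparator.

## Worked example

Run the full pipeline on the default 500-encounter synthetic demo cohort:

```
$ pedaki run --out demo/
{
  "pooled_auroc": 0.6471477607061131,
  "episode_metrics": {
    "any_aki": {"tp": 5, "fp": 5, "fn": 10, "n_outcome_episodes": 15,
                "sensitivity": 0.333, "ppv": 0.5, "tp_fp_ratio": 1.0},
    "stage23": {"tp": 1, "fp": 9, "fn": 3, "n_outcome_episodes": 4,
                "sensitivity": 0.25, "ppv": 0.1, "tp_fp_ratio": 0.111},
    "rrt":     {"tp": 0, "fp": 10, "fn": 2, "n_outcome_episodes": 2,
                "sensitivity": 0.0, "ppv": 0.0, "tp_fp_ratio": 0.0}
  },
  "median_lead_h": 46.57
}
```

`pooled_auroc` is the discrimination of the model over all holdout
predictions made 6–48 h before (pseudo-)onset; `sensitivity` is the fraction
of outcome episodes with at least one alert in that window; `median_lead_h`
is the median warning time the alerts would have bought. At demo scale the
holdout contains only four stage-2/3 episodes, so these numbers are noisy by
design — at the study scale (2000 encounters, `n_encounters: 2000` in the
config, or `scripts/acceptance.py` below) the holdout pooled AUROC is ≈ 0.96
with a validation-tuned one-to-one true-to-false any-AKI alert ratio. All
artifacts
(labels, features, model tables, predictions, RAI, report.json and a
SHA-256 manifest) land in `demo/`; a rerun with the same config is
byte-identical. Individual stages are exposed as subcommands
(`pedaki simulate | validate | label | featurize | train | predict |
explain | rai | evaluate`), and the same functionality is importable from
`pedaki.*` modules.

To inspect why one prediction fired:

```
$ pedaki explain --model demo/model --features demo/features.csv \
    --data-dir demo/data --at E00042,36.0
```

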