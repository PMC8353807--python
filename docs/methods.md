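# Methods

## Cohort labeling

AKI is staged from serum creatinine alone (the urine-output arm of the KDIGO
guidelines is deliberately out of scope: ICU urine records are too unreliable
to stage from). The staging baseline is the *static* age/sex normal mean
creatinine — never a measured minimum — looked up in a half-open age-interval
table; the 0.3 mg/dL-in-48 h rise clause uses the rolling measured minimum
over the half-open lookback `(t − 48 h, t]`. The stage-3 absolute clause
(SCr ≥ 4.0 mg/dL) is included and can be disabled
(`stage_creatinine_series(..., use_abs_stage3=False)`).

The packaged baseline table (`pedaki/data/baseline_creatinine.csv`) is
transcribed from standard pediatric normative means and **must be reviewed**
before use on real data, as must the drug-category map
(`pedaki/data/drug_categories.csv`), which is a reasonable but non-exhaustive
classification of high/low-nephrotoxic-potential and vasoactive agents. Both
files are plain CSV precisely so they can be replaced.

Onset is the first measurement contributing to stage ≥ 2 for primary cases,
the first stage ≥ 1 measurement for mild (stage-1-only) encounters, and a
seeded uniform pseudo-onset in `[admit + 24 h, discharge]` for controls —
the lower bound guarantees controls contribute grid points, and stays under
24 h are excluded anyway. Exclusions: age outside [1, 252] months or missing;
any stage ≥ 1 creatinine in the first 12 h of stay; stay < 24 h; one
encounter per patient (highest stage, then longest stay, then earliest
admission). Splitting is by patient, stratified by primary-case status,
using largest-remainder allocation at 70/15/15.

## Feature engineering

Predictions are made every 6 h from admission, truncated at onset for
stage ≥ 1 encounters. All windows are half-open lookbacks `(t − W, t]` with
the value at `t` included — a single convention applied to window statistics
(30 h), the creatinine slope (48 h) and medication counts (168 h). `change`
is last − first within the window. The shock index pairs each heart-rate
point with the nearest systolic blood pressure within 15 min (conventional
definition; the tolerance absorbs asynchronous charting). An empty window is
MISSING (NaN); medication categories with no events count 0; the
mean-airway-pressure predictor is MISSING whenever the patient is not
ventilated. Age at the grid time advances with time since admission
(1 month = 730.5 h) and is capped at 252 months. No unit conversion is
performed anywhere; units are trusted as charted (including the PaCO2 unit
printed as "%", kept as given).

Training examples are grid points with lead time in [24, 48] h before
(pseudo-)onset, labeled with the stage-2/3 primary outcome; the holdout
window extends to [6, 48] h.

## The age-conditioned additive ensemble

Each weak classifier is a lookup table over (age bin, value bin) plus a
dedicated missing cell per age bin. Age bins are fixed at
[1, 6, 12, 24, 72, 144, 192, 252] months; continuous predictors get 16
empirical-quantile value bins (deduplicated); integer-valued predictors
(counts) get one bin per integer up to 6 distinct values, with larger
supports pooling the overflow into the top bin so the sparse high-count tail
still lands in a populated cell.

Fitting is cyclic squared-loss boosting: for 50 rounds, each table in turn
updates every cell by

```
ΔC = lr · (Σ residual − λ·C) / (n + λ),    lr = 0.1,  λ = 20
```

where the residual is label − clipped risk. The update is a relaxation whose
fixpoint is `mean(partial residual) · n/(n + λ)` — i.e. the count shrinkage
*persists* at convergence instead of washing out. This matters at desk
scale: with ≈ 120 cells per table and a few hundred positive examples, an
unshrunk fixpoint chases per-cell noise, which destabilises forward
selection and inflates the variance cost of every added predictor.

Predictors enter by greedy forward selection: each unselected candidate is
tentatively fitted from scratch together with the current set and scored by
validation AUROC; selection stops at 15 predictors or when the gain drops
below 0.001. The final model is a fresh refit of the selected ordered set.
Everything is deterministic — there is no randomness anywhere in fitting.

Finalized tables and the intercept are quantized to multiples of 2⁻²⁰ risk
units. Contributions are then dyadic rationals with ≤ 20 fractional bits, so
floating-point sums of up to dozens of contributions are exact: additive
conservation (`b0 + Σ contributions = pre-clip score`) and single-classifier
ablation identities hold bit-for-bit, and model files diff cleanly. The
quantum (≈ 1e-6 risk) is far below any clinically meaningful resolution.

Contributions are reported in risk units as stored; negative contributions
appear in the full output but are excluded from the "top contributors" list
shown with an alert. The alert threshold is the smallest value whose
episode-level TP:FP ratio on validation reaches the target (default
one-to-one for any-AKI), falling back to the max-Youden point when the
target is unattainable.

## Renal angina index comparator

RAI = risk stratum × injury stratum, angina at ≥ 8. Risk stratum is 5 for
patients both ventilated (any mean-airway-pressure charting in the past
24 h) and on vasoactive support (any administration in the past 24 h), else
1; the transplant stratum is disabled because transplant status is not in
the data model. The injury strata are the published estimated-clearance
decline bands translated to creatinine fold-change (clearance ∝ 1/SCr):
f ≤ 1 → 1, f < 4/3 → 2, f < 2 → 4, f ≥ 2 → 8; band edges are overridable.
The fluid-overload injury arm is omitted (no fluid-balance data), a
documented limitation. RAI is evaluated at every prediction grid time
through the identical episode machinery, with angina playing the alert role.

## Evaluation protocol

The unit of sensitivity/PPV is the episode (one encounter after exclusions).
An episode is alerted if any prediction at lead 6–48 h crosses the
threshold; the first alert is the one with the largest lead. False-positive
pools per outcome: any-AKI counts only stage-0 episodes as false alarms;
stage-2/3 counts stage ≤ 1; RRT counts episodes without RRT. Raw
TP/FP/FN counts are always reported next to the rates because the
denominators differ by outcome. Lead-resolved AUROC compares case and
control predictions within the same 6 h lead bin (controls' leads are
relative to their pseudo-onset, mirroring case windows); per-bin results
with fewer than two cases or controls are omitted. Subgroup AUROC uses the
CDC age groups (1 mo–2 y, 2–12 y, 12–16 y, 16–21 y) and the ICU unit type.

## The synthetic cohort generator

The generator emulates the *structure* of pediatric ICU EHR data with exact
ground truth; it does not claim demographic realism. Per encounter: age
log-normal (median 48 months, σ = 1.3, clipped to [1, 252]); stay log-normal
(median 4 days, σ = 0.6, capped at 30 days); vitals roughly hourly, SpO2
2-hourly, labs every 12–24 h with per-variable encounter-level missingness
(e.g. gentamicin trough present in 12% of encounters); 40% ventilated; 20%
CTICU. Stage-2/3 cases are 5% of encounters (a typical pediatric rate),
stage-1-only 7%, and 20% of stage-2/3 cases receive RRT starting 2–12 h
after onset. Cases and controls have near-identical stay conditioning
(cases only require room for an onset ≥ 30 h), so stay length and grid
position carry no class information by construction.

Creatinine trajectories are piecewise-linear latent curves times 3%
multiplicative noise (truncated at 2.5 σ), snapped to whole minutes so CSV
round trips are exact. Controls stay below every stage-1 clause; stage-1
encounters reach [1.5, 2.0)× baseline but never 2.0×; stage-2/3 cases first
reach ≥ 2.0× exactly at the true onset, preceded by a latent creep toward
1.45× baseline beginning 56–72 h pre-onset. A staging-oracle rejection step
re-draws the noise (then the encounter, up to a retry cap) until the
intended class is realised, so labeling recovers the truth exactly.

Pre-onset covariate signals are controlled by four effect sizes —
BUN drift (+18 mg/dL at full severity), shock-index elevation (+45% of the
age norm via heart rate up / SBP down), high-nephrotoxic administration
intensity (+3.0/day on a 0.2/day background), and the creatinine creep
(CRoC) — with the covariate insult saturating 24 h after drift start
(the physiological insult precedes and plateaus before the creatinine rise).
Each case draws one dominant aetiology (shock, azotemia, or nephrotoxic
exposure, weight 2.4) with a 0.35 floor on the others and a uniform
creep weight in [0.5, 1.2]; stage-1 encounters express covariate signals at
0.3× (mild renal stress), making them plausible hard controls. These values
were chosen once as clinically plausible pre-AKI shifts that make each
predictor informative for a distinct share of cases. Setting all four
effects to zero yields a null cohort in which pre-onset data carry no
information about the coming label. The generating monotone risk surfaces
(normalised to [0, 1]) are exposed per signal predictor for shape-recovery
testing.

What passing tests on this generator do **not** show: performance on real
EHR data, with its charting artifacts, unit errors, informative missingness,
inter-site drift and urine-output-staged AKI. The generator's signals are
cleaner and its missingness more benign than reality; synthetic results are
an upper bound and a correctness harness, not a clinical validation.

## Numerical and statistical choices

- AUROC is Mann–Whitney with ties counted ½ (scikit-learn); tests verify it
  against brute-force pair counting.
- The creatinine slope uses centered normal equations (numerically stable
  against the cancellation the uncentered form suffers with clustered
  timestamps); fewer than two points, or zero time spread, is MISSING.
- Calibration uses risk deciles (`qcut`, duplicate edges dropped) and
  reports the mean absolute gap between mean predicted risk and observed
  event rate over occupied deciles.
- Degenerate inputs: a constant predictor collapses to one value bin;
  single-class validation labels abort fitting; encounters without
  creatinine are stage-0 controls; thresholds falling above every score
  yield zero alerts and undefined PPV, reported as NaN.
- All internal times are hours since admission (float, minute-resolution in
  simulated data); CSV timestamps are ISO-8601 UTC rounded to seconds.

## Problem sizes

Tests and the acceptance script use 2000-encounter cohorts (≈ 100 stage-2/3
cases; 70/15/15 patient-level split), the scale at which a desk machine
fits the whole pipeline in about a minute. At this scale the validation
split contains only ≈ 15 case episodes, and the forward-selection stop rule
(validation-AUROC gain < 0.001) operates near its noise floor: on some
cohort seeds one signal predictor is genuinely redundant given the other
three and is not selected before the stop fires. This is a property of
greedy selection on small validation sets worth knowing about when applying
the method, and it is why selection results should be read together with
the holdout AUROC rather than as a definitive variable-importance ranking.

## Known limitations

- Urine-output staging, eGFR-based stage 3, and chronic-kidney-disease
  history adjustment are out of scope.
- The RAI comparator omits the transplant and fluid-overload arms (data not
  modelled) and therefore underestimates the published index.
- The packaged baseline-creatinine and drug-category tables are editable
  defaults, not authoritative clinical references.
- One encounter per patient is assumed downstream of exclusions; the
  generator emits one encounter per patient by default.
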