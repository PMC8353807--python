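"""Synthetic pediatric-ICU cohort generator with known ground truth.

Emulates the *structure* of multi-center pediatric critical-care EHR data —
irregularly sampled vitals and labs, medication administrations, a ventilated
subset, renal-replacement-therapy episodes, and age/sex-dependent creatinine
trajectories with and without AKI — so that staging, featurization, training
and evaluation are all testable offline with an exact oracle.

Encounter classes (drawn per encounter):

- ``control``: creatinine stays strictly below both the 1.5x-baseline ratio
  and the 0.3 mg/dL-in-48 h rise;
- ``stage1``: creatinine reaches [1.5, 2.0) x baseline but never 2.0x;
- ``stage23`` (optionally with RRT): creatinine first reaches >= 2.0x baseline
  exactly at the true onset time, with a latent pre-onset drift beginning
  48-72 h earlier.

Pre-onset signal is injected through four configurable effect sizes (BUN
drift, shock-index elevation, high-nephrotoxic drug intensity, creatinine
ramp). Each signal predictor's generating risk surface — a monotone function
of (age, value) normalised to [0, 1] — is exposed in :class:`GroundTruth` so
that learned weak-classifier shapes can be checked against it. Setting every
effect size to zero yields a null cohort in which pre-onset data carry no
information about the coming label.

Trajectory noise is multiplicative with sigma = 3 %, truncated at 2.5 sigma,
and a rejection step re-draws the noise (then the encounter) until the
staging oracle confirms the intended class, so ground truth is unambiguous.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np
import pandas as pd

from . import cohort_labeling
from .ehr_data import (
    EncounterSet,
    MedicationStore,
    ObservationStore,
    RRTStore,
    EXPECTED_UNITS,
)

SIM_EPOCH = pd.Timestamp("2024-01-01T00:00:00Z")

NOISE_SD = 0.03
NOISE_CLIP = 2.5 * NOISE_SD

#: drug names emitted per category (a subset of the packaged default map)
DRUGS = {
    "high_nephrotoxic": ["gentamicin", "vancomycin", "tobramycin", "acyclovir"],
    "low_nephrotoxic": ["furosemide", "ceftriaxone", "piperacillin_tazobactam"],
    "vasoactive": ["epinephrine", "milrinone", "dopamine"],
}


class SimulationError(RuntimeError):
    """Raised when an encounter cannot be realised within the retry cap."""


@dataclasses.dataclass
class EffectSizes:
    """Strength of the pre-onset signals linking covariates to cases.

    Defaults are clinically plausible pre-AKI shifts at full severity:
    BUN +18 mg/dL, shock index +45 % of its age norm, +2.0 high-nephrotoxic
    administrations/day, and a creatinine ramp to 1.45x baseline just before
    the stage-2 crossing.
    """

    bun_shift: float = 18.0
    shock_index_shift: float = 0.45
    high_nephro_rate: float = 3.0  # extra administrations/day at full severity
    creat_ramp: float = 0.45  # pre-onset latent rise as a fraction of baseline

    def zeroed(self) -> "EffectSizes":
        return EffectSizes(0.0, 0.0, 0.0, 0.0)

    @property
    def all_zero(self) -> bool:
        return (
            self.bun_shift == 0
            and self.shock_index_shift == 0
            and self.high_nephro_rate == 0
            and self.creat_ramp == 0
        )


#: encounter-level probability that a variable is measured at all
DEFAULT_MISSINGNESS = {
    "bun": 0.95,
    "bilirubin": 0.60,
    "paco2": 0.50,
    "anion_gap": 0.80,
    "wbc": 0.90,
    "albumin": 0.70,
    "chloride": 0.90,
    "gentamicin_trough": 0.12,
}


@dataclasses.dataclass
class SimConfig:
    """Cohort-level simulation parameters (the study conditions)."""

    n_encounters: int = 500
    fraction_stage23: float = 0.05
    fraction_stage1_only: float = 0.07
    fraction_rrt_given_stage23: float = 0.2
    age_lognorm_median_months: float = 48.0
    age_lognorm_sigma: float = 1.3
    stay_lognorm_median_h: float = 96.0  # median ~= 4 days
    stay_lognorm_sigma: float = 0.6
    ventilation_prevalence: float = 0.4
    cticu_fraction: float = 0.2
    mortality: float = 0.04
    effects: EffectSizes = dataclasses.field(default_factory=EffectSizes)
    missingness: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.fraction_stage23, self.fraction_stage1_only,
                  self.fraction_rrt_given_stage23):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.fraction_stage23 + self.fraction_stage1_only > 1.0:
            raise ValueError("case fractions must sum to <= 1")


@dataclasses.dataclass
class GroundTruth:
    """Per-encounter truth plus the generating risk surfaces.

    ``surfaces`` maps signal-predictor name to a function
    ``f(age_months, value) -> relative risk in [0, 1]`` describing the latent
    monotone surface the covariate shifts were drawn from; used by
    shape-recovery tests against the fitted weak classifiers.
    """

    frame: pd.DataFrame  # index encounter_id; columns true_class, true_onset_h, ...
    surfaces: dict[str, Callable[[np.ndarray, np.ndarray], np.ndarray]]
    signal_predictors: tuple[str, ...]


# ---------------------------------------------------------------------------
# Age-dependent physiology norms
# ---------------------------------------------------------------------------


def heart_rate_norm(age_months: float | np.ndarray) -> np.ndarray:
    """Resting heart rate norm (bpm), ~150 in infancy to ~78 at 21 y."""
    return 150.0 - 30.0 * np.log10(np.asarray(age_months, dtype=float))


def sbp_norm(age_months: float | np.ndarray) -> np.ndarray:
    """Systolic blood pressure norm (mmHg), ~75 in infancy to ~111 at 21 y."""
    return 75.0 + 15.0 * np.log10(np.asarray(age_months, dtype=float))


def shock_index_norm(age_months: float | np.ndarray) -> np.ndarray:
    return heart_rate_norm(age_months) / sbp_norm(age_months)


def _surfaces(effects: EffectSizes) -> tuple[dict, tuple[str, ...]]:
    surfaces: dict[str, Callable] = {}
    signal: list[str] = []
    if effects.bun_shift > 0:
        shift = effects.bun_shift
        surfaces["bun_last"] = lambda age, v: np.clip((np.asarray(v) - 12.0) / shift, 0, 1)
        signal.append("bun_last")
    if effects.shock_index_shift > 0:
        rel = effects.shock_index_shift
        surfaces["shock_index_max"] = lambda age, v: np.clip(
            (np.asarray(v) / shock_index_norm(age) - 1.0) / rel, 0, 1
        )
        signal.append("shock_index_max")
    if effects.high_nephro_rate > 0:
        # weekly background exposure is ~1.4 events, so generated risk rises
        # from roughly the second administration upward
        scale = 2.0 * effects.high_nephro_rate + 1.0
        surfaces["high_nephrotoxic_count"] = lambda age, v: np.clip(
            (np.asarray(v, dtype=float) - 1.0) / scale, 0, 1
        )
        signal.append("high_nephrotoxic_count")
    if effects.creat_ramp > 0:
        surfaces["creatinine_roc"] = lambda age, v: np.clip(
            np.asarray(v) / 0.003, 0, 1
        )
        signal.append("creatinine_roc")
    return surfaces, tuple(signal)


# ---------------------------------------------------------------------------
# Creatinine trajectory
# ---------------------------------------------------------------------------


def _severity(t: np.ndarray, onset_h: float, drift_h: float) -> np.ndarray:
    """Latent creatinine severity: linear from 0 at onset - drift to 1 at onset."""
    start = onset_h - drift_h
    return np.clip((np.asarray(t, dtype=float) - start) / drift_h, 0.0, 1.0)


#: hours for the covariate insult to saturate after drift onset
COVARIATE_RAMP_H = 24.0


def _covariate_severity(t: np.ndarray, onset_h: float, drift_h: float,
                        ramp_h: float = COVARIATE_RAMP_H) -> np.ndarray:
    """Latent covariate severity: the physiological insult (nephrotoxic
    exposure, hypoperfusion, urea accumulation) begins 48-72 h before the
    creatinine crossing and saturates within ~24 h, while creatinine itself
    lags and keeps rising to onset."""
    start = onset_h - drift_h
    return np.clip((np.asarray(t, dtype=float) - start) / ramp_h, 0.0, 1.0)


def simulate_creatinine_trajectory(
    true_class: str,
    baseline_scr: float,
    onset_h: float | None,
    stay_h: float,
    rng: np.random.Generator,
    ramp: float = 0.45,
    drift_h: float = 60.0,
    rrt_intervals: np.ndarray | None = None,
    max_tries: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled creatinine series (times_h, mg/dL) realising ``true_class``.

    The class guarantee is enforced by a staging-oracle rejection step:
    controls never reach stage 1; ``stage1`` reaches [1.5, 2.0) x baseline but
    never 2.0x; ``stage23`` first reaches >= 2.0x exactly at ``onset_h`` (a
    sampled measurement time) and not before.
    """
    if baseline_scr <= 0:
        raise ValueError("baseline_scr must be positive")
    # irregular sampling ~ every 12 h from the first hour of stay;
    # times snap to whole minutes so CSV round-trips are exact
    times = [1.0 + rng.uniform(0.0, 2.0)]
    while times[-1] < stay_h - 4.0:
        times.append(times[-1] + rng.uniform(8.0, 16.0))
    t = np.round(np.array([x for x in times if x <= stay_h]) * 60.0) / 60.0
    if true_class != "control" and onset_h is not None:
        t = t[np.abs(t - onset_h) > 1.0]
        t = np.sort(np.append(t, onset_h))

    if true_class == "stage23":
        jump = rng.uniform(2.15, 2.6)
    elif true_class == "stage1":
        jump = rng.uniform(1.62, 1.85)
    else:
        jump = 1.0

    latent = np.full_like(t, baseline_scr, dtype=float)
    if true_class != "control" and onset_h is not None:
        pre = t < onset_h
        latent[pre] = baseline_scr * (1.0 + ramp * _severity(t[pre], onset_h, drift_h))
        latent[~pre] = baseline_scr * jump

    for _ in range(max_tries):
        noise = np.clip(rng.normal(0.0, NOISE_SD, len(t)), -NOISE_CLIP, NOISE_CLIP)
        v = np.round(latent * (1.0 + noise), 3)
        stages = cohort_labeling.stage_creatinine_series(
            t, v, baseline_scr, rrt_intervals
        )
        if true_class == "control":
            ok = stages.max(initial=0) == 0
        elif true_class == "stage1":
            ok = stages.max(initial=0) == 1
        else:
            first2 = np.argmax(stages >= 2) if (stages >= 2).any() else -1
            ok = (
                first2 >= 0
                and np.isclose(t[first2], onset_h)
                and not ((t <= cohort_labeling.EARLY_AKI_WINDOW_H) & (stages >= 1)).any()
            )
        if ok:
            return t, v
    raise SimulationError(f"could not realise class {true_class!r} within retry cap")


# ---------------------------------------------------------------------------
# Whole-cohort simulation
# ---------------------------------------------------------------------------


def _sample_times(rng: np.random.Generator, stay_h: float, mean_gap_h: float,
                  start_h: float = 0.5) -> np.ndarray:
    times = [start_h + rng.uniform(0.0, mean_gap_h)]
    while times[-1] < stay_h:
        times.append(times[-1] + rng.uniform(0.6 * mean_gap_h, 1.4 * mean_gap_h))
    return np.array(times[:-1]) if times[-1] >= stay_h else np.array(times)


def _poisson_events(rng: np.random.Generator, stay_h: float,
                    rate_per_day: Callable[[np.ndarray], np.ndarray]) -> np.ndarray:
    """Nonhomogeneous Poisson sampling on a 6 h grid."""
    edges = np.arange(0.0, stay_h, 6.0)
    out = []
    for lo in edges:
        hi = min(lo + 6.0, stay_h)
        lam = float(rate_per_day(np.array([(lo + hi) / 2.0]))[0]) * (hi - lo) / 24.0
        n = rng.poisson(lam)
        if n:
            out.append(rng.uniform(lo, hi, n))
    return np.sort(np.concatenate(out)) if out else np.empty(0)


def simulate_cohort(
    config: SimConfig,
) -> tuple[EncounterSet, ObservationStore, MedicationStore, RRTStore, GroundTruth]:
    """Generate a full synthetic cohort; bit-for-bit deterministic under seed."""
    baselines = cohort_labeling.BaselineTable.default()
    eff = config.effects

    enc_rows, obs_rows, med_rows, rrt_rows, truth_rows = [], [], [], [], []

    for i in range(config.n_encounters):
        rng = np.random.default_rng([config.seed, i])
        enc_id = f"E{i:05d}"

        # demographics
        sex = "F" if rng.random() < 0.5 else "M"
        age = float(np.clip(
            np.exp(rng.normal(np.log(config.age_lognorm_median_months),
                              config.age_lognorm_sigma)), 1.0, 252.0))
        unit = "CTICU" if rng.random() < config.cticu_fraction else "PICU"
        died = rng.random() < config.mortality
        baseline_scr = baselines.lookup(age, sex)

        u = rng.random()
        if u < config.fraction_stage23:
            true_class = "stage23"
            has_rrt = rng.random() < config.fraction_rrt_given_stage23
        elif u < config.fraction_stage23 + config.fraction_stage1_only:
            true_class, has_rrt = "stage1", False
        else:
            true_class, has_rrt = "control", False

        for attempt in range(20):
            # stay and onset placement; cases need room for a >= 30 h onset
            stay = float(np.exp(rng.normal(np.log(config.stay_lognorm_median_h),
                                           config.stay_lognorm_sigma)))
            stay = min(stay, 24.0 * 30)
            # near-identical stay conditioning for cases and controls, so
            # stay length and grid position carry no class information on
            # their own (cases only need room for an onset >= 30 h)
            if true_class == "control":
                if stay >= 26.0:
                    onset = None
                    break
            else:
                if stay >= 36.0:
                    onset = round(float(rng.uniform(30.0, stay - 6.0)) * 60.0) / 60.0
                    break
        else:
            raise SimulationError(f"{enc_id}: no feasible stay after retries")

        drift_h = float(rng.uniform(56.0, 72.0))
        sev = (lambda t: _covariate_severity(np.asarray(t, dtype=float), onset, drift_h)) \
            if onset is not None else (lambda t: np.zeros(np.shape(np.atleast_1d(t))))
        # heterogeneous aetiology: each case has one dominant mechanism
        # (shock-driven vs azotemia-dominant vs drug-driven) with faint
        # expression of the others, so no single predictor subsumes the rest
        # heterogeneous aetiology: each case expresses each covariate signal
        # independently (shock, azotemia, nephrotoxic exposure), at least one
        # active, so no single predictor subsumes the others yet every
        # predictor is informative across a majority of cases
        # heterogeneous aetiology: every case shows some creatinine creep and
        # a baseline level of each covariate signal, plus one dominant
        # mechanism (hypoperfusion/shock, azotemia, or nephrotoxic exposure),
        # so each predictor carries both shared and unique information
        mech = int(rng.integers(3))
        w_shock, w_bun, w_drug = (2.4 if mech == k else 0.35 for k in range(3))
        w_croc = float(rng.uniform(0.5, 1.2))
        if true_class == "stage1":
            # mild AKI: renal stress present but damped, so stage-1 stays a
            # plausible hard control for the stage-2/3 outcome
            w_shock, w_bun, w_drug = 0.3 * w_shock, 0.3 * w_bun, 0.3 * w_drug

        rrt_iv = None
        if has_rrt:
            start = round((onset + float(rng.uniform(2.0, 12.0))) * 60.0) / 60.0
            end = round(min(start + float(rng.uniform(24.0, 72.0)), stay) * 60.0) / 60.0
            if end > start:
                rrt_iv = np.array([[start, end]])
                rrt_rows.append((enc_id, start, end))

        t_cr, v_cr = simulate_creatinine_trajectory(
            true_class, baseline_scr, onset, stay, rng,
            ramp=eff.creat_ramp * w_croc, drift_h=drift_h, rrt_intervals=rrt_iv,
        )
        _emit(obs_rows, enc_id, "creatinine", t_cr, v_cr)

        # vitals: heart rate / SBP hourly, SpO2 every 2 h
        hr0, sbp0 = heart_rate_norm(age), sbp_norm(age)
        shock_scale = eff.shock_index_shift / 0.45 if eff.shock_index_shift else 0.0
        t_hr = _sample_times(rng, stay, 1.0)
        s = sev(t_hr) * w_shock
        hr = hr0 * (1.0 + 0.20 * s * shock_scale) + rng.normal(0, 7.0, len(t_hr))
        _emit(obs_rows, enc_id, "heart_rate", t_hr, np.round(hr, 1))
        t_bp = _sample_times(rng, stay, 1.0)
        s = sev(t_bp) * w_shock
        sbp = sbp0 * (1.0 - 0.17 * s * shock_scale) + rng.normal(0, 6.0, len(t_bp))
        _emit(obs_rows, enc_id, "sbp", t_bp, np.round(np.maximum(sbp, 30.0), 1))
        t_sp = _sample_times(rng, stay, 2.0)
        spo2 = np.minimum(100.0, 97.0 + rng.normal(0, 1.5, len(t_sp)))
        _emit(obs_rows, enc_id, "spo2", t_sp, np.round(spo2, 1))

        # labs
        lab_norms = {
            "bun": (12.0, 4.0, 12.0),
            "bilirubin": (0.7, 0.3, 24.0),
            "paco2": (40.0, 6.0, 12.0),
            "anion_gap": (12.0, 3.0, 24.0),
            "wbc": (10.0, 3.0, 24.0),
            "albumin": (3.8, 0.5, 24.0),
            "chloride": (104.0, 4.0, 24.0),
            "gentamicin_trough": (1.0, 0.4, 24.0),
        }
        for var, (mu, sd, gap) in lab_norms.items():
            if rng.random() >= config.missingness.get(var, 1.0):
                continue
            t_lab = _sample_times(rng, stay, gap, start_h=1.0)
            vals = mu + rng.normal(0, sd, len(t_lab))
            if var == "bun" and eff.bun_shift:
                vals = vals + eff.bun_shift * w_bun * sev(t_lab)
            _emit(obs_rows, enc_id, var, t_lab, np.round(np.maximum(vals, 0.05), 2))

        ventilated = rng.random() < config.ventilation_prevalence
        if ventilated:
            t_map = _sample_times(rng, stay, 4.0)
            vals = 11.0 + rng.normal(0, 2.0, len(t_map))
            _emit(obs_rows, enc_id, "mean_airway_pressure", t_map,
                  np.round(np.maximum(vals, 4.0), 1))

        # medications (names drawn from the packaged category lists)
        rates = {
            "high_nephrotoxic": lambda t: 0.2 + eff.high_nephro_rate * w_drug * sev(t),
            "low_nephrotoxic": lambda t: 1.0 + 0.0 * np.asarray(t, dtype=float),
            "vasoactive": lambda t: 0.3 + 0.0 * np.asarray(t, dtype=float),
        }
        for cat, rate in rates.items():
            ev = _poisson_events(rng, stay, rate)
            names = DRUGS[cat]
            for te in ev:
                med_rows.append((enc_id, round(te * 60.0) / 60.0,
                                 names[int(rng.integers(len(names)))], cat))

        admit = SIM_EPOCH + pd.to_timedelta(int(rng.integers(0, 365 * 24 * 60)), unit="m")
        stay_min = int(np.ceil(stay * 60.0))  # ceil: minute-snapped events stay in-window
        enc_rows.append(
            dict(encounter_id=enc_id, patient_id=f"P{i:05d}", sex=sex,
                 age_months=round(age, 1), admit_ts=admit,
                 discharge_ts=admit + pd.to_timedelta(stay_min, unit="m"),
                 unit=unit, died=died)
        )
        label = "stage23_rrt" if (true_class == "stage23" and has_rrt) else true_class
        truth_rows.append(
            dict(encounter_id=enc_id, true_class=label,
                 true_onset_h=np.nan if onset is None else onset,
                 baseline_scr=baseline_scr, ventilated=ventilated,
                 drift_h=drift_h)
        )

    encounters = EncounterSet(pd.DataFrame(enc_rows))
    observations = ObservationStore(_obs_frame(obs_rows))
    medications = MedicationStore(
        pd.DataFrame(med_rows, columns=MedicationStore.COLUMNS)
    )
    rrt = RRTStore(pd.DataFrame(rrt_rows, columns=RRTStore.COLUMNS))

    # for stage-1 encounters the true onset is the first stage-1 crossing,
    # which the rejection step leaves to the staging oracle to pin down
    truth = pd.DataFrame(truth_rows).set_index("encounter_id")
    for enc_id in truth.index[truth["true_class"] == "stage1"]:
        t, v = observations.series(enc_id, "creatinine")
        stages = cohort_labeling.stage_creatinine_series(
            t, v, float(truth.loc[enc_id, "baseline_scr"])
        )
        truth.loc[enc_id, "true_onset_h"] = float(t[np.argmax(stages >= 1)])

    surfaces, signal = _surfaces(eff)
    return encounters, observations, medications, rrt, GroundTruth(truth, surfaces, signal)


def _emit(rows: list, enc_id: str, variable: str, t: np.ndarray, v: np.ndarray) -> None:
    # snap to whole minutes (idempotent for already-snapped series) so that
    # ISO-8601 second-resolution CSV output round-trips exactly
    t = np.round(np.asarray(t, dtype=float) * 60.0) / 60.0
    rows.append((enc_id, variable, t, np.asarray(v, dtype=float)))


def _obs_frame(chunks: list) -> pd.DataFrame:
    if not chunks:
        return pd.DataFrame(columns=ObservationStore.COLUMNS)
    return pd.DataFrame(
        {
            "encounter_id": np.repeat([c[0] for c in chunks],
                                      [len(c[2]) for c in chunks]),
            "t_h": np.concatenate([c[2] for c in chunks]),
            "variable": np.repeat([c[1] for c in chunks],
                                  [len(c[2]) for c in chunks]),
            "value": np.concatenate([c[3] for c in chunks]),
            "unit": np.repeat([EXPECTED_UNITS.get(c[1], "") for c in chunks],
                              [len(c[2]) for c in chunks]),
        }
    )
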