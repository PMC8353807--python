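"""Prediction grid and windowed predictor engineering.

Predictions are made on a 6-hourly grid anchored at admission. Each predictor
is a windowed statistic of one source series over a half-open lookback
``(t - W, t]``: 30 h for routine vitals/labs statistics (mean, median, min,
max, change = last - first, last), 48 h for the creatinine rate of change
(ordinary least-squares slope, mg/dL/h), and 168 h (one week) for medication
administration counts per nephrotoxicity/vasoactive category. The shock index
is a derived series (heart rate / systolic BP, paired within 15 min). An
empty window yields MISSING (NaN) — never an imputation; medication counts
with no events yield 0. The ventilation predictor (mean airway pressure) is
MISSING for patients never ventilated, exactly as charted.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .cohort_labeling import AKILabel
from .ehr_data import EncounterSet, MedicationStore, ObservationStore

GRID_STEP_H = 6.0
STATS_WINDOW_H = 30.0
CROC_WINDOW_H = 48.0
MED_WINDOW_H = 168.0
SHOCK_PAIR_TOL_H = 0.25  # 15 min

HOURS_PER_MONTH = 730.5

TRAIN_LEAD_H = (24.0, 48.0)
TEST_LEAD_H = (6.0, 48.0)


@dataclasses.dataclass(frozen=True)
class FeatureSpec:
    """One predictor: a statistic of a source series over a lookback window."""

    name: str
    variable: str
    statistic: str  # mean | median | min | max | change | last | slope | count | elapsed
    window_h: float
    unit: str


#: The default final predictor set, in model selection order.
DEFAULT_FEATURES: tuple[FeatureSpec, ...] = (
    FeatureSpec("shock_index_max", "shock_index", "max", STATS_WINDOW_H, "bpm/mmHg"),
    FeatureSpec("spo2_mean", "spo2", "mean", STATS_WINDOW_H, "%"),
    FeatureSpec("bun_last", "bun", "last", STATS_WINDOW_H, "mg/dL"),
    FeatureSpec("creatinine_roc", "creatinine", "slope", CROC_WINDOW_H, "mg/dL/hr"),
    FeatureSpec("bilirubin_last", "bilirubin", "last", STATS_WINDOW_H, "mg/dL"),
    FeatureSpec("paco2_max", "paco2", "max", STATS_WINDOW_H, "%"),
    FeatureSpec("anion_gap_last", "anion_gap", "last", STATS_WINDOW_H, "mmol/L"),
    FeatureSpec("wbc_last", "wbc", "last", STATS_WINDOW_H, "10^9/L"),
    FeatureSpec("albumin_last", "albumin", "last", STATS_WINDOW_H, "g/dL"),
    FeatureSpec("chloride_last", "chloride", "last", STATS_WINDOW_H, "mmol/L"),
    FeatureSpec("gentamicin_trough_last", "gentamicin_trough", "last", STATS_WINDOW_H, "mg/L"),
    FeatureSpec("vasoactive_count", "vasoactive", "count", MED_WINDOW_H, "count"),
    FeatureSpec("high_nephrotoxic_count", "high_nephrotoxic", "count", MED_WINDOW_H, "count"),
    FeatureSpec("mean_airway_pressure_median", "mean_airway_pressure", "median",
                STATS_WINDOW_H, "cmH2O"),
    FeatureSpec("time_since_admission", "", "elapsed", 0.0, "hours"),
)

FEATURE_UNITS = {s.name: s.unit for s in DEFAULT_FEATURES}
COUNT_FEATURES = tuple(s.name for s in DEFAULT_FEATURES if s.statistic == "count")


def build_prediction_grid(stay_h: float, onset_h: float | None = None) -> np.ndarray:
    """Grid times admit + 6 h, 12 h, ... up to min(discharge, onset)."""
    end = stay_h if onset_h is None else min(stay_h, onset_h)
    n = int(np.floor(end / GRID_STEP_H))
    return GRID_STEP_H * np.arange(1, n + 1)


def _window_slice(t: np.ndarray, at: float, window_h: float) -> slice:
    lo = np.searchsorted(t, at - window_h, side="right")
    hi = np.searchsorted(t, at, side="right")
    return slice(lo, hi)


def window_statistics(
    t: np.ndarray,
    v: np.ndarray,
    at: float,
    window_h: float = STATS_WINDOW_H,
    stats: tuple[str, ...] = ("mean", "median", "min", "max", "change", "last"),
) -> dict[str, float]:
    """Window statistics over observations in ``(at - window, at]``.

    ``change`` is last minus first within the window. An empty window maps
    every requested statistic to NaN.
    """
    w = v[_window_slice(t, at, window_h)]
    if len(w) == 0:
        return {s: np.nan for s in stats}
    fns = {
        "mean": lambda x: float(np.mean(x)),
        "median": lambda x: float(np.median(x)),
        "min": lambda x: float(np.min(x)),
        "max": lambda x: float(np.max(x)),
        "change": lambda x: float(x[-1] - x[0]),
        "last": lambda x: float(x[-1]),
    }
    return {s: fns[s](w) for s in stats}


def creatinine_rate_of_change(
    t: np.ndarray, v: np.ndarray, at: float, window_h: float = CROC_WINDOW_H
) -> float:
    """OLS slope (mg/dL per hour) of creatinine in ``(at - 48 h, at]``.

    Fewer than two points (or zero time spread) yields NaN.
    """
    sl = _window_slice(t, at, window_h)
    tw, vw = t[sl], v[sl]
    if len(tw) < 2 or np.ptp(tw) == 0:
        return np.nan
    tc = tw - tw.mean()
    return float(np.dot(tc, vw - vw.mean()) / np.dot(tc, tc))


def medication_counts(
    medications: MedicationStore,
    encounter_id: str,
    at: float,
    window_h: float = MED_WINDOW_H,
) -> dict[str, int]:
    """Administration counts per category in ``(at - 168 h, at]`` (0 if none)."""
    out = {}
    for cat in ("high_nephrotoxic", "low_nephrotoxic", "vasoactive"):
        ev = medications.events(encounter_id, cat)
        sl = _window_slice(ev, at, window_h)
        out[cat] = int(sl.stop - sl.start)
    return out


def shock_index_series(
    t_hr: np.ndarray,
    hr: np.ndarray,
    t_sbp: np.ndarray,
    sbp: np.ndarray,
    tol_h: float = SHOCK_PAIR_TOL_H,
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise heart rate / systolic BP at heart-rate times.

    Each heart-rate point is paired with the nearest SBP within ``tol_h``
    (15 min); unpaired points and non-positive SBP are dropped.
    """
    if len(t_hr) == 0 or len(t_sbp) == 0:
        return np.empty(0), np.empty(0)
    idx = np.searchsorted(t_sbp, t_hr)
    left = np.clip(idx - 1, 0, len(t_sbp) - 1)
    right = np.clip(idx, 0, len(t_sbp) - 1)
    pick = np.where(
        np.abs(t_sbp[left] - t_hr) <= np.abs(t_sbp[right] - t_hr), left, right
    )
    dist = np.abs(t_sbp[pick] - t_hr)
    ok = (dist <= tol_h) & (sbp[pick] > 0)
    return t_hr[ok], hr[ok] / sbp[pick[ok]]


derived_series = shock_index_series


def assemble_features(
    encounters: EncounterSet,
    observations: ObservationStore,
    medications: MedicationStore,
    labels: dict[str, AKILabel],
    kept_ids: list[str] | None = None,
    specs: tuple[FeatureSpec, ...] = DEFAULT_FEATURES,
) -> pd.DataFrame:
    """One row per (encounter, grid time) with predictor values and lead time.

    The grid is truncated at AKI onset for stage >= 1 encounters; lead_time_h
    is (pseudo-)onset minus grid time. MISSING predictors are NaN.
    """
    known = {s.statistic for s in specs}
    allowed = {"mean", "median", "min", "max", "change", "last", "slope", "count", "elapsed"}
    if not known <= allowed:
        raise ValueError(f"unknown statistic(s): {sorted(known - allowed)}")

    ids = list(kept_ids) if kept_ids is not None else list(labels)
    records: list[dict] = []
    for enc_id in ids:
        row = encounters.row(enc_id)
        lab = labels[enc_id]
        onset = lab.onset_h if lab.max_stage >= 1 else None
        grid = build_prediction_grid(float(row["stay_h"]), onset)
        if len(grid) == 0:
            continue

        series_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}

        def get_series(variable: str) -> tuple[np.ndarray, np.ndarray]:
            if variable not in series_cache:
                if variable == "shock_index":
                    t_hr, hr = observations.series(enc_id, "heart_rate")
                    t_bp, bp = observations.series(enc_id, "sbp")
                    series_cache[variable] = shock_index_series(t_hr, hr, t_bp, bp)
                else:
                    series_cache[variable] = observations.series(enc_id, variable)
            return series_cache[variable]

        for g in grid:
            rec = {
                "encounter_id": enc_id,
                "grid_h": float(g),
                "age_months": min(float(row["age_months"]) + g / HOURS_PER_MONTH, 252.0),
                "lead_time_h": float(lab.onset_h - g),
            }
            for spec in specs:
                if spec.statistic == "elapsed":
                    rec[spec.name] = float(g)
                elif spec.statistic == "count":
                    ev = medications.events(enc_id, spec.variable)
                    sl = _window_slice(ev, g, spec.window_h)
                    rec[spec.name] = float(sl.stop - sl.start)
                elif spec.statistic == "slope":
                    t, v = get_series(spec.variable)
                    rec[spec.name] = creatinine_rate_of_change(t, v, g, spec.window_h)
                else:
                    t, v = get_series(spec.variable)
                    rec[spec.name] = window_statistics(
                        t, v, g, spec.window_h, (spec.statistic,)
                    )[spec.statistic]
            records.append(rec)

    cols = ["encounter_id", "grid_h", "age_months", "lead_time_h"] + [s.name for s in specs]
    return pd.DataFrame.from_records(records, columns=cols)


def select_leads(features: pd.DataFrame, leads: tuple[float, float]) -> pd.DataFrame:
    """Rows whose lead time falls in the closed interval ``leads``."""
    lo, hi = leads
    return features[(features["lead_time_h"] >= lo) & (features["lead_time_h"] <= hi)]


def build_training_set(
    features: pd.DataFrame,
    labels: dict[str, AKILabel],
    split: pd.Series,
    train_leads: tuple[float, float] = TRAIN_LEAD_H,
    test_leads: tuple[float, float] = TEST_LEAD_H,
) -> dict[str, pd.DataFrame]:
    """Training/validation examples at lead 24-48 h; holdout test at 6-48 h.

    Adds the binary primary-outcome label (stage 2/3) and split tag; grid
    points outside the lead window contribute nothing.
    """
    f = features.copy()
    f["split"] = f["encounter_id"].map(split)
    f["label"] = f["encounter_id"].map(lambda e: int(labels[e].primary_case))
    out = {}
    for name, leads in (("derivation", train_leads), ("validation", train_leads),
                        ("holdout", test_leads)):
        sub = select_leads(f[f["split"] == name], leads)
        out[name] = sub.reset_index(drop=True)
    return out
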