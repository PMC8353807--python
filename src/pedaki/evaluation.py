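"""Evaluation protocol: lead-time-resolved AUROC, episode metrics, lead-time
distribution, subgroup AUROC and actionability.

The unit of sensitivity/PPV is the *episode* (one labeled encounter). An
episode counts as alerted when at least one prediction inside the 6-48 h
lead window crosses the alert threshold; the first alert is the one with the
largest lead (earliest in clock time). For each outcome definition
(any_aki / stage23 / rrt), false positives are alerted episodes outside the
outcome class (any_aki: stage 0 only; stage23: stage <= 1; rrt: no RRT) and
raw TP/FP/FN counts are always reported alongside the rates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .cohort_labeling import AKILabel
from .ehr_data import MedicationStore

LEAD_WINDOW_H = (6.0, 48.0)
LEAD_BIN_EDGES = tuple(np.arange(6.0, 49.0, 6.0))  # 6,12,...,48

CDC_AGE_GROUPS = (
    ("1mo-2y", 1.0, 24.0),
    ("2-12y", 24.0, 144.0),
    ("12-16y", 144.0, 192.0),
    ("16-21y", 192.0, 252.0),
)

OUTCOMES = ("any_aki", "stage23", "rrt")


def _outcome_mask(labels: dict[str, AKILabel], enc_ids: pd.Series, outcome: str) -> np.ndarray:
    if outcome == "any_aki":
        return enc_ids.map(lambda e: labels[e].max_stage >= 1).to_numpy(dtype=bool)
    if outcome == "stage23":
        return enc_ids.map(lambda e: labels[e].max_stage >= 2).to_numpy(dtype=bool)
    if outcome == "rrt":
        return enc_ids.map(lambda e: labels[e].rrt_required).to_numpy(dtype=bool)
    raise ValueError(f"unknown outcome {outcome!r}")


def _fp_mask(labels: dict[str, AKILabel], enc_ids: pd.Series, outcome: str) -> np.ndarray:
    """Episodes that count as false alarms for this outcome."""
    if outcome == "any_aki":
        return enc_ids.map(lambda e: labels[e].max_stage == 0).to_numpy(dtype=bool)
    if outcome == "stage23":
        return enc_ids.map(lambda e: labels[e].max_stage <= 1).to_numpy(dtype=bool)
    if outcome == "rrt":
        return enc_ids.map(lambda e: not labels[e].rrt_required).to_numpy(dtype=bool)
    raise ValueError(f"unknown outcome {outcome!r}")


def pooled_auroc(predictions: pd.DataFrame, labels: dict[str, AKILabel],
                 score_col: str = "risk",
                 lead_window: tuple[float, float] = LEAD_WINDOW_H) -> float:
    """AUROC over all predictions with lead in the window (primary outcome)."""
    sub = predictions[
        (predictions["lead_time_h"] >= lead_window[0])
        & (predictions["lead_time_h"] <= lead_window[1])
        & np.isfinite(predictions[score_col])
    ]
    y = _outcome_mask(labels, sub["encounter_id"], "stage23")
    if y.all() or not y.any():
        return np.nan
    return float(roc_auc_score(y, sub[score_col].to_numpy()))


def auroc_by_leadtime(
    predictions: pd.DataFrame,
    labels: dict[str, AKILabel],
    score_col: str = "risk",
    bin_edges: tuple[float, ...] = LEAD_BIN_EDGES,
) -> pd.DataFrame:
    """Per-lead-bin AUROC: case predictions at that lead vs control
    predictions at the matched lead bin (relative to pseudo-onset).

    Bins with fewer than 2 cases or 2 controls are omitted.
    """
    rows = []
    y_all = _outcome_mask(labels, predictions["encounter_id"], "stage23")
    lead = predictions["lead_time_h"].to_numpy()
    score = predictions[score_col].to_numpy()
    finite = np.isfinite(score)
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        m = (lead >= lo) & ((lead < hi) | (hi == bin_edges[-1]) & (lead <= hi)) & finite
        y = y_all[m]
        if (y.sum() < 2) or ((~y).sum() < 2):
            continue
        rows.append(
            {"lead_lo_h": lo, "lead_hi_h": hi, "n_case": int(y.sum()),
             "n_control": int((~y).sum()),
             "auroc": float(roc_auc_score(y, score[m]))}
        )
    return pd.DataFrame(rows)


def episode_table(
    predictions: pd.DataFrame,
    labels: dict[str, AKILabel],
    alert_col: str = "alert",
    lead_window: tuple[float, float] = LEAD_WINDOW_H,
) -> pd.DataFrame:
    """One row per scored episode: outcome flags, alerted, first alert lead.

    Duplicate predictions at the same grid time do not change the result
    (episode aggregation is by any/max).
    """
    sub = predictions[
        (predictions["lead_time_h"] >= lead_window[0])
        & (predictions["lead_time_h"] <= lead_window[1])
    ].copy()
    rows = []
    for enc_id, grp in sub.groupby("encounter_id", sort=True):
        lab = labels[enc_id]
        alerts = grp[grp[alert_col].astype(bool)]
        rows.append(
            {
                "encounter_id": enc_id,
                "max_stage": lab.max_stage,
                "rrt_required": lab.rrt_required,
                "onset_h": lab.onset_h,
                "alerted": len(alerts) > 0,
                "first_alert_lead_h": float(alerts["lead_time_h"].max())
                if len(alerts) else np.nan,
                "max_risk": float(grp["risk"].max()) if "risk" in grp else np.nan,
            }
        )
    return pd.DataFrame(rows)


def episode_metrics(
    episodes: pd.DataFrame, labels: dict[str, AKILabel], outcome: str
) -> dict:
    """Episode-level sensitivity, PPV and TP:FP for one outcome definition."""
    is_outcome = _outcome_mask(labels, episodes["encounter_id"], outcome)
    is_fp_pool = _fp_mask(labels, episodes["encounter_id"], outcome)
    alerted = episodes["alerted"].to_numpy(dtype=bool)
    tp = int((is_outcome & alerted).sum())
    fn = int((is_outcome & ~alerted).sum())
    fp = int((is_fp_pool & alerted).sum())
    n_outcome = tp + fn
    return {
        "outcome": outcome,
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "n_outcome_episodes": n_outcome,
        "sensitivity": tp / n_outcome if n_outcome else np.nan,
        "ppv": tp / (tp + fp) if (tp + fp) else np.nan,
        "tp_fp_ratio": tp / fp if fp else (np.inf if tp else np.nan),
    }


def leadtime_distribution(
    episodes: pd.DataFrame,
    labels: dict[str, AKILabel],
    outcome: str = "stage23",
    bin_edges: tuple[float, ...] = LEAD_BIN_EDGES,
) -> dict:
    """Lead-time statistics of true-positive episodes plus the cumulative
    identification curve (fraction of outcome episodes identifiable at
    lead >= L, non-decreasing as L shrinks)."""
    is_outcome = _outcome_mask(labels, episodes["encounter_id"], outcome)
    outcome_eps = episodes[is_outcome]
    n_outcome = len(outcome_eps)
    leads = outcome_eps.loc[outcome_eps["alerted"], "first_alert_lead_h"].to_numpy()
    curve = {
        float(L): float((leads >= L).sum() / n_outcome) if n_outcome else np.nan
        for L in bin_edges
    }
    return {
        "outcome": outcome,
        "n_tp": int(len(leads)),
        "median_lead_h": float(np.median(leads)) if len(leads) else np.nan,
        "iqr_lead_h": [float(np.percentile(leads, 25)), float(np.percentile(leads, 75))]
        if len(leads) else [np.nan, np.nan],
        "fraction_identified_at_lead": curve,
        # "at 48 h" = first alert in the farthest 6 h lead bin; an exact
        # lead of 48.0 h almost never occurs on the 6 h grid
        "fraction_at_48h": curve[bin_edges[-2]],
        "fraction_at_6h": curve[6.0],
    }


def actionability(
    episodes: pd.DataFrame,
    labels: dict[str, AKILabel],
    medications: MedicationStore,
    outcome: str = "stage23",
) -> dict:
    """Fractions of true-positive episodes receiving nephrotoxic medication
    between the first alert and AKI onset (the window in which an alert could
    have changed prescribing)."""
    is_outcome = _outcome_mask(labels, episodes["encounter_id"], outcome)
    tps = episodes[is_outcome & episodes["alerted"]]
    n = len(tps)
    got = {"high": 0, "low": 0, "any": 0}
    for _, row in tps.iterrows():
        onset = labels[row["encounter_id"]].onset_h
        alert_t = onset - row["first_alert_lead_h"]
        high = medications.events(row["encounter_id"], "high_nephrotoxic")
        low = medications.events(row["encounter_id"], "low_nephrotoxic")
        has_high = bool(np.any((high > alert_t) & (high < onset)))
        has_low = bool(np.any((low > alert_t) & (low < onset)))
        got["high"] += has_high
        got["low"] += has_low
        got["any"] += has_high or has_low
    return {
        "outcome": outcome,
        "n_tp": n,
        "fraction_high": got["high"] / n if n else np.nan,
        "fraction_low": got["low"] / n if n else np.nan,
        "fraction_any": got["any"] / n if n else np.nan,
    }


def subgroup_auroc(
    predictions: pd.DataFrame,
    labels: dict[str, AKILabel],
    encounters_df: pd.DataFrame,
    grouping: str = "cdc_age",
    score_col: str = "risk",
    lead_window: tuple[float, float] = LEAD_WINDOW_H,
) -> pd.DataFrame:
    """AUROC per CDC age group or per ICU unit, pooled over lead times.

    Groups without both classes are omitted.
    """
    sub = predictions[
        (predictions["lead_time_h"] >= lead_window[0])
        & (predictions["lead_time_h"] <= lead_window[1])
        & np.isfinite(predictions[score_col])
    ].copy()
    y = _outcome_mask(labels, sub["encounter_id"], "stage23")
    if grouping == "cdc_age":
        age = encounters_df["age_months"].reindex(sub["encounter_id"]).to_numpy()
        groups = [(name, (age >= lo) & (age < hi) | ((hi == 252.0) & (age == hi)))
                  for name, lo, hi in CDC_AGE_GROUPS]
    elif grouping == "unit":
        unit = encounters_df["unit"].reindex(sub["encounter_id"]).to_numpy()
        groups = [(u, unit == u) for u in ("PICU", "CTICU")]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    rows = []
    for name, mask in groups:
        yg = y[mask]
        if yg.sum() < 2 or (~yg).sum() < 2:
            continue
        rows.append(
            {"group": name, "n_case": int(yg.sum()), "n_control": int((~yg).sum()),
             "auroc": float(roc_auc_score(yg, sub.loc[mask, score_col].to_numpy()))}
        )
    return pd.DataFrame(rows)


def evaluation_report(
    predictions: pd.DataFrame,
    labels: dict[str, AKILabel],
    encounters_df: pd.DataFrame,
    medications: MedicationStore,
    rai: pd.DataFrame | None = None,
) -> dict:
    """Full holdout evaluation bundle as a JSON-serialisable dict."""
    episodes = episode_table(predictions, labels)
    report = {
        "pooled_auroc": pooled_auroc(predictions, labels),
        "auroc_by_lead": auroc_by_leadtime(predictions, labels).to_dict("records"),
        "episode_metrics": {o: episode_metrics(episodes, labels, o) for o in OUTCOMES},
        "leadtime": leadtime_distribution(episodes, labels),
        "actionability": actionability(episodes, labels, medications),
        "subgroup_auroc": {
            g: subgroup_auroc(predictions, labels, encounters_df, g).to_dict("records")
            for g in ("cdc_age", "unit")
        },
        "n_episodes_scored": int(len(episodes)),
    }
    if rai is not None and len(rai):
        rai_scored = rai.rename(columns={"rai": "risk"}).copy()
        rai_scored["alert"] = rai_scored["angina"]
        rai_eps = episode_table(rai_scored, labels)
        report["rai"] = {
            "pooled_auroc": pooled_auroc(rai, labels, score_col="rai"),
            "episode_metrics": {
                o: episode_metrics(rai_eps, labels, o) for o in OUTCOMES
            },
        }
    return report
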