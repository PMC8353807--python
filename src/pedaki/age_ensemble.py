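"""Age-conditioned additive ensemble of lookup-table weak classifiers.

The model is a sum of per-predictor "weak classifiers". Each weak classifier
is a lookup table indexed by (age bin, predictor-value bin): given a
patient's age and the measured value of one predictor (or its missingness),
it returns an additive risk contribution. The predicted AKI risk is

    risk = clip(b0 + sum_j C_j(age, x_j), 0, 1)

with ``b0`` the training prevalence. Because the prediction is a plain sum,
the contribution of every non-age predictor can be separated and ranked for
each individual prediction, which is what makes alerts explainable.

Fitting is squared-loss cyclic boosting over the cell tables: each update
adds ``learning_rate * mean(residual) * n/(n + lambda)`` to a cell, where the
residual is label minus current (clipped) risk and ``lambda = 20`` shrinks
sparse cells. Predictors enter by greedy forward selection scored on
validation AUROC, stopping when the gain drops below 0.001 or at the
predictor cap. Missing values occupy a dedicated cell per age bin, so
predictions never require imputation.

Finalized tables are quantized to multiples of 2**-20 risk units. Every
contribution is then a dyadic rational with at most 20 fractional bits, so
sums of up to dozens of contributions are *exact* in float64: additive
conservation and single-classifier ablation hold to the last bit, and model
files are diffable.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import roc_auc_score

DEFAULT_AGE_EDGES = (1.0, 6.0, 12.0, 24.0, 72.0, 144.0, 192.0, 252.0)
QUANTUM = 2.0 ** -20
# integer-valued predictors (counts) get one bin per integer up to this cap;
# values beyond the cap pool into the top bin so the sparse high-count tail
# still lands in an adequately populated cell
INT_BIN_CAP = 6
SHRINKAGE = 20.0

AMINOGLYCOSIDES = ("gentamicin", "tobramycin", "amikacin")


class DegenerateDataError(RuntimeError):
    """No candidate predictor improves validation AUROC at the first step."""


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class BinSpec:
    """Value-bin edges for one predictor (interior edges, half-open bins)."""

    interior_edges: np.ndarray  # length n_bins - 1
    is_integer: bool

    @property
    def n_bins(self) -> int:
        return len(self.interior_edges) + 1

    def index(self, values: np.ndarray) -> np.ndarray:
        """Bin index per value; NaN maps to the dedicated missing bin."""
        v = np.asarray(values, dtype=float)
        idx = np.searchsorted(self.interior_edges, v, side="right")
        idx[np.isnan(v)] = self.n_bins  # missing cell
        return idx


def init_bins(
    train: pd.DataFrame,
    predictors: list[str],
    n_value_bins: int = 16,
    min_values: int = 50,
) -> dict[str, BinSpec]:
    """Per-predictor value-bin edges from training data.

    Continuous predictors get (deduplicated) empirical-quantile edges;
    integer-valued predictors (e.g. medication counts) are binned per integer
    up to a cap. A constant predictor collapses to a single bin.
    """
    bins: dict[str, BinSpec] = {}
    for name in predictors:
        vals = train[name].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            bins[name] = BinSpec(np.empty(0), False)
            continue
        distinct = np.unique(vals)
        if np.all(distinct == np.round(distinct)):
            if len(distinct) == 1:
                bins[name] = BinSpec(np.empty(0), True)
            elif len(distinct) <= INT_BIN_CAP:
                edges = (distinct[:-1] + distinct[1:]) / 2.0
                bins[name] = BinSpec(edges, True)
            else:
                # one bin per integer up to the cap, overflow pooled on top
                capped = distinct[: INT_BIN_CAP]
                edges = (capped[:-1] + capped[1:]) / 2.0
                edges = np.append(edges, capped[-1] + 0.5)
                bins[name] = BinSpec(edges, True)
            continue
        qs = np.quantile(vals, np.linspace(0.0, 1.0, n_value_bins + 1)[1:-1])
        bins[name] = BinSpec(np.unique(qs), False)
    return bins


def age_bin_index(age_months: np.ndarray, age_edges: np.ndarray) -> np.ndarray:
    a = np.asarray(age_months, dtype=float)
    if np.any(a < age_edges[0]) or np.any(a > age_edges[-1]):
        raise ValueError("age outside supported range [1, 252] months")
    return np.clip(np.searchsorted(age_edges[1:-1], a, side="right"),
                   0, len(age_edges) - 2)


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class WeakClassifier:
    """One predictor's (age bin x value bin) contribution lookup table.

    ``table`` has shape (n_age_bins, n_value_bins + 1); the final column is
    the missing-value cell per age bin. Contributions are clipped to [-1, 1].
    """

    name: str
    bins: BinSpec
    table: np.ndarray
    selection_rank: int

    def contributions(self, age_bin: np.ndarray, values: np.ndarray) -> np.ndarray:
        return self.table[age_bin, self.bins.index(values)]

    @property
    def missing_contribution(self) -> np.ndarray:
        return self.table[:, -1]


@dataclasses.dataclass
class EnsembleModel:
    """Ordered weak classifiers plus intercept, threshold and provenance."""

    classifiers: list[WeakClassifier]
    b0: float
    age_edges: np.ndarray
    learning_rate: float
    n_rounds: int
    alert_threshold: float = 0.5
    provenance: dict = dataclasses.field(default_factory=dict)

    @property
    def predictor_names(self) -> list[str]:
        return [c.name for c in self.classifiers]

    def contribution_matrix(self, features: pd.DataFrame) -> np.ndarray:
        ab = age_bin_index(features["age_months"].to_numpy(), self.age_edges)
        cols = [
            c.contributions(ab, features[c.name].to_numpy(dtype=float))
            for c in self.classifiers
        ]
        return np.column_stack(cols) if cols else np.empty((len(features), 0))

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": 1,
            "b0": float(self.b0),
            "age_edges": [float(x) for x in self.age_edges],
            "learning_rate": self.learning_rate,
            "n_rounds": self.n_rounds,
            "alert_threshold": float(self.alert_threshold),
            "predictors": [
                {"name": c.name, "rank": c.selection_rank,
                 "is_integer": bool(c.bins.is_integer)}
                for c in self.classifiers
            ],
            "provenance": self.provenance,
        }
        with open(out_dir / "model.yaml", "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)
        for c in self.classifiers:
            df = pd.DataFrame(c.table)
            df.columns = [f"bin_{i}" for i in range(c.table.shape[1] - 1)] + ["missing"]
            df.insert(0, "age_bin", range(c.table.shape[0]))
            df.to_csv(out_dir / f"table_{c.name}.csv", index=False)
            pd.DataFrame({"interior_edge": c.bins.interior_edges}).to_csv(
                out_dir / f"edges_{c.name}.csv", index=False
            )

    @classmethod
    def load(cls, model_dir: str | Path) -> "EnsembleModel":
        model_dir = Path(model_dir)
        with open(model_dir / "model.yaml") as fh:
            meta = yaml.safe_load(fh)
        classifiers = []
        for p in meta["predictors"]:
            table = pd.read_csv(model_dir / f"table_{p['name']}.csv")
            edges = pd.read_csv(model_dir / f"edges_{p['name']}.csv")
            classifiers.append(
                WeakClassifier(
                    name=p["name"],
                    bins=BinSpec(edges["interior_edge"].to_numpy(dtype=float),
                                 p["is_integer"]),
                    table=table.drop(columns="age_bin").to_numpy(dtype=float),
                    selection_rank=p["rank"],
                )
            )
        classifiers.sort(key=lambda c: c.selection_rank)
        return cls(
            classifiers=classifiers,
            b0=float(meta["b0"]),
            age_edges=np.asarray(meta["age_edges"], dtype=float),
            learning_rate=meta["learning_rate"],
            n_rounds=meta["n_rounds"],
            alert_threshold=float(meta["alert_threshold"]),
            provenance=meta.get("provenance", {}),
        )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _cells(features: pd.DataFrame, predictors: list[str], bins: dict[str, BinSpec],
           age_edges: np.ndarray) -> dict[str, tuple[np.ndarray, int]]:
    """Flat (age, value) cell index per example, per predictor."""
    ab = age_bin_index(features["age_months"].to_numpy(), age_edges)
    n_age = len(age_edges) - 1
    out = {}
    for name in predictors:
        b = bins[name]
        width = b.n_bins + 1
        idx = ab * width + b.index(features[name].to_numpy(dtype=float))
        out[name] = (idx, n_age * width)
    return out


def _boost(
    order: list[str],
    cells: dict[str, tuple[np.ndarray, int]],
    y: np.ndarray,
    b0: float,
    rounds: int,
    lr: float,
) -> dict[str, np.ndarray]:
    """Cyclic squared-loss boosting over the cell tables; returns flat tables."""
    tables = {name: np.zeros(cells[name][1]) for name in order}
    counts = {
        name: np.bincount(cells[name][0], minlength=cells[name][1]) for name in order
    }
    score = np.full(len(y), b0)
    for _ in range(rounds):
        for name in order:
            idx, ncell = cells[name]
            resid = y - np.clip(score, 0.0, 1.0)
            sums = np.bincount(idx, weights=resid, minlength=ncell)
            # relaxation toward the ridge fixpoint
            #   C* = mean(partial residual) * n/(n + lambda):
            # increment = lr * (sum(resid) - lambda*C) / (n + lambda), so the
            # n/(n+lambda) shrinkage persists at convergence instead of
            # washing out, keeping sparse cells from chasing noise
            delta = lr * (sums - SHRINKAGE * tables[name]) / (counts[name] + SHRINKAGE)
            new = np.clip(tables[name] + delta, -1.0, 1.0)
            score += (new - tables[name])[idx]
            tables[name] = new
    return tables


def _score_with(tables: dict[str, np.ndarray], cells, b0: float, n: int) -> np.ndarray:
    s = np.full(n, b0)
    for name, table in tables.items():
        s += table[cells[name][0]]
    return np.clip(s, 0.0, 1.0)


def _safe_auc(y: np.ndarray, s: np.ndarray) -> float:
    if len(np.unique(y)) < 2:
        return np.nan
    return float(roc_auc_score(y, s))


def fit_ensemble(
    train: pd.DataFrame,
    val: pd.DataFrame,
    candidates: list[str],
    max_predictors: int = 15,
    learning_rate: float = 0.1,
    rounds: int = 50,
    min_gain: float = 0.001,
    n_value_bins: int = 16,
    age_edges: tuple[float, ...] = DEFAULT_AGE_EDGES,
    provenance: dict | None = None,
) -> EnsembleModel:
    """Greedy forward selection + cyclic boosting; fully deterministic.

    ``train`` and ``val`` carry ``age_months``, a binary ``label`` column and
    the candidate predictor columns (NaN = missing). At each step every
    unselected candidate is tentatively fitted (from scratch, ``rounds``
    cyclic passes) together with the current set and scored by validation
    AUROC; the best is added permanently. Selection stops at
    ``max_predictors`` or when the AUROC gain falls below ``min_gain``; no
    improvement at the first step is fatal. The returned model is a fresh
    refit of the selected ordered set with quantized tables.
    """
    edges = np.asarray(age_edges, dtype=float)
    y = train["label"].to_numpy(dtype=float)
    y_val = val["label"].to_numpy(dtype=float)
    b0 = float(np.mean(y))
    bins = init_bins(train, candidates, n_value_bins=n_value_bins)
    cells_tr = _cells(train, candidates, bins, edges)
    cells_va = _cells(val, candidates, bins, edges)

    selected: list[str] = []
    best_auc = 0.5
    log: list[dict] = []
    while len(selected) < min(max_predictors, len(candidates)):
        step_best: tuple[float, str] | None = None
        for cand in candidates:
            if cand in selected:
                continue
            tables = _boost(selected + [cand], cells_tr, y, b0, rounds, learning_rate)
            auc = _safe_auc(y_val, _score_with(tables, cells_va, b0, len(val)))
            if np.isnan(auc):
                raise DegenerateDataError("validation labels are single-class")
            if step_best is None or auc > step_best[0]:
                step_best = (auc, cand)
        assert step_best is not None
        gain = step_best[0] - best_auc
        if gain < min_gain:
            if not selected:
                raise DegenerateDataError(
                    "no candidate predictor improves validation AUROC"
                )
            break
        selected.append(step_best[1])
        best_auc = step_best[0]
        log.append({"rank": len(selected), "predictor": step_best[1],
                    "val_auroc": round(step_best[0], 6)})

    tables = _boost(selected, cells_tr, y, b0, rounds, learning_rate)
    classifiers = []
    for rank, name in enumerate(selected, start=1):
        width = bins[name].n_bins + 1
        flat = np.round(tables[name] / QUANTUM) * QUANTUM
        classifiers.append(
            WeakClassifier(
                name=name,
                bins=bins[name],
                table=flat.reshape(len(edges) - 1, width),
                selection_rank=rank,
            )
        )
    prov = dict(provenance or {})
    prov["selection_log"] = log
    return EnsembleModel(
        classifiers=classifiers,
        b0=float(np.round(b0 / QUANTUM) * QUANTUM),
        age_edges=edges,
        learning_rate=learning_rate,
        n_rounds=rounds,
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# Prediction, explanation, calibration, alerting
# ---------------------------------------------------------------------------


def predict_risk(model: EnsembleModel, features: pd.DataFrame) -> pd.DataFrame:
    """Risk, alert flag and per-predictor contributions for each grid row.

    Missing predictors contribute their age bin's missing-cell value; the
    pre-clip score equals ``b0`` plus the contribution sum exactly (tables
    are quantized to dyadic rationals).
    """
    contrib = model.contribution_matrix(features)
    score = model.b0 + contrib.sum(axis=1)
    risk = np.clip(score, 0.0, 1.0)
    out = pd.DataFrame(
        {
            "encounter_id": features["encounter_id"].to_numpy()
            if "encounter_id" in features else "",
            "grid_h": features["grid_h"].to_numpy() if "grid_h" in features else np.nan,
            "lead_time_h": features["lead_time_h"].to_numpy()
            if "lead_time_h" in features else np.nan,
            "risk": risk,
            "score_preclip": score,
            "alert": risk >= model.alert_threshold,
        }
    )
    for j, c in enumerate(model.classifiers):
        out[f"contrib_{c.name}"] = contrib[:, j]
    return out


@dataclasses.dataclass
class Explanation:
    """Ranked top contributors with values/units, context and suggested action."""

    encounter_id: str
    grid_h: float
    risk: float
    top: list[dict]  # name, value, unit, contribution — descending contribution
    context: list[str]
    action: str


def explain(
    prediction: pd.Series,
    features_row: pd.Series,
    medications=None,
    units: dict[str, str] | None = None,
    k: int = 3,
) -> Explanation:
    """Top-k positive contributors for one prediction, plus medication context.

    If an aminoglycoside was administered in the past week the suggested
    action is to check the level and review dose and indication.
    """
    from .featurization import FEATURE_UNITS, MED_WINDOW_H

    units = units or FEATURE_UNITS
    contribs = {
        col[len("contrib_"):]: prediction[col]
        for col in prediction.index
        if col.startswith("contrib_")
    }
    positive = sorted(
        ((name, c) for name, c in contribs.items() if c > 0),
        key=lambda x: -x[1],
    )[:k]
    top = [
        {
            "predictor": name,
            "value": float(features_row.get(name, np.nan)),
            "unit": units.get(name, ""),
            "contribution": float(c),
        }
        for name, c in positive
    ]

    context: list[str] = []
    action = "Review AKI risk factors and ensure adequate renal perfusion."
    if medications is not None:
        t = float(prediction["grid_h"])
        drugs = medications.drugs_in_window(
            str(prediction["encounter_id"]), "high_nephrotoxic", t - MED_WINDOW_H, t
        )
        if drugs:
            context.append("active high-nephrotoxic drugs: " + ", ".join(drugs))
        if any(d in AMINOGLYCOSIDES for d in drugs):
            context.append("patient on aminoglycosides")
            action = "Patient on aminoglycosides: check level and review dose and indication."
    return Explanation(
        encounter_id=str(prediction.get("encounter_id", "")),
        grid_h=float(prediction.get("grid_h", np.nan)),
        risk=float(prediction["risk"]),
        top=top,
        context=context,
        action=action,
    )


def calibration_check(predictions: pd.DataFrame, labels: np.ndarray,
                      n_bins: int = 10) -> tuple[pd.DataFrame, float]:
    """Decile reliability table: mean predicted risk vs observed event rate.

    Returns (table, mean absolute gap over occupied deciles).
    """
    risk = predictions["risk"].to_numpy()
    y = np.asarray(labels, dtype=float)
    dec = pd.qcut(pd.Series(risk), q=n_bins, duplicates="drop")
    if dec.isna().all():  # constant predictions collapse to a single bin
        dec = pd.Series(np.zeros(len(risk), dtype=int))
    tab = (
        pd.DataFrame({"decile": dec, "risk": risk, "y": y})
        .groupby("decile", observed=True)
        .agg(n=("y", "size"), mean_risk=("risk", "mean"), event_rate=("y", "mean"))
        .reset_index(drop=True)
    )
    gap = float(np.mean(np.abs(tab["mean_risk"] - tab["event_rate"])))
    return tab, gap


def choose_alert_threshold(
    episode_scores: pd.DataFrame,
    target_ratio: float = 1.0,
) -> float:
    """Smallest threshold whose episode-level TP:FP ratio meets the target.

    ``episode_scores`` carries one row per validation episode with ``score``
    (the episode's maximum predicted risk inside the 6-48 h lead window) and
    boolean ``is_outcome``. Falls back to the max-Youden threshold when no
    threshold attains the target ratio.
    """
    s = episode_scores["score"].to_numpy(dtype=float)
    y = episode_scores["is_outcome"].to_numpy(dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    best_youden, youden_thr = -np.inf, 0.5
    for thr in np.unique(s):
        alerted = s >= thr
        tp = int((alerted & y).sum())
        fp = int((alerted & ~y).sum())
        if tp > 0 and (fp == 0 or tp / fp >= target_ratio):
            return float(thr)
        sens = tp / n_pos if n_pos else 0.0
        fpr = fp / n_neg if n_neg else 0.0
        if sens - fpr > best_youden:
            best_youden, youden_thr = sens - fpr, float(thr)
    return youden_thr
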