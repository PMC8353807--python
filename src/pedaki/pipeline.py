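"""One-config orchestration: simulate -> label -> featurize -> train ->
predict -> evaluate, with deterministic, hash-manifested artifacts.

Every stage writes plain CSV/JSON/YAML artifacts into the run directory and
the manifest records a SHA-256 per artifact, so a rerun with the same config
is byte-identical and any divergence is attributable to a specific stage.
Seeds are isolated per randomness source (simulation, pseudo-onset draws,
splitting), so changing one does not perturb the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .age_ensemble import choose_alert_threshold, fit_ensemble, predict_risk
from .cohort_labeling import (
    BaselineTable,
    apply_exclusions,
    label_encounters,
    labels_frame,
    split_cohort,
)
from .ehr_data import read_dataset, write_dataset
from .evaluation import LEAD_WINDOW_H, evaluation_report
from .featurization import DEFAULT_FEATURES, assemble_features, build_training_set, select_leads
from .rai_baseline import compute_rai_series
from .synthetic_ehr import EffectSizes, SimConfig, simulate_cohort


@dataclasses.dataclass
class RunConfig:
    """Everything one end-to-end run needs; round-trips losslessly via YAML."""

    n_encounters: int = 500
    fraction_stage23: float = 0.05
    fraction_stage1_only: float = 0.07
    fraction_rrt_given_stage23: float = 0.2
    effects: dict = dataclasses.field(
        default_factory=lambda: dataclasses.asdict(EffectSizes())
    )
    seeds: dict = dataclasses.field(
        default_factory=lambda: {"simulation": 1, "pseudo_onset": 2, "split": 3}
    )
    max_predictors: int = 15
    learning_rate: float = 0.1
    rounds: int = 50
    min_gain: float = 0.001
    n_value_bins: int = 16
    alert_target_ratio: float = 1.0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def sim_config(self) -> SimConfig:
        return SimConfig(
            n_encounters=self.n_encounters,
            fraction_stage23=self.fraction_stage23,
            fraction_stage1_only=self.fraction_stage1_only,
            fraction_rrt_given_stage23=self.fraction_rrt_given_stage23,
            effects=EffectSizes(**self.effects),
            seed=self.seeds["simulation"],
        )


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, np.bool_):
        return bool(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the whole pipeline; returns the evaluation report dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    # 1. simulate and write the raw five-table dataset (+ truth)
    encounters, observations, medications, rrt, truth = simulate_cohort(
        config.sim_config()
    )
    data_dir = out / "data"
    write_dataset(data_dir, encounters, observations, medications, rrt)
    truth.frame.to_csv(data_dir / "truth.csv")
    log.append(f"simulated {len(encounters)} encounters")

    # 2. read back through the standard loader (the only file path downstream)
    encounters, observations, medications, rrt, diags = read_dataset(data_dir)
    log.extend(diags)

    # 3. KDIGO labeling + exclusions
    baselines = BaselineTable.default()
    labels = label_encounters(
        encounters, observations, rrt, baselines, seed=config.seeds["pseudo_onset"]
    )
    kept, excluded = apply_exclusions(encounters, labels)
    labels_frame(labels).to_csv(out / "labels.csv")
    pd.Series(excluded, name="reason").rename_axis("encounter_id").sort_index().to_csv(
        out / "exclusions.csv"
    )
    log.append(f"kept {len(kept)} encounters, excluded {len(excluded)}")

    # 4. features
    features = assemble_features(encounters, observations, medications, labels, kept)
    features.to_csv(out / "features.csv", index=False)

    # 5. patient-level stratified split
    split = split_cohort(encounters, labels, kept, seed=config.seeds["split"])
    split.to_csv(out / "split.csv")

    # 6. train
    sets = build_training_set(features, labels, split)
    candidates = [s.name for s in DEFAULT_FEATURES]
    model = fit_ensemble(
        sets["derivation"],
        sets["validation"],
        candidates,
        max_predictors=config.max_predictors,
        learning_rate=config.learning_rate,
        rounds=config.rounds,
        min_gain=config.min_gain,
        n_value_bins=config.n_value_bins,
        provenance={"seeds": config.seeds, "n_encounters": config.n_encounters},
    )
    log.append(f"selected predictors: {model.predictor_names}")

    # 7. alert threshold from validation episodes (any-AKI target)
    f_split = features["encounter_id"].map(split)
    val_feats = select_leads(features[f_split == "validation"], LEAD_WINDOW_H)
    val_preds = predict_risk(model, val_feats)
    ep_scores = (
        val_preds.groupby("encounter_id")["risk"].max().rename("score").reset_index()
    )
    ep_scores["is_outcome"] = ep_scores["encounter_id"].map(
        lambda e: labels[e].max_stage >= 1
    )
    model.alert_threshold = choose_alert_threshold(
        ep_scores, target_ratio=config.alert_target_ratio
    )
    model.save(out / "model")
    log.append(f"alert threshold {model.alert_threshold:.6f}")

    # 8. predictions for every kept grid point
    predictions = predict_risk(model, features)
    predictions.to_csv(out / "predictions.csv", index=False)

    # 9. RAI comparator on the same grid
    rai = compute_rai_series(
        encounters, observations, medications, labels, kept, baselines
    )
    rai.to_csv(out / "rai.csv", index=False)

    # 10. holdout evaluation
    hold_ids = set(split[split == "holdout"].index)
    hold_preds = predictions[predictions["encounter_id"].isin(hold_ids)]
    hold_rai = rai[rai["encounter_id"].isin(hold_ids)]
    report = evaluation_report(
        hold_preds, labels, encounters.df, medications, rai=hold_rai
    )
    report["config"] = dataclasses.asdict(config)
    report["version"] = __version__
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)

    config.to_yaml(out / "config.yaml")
    (out / "run.log").write_text("\n".join(log) + "\n")

    # manifest with per-artifact hashes (excluding the manifest itself)
    manifest = {
        "version": __version__,
        "config_sha256": _sha256(out / "config.yaml"),
        "artifacts": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return report
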