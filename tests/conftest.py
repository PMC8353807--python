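"""Shared fixtures: seeded synthetic cohorts and fitted pipelines.

The heavy end-to-end pipeline (2000 encounters) is built once per session and
reused by the acceptance tests; unit tests use a small cohort or construct
their inputs inline.
"""

from __future__ import annotations

from types import SimpleNamespace

import pytest

from pedaki.age_ensemble import choose_alert_threshold, fit_ensemble, predict_risk
from pedaki.cohort_labeling import apply_exclusions, label_encounters, split_cohort
from pedaki.evaluation import LEAD_WINDOW_H
from pedaki.featurization import (
    DEFAULT_FEATURES,
    assemble_features,
    build_training_set,
    select_leads,
)
from pedaki.synthetic_ehr import EffectSizes, SimConfig, simulate_cohort

# frozen study-condition seeds
STRONG_SIM_SEED = 11
LABEL_SEED = 2
SPLIT_SEED = 3
RAI_ORDERING_SEEDS = (11, 21, 31)
NULL_SEEDS = (101, 102, 103)
ACCEPT_N = 2000

SIGNAL_PREDICTORS = frozenset(
    {"creatinine_roc", "shock_index_max", "bun_last", "high_nephrotoxic_count"}
)


def run_pipeline(sim_seed: int, n: int = ACCEPT_N, effects: EffectSizes | None = None):
    """Simulate -> label -> featurize -> split -> fit -> threshold -> score."""
    cfg = SimConfig(n_encounters=n, seed=sim_seed,
                    effects=effects if effects is not None else EffectSizes())
    encounters, observations, medications, rrt, truth = simulate_cohort(cfg)
    labels = label_encounters(encounters, observations, rrt, seed=LABEL_SEED)
    kept, excluded = apply_exclusions(encounters, labels)
    features = assemble_features(encounters, observations, medications, labels, kept)
    split = split_cohort(encounters, labels, kept, seed=SPLIT_SEED)
    sets = build_training_set(features, labels, split)
    model = fit_ensemble(
        sets["derivation"], sets["validation"], [s.name for s in DEFAULT_FEATURES]
    )
    f_split = features["encounter_id"].map(split)
    val_feats = select_leads(features[f_split == "validation"], LEAD_WINDOW_H)
    val_preds = predict_risk(model, val_feats)
    episodes = (
        val_preds.groupby("encounter_id")["risk"].max().rename("score").reset_index()
    )
    episodes["is_outcome"] = episodes["encounter_id"].map(
        lambda e: labels[e].max_stage >= 1
    )
    model.alert_threshold = choose_alert_threshold(episodes)
    hold_feats = features[f_split == "holdout"].reset_index(drop=True)
    hold_preds = predict_risk(model, hold_feats)
    return SimpleNamespace(
        config=cfg,
        encounters=encounters,
        observations=observations,
        medications=medications,
        rrt=rrt,
        truth=truth,
        labels=labels,
        kept=kept,
        excluded=excluded,
        features=features,
        split=split,
        sets=sets,
        model=model,
        val_episodes=episodes,
        hold_feats=hold_feats,
        hold_preds=hold_preds,
    )


def shape_recovery(model, train, truth, min_examples: int = 50,
                   level_width: float = 0.1):
    """Spearman rank agreement between learned weak-classifier responses and
    the generating risk surfaces.

    Value bins with at least ``min_examples`` training examples are merged
    into generated-risk levels (the surface averaged over the bin's examples,
    rounded to ``level_width``); the statistic is the Spearman correlation
    between level and the example-weighted mean learned contribution.
    Returns ``{predictor: (n_levels, spearman)}`` for the selected signal
    classifiers.
    """
    import numpy as np
    from scipy.stats import spearmanr

    from pedaki.age_ensemble import age_bin_index

    ab = age_bin_index(train["age_months"].to_numpy(), model.age_edges)
    out = {}
    for clf in model.classifiers:
        if clf.name not in truth.surfaces:
            continue
        v = train[clf.name].to_numpy(dtype=float)
        finite = ~np.isnan(v)
        idx = clf.bins.index(v)
        surface = truth.surfaces[clf.name](train["age_months"].to_numpy(), v)
        levels: dict[float, list[float]] = {}
        for b in range(clf.bins.n_bins):
            m = finite & (idx == b)
            if m.sum() >= min_examples:
                lev = round(float(np.nanmean(surface[m])) / level_width) * level_width
                levels.setdefault(lev, []).append(float(np.mean(clf.table[ab[m], b])))
        ks = sorted(levels)
        rho = (
            float(spearmanr(ks, [np.mean(levels[k]) for k in ks]).statistic)
            if len(ks) >= 3
            else float("nan")
        )
        out[clf.name] = (len(ks), rho)
    return out


@pytest.fixture(scope="session")
def strong_pipeline():
    """The seeded strong-signal study cohort, fitted end to end."""
    return run_pipeline(STRONG_SIM_SEED)


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort (n=250) with labels and features for integration tests."""
    cfg = SimConfig(n_encounters=250, seed=7)
    encounters, observations, medications, rrt, truth = simulate_cohort(cfg)
    labels = label_encounters(encounters, observations, rrt, seed=LABEL_SEED)
    kept, excluded = apply_exclusions(encounters, labels)
    features = assemble_features(encounters, observations, medications, labels, kept)
    return SimpleNamespace(
        config=cfg,
        encounters=encounters,
        observations=observations,
        medications=medications,
        rrt=rrt,
        truth=truth,
        labels=labels,
        kept=kept,
        excluded=excluded,
        features=features,
    )
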