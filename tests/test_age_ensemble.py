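"""Additive lookup-table ensemble: bins, fitting, prediction semantics."""

import numpy as np
import pandas as pd
import pytest

from pedaki.age_ensemble import (
    DegenerateDataError,
    EnsembleModel,
    calibration_check,
    choose_alert_threshold,
    explain,
    fit_ensemble,
    init_bins,
    predict_risk,
)


def _frame(rng, n, cols):
    df = pd.DataFrame({k: v for k, v in cols.items()})
    df["age_months"] = rng.uniform(1, 252, n)
    return df


def _toy_data(rng, n=3000, signal=True):
    """One informative predictor plus noise; label from the informative one."""
    x = rng.normal(0, 1, n)
    noise1 = rng.normal(0, 1, n)
    noise2 = rng.normal(0, 1, n)
    p = 1 / (1 + np.exp(-(x * 2 - 2))) if signal else np.full(n, 0.15)
    y = (rng.random(n) < p).astype(float)
    df = _frame(rng, n, {"x": x, "noise1": noise1, "noise2": noise2})
    df["label"] = y
    return df


# ---------------------------------------------------------------------------
# bins
# ---------------------------------------------------------------------------


def test_quantile_bins_have_near_equal_mass():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({"u": rng.uniform(0, 1, 4000)})
    bins = init_bins(df, ["u"])
    assert bins["u"].n_bins == 16
    idx = bins["u"].index(df["u"].to_numpy())
    counts = np.bincount(idx, minlength=16)[:16]
    assert counts.min() > 0.6 * counts.max()


def test_constant_predictor_collapses_to_one_bin():
    df = pd.DataFrame({"c": np.full(200, 3.0)})
    assert init_bins(df, ["c"])["c"].n_bins == 1


def test_small_integer_support_gets_one_bin_per_integer():
    rng = np.random.default_rng(1)
    df = pd.DataFrame({"k": rng.integers(0, 6, 500).astype(float)})
    bins = init_bins(df, ["k"])
    assert bins["k"].n_bins == 6 and bins["k"].is_integer
    assert bins["k"].index(np.array([0.0, 5.0])).tolist() == [0, 5]


def test_wide_integer_support_pools_overflow_into_top_bin():
    vals = np.concatenate([np.repeat(np.arange(12), 30), [40.0]])
    df = pd.DataFrame({"k": vals})
    bins = init_bins(df, ["k"])
    assert bins["k"].is_integer
    top = bins["k"].n_bins - 1
    assert bins["k"].index(np.array([11.0, 40.0])).tolist() == [top, top]


def test_missing_values_map_to_the_dedicated_bin():
    df = pd.DataFrame({"u": np.linspace(0, 1, 300)})
    bins = init_bins(df, ["u"])
    idx = bins["u"].index(np.array([np.nan, 0.5]))
    assert idx[0] == bins["u"].n_bins
    assert idx[1] < bins["u"].n_bins


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def test_separating_predictor_is_selected_first_with_high_train_auroc():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(7)
    n = 3000
    x = (rng.random(n) > 0.8).astype(float)
    y = x.copy()  # perfectly separating binary predictor
    df = _frame(rng, n, {"x": x, "noise1": rng.normal(0, 1, n)})
    df["label"] = y
    val = df.iloc[2000:].reset_index(drop=True)
    train = df.iloc[:2000].reset_index(drop=True)
    model = fit_ensemble(train, val, ["noise1", "x"], rounds=50)
    assert model.predictor_names[0] == "x"
    preds = predict_risk(model, train)
    assert roc_auc_score(train["label"], preds["risk"]) > 0.999


def test_null_labels_stop_selection_early_or_degenerate():
    rng = np.random.default_rng(3)
    df = _toy_data(rng, n=6000, signal=False)
    train = df.iloc[:4500].reset_index(drop=True)
    val = df.iloc[4500:].reset_index(drop=True)
    try:
        model = fit_ensemble(train, val, ["x", "noise1", "noise2"])
        assert len(model.classifiers) <= 2
    except DegenerateDataError:
        pass  # no candidate cleared the gain threshold at step one


def test_fit_is_deterministic():
    rng = np.random.default_rng(5)
    df = _toy_data(rng)
    train = df.iloc[:2000].reset_index(drop=True)
    val = df.iloc[2000:].reset_index(drop=True)
    m1 = fit_ensemble(train, val, ["x", "noise1"])
    m2 = fit_ensemble(train, val, ["x", "noise1"])
    assert m1.predictor_names == m2.predictor_names
    for a, b in zip(m1.classifiers, m2.classifiers):
        np.testing.assert_array_equal(a.table, b.table)


def test_contributions_are_bounded():
    rng = np.random.default_rng(6)
    df = _toy_data(rng)
    train = df.iloc[:2000].reset_index(drop=True)
    val = df.iloc[2000:].reset_index(drop=True)
    model = fit_ensemble(train, val, ["x", "noise1"])
    for c in model.classifiers:
        assert np.all(np.abs(c.table) <= 1.0)
        assert np.all(np.isfinite(c.table))


# ---------------------------------------------------------------------------
# prediction semantics
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def toy_model():
    rng = np.random.default_rng(11)
    df = _toy_data(rng)
    train = df.iloc[:2000].reset_index(drop=True)
    val = df.iloc[2000:].reset_index(drop=True)
    model = fit_ensemble(train, val, ["x", "noise1", "noise2"])
    return model, val


def test_conservation_score_equals_b0_plus_contributions(toy_model):
    model, val = toy_model
    preds = predict_risk(model, val)
    contrib_cols = [c for c in preds.columns if c.startswith("contrib_")]
    total = model.b0 + preds[contrib_cols].sum(axis=1)
    assert (total == preds["score_preclip"]).all()  # exact, quantized tables
    assert (preds["risk"] == np.clip(preds["score_preclip"], 0, 1)).all()


def test_missingness_substitutes_the_missing_cell_only(toy_model):
    model, val = toy_model
    row = val.iloc[[0]].copy()
    base = predict_risk(model, row)
    row2 = row.copy()
    row2["x"] = np.nan
    alt = predict_risk(model, row2)
    cx = [c for c in model.classifiers if c.name == "x"][0]
    from pedaki.age_ensemble import age_bin_index

    ab = age_bin_index(row["age_months"].to_numpy(), model.age_edges)[0]
    assert alt["contrib_x"].iloc[0] == cx.table[ab, -1]
    for name in ("noise1", "noise2"):
        if f"contrib_{name}" in base:
            assert alt[f"contrib_{name}"].iloc[0] == base[f"contrib_{name}"].iloc[0]


def test_all_missing_prediction_is_defined(toy_model):
    model, val = toy_model
    row = val.iloc[[0]].copy()
    for name in model.predictor_names:
        row[name] = np.nan
    pred = predict_risk(model, row)
    assert 0.0 <= pred["risk"].iloc[0] <= 1.0


def test_perturbing_within_a_bin_leaves_risk_unchanged(toy_model):
    model, val = toy_model
    cx = [c for c in model.classifiers if c.name == "x"][0]
    row = val.iloc[[3]].copy()
    base = predict_risk(model, row)["risk"].iloc[0]
    x = row["x"].iloc[0]
    idx = cx.bins.index(np.array([x]))[0]
    nudged = x + 1e-9
    if cx.bins.index(np.array([nudged]))[0] == idx:
        row["x"] = nudged
        assert predict_risk(model, row)["risk"].iloc[0] == base


def test_ablating_a_classifier_shifts_scores_by_exactly_its_contribution(toy_model):
    import dataclasses

    model, val = toy_model
    preds = predict_risk(model, val)
    victim = model.classifiers[-1]
    ablated = dataclasses.replace(
        model, classifiers=[c for c in model.classifiers if c is not victim]
    )
    preds2 = predict_risk(ablated, val)
    shift = preds["score_preclip"] - preds2["score_preclip"]
    assert (shift == preds[f"contrib_{victim.name}"]).all()


def test_age_outside_supported_range_is_fatal(toy_model):
    model, val = toy_model
    row = val.iloc[[0]].copy()
    row["age_months"] = 300.0
    with pytest.raises(ValueError, match="age outside"):
        predict_risk(model, row)


def test_model_save_load_round_trip(tmp_path, toy_model):
    model, val = toy_model
    model.save(tmp_path / "model")
    loaded = EnsembleModel.load(tmp_path / "model")
    a = predict_risk(model, val)
    b = predict_risk(loaded, val)
    pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------------
# explanation
# ---------------------------------------------------------------------------


def _prediction_row(contribs, risk=0.9):
    data = {"encounter_id": "E1", "grid_h": 12.0, "risk": risk}
    for k, v in contribs.items():
        data[f"contrib_{k}"] = v
    return pd.Series(data)


def test_explain_ranks_positive_contributions():
    pred = _prediction_row({"creatinine_roc": 0.6, "high_nephrotoxic_count": 0.14,
                            "wbc_last": -0.05})
    feats = pd.Series({"creatinine_roc": 0.01, "high_nephrotoxic_count": 5.0,
                       "wbc_last": 9.0})
    exp = explain(pred, feats, k=2)
    assert [e["predictor"] for e in exp.top] == [
        "creatinine_roc", "high_nephrotoxic_count"
    ]
    assert exp.top[0]["contribution"] == 0.6


def test_explain_with_no_positive_contributors_is_empty_but_reports_risk():
    pred = _prediction_row({"wbc_last": -0.05, "bun_last": -0.01}, risk=0.02)
    exp = explain(pred, pd.Series({"wbc_last": 9.0, "bun_last": 12.0}))
    assert exp.top == [] and exp.risk == 0.02


def test_explain_aminoglycoside_context(small_cohort):
    meds = small_cohort.medications
    sub = meds.df[meds.df["drug_name"] == "gentamicin"]
    assert len(sub), "synthetic cohort should administer gentamicin somewhere"
    enc_id = sub.iloc[0]["encounter_id"]
    t = sub.iloc[0]["t_h"] + 1.0
    pred = _prediction_row({"bun_last": 0.2})
    pred["encounter_id"] = enc_id
    pred["grid_h"] = t
    exp = explain(pred, pd.Series({"bun_last": 30.0}), medications=meds)
    assert "patient on aminoglycosides" in exp.context
    assert "check level and review dose and indication" in exp.action


# ---------------------------------------------------------------------------
# calibration and threshold
# ---------------------------------------------------------------------------


def test_calibration_constant_model_single_decile_equals_prevalence():
    preds = pd.DataFrame({"risk": np.full(400, 0.25)})
    y = np.zeros(400)
    y[:100] = 1.0
    table, gap = calibration_check(preds, y)
    assert len(table) == 1
    assert table["event_rate"].iloc[0] == 0.25
    assert gap == pytest.approx(0.0)


def test_calibration_gap_shrinks_for_well_calibrated_scores():
    rng = np.random.default_rng(21)
    p = rng.uniform(0, 1, 20000)
    y = (rng.random(20000) < p).astype(float)
    _, gap = calibration_check(pd.DataFrame({"risk": p}), y)
    assert gap < 0.02


def test_threshold_is_smallest_meeting_target_ratio():
    eps = pd.DataFrame(
        {
            "score": [0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2],
            "is_outcome": [True, True, False, True, False, False, False, False],
        }
    )
    # at 0.4: TP=3, FP=3 (1.0); at 0.5: TP=3, FP=2 (1.5); at 0.6: TP=3, FP=1 (3.0)
    assert choose_alert_threshold(eps, target_ratio=1.0) == 0.4
    assert choose_alert_threshold(eps, target_ratio=1.5) == 0.5
    assert choose_alert_threshold(eps, target_ratio=2.0) == 0.6


def test_threshold_boundary_semantics():
    eps = pd.DataFrame({"score": [0.2, 0.3], "is_outcome": [False, False]})
    thr = choose_alert_threshold(eps)  # no outcome episodes: Youden fallback
    assert 0.0 <= thr <= 1.0
    # threshold above every score yields zero alerts hence zero sensitivity
    assert (eps["score"] >= 1.0).sum() == 0


def test_episode_sensitivity_monotone_in_threshold(strong_pipeline):
    eps = strong_pipeline.val_episodes
    thresholds = np.linspace(0, 1, 20)
    sens = []
    n_outcome = eps["is_outcome"].sum()
    for thr in thresholds:
        tp = ((eps["score"] >= thr) & eps["is_outcome"]).sum()
        sens.append(tp / n_outcome)
    assert all(a >= b for a, b in zip(sens, sens[1:]))
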