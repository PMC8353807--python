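"""Prediction grid and windowed predictor engineering."""

import numpy as np
import pandas as pd
import pytest

from pedaki.featurization import (
    DEFAULT_FEATURES,
    build_prediction_grid,
    build_training_set,
    creatinine_rate_of_change,
    medication_counts,
    shock_index_series,
    window_statistics,
)
from pedaki.ehr_data import MedicationStore


def brute_croc(t, v, at, window=48.0):
    """Closed-form least-squares slope oracle over the half-open lookback
    window (centered normal equations, plain Python accumulation)."""
    pts = [(ti, vi) for ti, vi in zip(t, v) if at - window < ti <= at]
    if len(pts) < 2:
        return np.nan
    n = len(pts)
    tbar = sum(p[0] for p in pts) / n
    vbar = sum(p[1] for p in pts) / n
    num = sum((p[0] - tbar) * (p[1] - vbar) for p in pts)
    den = sum((p[0] - tbar) ** 2 for p in pts)
    if den == 0:
        return np.nan
    return num / den


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------


def test_grid_spacing_and_truncation():
    assert build_prediction_grid(30.0).tolist() == [6.0, 12.0, 18.0, 24.0, 30.0]
    assert build_prediction_grid(100.0, onset_h=20.0).tolist() == [6.0, 12.0, 18.0]
    assert build_prediction_grid(100.0, onset_h=18.0).tolist() == [6.0, 12.0, 18.0]


# ---------------------------------------------------------------------------
# window statistics
# ---------------------------------------------------------------------------


def test_window_statistics_hand_example():
    t = np.array([1.0, 10.0, 20.0])
    v = np.array([2.0, 4.0, 9.0])
    got = window_statistics(t, v, at=20.0)
    assert got == {"mean": 5.0, "median": 4.0, "min": 2.0, "max": 9.0,
                   "change": 7.0, "last": 9.0}


def test_window_statistics_degenerate_and_empty():
    got = window_statistics(np.array([5.0]), np.array([3.0]), at=10.0)
    assert got["change"] == 0.0
    assert got["mean"] == got["last"] == got["min"] == got["max"] == 3.0
    empty = window_statistics(np.array([5.0]), np.array([3.0]), at=60.0)
    assert all(np.isnan(x) for x in empty.values())


def test_window_is_half_open_lookback_including_t():
    t = np.array([0.0, 30.0])
    v = np.array([1.0, 2.0])
    got = window_statistics(t, v, at=30.0, window_h=30.0)
    assert got["mean"] == 2.0  # the point exactly at t-30 is excluded


def test_window_statistics_match_brute_force_on_random_windows():
    rng = np.random.default_rng(12)
    for _ in range(200):
        n = rng.integers(0, 25)
        t = np.sort(rng.uniform(0, 100, n))
        v = rng.normal(5, 2, n)
        at = rng.uniform(0, 110)
        got = window_statistics(t, v, at)
        w = [vi for ti, vi in zip(t, v) if at - 30.0 < ti <= at]
        if not w:
            assert all(np.isnan(x) for x in got.values())
        else:
            assert got["mean"] == pytest.approx(np.mean(w))
            assert got["median"] == pytest.approx(np.median(w))
            assert got["min"] == min(w) and got["max"] == max(w)
            assert got["change"] == pytest.approx(w[-1] - w[0])
            assert got["last"] == w[-1]


# ---------------------------------------------------------------------------
# creatinine rate of change
# ---------------------------------------------------------------------------


def test_croc_two_point_line():
    t = np.array([8.0, 48.0])
    v = np.array([0.5, 0.9])
    assert creatinine_rate_of_change(t, v, at=48.0) == pytest.approx(0.4 / 40.0)
    # a point exactly at t - 48 falls outside the half-open lookback
    assert np.isnan(creatinine_rate_of_change(np.array([0.0, 48.0]), v, at=48.0))


def test_croc_three_point_closed_form():
    t = np.array([2.0, 24.0, 48.0])
    v = np.array([0.4, 0.5, 0.9])
    # normal equations: slope = (n*sum(tv) - sum(t)sum(v)) / (n*sum(t^2) - sum(t)^2)
    want = (3 * 56.0 - 74.0 * 1.8) / (3 * 2884.0 - 74.0**2)  # = 34.8 / 3176
    assert creatinine_rate_of_change(t, v, at=48.0) == pytest.approx(want, rel=1e-12)


def test_croc_translation_invariance():
    rng = np.random.default_rng(3)
    t = np.sort(rng.uniform(0, 48, 6))
    v = rng.uniform(0.3, 1.5, 6)
    a = creatinine_rate_of_change(t, v, at=48.0)
    b = creatinine_rate_of_change(t + 10.0, v, at=58.0)
    assert a == pytest.approx(b, rel=1e-12)


def test_croc_missing_below_two_points():
    assert np.isnan(creatinine_rate_of_change(np.array([1.0]), np.array([0.5]), 48.0))
    assert np.isnan(creatinine_rate_of_change(np.empty(0), np.empty(0), 48.0))


def test_croc_matches_normal_equations_on_random_windows():
    rng = np.random.default_rng(99)
    for _ in range(200):
        n = rng.integers(2, 12)
        t = np.sort(rng.uniform(0, 96, n))
        v = rng.uniform(0.2, 3.0, n)
        at = rng.uniform(10, 100)
        got = creatinine_rate_of_change(t, v, at)
        want = brute_croc(t, v, at)
        if np.isnan(want):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(want, rel=1e-12, abs=1e-15)


# ---------------------------------------------------------------------------
# medication counts
# ---------------------------------------------------------------------------


def _med_store(rows):
    return MedicationStore(
        pd.DataFrame(rows, columns=["encounter_id", "t_h", "drug_name", "category"])
    )


def test_medication_counts_per_category_with_zero_default():
    meds = _med_store(
        [("E", 10.0, "epinephrine", "vasoactive")] * 3
        + [("E", 12.0, "gentamicin", "high_nephrotoxic")] * 2
    )
    got = medication_counts(meds, "E", at=20.0)
    assert got == {"high_nephrotoxic": 2, "low_nephrotoxic": 0, "vasoactive": 3}


def test_medication_count_window_is_half_open():
    meds = _med_store([("E", 32.0, "gentamicin", "high_nephrotoxic"),
                       ("E", 200.0, "gentamicin", "high_nephrotoxic")])
    got = medication_counts(meds, "E", at=200.0)
    assert got["high_nephrotoxic"] == 1  # the event exactly at t-168 is excluded


def test_no_medication_table_counts_zero():
    meds = _med_store([])
    assert medication_counts(meds, "E", at=20.0) == {
        "high_nephrotoxic": 0, "low_nephrotoxic": 0, "vasoactive": 0,
    }


# ---------------------------------------------------------------------------
# shock index
# ---------------------------------------------------------------------------


def test_shock_index_pairs_nearest_sbp_within_15_minutes():
    t, si = shock_index_series(
        np.array([10.0]), np.array([120.0]),
        np.array([10.0 + 5 / 60.0]), np.array([80.0]),
    )
    assert t.tolist() == [10.0]
    assert si.tolist() == [1.5]


def test_shock_index_skips_unpaired_and_nonpositive_sbp():
    t, si = shock_index_series(
        np.array([10.0, 20.0]), np.array([100.0, 100.0]),
        np.array([10.1, 21.0]), np.array([-5.0, 100.0]),
    )
    assert t.tolist() == []  # first paired but SBP <= 0; second beyond 15 min


def test_shock_index_identity():
    _, si = shock_index_series(
        np.array([5.0]), np.array([100.0]), np.array([5.0]), np.array([100.0])
    )
    assert si.tolist() == [1.0]


# ---------------------------------------------------------------------------
# assembled features
# ---------------------------------------------------------------------------


def test_assembled_features_cover_default_predictors(small_cohort):
    feats = small_cohort.features
    names = [s.name for s in DEFAULT_FEATURES]
    assert list(feats.columns[4:]) == names
    assert (feats["time_since_admission"] == feats["grid_h"]).all()
    assert (feats["lead_time_h"] == [
        small_cohort.labels[e].onset_h for e in feats["encounter_id"]
    ] - feats["grid_h"]).all()


def test_never_ventilated_patient_has_missing_airway_pressure(small_cohort):
    truth = small_cohort.truth.frame
    feats = small_cohort.features
    for enc_id in small_cohort.kept[:50]:
        sub = feats[feats["encounter_id"] == enc_id]
        if not truth.loc[enc_id, "ventilated"]:
            assert sub["mean_airway_pressure_median"].isna().all()


def test_count_predictors_are_never_missing(small_cohort):
    feats = small_cohort.features
    assert feats["vasoactive_count"].notna().all()
    assert feats["high_nephrotoxic_count"].notna().all()


def test_assembled_values_match_single_purpose_recomputation(small_cohort):
    feats = small_cohort.features
    obs, meds = small_cohort.observations, small_cohort.medications
    rng = np.random.default_rng(0)
    rows = feats.sample(40, random_state=17)
    for _, row in rows.iterrows():
        enc_id, g = row["encounter_id"], row["grid_h"]
        t, v = obs.series(enc_id, "bun")
        want = window_statistics(t, v, g, stats=("last",))["last"]
        assert (np.isnan(want) and np.isnan(row["bun_last"])) or want == row["bun_last"]
        t, v = obs.series(enc_id, "creatinine")
        want = brute_croc(t, v, g)
        got = row["creatinine_roc"]
        assert (np.isnan(want) and np.isnan(got)) or got == pytest.approx(want, rel=1e-12)
        want = medication_counts(meds, enc_id, g)["high_nephrotoxic"]
        assert row["high_nephrotoxic_count"] == want


def test_removing_one_variable_flips_only_its_predictor(small_cohort):
    from pedaki.featurization import assemble_features
    from pedaki.ehr_data import ObservationStore

    enc_id = small_cohort.kept[0]
    obs_df = small_cohort.observations.df
    pruned = ObservationStore(
        obs_df[~((obs_df["encounter_id"] == enc_id) & (obs_df["variable"] == "bun"))]
    )
    feats2 = assemble_features(
        small_cohort.encounters, pruned, small_cohort.medications,
        small_cohort.labels, [enc_id],
    )
    feats1 = small_cohort.features[
        small_cohort.features["encounter_id"] == enc_id
    ].reset_index(drop=True)
    assert feats2["bun_last"].isna().all()
    others = [c for c in feats1.columns if c != "bun_last"]
    pd.testing.assert_frame_equal(feats1[others], feats2[others])


def test_training_window_interval_arithmetic(small_cohort):
    from pedaki.cohort_labeling import split_cohort

    split = split_cohort(
        small_cohort.encounters, small_cohort.labels, small_cohort.kept, seed=3
    )
    sets = build_training_set(small_cohort.features, small_cohort.labels, split)
    for name in ("derivation", "validation"):
        lead = sets[name]["lead_time_h"]
        assert ((lead >= 24.0) & (lead <= 48.0)).all()
    lead = sets["holdout"]["lead_time_h"]
    assert ((lead >= 6.0) & (lead <= 48.0)).all()
    # the binary label is the stage-2/3 primary outcome
    for name, df in sets.items():
        want = df["encounter_id"].map(
            lambda e: int(small_cohort.labels[e].primary_case)
        )
        assert (df["label"] == want).all()


def test_case_training_points_stop_before_onset():
    # onset at 60 h, grid 6..54: training leads 48..24 are grid 12..36
    grid = build_prediction_grid(100.0, onset_h=60.0)
    leads = 60.0 - grid
    train = grid[(leads >= 24.0) & (leads <= 48.0)]
    assert train.tolist() == [12.0, 18.0, 24.0, 30.0, 36.0]
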