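"""KDIGO serum-creatinine staging, onset assignment, exclusions, splitting.

Staging uses the serum-creatinine arm of the KDIGO guidelines only (urine
output is deliberately out of scope): with ``r = SCr / baseline`` and
``rise48 = SCr - min(SCr in the prior 48 h)``,

- stage 3 if r >= 3.0, or SCr >= 4.0 mg/dL (configurable), or the measurement
  falls inside a renal-replacement-therapy episode;
- stage 2 if r >= 2.0;
- stage 1 if r >= 1.5 or rise48 >= 0.3 mg/dL.

The baseline is the static age/sex normal mean (never a measured minimum);
the 48 h-rise clause uses the rolling measured minimum. Moderate-to-severe
AKI (stage >= 2) defines the primary cases; stage-0/1 encounters are the
controls, with a seeded pseudo-onset drawn for stage-0 stays.
"""

from __future__ import annotations

import dataclasses
import zlib
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .ehr_data import DatasetError, EncounterSet, ObservationStore, RRTStore

AGE_MIN_MONTHS = 1.0
AGE_MAX_MONTHS = 252.0  # 21 years; exactly 252 is kept
EARLY_AKI_WINDOW_H = 12.0
MIN_STAY_H = 24.0
PSEUDO_ONSET_MIN_H = 24.0

SPLIT_NAMES = ("derivation", "validation", "holdout")


class BaselineTable:
    """Age/sex table of normal mean serum creatinine (mg/dL).

    Rows carry half-open age intervals ``[age_min_months, age_max_months)``
    which must partition [1, 252] months for each sex. The packaged default is
    transcribed from published pediatric norms and is meant to be reviewed and
    replaced with site-specific values where available.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"sex", "age_min_months", "age_max_months", "scr_mgdl"}
        if not required.issubset(df.columns):
            raise DatasetError(f"baseline table needs columns {sorted(required)}")
        if (df["scr_mgdl"] <= 0).any():
            raise DatasetError("baseline scr_mgdl must be positive")
        self.df = df.sort_values(["sex", "age_min_months"]).reset_index(drop=True)
        for sex, sub in self.df.groupby("sex"):
            lo = sub["age_min_months"].to_numpy(dtype=float)
            hi = sub["age_max_months"].to_numpy(dtype=float)
            if lo[0] > AGE_MIN_MONTHS or hi[-1] <= AGE_MAX_MONTHS:
                raise DatasetError(f"baseline table for sex {sex} does not cover [1, 252]")
            if not np.allclose(hi[:-1], lo[1:]):
                raise DatasetError(f"baseline table for sex {sex} has gaps or overlaps")

    @classmethod
    def from_csv(cls, path: str | Path) -> "BaselineTable":
        return cls(pd.read_csv(path))

    @classmethod
    def default(cls) -> "BaselineTable":
        return cls.from_csv(resources.files("pedaki") / "data" / "baseline_creatinine.csv")

    def lookup(self, age_months: float, sex: str) -> float:
        """Baseline SCr for the half-open age interval containing ``age_months``."""
        sub = self.df[self.df["sex"] == sex]
        if not len(sub):
            raise DatasetError(f"no baseline rows for sex {sex!r}")
        hit = sub[(sub["age_min_months"] <= age_months) & (age_months < sub["age_max_months"])]
        if len(hit) != 1:
            raise DatasetError(f"age {age_months} months outside baseline table coverage")
        return float(hit["scr_mgdl"].iloc[0])


def baseline_creatinine(
    age_months: float, sex: str, table: BaselineTable | None = None
) -> float:
    """Normal mean serum creatinine (mg/dL) for an age/sex group."""
    return (table or BaselineTable.default()).lookup(age_months, sex)


@dataclasses.dataclass
class AKILabel:
    """Per-encounter staging result."""

    encounter_id: str
    max_stage: int
    onset_h: float  # cases: measurement time; stage-0 controls: pseudo-onset
    stage_sequence: np.ndarray  # per-measurement stage, time order
    measurement_times: np.ndarray
    rrt_required: bool
    primary_case: bool  # max_stage >= 2
    exclusion_reason: str | None = None


def stage_creatinine_series(
    times_h: np.ndarray,
    values: np.ndarray,
    baseline: float,
    rrt_intervals: np.ndarray | None = None,
    use_abs_stage3: bool = True,
) -> np.ndarray:
    """Per-measurement KDIGO stage for a time-sorted creatinine series.

    ``rise48`` for the measurement at ``t`` is the value minus the minimum
    over the half-open lookback ``(t - 48 h, t]`` (the value itself included,
    so the rise is never negative).
    """
    if baseline <= 0:
        raise DatasetError("baseline creatinine must be positive")
    t = np.asarray(times_h, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(t) == 0:
        return np.empty(0, dtype=int)
    if np.any(np.diff(t) < 0):
        order = np.argsort(t, kind="stable")
        t, v = t[order], v[order]

    ratio = v / baseline
    rise48 = np.empty_like(v)
    for i in range(len(t)):
        lo = np.searchsorted(t, t[i] - 48.0, side="right")
        rise48[i] = v[i] - v[lo : i + 1].min()

    on_rrt = np.zeros(len(t), dtype=bool)
    if rrt_intervals is not None and len(rrt_intervals):
        iv = np.asarray(rrt_intervals, dtype=float)
        for s, e in iv:
            on_rrt |= (t >= s) & (t < e)

    stage = np.zeros(len(t), dtype=int)
    stage[(ratio >= 1.5) | (rise48 >= 0.3)] = 1
    stage[ratio >= 2.0] = 2
    s3 = (ratio >= 3.0) | on_rrt
    if use_abs_stage3:
        s3 |= v >= 4.0
    stage[s3] = 3
    return stage


def _encounter_rng(seed: int, encounter_id: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(encounter_id.encode())])


def assign_onset(
    encounter_id: str,
    times_h: np.ndarray,
    stages: np.ndarray,
    stay_h: float,
    rrt_required: bool,
    seed: int = 0,
) -> AKILabel:
    """Onset rule: first stage >= 2 measurement for primary cases; first
    stage >= 1 for stage-1-only; a seeded uniform pseudo-onset in
    [admit + 24 h, discharge] for stage-0 controls."""
    stages = np.asarray(stages, dtype=int)
    times_h = np.asarray(times_h, dtype=float)
    max_stage = int(stages.max()) if len(stages) else 0
    if max_stage >= 2:
        onset = float(times_h[np.argmax(stages >= 2)])
    elif max_stage == 1:
        onset = float(times_h[np.argmax(stages >= 1)])
    else:
        rng = _encounter_rng(seed, encounter_id)
        onset = float(rng.uniform(min(PSEUDO_ONSET_MIN_H, stay_h), stay_h))
    return AKILabel(
        encounter_id=encounter_id,
        max_stage=max_stage,
        onset_h=onset,
        stage_sequence=stages,
        measurement_times=times_h,
        rrt_required=rrt_required,
        primary_case=max_stage >= 2,
    )


def label_encounters(
    encounters: EncounterSet,
    observations: ObservationStore,
    rrt: RRTStore,
    baselines: BaselineTable | None = None,
    seed: int = 0,
    use_abs_stage3: bool = True,
) -> dict[str, AKILabel]:
    """Stage every encounter's creatinine series and assign onsets."""
    baselines = baselines or BaselineTable.default()
    labels: dict[str, AKILabel] = {}
    for enc_id in encounters.ids:
        row = encounters.row(enc_id)
        t, v = observations.series(enc_id, "creatinine")
        age = row["age_months"]
        if np.isfinite(age) and AGE_MIN_MONTHS <= age <= AGE_MAX_MONTHS and len(t):
            base = baselines.lookup(float(age), row["sex"])
            stages = stage_creatinine_series(
                t, v, base, rrt.intervals(enc_id), use_abs_stage3=use_abs_stage3
            )
        else:
            stages = np.zeros(len(t), dtype=int)
        labels[enc_id] = assign_onset(
            enc_id, t, stages, float(row["stay_h"]), rrt.has_rrt(enc_id), seed=seed
        )
    return labels


def apply_exclusions(
    encounters: EncounterSet, labels: dict[str, AKILabel]
) -> tuple[list[str], dict[str, str]]:
    """Apply the cohort exclusion rules; returns (kept ids, excluded id -> reason).

    Rules, in order: invalid age (< 1 month, > 252 months, or missing); any
    stage >= 1 creatinine within the first 12 h of stay; stay < 24 h; and one
    encounter per patient (keep highest max stage, then longest stay, then
    earliest admission).
    """
    excluded: dict[str, str] = {}
    survivors: list[str] = []
    for enc_id in encounters.ids:
        row = encounters.row(enc_id)
        lab = labels[enc_id]
        age = row["age_months"]
        if not np.isfinite(age) or age < AGE_MIN_MONTHS or age > AGE_MAX_MONTHS:
            excluded[enc_id] = "age"
        elif np.any(
            (lab.measurement_times <= EARLY_AKI_WINDOW_H) & (lab.stage_sequence >= 1)
        ):
            excluded[enc_id] = "early_aki"
        elif row["stay_h"] < MIN_STAY_H:
            excluded[enc_id] = "short_stay"
        else:
            survivors.append(enc_id)

    by_patient: dict[str, list[str]] = {}
    for enc_id in survivors:
        by_patient.setdefault(encounters.row(enc_id)["patient_id"], []).append(enc_id)
    kept: list[str] = []
    for _, enc_ids in by_patient.items():
        if len(enc_ids) == 1:
            kept.extend(enc_ids)
            continue
        ranked = sorted(
            enc_ids,
            key=lambda e: (
                -labels[e].max_stage,
                -encounters.row(e)["stay_h"],
                encounters.row(e)["admit_ts"],
                e,
            ),
        )
        kept.append(ranked[0])
        for e in ranked[1:]:
            excluded[e] = "duplicate_patient"
    kept = [e for e in encounters.ids if e in set(kept)]
    return kept, excluded


def split_cohort(
    encounters: EncounterSet,
    labels: dict[str, AKILabel],
    kept_ids: list[str],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> pd.Series:
    """Patient-level derivation/validation/holdout split, stratified by
    primary-case status (and a ``site`` column when the encounter table has
    one). No patient appears in two splits; deterministic under ``seed``."""
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)

    sub = encounters.df.loc[kept_ids]
    strata: dict[tuple, list[str]] = {}
    for patient_id, enc_rows in sub.groupby("patient_id", sort=True):
        is_case = any(labels[e].primary_case for e in enc_rows.index)
        site = enc_rows["site"].iloc[0] if "site" in enc_rows.columns else ""
        strata.setdefault((is_case, site), []).append(patient_id)

    assignment: dict[str, str] = {}
    for key in sorted(strata):
        patients = sorted(strata[key])
        rng.shuffle(patients)
        n = len(patients)
        # largest-remainder allocation of n patients over the three splits
        raw = np.array(fractions) * n
        counts = np.floor(raw).astype(int)
        rem = raw - counts
        for idx in np.argsort(-rem)[: n - counts.sum()]:
            counts[idx] += 1
        start = 0
        for split_name, c in zip(SPLIT_NAMES, counts):
            for p in patients[start : start + c]:
                assignment[p] = split_name
            start += c

    out = pd.Series(
        {e: assignment[sub.loc[e, "patient_id"]] for e in kept_ids}, name="split"
    )
    out.index.name = "encounter_id"
    return out


def labels_frame(labels: dict[str, AKILabel]) -> pd.DataFrame:
    """Flatten labels to a per-encounter table (for labels.csv)."""
    rows = [
        {
            "encounter_id": lab.encounter_id,
            "max_stage": lab.max_stage,
            "onset_h": lab.onset_h,
            "rrt_required": lab.rrt_required,
            "primary_case": lab.primary_case,
            "exclusion_reason": lab.exclusion_reason or "",
        }
        for lab in labels.values()
    ]
    return pd.DataFrame(rows).set_index("encounter_id").sort_index()
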