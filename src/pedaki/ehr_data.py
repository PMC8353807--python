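"""Longitudinal EHR data model and CSV I/O.

Every downstream stage (labeling, featurization, training, evaluation)
consumes the four in-memory stores defined here and never touches files
directly. Timestamps are parsed from ISO-8601 to UTC and held internally as
hours since the encounter's admission; all lookback windows elsewhere in the
package are half-open ``(t - W, t]`` with the value at ``t`` included.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: Controlled vocabulary of observation variables used by downstream stages.
#: Variables outside this set are preserved in the store but ignored.
VARIABLE_VOCABULARY = frozenset(
    {
        "heart_rate",
        "sbp",
        "spo2",
        "creatinine",
        "bun",
        "bilirubin",
        "paco2",
        "anion_gap",
        "wbc",
        "albumin",
        "chloride",
        "gentamicin_trough",
        "mean_airway_pressure",
    }
)

#: Expected unit string per vocabulary variable (no conversion is performed;
#: validation only flags unexpected strings).
EXPECTED_UNITS = {
    "heart_rate": "bpm",
    "sbp": "mmHg",
    "spo2": "%",
    "creatinine": "mg/dL",
    "bun": "mg/dL",
    "bilirubin": "mg/dL",
    "paco2": "%",
    "anion_gap": "mmol/L",
    "wbc": "10^9/L",
    "albumin": "g/dL",
    "chloride": "mmol/L",
    "gentamicin_trough": "mg/L",
    "mean_airway_pressure": "cmH2O",
}

MEDICATION_CATEGORIES = ("high_nephrotoxic", "low_nephrotoxic", "vasoactive")
UNCATEGORIZED = "uncategorized"

#: Pre-admission laboratory results are tolerated this far before admission.
PREADMISSION_TOLERANCE_H = 7 * 24.0


class DatasetError(ValueError):
    """Fatal dataset problem (missing file, missing required column, ...)."""


# ---------------------------------------------------------------------------
# Stores
# ---------------------------------------------------------------------------


class EncounterSet:
    """Encounter-level table indexed by ``encounter_id``.

    Columns: patient_id, sex (F/M), age_months, admit_ts, discharge_ts
    (tz-aware UTC), unit (PICU/CTICU), died (bool), stay_h (derived).
    """

    REQUIRED = [
        "encounter_id",
        "patient_id",
        "sex",
        "age_months",
        "admit_ts",
        "discharge_ts",
        "unit",
        "died",
    ]

    def __init__(self, df: pd.DataFrame):
        if df.index.name != "encounter_id":
            df = df.set_index("encounter_id")
        if not df.index.is_unique:
            raise DatasetError("encounter_id values must be unique")
        df = df.copy()
        df["stay_h"] = (
            (df["discharge_ts"] - df["admit_ts"]).dt.total_seconds() / 3600.0
        )
        if (df["stay_h"] <= 0).any():
            bad = df.index[df["stay_h"] <= 0].tolist()
            raise DatasetError(f"admit_ts must precede discharge_ts: {bad[:5]}")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, encounter_id: str) -> bool:
        return encounter_id in self.df.index

    @property
    def ids(self) -> pd.Index:
        return self.df.index

    def row(self, encounter_id: str) -> pd.Series:
        return self.df.loc[encounter_id]


class _EventStore:
    """Base for per-encounter event tables with times in hours since admit."""

    def __init__(self, df: pd.DataFrame):
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


class ObservationStore(_EventStore):
    """Timestamped (encounter_id, t_h, variable, value, unit) observations."""

    COLUMNS = ["encounter_id", "t_h", "variable", "value", "unit"]

    def __init__(self, df: pd.DataFrame):
        super().__init__(df[self.COLUMNS] if len(df) else df.reindex(columns=self.COLUMNS))
        self._cache: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] | None = None

    def _build_cache(self) -> dict:
        cache: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        if len(self.df):
            d = self.df.sort_values("t_h", kind="stable")
            for key, sub in d.groupby(["encounter_id", "variable"], sort=False):
                cache[key] = (
                    sub["t_h"].to_numpy(dtype=float),
                    sub["value"].to_numpy(dtype=float),
                )
        return cache

    def series(self, encounter_id: str, variable: str) -> tuple[np.ndarray, np.ndarray]:
        """Time-sorted (times_h, values) for one encounter and variable."""
        if self._cache is None:
            self._cache = self._build_cache()
        return self._cache.get((encounter_id, variable), (np.empty(0), np.empty(0)))

    def resolve_duplicates(self) -> int:
        """Keep the last-read row per (encounter_id, t_h, variable); return count dropped."""
        before = len(self.df)
        self.df = self.df.drop_duplicates(
            subset=["encounter_id", "t_h", "variable"], keep="last"
        ).reset_index(drop=True)
        self._cache = None
        return before - len(self.df)


class MedicationStore(_EventStore):
    """Medication administrations with resolved nephrotoxic/vasoactive category.

    A drug mapped to several categories contributes one row per category per
    administration; unmappable drugs carry category ``uncategorized`` and are
    ignored by downstream counts.
    """

    COLUMNS = ["encounter_id", "t_h", "drug_name", "category"]

    def __init__(self, df: pd.DataFrame):
        super().__init__(df[self.COLUMNS] if len(df) else df.reindex(columns=self.COLUMNS))
        self._cache: dict[tuple[str, str], np.ndarray] | None = None
        self._drug_cache: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def events(self, encounter_id: str, category: str) -> np.ndarray:
        """Sorted administration times (hours) for one encounter and category."""
        if self._cache is None:
            cache: dict[tuple[str, str], np.ndarray] = {}
            if len(self.df):
                d = self.df.sort_values("t_h", kind="stable")
                for key, sub in d.groupby(["encounter_id", "category"], sort=False):
                    cache[key] = sub["t_h"].to_numpy(dtype=float)
            self._cache = cache
        return self._cache.get((encounter_id, category), np.empty(0))

    def drugs_in_window(
        self, encounter_id: str, category: str, t0: float, t1: float
    ) -> list[str]:
        """Distinct drug names of `category` administered in (t0, t1]."""
        if self._drug_cache is None:
            cache: dict[str, tuple] = {}
            if len(self.df):
                for enc, sub in self.df.groupby("encounter_id", sort=False):
                    cache[enc] = sub
            self._drug_cache = cache
        sub = self._drug_cache.get(encounter_id)
        if sub is None:
            return []
        m = (sub["category"] == category) & (sub["t_h"] > t0) & (sub["t_h"] <= t1)
        return sorted(sub.loc[m, "drug_name"].unique())


class RRTStore(_EventStore):
    """Renal-replacement-therapy episodes, half-open [start_h, end_h)."""

    COLUMNS = ["encounter_id", "start_h", "end_h"]

    def __init__(self, df: pd.DataFrame):
        super().__init__(df[self.COLUMNS] if len(df) else df.reindex(columns=self.COLUMNS))
        if len(self.df) and (self.df["start_h"] >= self.df["end_h"]).any():
            raise DatasetError("RRT episodes require start_ts < end_ts")

    def intervals(self, encounter_id: str) -> np.ndarray:
        if not len(self.df):
            return np.empty((0, 2))
        sub = self.df[self.df["encounter_id"] == encounter_id]
        return sub[["start_h", "end_h"]].to_numpy(dtype=float)

    def covers(self, encounter_id: str, t_h: float) -> bool:
        iv = self.intervals(encounter_id)
        return bool(((iv[:, 0] <= t_h) & (t_h < iv[:, 1])).any()) if len(iv) else False

    def has_rrt(self, encounter_id: str) -> bool:
        return len(self.df) > 0 and (self.df["encounter_id"] == encounter_id).any()


@dataclasses.dataclass
class ValidationReport:
    """Row-level dataset quality findings (report-only; never raises)."""

    orphan_rows: int = 0
    nonfinite_values: int = 0
    out_of_window: int = 0
    duplicates: int = 0
    unexpected_units: int = 0
    messages: list[str] = dataclasses.field(default_factory=list)

    @property
    def n_flags(self) -> int:
        return (
            self.orphan_rows
            + self.nonfinite_values
            + self.out_of_window
            + self.duplicates
            + self.unexpected_units
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def default_drug_map_path() -> Path:
    """Path of the packaged default drug-category map (editable placeholder)."""
    return Path(resources.files("pedaki") / "data" / "drug_categories.csv")


def read_drug_map(path: str | Path) -> dict[str, list[str]]:
    """drug_name -> list of categories. Multiple rows per drug are allowed."""
    df = _read_csv(path, ["drug_name", "category"])
    mapping: dict[str, list[str]] = {}
    for drug, cat in zip(df["drug_name"], df["category"]):
        if cat not in MEDICATION_CATEGORIES:
            raise DatasetError(f"unknown medication category {cat!r} for {drug!r}")
        mapping.setdefault(str(drug), [])
        if cat not in mapping[str(drug)]:
            mapping[str(drug)].append(cat)
    return mapping


def _read_csv(path: str | Path, required: Iterable[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"missing input file: {path}")
    df = pd.read_csv(path, dtype={"encounter_id": str, "patient_id": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DatasetError(f"{path.name}: missing required column(s) {missing}")
    return df


def _hours_since_admit(ts: pd.Series, encounters: EncounterSet, enc_ids: pd.Series) -> np.ndarray:
    admit = pd.DatetimeIndex(
        encounters.df["admit_ts"].reindex(enc_ids.to_numpy())
    ).tz_localize(None).to_numpy()
    t = pd.DatetimeIndex(
        pd.to_datetime(ts, utc=True, format="ISO8601")
    ).tz_localize(None).to_numpy()
    return (t - admit) / np.timedelta64(1, "h")


def read_dataset(
    data_dir: str | Path,
    drug_map: str | Path | None = None,
) -> tuple[EncounterSet, ObservationStore, MedicationStore, RRTStore, list[str]]:
    """Read the five-table CSV dataset from ``data_dir``.

    Expected files: encounters.csv, observations.csv, medications.csv,
    rrt.csv (optional), and a drug-category map (``drug_map`` or
    data_dir/drug_categories.csv, falling back to the packaged default).

    Returns the four stores plus a list of row-level diagnostics
    (warnings; fatal problems raise :class:`DatasetError`). Duplicate
    (encounter_id, ts, variable) observation rows are resolved last-read-wins.
    """
    data_dir = Path(data_dir)
    diagnostics: list[str] = []

    enc_raw = _read_csv(data_dir / "encounters.csv", EncounterSet.REQUIRED)
    enc_raw["admit_ts"] = pd.to_datetime(enc_raw["admit_ts"], utc=True, format="ISO8601")
    enc_raw["discharge_ts"] = pd.to_datetime(enc_raw["discharge_ts"], utc=True, format="ISO8601")
    enc_raw["age_months"] = pd.to_numeric(enc_raw["age_months"], errors="coerce")
    enc_raw["died"] = enc_raw["died"].astype(str).str.lower().isin(["true", "1", "yes"])
    encounters = EncounterSet(enc_raw)

    obs_raw = _read_csv(data_dir / "observations.csv", ["encounter_id", "ts", "variable", "value"])
    if "unit" not in obs_raw.columns:
        obs_raw["unit"] = ""
    if len(obs_raw):
        known = obs_raw["encounter_id"].isin(encounters.ids)
        if not known.all():
            diagnostics.append(
                f"observations.csv: {int((~known).sum())} row(s) with unknown encounter_id"
            )
        obs_raw = obs_raw[known].reset_index(drop=True)
        obs_raw["t_h"] = _hours_since_admit(obs_raw["ts"], encounters, obs_raw["encounter_id"])
        obs_raw["value"] = pd.to_numeric(obs_raw["value"], errors="coerce")
    else:
        obs_raw["t_h"] = pd.Series(dtype=float)
    observations = ObservationStore(obs_raw)
    dropped = observations.resolve_duplicates()
    if dropped:
        diagnostics.append(f"observations.csv: {dropped} duplicate row(s) resolved last-wins")

    if drug_map is None:
        local = data_dir / "drug_categories.csv"
        drug_map = local if local.exists() else default_drug_map_path()
    mapping = read_drug_map(drug_map)

    med_path = data_dir / "medications.csv"
    if med_path.exists():
        med_raw = _read_csv(med_path, ["encounter_id", "ts", "drug_name"])
    else:
        med_raw = pd.DataFrame(columns=["encounter_id", "ts", "drug_name"])
    rows = []
    if len(med_raw):
        known = med_raw["encounter_id"].isin(encounters.ids)
        if not known.all():
            diagnostics.append(
                f"medications.csv: {int((~known).sum())} row(s) with unknown encounter_id"
            )
        med_raw = med_raw[known].reset_index(drop=True)
        med_raw["t_h"] = _hours_since_admit(med_raw["ts"], encounters, med_raw["encounter_id"])
        unmapped: set[str] = set()
        for enc, t_h, drug in zip(med_raw["encounter_id"], med_raw["t_h"], med_raw["drug_name"]):
            cats = mapping.get(str(drug))
            if not cats:
                unmapped.add(str(drug))
                cats = [UNCATEGORIZED]
            for cat in cats:
                rows.append((enc, t_h, str(drug), cat))
        if unmapped:
            diagnostics.append(
                "medications.csv: unmapped drug name(s) kept as uncategorized: "
                + ", ".join(sorted(unmapped))
            )
    medications = MedicationStore(
        pd.DataFrame(rows, columns=MedicationStore.COLUMNS)
    )

    rrt_path = data_dir / "rrt.csv"
    if rrt_path.exists():
        rrt_raw = _read_csv(rrt_path, ["encounter_id", "start_ts", "end_ts"])
        if len(rrt_raw):
            known = rrt_raw["encounter_id"].isin(encounters.ids)
            if not known.all():
                diagnostics.append(
                    f"rrt.csv: {int((~known).sum())} row(s) with unknown encounter_id"
                )
            rrt_raw = rrt_raw[known].reset_index(drop=True)
            rrt_raw["start_h"] = _hours_since_admit(
                rrt_raw["start_ts"], encounters, rrt_raw["encounter_id"]
            )
            rrt_raw["end_h"] = _hours_since_admit(
                rrt_raw["end_ts"], encounters, rrt_raw["encounter_id"]
            )
        else:
            rrt_raw["start_h"] = pd.Series(dtype=float)
            rrt_raw["end_h"] = pd.Series(dtype=float)
    else:
        rrt_raw = pd.DataFrame(columns=RRTStore.COLUMNS)
    rrt = RRTStore(rrt_raw)

    return encounters, observations, medications, rrt, diagnostics


def write_dataset(
    out_dir: str | Path,
    encounters: EncounterSet,
    observations: ObservationStore,
    medications: MedicationStore,
    rrt: RRTStore,
) -> None:
    """Write the stores back to the five-table CSV layout (ISO-8601 UTC)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    enc = encounters.df.reset_index()[EncounterSet.REQUIRED].copy()
    for col in ("admit_ts", "discharge_ts"):
        enc[col] = enc[col].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    enc.to_csv(out_dir / "encounters.csv", index=False)

    admit = encounters.df["admit_ts"]

    def _abs_ts(enc_ids: pd.Series, hours: pd.Series) -> pd.Series:
        base = admit.reindex(enc_ids.to_numpy()).reset_index(drop=True)
        ts = base + pd.to_timedelta(hours.to_numpy(), unit="h")
        return ts.dt.round("s").dt.strftime("%Y-%m-%dT%H:%M:%SZ")

    obs = observations.df.copy()
    if len(obs):
        obs["ts"] = _abs_ts(obs["encounter_id"], obs["t_h"])
    else:
        obs["ts"] = pd.Series(dtype=str)
    obs[["encounter_id", "ts", "variable", "value", "unit"]].to_csv(
        out_dir / "observations.csv", index=False
    )

    med = medications.df.copy()
    # one CSV row per administration: collapse category-expanded rows
    if len(med):
        med = med.drop_duplicates(subset=["encounter_id", "t_h", "drug_name"])
        med["ts"] = _abs_ts(med["encounter_id"], med["t_h"])
    else:
        med["ts"] = pd.Series(dtype=str)
    med[["encounter_id", "ts", "drug_name"]].to_csv(out_dir / "medications.csv", index=False)

    r = rrt.df.copy()
    if len(r):
        r["start_ts"] = _abs_ts(r["encounter_id"], r["start_h"])
        r["end_ts"] = _abs_ts(r["encounter_id"], r["end_h"])
    else:
        r["start_ts"] = pd.Series(dtype=str)
        r["end_ts"] = pd.Series(dtype=str)
    r[["encounter_id", "start_ts", "end_ts"]].to_csv(out_dir / "rrt.csv", index=False)


def validate_dataset(
    encounters: EncounterSet,
    observations: ObservationStore,
    medications: MedicationStore,
    rrt: RRTStore,
) -> ValidationReport:
    """Report-only quality checks on loaded stores.

    Flags orphan rows, non-finite values, timestamps outside
    [admit - 7 d, discharge], duplicate (encounter_id, ts, variable) rows and
    unexpected unit strings.
    """
    rep = ValidationReport()

    for name, df in (("observations", observations.df),
                     ("medications", medications.df),
                     ("rrt", rrt.df)):
        if len(df):
            orphans = int((~df["encounter_id"].isin(encounters.ids)).sum())
            if orphans:
                rep.orphan_rows += orphans
                rep.messages.append(f"{name}: {orphans} orphan row(s)")

    obs = observations.df
    if len(obs):
        nonfinite = int((~np.isfinite(obs["value"].to_numpy(dtype=float))).sum())
        if nonfinite:
            rep.nonfinite_values += nonfinite
            rep.messages.append(f"observations: {nonfinite} non-finite value(s)")

        stay = encounters.df["stay_h"].reindex(obs["encounter_id"].to_numpy()).to_numpy()
        t = obs["t_h"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            oow = (t < -PREADMISSION_TOLERANCE_H) | (t > stay)
        oow = int(np.nansum(oow))
        if oow:
            rep.out_of_window += oow
            rep.messages.append(f"observations: {oow} timestamp(s) outside window")

        dup = int(obs.duplicated(subset=["encounter_id", "t_h", "variable"]).sum())
        if dup:
            rep.duplicates += dup
            rep.messages.append(f"observations: {dup} duplicate row(s) (last-read wins)")
            observations.resolve_duplicates()

        vocab = obs["variable"].isin(list(EXPECTED_UNITS))
        expected = obs["variable"].map(EXPECTED_UNITS)
        has_unit = obs["unit"].astype(str).str.len() > 0
        bad_units = int((vocab & has_unit & (obs["unit"] != expected)).sum())
        if bad_units:
            rep.unexpected_units += bad_units
            rep.messages.append(f"observations: {bad_units} unexpected unit string(s)")

    return rep
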