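"""Renal angina index (RAI) comparator.

The RAI is the product of a patient-risk stratum and a kidney-injury stratum,
with "renal angina" declared at RAI >= 8. Here the risk stratum is 5 when
the patient is both mechanically ventilated and on vasoactive support
(any vasoactive administration in the past 24 h), else 1 (ICU admission);
the transplant stratum (3) is disabled because transplant status is not in
the data model. The injury stratum maps the serum-creatinine fold-change
``f = latest SCr / baseline`` through the estimated-creatinine-clearance
decline bands translated to fold-change (clearance proportional to 1/SCr):

    f <= 1 -> 1,  1 < f < 4/3 -> 2,  4/3 <= f < 2 -> 4,  f >= 2 -> 8.

The fluid-overload injury arm is omitted (no fluid balance in the data
model); band edges are overridable. RAI is evaluated at every prediction
grid time through the same episode machinery as the model, with angina
(RAI >= 8) playing the role of the alert.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort_labeling import AKILabel, BaselineTable
from .ehr_data import EncounterSet, MedicationStore, ObservationStore
from .featurization import build_prediction_grid

RAI_ANGINA_THRESHOLD = 8
DEFAULT_INJURY_BANDS = (1.0, 4.0 / 3.0, 2.0)  # upper-open edges for strata 1/2/4
VENT_LOOKBACK_H = 24.0
VASO_LOOKBACK_H = 24.0


def injury_stratum(fold_change: float, bands: tuple[float, ...] = DEFAULT_INJURY_BANDS) -> int:
    if fold_change <= bands[0]:
        return 1
    if fold_change < bands[1]:
        return 2
    if fold_change < bands[2]:
        return 4
    return 8


def compute_rai(
    fold_change: float,
    ventilated: bool,
    on_vasoactives: bool,
    bands: tuple[float, ...] = DEFAULT_INJURY_BANDS,
) -> tuple[int, int, int, bool]:
    """(risk_stratum, injury_stratum, rai, angina) for one grid time."""
    risk = 5 if (ventilated and on_vasoactives) else 1
    inj = injury_stratum(fold_change, bands)
    rai = risk * inj
    return risk, inj, rai, rai >= RAI_ANGINA_THRESHOLD


def compute_rai_series(
    encounters: EncounterSet,
    observations: ObservationStore,
    medications: MedicationStore,
    labels: dict[str, AKILabel],
    kept_ids: list[str] | None = None,
    baselines: BaselineTable | None = None,
    bands: tuple[float, ...] = DEFAULT_INJURY_BANDS,
) -> pd.DataFrame:
    """RAI at every prediction grid time, mirroring the model's grid.

    Grid times with no creatinine measured yet yield a MISSING row (NaN RAI).
    Ventilation at t means any mean-airway-pressure charting in (t - 24 h, t].
    """
    baselines = baselines or BaselineTable.default()
    ids = list(kept_ids) if kept_ids is not None else list(labels)
    rows = []
    for enc_id in ids:
        row = encounters.row(enc_id)
        lab = labels[enc_id]
        onset = lab.onset_h if lab.max_stage >= 1 else None
        grid = build_prediction_grid(float(row["stay_h"]), onset)
        if len(grid) == 0:
            continue
        base = baselines.lookup(float(row["age_months"]), row["sex"])
        t_cr, v_cr = observations.series(enc_id, "creatinine")
        t_map, _ = observations.series(enc_id, "mean_airway_pressure")
        t_vaso = medications.events(enc_id, "vasoactive")
        for g in grid:
            i = np.searchsorted(t_cr, g, side="right")
            rec = {
                "encounter_id": enc_id,
                "grid_h": float(g),
                "lead_time_h": float(lab.onset_h - g),
            }
            if i == 0:
                rec.update(risk_stratum=np.nan, injury_stratum=np.nan,
                           rai=np.nan, angina=False)
            else:
                f = float(v_cr[i - 1]) / base
                vent = bool(np.any((t_map > g - VENT_LOOKBACK_H) & (t_map <= g)))
                vaso = bool(np.any((t_vaso > g - VASO_LOOKBACK_H) & (t_vaso <= g)))
                risk, inj, rai, angina = compute_rai(f, vent, vaso, bands)
                rec.update(risk_stratum=risk, injury_stratum=inj, rai=rai,
                           angina=angina)
            rows.append(rec)
    return pd.DataFrame(rows)
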