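"""Binary clinical outcomes and the hemodynamic-instability flag.

Three outcomes are derived per included patient: ICU mortality, prolonged
stay (LOS > 48 h) and need for mechanical ventilation assessed over the
first 48 h of admission.  Derivation is a pure function of the patient
record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import pandas as pd

from .records import PatientRecord

#: ICD-10 flags accepted as evidence of arrhythmia (waveforms are absent
#: from tabular extracts, so the abnormal-rhythm criterion is code-based)
DEFAULT_ARRHYTHMIA_CODES = frozenset({"I48.91", "I49.9", "I47.1", "I49.01"})

MvAssessment = Literal["within48h", "at48h"]


@dataclass(frozen=True)
class OutcomeSet:
    patient_id: str
    mortality: bool
    los_hours: float
    los_gt_48: bool
    mv: bool
    hemodynamic_instability: bool | None = None


class OutcomeError(ValueError):
    """Outcome undefined for this record (e.g. missing discharge time)."""


def hemodynamic_instability(
    vitals: Mapping[str, float],
    arrhythmia: bool = False,
) -> bool:
    """Hypotension, low MAP or abnormal heart rate (any criterion suffices).

    Criteria: systolic blood pressure < 100 mmHg; mean arterial pressure
    < 65 mmHg; heart rate < 60 or > 100 bpm, or a documented arrhythmia.
    Missing vitals are skipped; with all three absent (and no arrhythmia
    flag) the flag is undefined and an error is raised.
    """
    checks = []
    sbp = vitals.get("sbp")
    if sbp is not None and not pd.isna(sbp):
        checks.append(sbp < 100.0)
    map_ = vitals.get("map")
    if map_ is not None and not pd.isna(map_):
        checks.append(map_ < 65.0)
    hr = vitals.get("hr")
    if hr is not None and not pd.isna(hr):
        checks.append(hr < 60.0 or hr > 100.0)
    if arrhythmia:
        checks.append(True)
    if not checks:
        raise OutcomeError("hemodynamic instability undefined: sbp, map, hr all missing")
    return any(checks)


def derive_outcomes(
    patient: PatientRecord,
    mv_assessment: MvAssessment = "within48h",
    arrhythmia_codes: frozenset[str] = DEFAULT_ARRHYTHMIA_CODES,
) -> OutcomeSet:
    """Map one patient record to its binary outcomes.

    LOS is discharge minus admission in hours, dichotomized at 48 h; the
    printed rule leaves exactly 48.0 h unassigned, so the boundary is closed
    upward (``los_hours >= 48`` counts as prolonged) to keep the map total.
    MV is positive under ``within48h`` when the patient spent any time
    ventilated (ventilation in this cohort begins within the first two days),
    or under ``at48h`` when still ventilated at hour 48 (``mv_hours >= 48``).
    """
    los = patient.los_hours
    if pd.isna(los):
        raise OutcomeError(f"patient {patient.patient_id}: missing discharge timestamp")
    if mv_assessment == "within48h":
        mv = patient.mv_hours > 0.0
    elif mv_assessment == "at48h":
        mv = patient.mv_hours >= 48.0
    else:
        raise ValueError(f"unknown mv_assessment {mv_assessment!r}")
    try:
        unstable = hemodynamic_instability(
            patient.vitals,
            arrhythmia=bool(patient.diagnoses & arrhythmia_codes),
        )
    except OutcomeError:
        unstable = None
    return OutcomeSet(
        patient_id=patient.patient_id,
        mortality=patient.died_in_icu,
        los_hours=float(los),
        los_gt_48=los >= 48.0,
        mv=mv,
        hemodynamic_instability=unstable,
    )


def derive_cohort_outcomes(
    patients: Sequence[PatientRecord],
    mv_assessment: MvAssessment = "within48h",
) -> dict[str, OutcomeSet]:
    return {p.patient_id: derive_outcomes(p, mv_assessment) for p in patients}
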