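"""Cohort and medication-record domain types, tabular IO and cohort filter.

Timestamps are ISO-8601 strings on disk and hours-since-epoch floats in
memory; all window arithmetic downstream is done in hours, matching how ICU
length of stay and ventilation duration are reported clinically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .weights import UnknownItemKeyError, WeightTable

#: the fifteen configured medication class labels
DRUG_CLASSES = (
    "anti_infectives",
    "anticoagulants",
    "vasopressors",
    "paralytics",
    "analgesics_sedatives",
    "psychiatric",
    "pulmonary",
    "cardiovascular",
    "diuretics",
    "vitamins",
    "iv_fluids",
    "gi_agents",
    "electrolytes",
    "endocrine",
    "others",
)

#: serum values that must be present at admission for a patient to enter the
#: analysis (the missing-laboratory exclusion); configurable per site.
DEFAULT_REQUIRED_LABS = ("bun", "scr", "sodium", "potassium")

VITAL_NAMES = ("sbp", "dbp", "map", "hr", "rr", "temp", "sao2")

#: hours in the maximum permitted stay (40 days)
MAX_LOS_HOURS = 40.0 * 24.0


class SchemaError(ValueError):
    """Input table does not match the declared schema."""


class IntegrityError(ValueError):
    """Input table violates a uniqueness or consistency rule."""


def iso_to_hours(value: str) -> float:
    """Parse an ISO-8601 timestamp to hours since the Unix epoch."""
    ts = pd.Timestamp(value)
    if pd.isna(ts):
        raise SchemaError(f"unparseable timestamp {value!r}")
    return ts.value / 3.6e12  # ns -> h


def hours_to_iso(hours: float) -> str:
    return pd.Timestamp(round(hours * 3.6e12)).isoformat()


@dataclass(frozen=True)
class MedicationOrder:
    """One timestamped medication order within an ICU stay.

    ``dosage_form``, ``frequency_code`` and ``additional_directions`` are item
    keys into the MRCI section A/B/C weight tables; ``mrc_icu_item`` (optional)
    keys into the critical-care item table.  ``stop_time`` of ``None`` marks an
    open order, active until the evaluation window closes.
    """

    patient_id: str
    drug_name: str
    drug_class: str
    dosage_form: str
    frequency_code: str
    start_time: float
    stop_time: float | None = None
    prn: bool = False
    continuous_infusion: bool = False
    additional_directions: tuple[str, ...] = ()
    mrc_icu_item: str | None = None

    def __post_init__(self):
        if self.drug_class not in DRUG_CLASSES:
            raise IntegrityError(
                f"unknown drug class {self.drug_class!r} for {self.drug_name!r}; "
                f"configured classes: {DRUG_CLASSES}"
            )
        if self.stop_time is not None and self.start_time > self.stop_time:
            raise IntegrityError(
                f"order {self.drug_name!r} for patient {self.patient_id}: "
                f"start_time {self.start_time} > stop_time {self.stop_time}"
            )

    def validate_keys(self, tables: Mapping[str, WeightTable]) -> None:
        """Check every item key resolves; raise rather than score silently as 0."""
        tables["MRCI_A"].weight(self.dosage_form)
        tables["MRCI_B"].weight(self.frequency_code)
        for key in self.additional_directions:
            tables["MRCI_C"].weight(key)
        if self.mrc_icu_item is not None:
            tables["MRC_ICU"].weight(self.mrc_icu_item)


@dataclass(frozen=True)
class PatientRecord:
    """Demographics, admission timestamps, severity scores and outcome primitives."""

    patient_id: str
    age: float
    sex: str
    race_ethnicity: str
    height: float  # cm
    weight: float  # kg
    bmi: float  # kg/m^2
    icu_admission: float  # hours since epoch
    icu_discharge: float
    died_in_icu: bool
    mv_hours: float
    apache2: int
    saps2: int
    cci: int
    gcs: int
    vitals: Mapping[str, float] = field(default_factory=dict)
    labs: Mapping[str, float] = field(default_factory=dict)
    diagnoses: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.age < 0:
            raise IntegrityError(f"patient {self.patient_id}: negative age {self.age}")
        if self.mv_hours < 0:
            raise IntegrityError(
                f"patient {self.patient_id}: negative mv_hours {self.mv_hours}"
            )
        if not self.icu_admission < self.icu_discharge:
            raise IntegrityError(
                f"patient {self.patient_id}: ICU admission must precede discharge"
            )

    @property
    def los_hours(self) -> float:
        return self.icu_discharge - self.icu_admission


@dataclass(frozen=True)
class ValidationReport:
    """Audit trail of the inclusion/exclusion filter."""

    n_input: int
    n_included: int
    exclusions: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self):
        if self.n_included + len(self.exclusions) != self.n_input:
            raise IntegrityError("included + excluded must partition the input")
        for pid, reasons in self.exclusions:
            if not reasons:
                raise IntegrityError(f"excluded patient {pid} carries no reason")


def exclusion_reasons(
    patient: PatientRecord,
    required_labs: Sequence[str] = DEFAULT_REQUIRED_LABS,
    max_los_hours: float = MAX_LOS_HOURS,
) -> tuple[str, ...]:
    """All inclusion rules violated by one patient (empty tuple = included).

    Rules: adult (age >= 18); ICU stay strictly longer than 24 h; stay not
    beyond 40 days; all required admission labs present.
    """
    reasons = []
    if patient.age < 18:
        reasons.append("age<18")
    if not patient.los_hours > 24.0:
        reasons.append("icu_stay<=24h")
    if patient.los_hours > max_los_hours:
        reasons.append("los>40d")
    if any(lab not in patient.labs or pd.isna(patient.labs[lab])
           for lab in required_labs):
        reasons.append("missing_labs")
    return tuple(reasons)


def apply_inclusion_filter(
    patients: Sequence[PatientRecord],
    required_labs: Sequence[str] = DEFAULT_REQUIRED_LABS,
    max_los_hours: float = MAX_LOS_HOURS,
) -> tuple[list[PatientRecord], ValidationReport]:
    included: list[PatientRecord] = []
    excluded: list[tuple[str, tuple[str, ...]]] = []
    for patient in patients:
        reasons = exclusion_reasons(patient, required_labs, max_los_hours)
        if reasons:
            excluded.append((patient.patient_id, reasons))
        else:
            included.append(patient)
    report = ValidationReport(
        n_input=len(patients),
        n_included=len(included),
        exclusions=tuple(excluded),
    )
    return included, report


# ---------------------------------------------------------------------------
# tabular IO


def load_schema_config(path: str | Path | None) -> dict[str, str]:
    """Column-name mapping (canonical -> file column) from YAML/JSON config."""
    if path is None:
        return {}
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    columns = config.get("columns", config)
    if not isinstance(columns, dict):
        raise SchemaError("schema config must map canonical to file column names")
    return {str(k): str(v) for k, v in columns.items()}


def _rename_from_schema(df: pd.DataFrame, schema: Mapping[str, str]) -> pd.DataFrame:
    return df.rename(columns={v: k for k, v in schema.items()})


_PATIENT_REQUIRED = (
    "patient_id", "age", "sex", "race_ethnicity", "height", "weight", "bmi",
    "icu_admission", "icu_discharge", "died_in_icu", "mv_hours",
    "apache2", "saps2", "cci", "gcs",
)


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"1", "true", "yes", "t"}:
        return True
    if text in {"0", "false", "no", "f"}:
        return False
    raise SchemaError(f"unparseable boolean {value!r}")


def read_patient_table(
    path: str | Path,
    schema_config: str | Path | Mapping[str, str] | None = None,
) -> list[PatientRecord]:
    """Read a patient-level CSV/TSV extract into records.

    Vitals are columns prefixed ``vital_``, labs ``lab_`` (empty cell = not
    measured), diagnoses a semicolon-joined ICD-10 flag column.  Unparseable
    timestamps and negative ages raise; they are never coerced.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    schema = (schema_config if isinstance(schema_config, Mapping)
              else load_schema_config(schema_config))
    df = _rename_from_schema(df, schema)
    for col in _PATIENT_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if df["patient_id"].duplicated().any():
        dupes = sorted(df.loc[df["patient_id"].duplicated(), "patient_id"])
        raise IntegrityError(f"{path}: duplicate patient_id values {dupes}")

    records = []
    for row in df.to_dict("records"):
        vitals = {c[len("vital_"):]: float(row[c]) for c in df.columns
                  if c.startswith("vital_") and row[c] != ""}
        labs = {c[len("lab_"):]: float(row[c]) for c in df.columns
                if c.startswith("lab_") and row[c] != ""}
        diagnoses = frozenset(
            code.strip() for code in str(row.get("diagnoses", "")).split(";")
            if code.strip()
        )
        records.append(PatientRecord(
            patient_id=str(row["patient_id"]),
            age=float(row["age"]),
            sex=str(row["sex"]),
            race_ethnicity=str(row["race_ethnicity"]),
            height=float(row["height"]),
            weight=float(row["weight"]),
            bmi=float(row["bmi"]),
            icu_admission=iso_to_hours(row["icu_admission"]),
            icu_discharge=iso_to_hours(row["icu_discharge"]),
            died_in_icu=_parse_bool(row["died_in_icu"]),
            mv_hours=float(row["mv_hours"]),
            apache2=int(float(row["apache2"])),
            saps2=int(float(row["saps2"])),
            cci=int(float(row["cci"])),
            gcs=int(float(row["gcs"])),
            vitals=vitals,
            labs=labs,
            diagnoses=diagnoses,
        ))
    return records


def write_patient_table(patients: Sequence[PatientRecord], path: str | Path) -> None:
    vital_cols = sorted({name for p in patients for name in p.vitals})
    lab_cols = sorted({name for p in patients for name in p.labs})
    rows = []
    for p in patients:
        row = {
            "patient_id": p.patient_id,
            "age": p.age,
            "sex": p.sex,
            "race_ethnicity": p.race_ethnicity,
            "height": p.height,
            "weight": p.weight,
            "bmi": p.bmi,
            "icu_admission": hours_to_iso(p.icu_admission),
            "icu_discharge": hours_to_iso(p.icu_discharge),
            "died_in_icu": p.died_in_icu,
            "mv_hours": p.mv_hours,
            "apache2": p.apache2,
            "saps2": p.saps2,
            "cci": p.cci,
            "gcs": p.gcs,
            "diagnoses": ";".join(sorted(p.diagnoses)),
        }
        for name in vital_cols:
            row[f"vital_{name}"] = p.vitals.get(name, "")
        for name in lab_cols:
            row[f"lab_{name}"] = p.labs.get(name, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


_MED_REQUIRED = (
    "patient_id", "drug_name", "drug_class", "dosage_form", "frequency_code",
    "prn", "continuous_infusion", "start_time",
)


def read_medication_table(
    path: str | Path,
    weight_tables: Mapping[str, WeightTable],
    schema_config: str | Path | Mapping[str, str] | None = None,
    allow_unknown_class_as_others: bool = False,
) -> list[MedicationOrder]:
    """Read a medication-administration CSV/TSV; every item key must resolve.

    Unknown weight-table keys raise :class:`UnknownItemKeyError` listing the
    nearest known keys — an unknown key is a data defect, never a zero score.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    schema = (schema_config if isinstance(schema_config, Mapping)
              else load_schema_config(schema_config))
    df = _rename_from_schema(df, schema)
    for col in _MED_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")

    orders = []
    for row in df.to_dict("records"):
        drug_class = str(row["drug_class"])
        if drug_class not in DRUG_CLASSES:
            if allow_unknown_class_as_others:
                drug_class = "others"
            else:
                raise IntegrityError(
                    f"{path}: unknown drug class {row['drug_class']!r} "
                    f"(pass allow_unknown_class_as_others=True to map to 'others')"
                )
        directions = tuple(
            key.strip() for key in str(row.get("additional_directions", "")).split(";")
            if key.strip()
        )
        item = str(row.get("mrc_icu_item", "")).strip() or None
        stop_raw = str(row.get("stop_time", "")).strip()
        order = MedicationOrder(
            patient_id=str(row["patient_id"]),
            drug_name=str(row["drug_name"]),
            drug_class=drug_class,
            dosage_form=str(row["dosage_form"]),
            frequency_code=str(row["frequency_code"]),
            prn=_parse_bool(row["prn"]),
            continuous_infusion=_parse_bool(row["continuous_infusion"]),
            additional_directions=directions,
            mrc_icu_item=item,
            start_time=iso_to_hours(row["start_time"]),
            stop_time=iso_to_hours(stop_raw) if stop_raw else None,
        )
        order.validate_keys(weight_tables)
        orders.append(order)
    return orders


def write_medication_table(orders: Sequence[MedicationOrder], path: str | Path) -> None:
    rows = []
    for o in orders:
        rows.append({
            "patient_id": o.patient_id,
            "drug_name": o.drug_name,
            "drug_class": o.drug_class,
            "dosage_form": o.dosage_form,
            "frequency_code": o.frequency_code,
            "prn": o.prn,
            "continuous_infusion": o.continuous_infusion,
            "additional_directions": ";".join(o.additional_directions),
            "mrc_icu_item": o.mrc_icu_item or "",
            "start_time": hours_to_iso(o.start_time),
            "stop_time": hours_to_iso(o.stop_time) if o.stop_time is not None else "",
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def orders_by_patient(
    orders: Iterable[MedicationOrder],
) -> dict[str, list[MedicationOrder]]:
    grouped: dict[str, list[MedicationOrder]] = {}
    for order in orders:
        grouped.setdefault(order.patient_id, []).append(order)
    return grouped
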