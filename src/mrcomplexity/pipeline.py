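"""End-to-end assembly: filter, score, derive outcomes, merge, model.

The merged per-patient analysis table is the single input to the
descriptive, association and prediction stages.  Columns: demographics
(with race expanded against the composite non-White/non-Hispanic
reference), severity scores, vitals/labs, diagnosis flags, the four
regimen-complexity scores, medication-class exposure indicators (any
order of the class active in the first 48 h) and the three binary
outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .association import (AssociationFit, build_design_matrix, model_candidates,
                          stepwise_forward_logistic)
from .descriptive import GroupComparison, build_table1, table1_frame
from .outcomes import OutcomeSet, derive_cohort_outcomes
from .prediction import (CLASSIFIER_SETS, PredictionResult, classifier_spec,
                         compare_classifiers, evaluate_classifier)
from .records import (DRUG_CLASSES, MedicationOrder, PatientRecord,
                      ValidationReport, apply_inclusion_filter, orders_by_patient)
from .scoring import ScorePanel, active_orders, score_cohort
from .simulate import GeneratorConfig, generate_cohort
from .weights import WeightTable, default_weight_tables

#: diagnosis-flag columns and the ICD-10 code each matches exactly
DX_FLAGS: dict[str, str] = {
    "dx_resp_failure": "J96.01",
    "dx_lactic_acidosis": "E87.2",
    "dx_hypokalemia": "E87.6",
    "dx_kidney_failure": "N17.9",
    "dx_hyponatremia": "E87.1",
    "dx_not_resuscitated": "Z66",
    "dx_ami": "I21.A",
    "dx_sepsis": "A41.9",
    "dx_covid": "U07.1",
}

_RACE_LEVELS = ("White", "Black", "Hispanic", "Asian")


def build_analysis_table(
    patients: Sequence[PatientRecord],
    panels: Mapping[str, ScorePanel],
    outcome_sets: Mapping[str, OutcomeSet],
    orders_by_pid: Mapping[str, Sequence[MedicationOrder]],
    class_window_hours: float = 48.0,
) -> pd.DataFrame:
    rows = []
    for p in patients:
        panel = panels[p.patient_id]
        outcome = outcome_sets[p.patient_id]
        active = active_orders(orders_by_pid.get(p.patient_id, ()),
                               p.icu_admission, class_window_hours)
        classes_present = {o.drug_class for o in active}
        row: dict[str, object] = {
            "patient_id": p.patient_id,
            "age": p.age,
            "sex_male": float(p.sex == "male"),
            "height": p.height,
            "weight": p.weight,
            "bmi": p.bmi,
            "apache2": p.apache2,
            "saps2": p.saps2,
            "cci": p.cci,
            "gcs": p.gcs,
            "mrci_24h": panel.mrci_24h,
            "mrci_48h": panel.mrci_48h,
            "mrc_icu_24h": panel.mrc_icu_24h,
            "mrc_icu_48h": panel.mrc_icu_48h,
            "mortality": float(outcome.mortality),
            "los_gt_48": float(outcome.los_gt_48),
            "mv": float(outcome.mv),
            "los_hours": outcome.los_hours,
            "mv_duration_hours": p.mv_hours,
            "hemodynamic_instability": (
                np.nan if outcome.hemodynamic_instability is None
                else float(outcome.hemodynamic_instability)),
        }
        for level in _RACE_LEVELS:
            row[f"race_{level.lower()}"] = float(p.race_ethnicity == level)
        for name in ("sbp", "dbp", "map", "hr", "rr", "temp", "sao2"):
            row[f"vital_{name}"] = p.vitals.get(name, np.nan)
        for name, value in p.labs.items():
            row[f"lab_{name}"] = value
        for column, code in DX_FLAGS.items():
            row[column] = float(code in p.diagnoses)
        for cls in DRUG_CLASSES:
            row[f"class_{cls}"] = float(cls in classes_present)
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id", drop=False)


@dataclass
class PipelineResult:
    analysis_table: pd.DataFrame
    validation: ValidationReport
    panels: Mapping[str, ScorePanel]
    table1: pd.DataFrame | None = None
    association_fits: dict[tuple[str, str], AssociationFit] = field(default_factory=dict)
    prediction_table: pd.DataFrame | None = None
    prediction_results: list[PredictionResult] = field(default_factory=list)
    truth: dict | None = None


def run_pipeline(
    config: GeneratorConfig | None = None,
    seed: int = 0,
    weight_tables: Mapping[str, WeightTable] | None = None,
    with_table1: bool = True,
    association_models: Sequence[str] = (),
    association_outcomes: Sequence[str] = ("mortality", "los_gt_48", "mv"),
    prediction_models: Sequence[str] = (),
    prediction_outcomes: Sequence[str] = ("mortality", "los_gt_48", "mv"),
    bootstrap_reps: int = 2000,
) -> PipelineResult:
    """Full run on a freshly generated synthetic cohort.

    Deterministic for a fixed (config, seed, bootstrap_reps): scores, fits
    and bootstrap CIs are bit-reproducible.  Association and prediction
    stages run only for the model names requested (e.g.
    ``association_models=("III",)``, ``prediction_models=("full",)``).
    """
    tables = weight_tables or default_weight_tables()
    patients, orders, truth = generate_cohort(config, seed, tables)
    included, report = apply_inclusion_filter(patients)
    grouped = orders_by_patient(orders)
    panels = score_cohort(included, grouped, tables)
    outcome_sets = derive_cohort_outcomes(included)
    analysis = build_analysis_table(included, panels, outcome_sets, grouped)

    result = PipelineResult(
        analysis_table=analysis, validation=report, panels=panels, truth=truth,
    )
    if with_table1:
        result.table1 = table1_frame(build_table1(analysis, group_col="mortality"))

    for model_id in association_models:
        for outcome in association_outcomes:
            spec = model_candidates(model_id, outcome)
            X, y, _ = build_design_matrix(spec, analysis)
            result.association_fits[(model_id, outcome)] = stepwise_forward_logistic(
                X, y, model_id=model_id, outcome=outcome,
            )

    predictions: list[PredictionResult] = []
    for name in prediction_models:
        for outcome in prediction_outcomes:
            spec = classifier_spec(name, outcome)
            predictions.append(evaluate_classifier(
                spec, analysis, repetitions=bootstrap_reps, seed=seed,
            ))
    if predictions:
        result.prediction_results = predictions
        result.prediction_table = compare_classifiers(predictions)
    return result
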