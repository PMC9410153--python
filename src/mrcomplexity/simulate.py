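"""Synthetic ICU cohort generator with plantable effect sizes.

The study conditions emulated by the defaults: a 317-patient adult ICU
cohort with ~23% ICU mortality, ~51% prolonged stay (> 48 h) and ~31%
mechanical ventilation; right-skewed regimen-complexity score
distributions with 24 h medians near the published cutoffs (63 for MRCI,
6 for MRC-ICU); medication-class mix led by IV fluids, GI agents,
analgesics, electrolytes and anti-infectives; and logistic outcome
dependence on the 24 h MRC-ICU score with odds ratios of 1.12 (mortality),
1.17 (prolonged stay) and 1.21 (ventilation) per score point.

Scores are not drawn directly: each patient receives timestamped
medication orders from a built-in drug catalog and the scoring engine
computes the panels, so the scoring and modelling stages are exercised
jointly.  A fast ``direct_scores`` mode draws score-like covariates from a
lognormal for statistics-only simulations (type-I error, parameter
recovery), where the regimen machinery would only add runtime.

Outcomes are drawn from a logistic model in the engine-computed scores
whose intercept is calibrated numerically to the target marginal rate.
Outcome-to-outcome correlation arises through the shared score (itself
driven by a latent severity factor), not through hidden direct effects, so
the planted odds ratios are the true conditional effects a correctly
specified model should recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .records import DRUG_CLASSES, MedicationOrder, PatientRecord
from .scoring import active_orders, mrc_icu_score, mrci_score
from .weights import WeightTable, default_weight_tables


class CalibrationError(ValueError):
    """Requested marginal rate unreachable for the planted effect sizes."""


# ---------------------------------------------------------------------------
# drug catalog


@dataclass(frozen=True)
class CatalogDrug:
    name: str
    drug_class: str
    forms: tuple[str, ...]
    frequencies: tuple[str, ...]
    mrc_icu_item: str | None = None
    continuous: bool = False


#: representative agents per class; forms/frequencies are MRCI item keys and
#: the optional item key maps into the critical-care weight table.
DRUG_CATALOG: tuple[CatalogDrug, ...] = (
    CatalogDrug("vancomycin", "anti_infectives", ("iv_infusion",), ("q12h",), "vancomycin"),
    CatalogDrug("piperacillin_tazobactam", "anti_infectives", ("iv_infusion",), ("q8h",)),
    CatalogDrug("ceftriaxone", "anti_infectives", ("iv_infusion",), ("once_daily",)),
    CatalogDrug("gentamicin", "anti_infectives", ("iv_infusion",), ("once_daily",), "aminoglycoside"),
    CatalogDrug("heparin", "anticoagulants", ("iv_infusion",), ("continuous",), "heparin_infusion", True),
    CatalogDrug("enoxaparin", "anticoagulants", ("injection",), ("q12h",)),
    CatalogDrug("warfarin", "anticoagulants", ("tablet",), ("once_daily",), "warfarin"),
    CatalogDrug("norepinephrine", "vasopressors", ("iv_infusion",), ("continuous",), "norepinephrine_infusion", True),
    CatalogDrug("vasopressin", "vasopressors", ("iv_infusion",), ("continuous",), "vasopressin", True),
    CatalogDrug("phenylephrine", "vasopressors", ("iv_infusion",), ("continuous",), "phenylephrine_infusion", True),
    CatalogDrug("cisatracurium", "paralytics", ("iv_infusion",), ("continuous",), "cisatracurium_infusion", True),
    CatalogDrug("rocuronium", "paralytics", ("injection",), ("q4h_prn",)),
    CatalogDrug("vecuronium", "paralytics", ("injection",), ("q6h_prn",)),
    CatalogDrug("acetaminophen", "analgesics_sedatives", ("tablet", "liquid"), ("q6h_prn", "q6h")),
    CatalogDrug("fentanyl", "analgesics_sedatives", ("iv_infusion",), ("continuous",), "fentanyl_infusion", True),
    CatalogDrug("propofol", "analgesics_sedatives", ("iv_infusion",), ("continuous",), "propofol_infusion", True),
    CatalogDrug("morphine", "analgesics_sedatives", ("injection",), ("q4h_prn",)),
    CatalogDrug("quetiapine", "psychiatric", ("tablet",), ("twice_daily",)),
    CatalogDrug("haloperidol", "psychiatric", ("injection",), ("q6h_prn",)),
    CatalogDrug("sertraline", "psychiatric", ("tablet",), ("once_daily",)),
    CatalogDrug("albuterol", "pulmonary", ("nebulizer", "inhaler"), ("q4h_prn", "q6h")),
    CatalogDrug("ipratropium", "pulmonary", ("nebulizer",), ("q6h",)),
    CatalogDrug("fluticasone", "pulmonary", ("inhaler",), ("twice_daily",)),
    CatalogDrug("metoprolol", "cardiovascular", ("tablet",), ("twice_daily",)),
    CatalogDrug("amiodarone", "cardiovascular", ("iv_infusion",), ("continuous",), "amiodarone_infusion", True),
    CatalogDrug("amlodipine", "cardiovascular", ("tablet",), ("once_daily",)),
    CatalogDrug("digoxin", "cardiovascular", ("tablet",), ("once_daily",), "digoxin"),
    CatalogDrug("furosemide", "diuretics", ("iv_infusion", "tablet"), ("twice_daily",)),
    CatalogDrug("spironolactone", "diuretics", ("tablet",), ("once_daily",)),
    CatalogDrug("bumetanide", "diuretics", ("iv_infusion",), ("once_daily",)),
    CatalogDrug("thiamine", "vitamins", ("tablet", "iv_infusion"), ("once_daily",)),
    CatalogDrug("multivitamin", "vitamins", ("tablet",), ("once_daily",)),
    CatalogDrug("folic_acid", "vitamins", ("tablet",), ("once_daily",)),
    CatalogDrug("normal_saline", "iv_fluids", ("iv_infusion",), ("continuous",), "continuous_iv_saline", True),
    CatalogDrug("lactated_ringers", "iv_fluids", ("iv_infusion",), ("continuous",), None, True),
    CatalogDrug("dextrose_5_with_kcl", "iv_fluids", ("iv_infusion",), ("continuous",), "iv_fluid_with_additives", True),
    CatalogDrug("pantoprazole", "gi_agents", ("tablet", "iv_infusion"), ("once_daily",)),
    CatalogDrug("famotidine", "gi_agents", ("tablet",), ("twice_daily",)),
    CatalogDrug("ondansetron", "gi_agents", ("injection",), ("q6h_prn",)),
    CatalogDrug("docusate", "gi_agents", ("capsule",), ("twice_daily",)),
    CatalogDrug("potassium_chloride", "electrolytes", ("tablet", "liquid"), ("twice_daily",), "electrolyte_protocol"),
    CatalogDrug("magnesium_sulfate", "electrolytes", ("iv_infusion",), ("once_daily",)),
    CatalogDrug("sodium_phosphate", "electrolytes", ("iv_infusion",), ("once_daily",)),
    CatalogDrug("insulin_regular", "endocrine", ("injection",), ("three_times_daily",), "sliding_scale_insulin"),
    CatalogDrug("insulin_glargine", "endocrine", ("injection",), ("once_daily",)),
    CatalogDrug("levothyroxine", "endocrine", ("tablet",), ("once_daily",)),
    CatalogDrug("hydrocortisone", "endocrine", ("injection",), ("q8h",)),
    CatalogDrug("chlorhexidine", "others", ("gargle",), ("twice_daily",)),
    CatalogDrug("nicotine", "others", ("patch",), ("once_daily",)),
    CatalogDrug("senna", "others", ("tablet",), ("twice_daily",)),
    CatalogDrug("artificial_tears", "others", ("eye_drops",), ("q6h_prn",)),
)

_CATALOG_BY_CLASS: dict[str, tuple[CatalogDrug, ...]] = {
    cls: tuple(d for d in DRUG_CATALOG if d.drug_class == cls)
    for cls in DRUG_CLASSES
}

#: relative prescription shares per class, anchored to the observed top-five
#: ordering (IV fluids > GI agents > analgesics > electrolytes >
#: anti-infectives); normalised internally before sampling.
DEFAULT_CLASS_SHARES: dict[str, float] = {
    "iv_fluids": 0.36,
    "gi_agents": 0.29,
    "analgesics_sedatives": 0.26,
    "electrolytes": 0.24,
    "anti_infectives": 0.23,
    "cardiovascular": 0.20,
    "anticoagulants": 0.18,
    "psychiatric": 0.15,
    "diuretics": 0.15,
    "others": 0.15,
    "vasopressors": 0.12,
    "pulmonary": 0.12,
    "vitamins": 0.12,
    "endocrine": 0.12,
    "paralytics": 0.04,
}

#: ICD-10 flag prevalences (cohort-wide), anchored to the cohort table
DEFAULT_DIAGNOSIS_PREVALENCES: dict[str, float] = {
    "J96.01": 0.394,  # acute respiratory failure with hypoxia
    "E87.2": 0.319,   # lactic acidosis
    "E87.6": 0.322,   # hypokalemia
    "N17.9": 0.303,   # kidney failure
    "E87.1": 0.281,   # hypo-osmolality / hyponatremia
    "Z66": 0.271,     # do-not-resuscitate order
    "I21.A": 0.246,   # acute myocardial infarction
    "A41.9": 0.240,   # unspecified sepsis
    "U07.1": 0.164,   # COVID-19
    "I48.91": 0.10,   # atrial fibrillation (arrhythmia flag)
}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    ``planted_log_or`` gives, per outcome, the true conditional log odds
    ratios of the outcome model; intercepts are calibrated at generation
    time so the marginal rates land on ``outcome_rates``.  ``meds_day1``
    and ``mrc_item_rate`` are calibrated once so the engine-computed 24 h
    score medians sit near the 63 / 6 targets, and are not per-run dials.
    """

    n_patients: int = 317
    n_invalid: int = 0  # extra filter-violating patients appended for IO tests
    class_shares: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SHARES))
    mrci_median_target: float = 63.0
    mrc_icu_median_target: float = 6.0
    meds_day1: float = 15.5       # mean day-1 medication draws at z = 0
    meds_day2: float = 3.0        # mean additional day-2 draws at z = 0
    severity_med_coupling: float = 0.35  # log-scale effect of latent severity
    mrc_item_rate: float = 0.8    # chance a catalog item key is charted
    direction_rate: float = 0.35  # chance an order carries an extra direction
    outcome_rates: Mapping[str, float] = field(default_factory=lambda: {
        "mortality": 0.23, "los_gt_48": 0.51, "mv": 0.31})
    planted_log_or: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "mortality": {"mrc_icu_24h": math.log(1.12)},
            "los_gt_48": {"mrc_icu_24h": math.log(1.17)},
            "mv": {"mrc_icu_24h": math.log(1.21)},
        })
    male_p: float = 0.552
    race_probs: Mapping[str, float] = field(default_factory=lambda: {
        "White": 0.650, "Black": 0.082, "Hispanic": 0.117,
        "Asian": 0.013, "other": 0.138})
    exact_outcome_counts: bool = False
    diagnosis_prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIAGNOSIS_PREVALENCES))

    def __post_init__(self):
        for name, p in {**self.outcome_rates, "male": self.male_p}.items():
            if not 0.0 < p < 1.0:
                raise CalibrationError(f"rate {name}={p} must lie in (0, 1)")
        for cls in self.class_shares:
            if cls not in DRUG_CLASSES:
                raise ValueError(f"unknown drug class {cls!r} in class_shares")


#: hours since epoch of the cohort window start (1 February 2020)
_BASE_HOURS = pd.Timestamp("2020-02-01").value / 3.6e12
_ENROLL_SPAN_HOURS = 210 * 24.0  # ~1 Feb to 30 Aug


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept a such that mean(expit(a + eta)) = target."""
    lo_rate = float(expit(-30.0 + eta).mean())
    hi_rate = float(expit(30.0 + eta).mean())
    if not lo_rate < target < hi_rate:
        raise CalibrationError(
            f"target rate {target} unreachable: achievable range "
            f"({lo_rate:.4f}, {hi_rate:.4f}) given the planted linear predictor"
        )
    return float(brentq(lambda a: expit(a + eta).mean() - target, -30.0, 30.0))


def _draw_binary(rng: np.random.Generator, p: np.ndarray, exact: bool) -> np.ndarray:
    if not exact:
        return (rng.random(len(p)) < p).astype(int)
    m = int(round(p.mean() * len(p)))
    out = np.zeros(len(p), dtype=int)
    odds = p / (1 - p)
    idx = rng.choice(len(p), size=m, replace=False, p=odds / odds.sum())
    out[idx] = 1
    return out


def _sample_orders(
    rng: np.random.Generator,
    pid: str,
    admission: float,
    z: float,
    config: GeneratorConfig,
) -> list[MedicationOrder]:
    shares = np.array([config.class_shares.get(c, 0.0) for c in DRUG_CLASSES])
    shares = shares / shares.sum()
    mult = math.exp(config.severity_med_coupling * z)
    counts = [
        (rng.poisson(config.meds_day1 * mult), 0.0),
        (rng.poisson(config.meds_day2 * mult), 24.0),
    ]
    chosen: set[str] = set()
    orders: list[MedicationOrder] = []
    for n_meds, day_offset in counts:
        for _ in range(n_meds):
            cls = DRUG_CLASSES[rng.choice(len(DRUG_CLASSES), p=shares)]
            pool = _CATALOG_BY_CLASS[cls]
            drug = pool[rng.integers(len(pool))]
            if drug.name in chosen:
                continue  # regimen-level: one order per drug
            chosen.add(drug.name)
            form = drug.forms[rng.integers(len(drug.forms))]
            freq = drug.frequencies[rng.integers(len(drug.frequencies))]
            if day_offset == 0.0:
                u = rng.random()
                if u < 0.10:  # continued home/ED medication
                    start = admission - rng.uniform(0.0, 6.0)
                else:
                    start = admission + rng.uniform(0.0, 22.0)
            else:
                start = admission + rng.uniform(24.0, 44.0)
            if rng.random() < 0.15:
                stop = None  # open order
            else:
                stop = start + float(rng.lognormal(math.log(48.0), 0.6))
            directions: tuple[str, ...] = ()
            if form in {"tablet", "capsule", "liquid"} and rng.random() < config.direction_rate:
                directions = (str(rng.choice(["with_food", "specific_time",
                                              "multiple_units", "break_tablet"])),)
            item = drug.mrc_icu_item
            if item is not None and rng.random() > config.mrc_item_rate:
                item = None
            orders.append(MedicationOrder(
                patient_id=pid,
                drug_name=drug.name,
                drug_class=drug.drug_class,
                dosage_form=form,
                frequency_code=freq,
                prn=freq.endswith("_prn"),
                continuous_infusion=drug.continuous or freq == "continuous",
                additional_directions=directions,
                mrc_icu_item=item,
                start_time=start,
                stop_time=stop,
            ))
    return orders


def generate_cohort(
    config: GeneratorConfig | None = None,
    seed: int = 0,
    weight_tables: Mapping[str, WeightTable] | None = None,
) -> tuple[list[PatientRecord], list[MedicationOrder], dict]:
    """Generate (patients, orders, true_parameters) for one synthetic cohort.

    Every generated patient (beyond the ``n_invalid`` planted violators)
    passes the inclusion filter; orders carry only resolvable weight-table
    keys; outcomes are drawn from the planted logistic model on the
    engine-computed 24 h MRC-ICU score.  ``true_parameters`` records every
    planted value for recovery tests.  Same (config, seed) gives an
    identical cohort.
    """
    config = config or GeneratorConfig()
    tables = weight_tables or default_weight_tables()
    rng = np.random.default_rng(seed)
    n = config.n_patients

    z = rng.normal(0.0, 1.0, n)  # latent severity factor
    age = np.clip(rng.normal(62.0, 16.0, n), 18.0, 95.0)
    sex = np.where(rng.random(n) < config.male_p, "male", "female")
    races = list(config.race_probs)
    race = rng.choice(races, size=n, p=np.array(list(config.race_probs.values())))
    height = rng.normal(170.0, 10.0, n)
    bmi = np.clip(rng.normal(28.5, 5.5, n), 16.0, 55.0)
    weight = bmi * (height / 100.0) ** 2

    apache2 = np.clip(np.round(17.0 + 5.5 * z + rng.normal(0, 3.0, n)), 0, 71)
    saps2 = np.clip(np.round(15.0 + 8.0 * z + rng.normal(0, 4.0, n)), 0, 100)
    cci = rng.poisson(np.exp(0.7 + 0.25 * z))
    gcs = np.clip(np.round(13.0 - 2.0 * z + rng.normal(0, 1.5, n)), 3, 15)

    sbp = rng.normal(120.0 - 8.0 * z, 12.0)
    dbp = rng.normal(70.0 - 5.0 * z, 8.0)
    map_ = dbp + (sbp - dbp) / 3.0
    hr = rng.normal(90.0 + 6.0 * z, 12.0)
    rr = rng.normal(20.0 + 2.0 * z, 3.0)
    temp = rng.normal(98.1, 0.8, n)
    sao2 = np.clip(rng.normal(96.0 - 1.2 * z, 2.0), 75.0, 100.0)

    # baseline renal labs; non-survivors get a planted 1.5x BUN shift below
    # (the survivor-vs-non-survivor contrast the cohort table reports)
    bun = np.exp(rng.normal(math.log(24.0), 0.35, n) + 0.15 * z)
    scr = np.exp(rng.normal(math.log(1.3), 0.35, n) + 0.20 * z)
    sodium = rng.normal(137.0, 4.0, n)
    potassium = rng.normal(4.1, 0.5, n)

    admission = _BASE_HOURS + rng.uniform(0.0, _ENROLL_SPAN_HOURS, n)

    pids = [f"P{i:04d}" for i in range(1, n + 1)]
    orders: list[MedicationOrder] = []
    mrc24 = np.empty(n)
    mrci24 = np.empty(n)
    for i, pid in enumerate(pids):
        patient_orders = _sample_orders(rng, pid, admission[i], z[i], config)
        orders.extend(patient_orders)
        day1 = active_orders(patient_orders, admission[i], 24.0)
        mrci24[i] = mrci_score(day1, tables)
        mrc24[i] = mrc_icu_score(day1, tables["MRC_ICU"])

    covariates = {"mrc_icu_24h": mrc24, "mrci_24h": mrci24, "age": age}
    flags: dict[str, np.ndarray] = {}
    intercepts: dict[str, float] = {}
    for outcome, rate in config.outcome_rates.items():
        eta = np.zeros(n)
        for var, beta in config.planted_log_or.get(outcome, {}).items():
            if var not in covariates:
                raise CalibrationError(f"no generated covariate {var!r} to plant on")
            eta = eta + beta * covariates[var]
        intercepts[outcome] = _calibrate_intercept(eta, rate)
        p = expit(intercepts[outcome] + eta)
        flags[outcome] = _draw_binary(rng, p, config.exact_outcome_counts)

    # planted non-survivor BUN shift (about 1.5x the survivor level)
    bun = bun * np.where(flags["mortality"] == 1, 1.5, 1.0)

    # LOS consistent with the planted prolonged-stay flag, inside (24 h, 40 d)
    los = np.where(
        flags["los_gt_48"] == 1,
        np.clip(48.0 + rng.lognormal(math.log(72.0), 0.8, n), 48.5, 40 * 24.0 - 1.0),
        rng.uniform(25.0, 47.5, n),
    )
    mv_hours = np.where(
        flags["mv"] == 1,
        np.clip(rng.lognormal(math.log(40.0), 0.9, n), 0.5, los * 0.95),
        0.0,
    )

    patients: list[PatientRecord] = []
    dx_codes = list(config.diagnosis_prevalences)
    dx_probs = np.array(list(config.diagnosis_prevalences.values()))
    for i, pid in enumerate(pids):
        # acuity-linked diagnoses lean on the latent severity factor
        p_dx = np.clip(dx_probs * np.exp(0.25 * z[i]), 0.0, 0.95)
        codes = frozenset(np.array(dx_codes)[rng.random(len(dx_codes)) < p_dx])
        patients.append(PatientRecord(
            patient_id=pid,
            age=float(age[i]),
            sex=str(sex[i]),
            race_ethnicity=str(race[i]),
            height=float(round(height[i], 1)),
            weight=float(round(weight[i], 1)),
            bmi=float(round(bmi[i], 1)),
            icu_admission=float(admission[i]),
            icu_discharge=float(admission[i] + los[i]),
            died_in_icu=bool(flags["mortality"][i]),
            mv_hours=float(round(mv_hours[i], 1)),
            apache2=int(apache2[i]),
            saps2=int(saps2[i]),
            cci=int(cci[i]),
            gcs=int(gcs[i]),
            vitals={"sbp": round(float(sbp[i]), 1), "dbp": round(float(dbp[i]), 1),
                    "map": round(float(map_[i]), 1), "hr": round(float(hr[i]), 1),
                    "rr": round(float(rr[i]), 1), "temp": round(float(temp[i]), 1),
                    "sao2": round(float(sao2[i]), 1)},
            labs={"bun": round(float(bun[i]), 1), "scr": round(float(scr[i]), 2),
                  "sodium": round(float(sodium[i]), 1),
                  "potassium": round(float(potassium[i]), 2)},
            diagnoses=codes,
        ))

    patients.extend(_invalid_patients(rng, config, admission.mean()))

    truth = {
        "seed": seed,
        "intercepts": intercepts,
        "planted_log_or": {k: dict(v) for k, v in config.planted_log_or.items()},
        "outcome_rates": dict(config.outcome_rates),
        "outcome_flags": {
            outcome: {pid: int(flags[outcome][i]) for i, pid in enumerate(pids)}
            for outcome in flags
        },
        "score_medians": {"mrci_24h": float(np.median(mrci24)),
                          "mrc_icu_24h": float(np.median(mrc24))},
    }
    return patients, orders, truth


def _invalid_patients(
    rng: np.random.Generator,
    config: GeneratorConfig,
    mean_admission: float,
) -> list[PatientRecord]:
    """Planted filter violators (LOS > 40 d, missing labs, minors, short stays)."""
    out = []
    reasons = ["los>40d", "missing_labs", "icu_stay<=24h", "age<18"]
    for j in range(config.n_invalid):
        reason = reasons[j % len(reasons)]
        age, los = 55.0, 120.0
        labs = {"bun": 20.0, "scr": 1.1, "sodium": 138.0, "potassium": 4.0}
        if reason == "los>40d":
            los = 41.0 * 24.0
        elif reason == "missing_labs":
            labs = {"sodium": 138.0, "potassium": 4.0}
        elif reason == "icu_stay<=24h":
            los = 20.0
        elif reason == "age<18":
            age = 17.0
        out.append(PatientRecord(
            patient_id=f"X{j:04d}",
            age=age, sex="female", race_ethnicity="White",
            height=168.0, weight=70.0, bmi=24.8,
            icu_admission=mean_admission,
            icu_discharge=mean_admission + los,
            died_in_icu=False, mv_hours=0.0,
            apache2=12, saps2=10, cci=1, gcs=15,
            vitals={"sbp": 120.0, "dbp": 72.0, "map": 88.0, "hr": 80.0,
                    "rr": 18.0, "temp": 98.2, "sao2": 97.0},
            labs=labs,
            diagnoses=frozenset(),
        ))
    return out


# ---------------------------------------------------------------------------
# fast statistics-only simulation and recovery harness


def direct_scores(
    n: int,
    rng: np.random.Generator,
    score_median: float = 6.0,
    score_sigma: float = 0.55,
    n_noise: int = 3,
) -> pd.DataFrame:
    """Score-like covariate table without the regimen machinery.

    The complexity score is lognormal (right-skewed, median
    ``score_median``); ``n_noise`` standard-normal covariates are appended
    as null candidates for selection studies.
    """
    frame = {"mrc_icu_24h": rng.lognormal(math.log(score_median), score_sigma, n)}
    for j in range(n_noise):
        frame[f"noise_{j + 1}"] = rng.normal(0.0, 1.0, n)
    return pd.DataFrame(frame)


def plant_outcome(
    covariates: pd.DataFrame,
    log_or: Mapping[str, float],
    target_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw a binary outcome from a logistic model with calibrated intercept."""
    eta = np.zeros(len(covariates))
    for var, beta in log_or.items():
        eta = eta + beta * covariates[var].to_numpy()
    a = _calibrate_intercept(eta, target_rate)
    return (rng.random(len(covariates)) < expit(a + eta)).astype(float)


def recovery_suite(
    planted_or: float = 1.12,
    target_rate: float = 0.23,
    n_replicates: int = 200,
    n_per_replicate: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Coverage and bias of the stepwise-selected fit for a planted effect.

    Each replicate draws a fresh score-plus-noise cohort, plants the outcome
    at ``planted_or`` per score point, runs forward selection over the score
    and the noise candidates, and (when the score is selected) records the
    fitted log-OR and whether its 95% Wald CI covers the planted value.
    """
    from .association import stepwise_forward_logistic

    beta_true = math.log(planted_or)
    rng = np.random.default_rng(seed)
    estimates, covered, selected = [], 0, 0
    for _ in range(n_replicates):
        X = direct_scores(n_per_replicate, rng)
        y = plant_outcome(X[["mrc_icu_24h"]], {"mrc_icu_24h": beta_true},
                          target_rate, rng)
        fit = stepwise_forward_logistic(X, pd.Series(y), alpha=alpha)
        if "mrc_icu_24h" not in fit.selected:
            continue
        selected += 1
        rec = fit.table.set_index("variable").loc["mrc_icu_24h"]
        estimates.append(float(rec["coef"]))
        lo, hi = math.log(rec["ci_low"]), math.log(rec["ci_high"])
        if lo <= beta_true <= hi:
            covered += 1
    if selected == 0:
        raise RuntimeError("planted effect never selected; nothing to report")
    mean_est = float(np.mean(estimates))
    return {
        "planted_log_or": beta_true,
        "n_replicates": n_replicates,
        "n_selected": selected,
        "selection_rate": selected / n_replicates,
        "mean_log_or": mean_est,
        "bias_log_or": mean_est - beta_true,
        "mean_or": float(np.exp(mean_est)),
        "ci_coverage": covered / selected,
    }


def null_selection_rate(
    n_replicates: int = 1000,
    n: int = 317,
    target_rate: float = 0.23,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """How often forward selection admits a pure-noise candidate (should be ~alpha)."""
    from .association import stepwise_forward_logistic

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        X = pd.DataFrame({"noise_1": rng.normal(0.0, 1.0, n)})
        y = (rng.random(n) < target_rate).astype(float)
        if y.sum() in (0, n):
            continue
        fit = stepwise_forward_logistic(X, pd.Series(y), alpha=alpha)
        if "noise_1" in fit.selected:
            hits += 1
    return hits / n_replicates


def null_loocv_auc(
    n_replicates: int = 200,
    n: int = 200,
    target_rate: float = 0.3,
    n_noise: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """LOOCV AUC distribution when predictors carry no signal (centred at 0.5)."""
    from sklearn.linear_model import LogisticRegression

    from .prediction import auc_rank

    rng = np.random.default_rng(seed)
    aucs = np.empty(n_replicates)
    for r in range(n_replicates):
        X = rng.normal(0.0, 1.0, (n, n_noise))
        y = (rng.random(n) < target_rate).astype(float)
        while y.sum() < 2 or y.sum() > n - 2:
            y = (rng.random(n) < target_rate).astype(float)
        probs = np.empty(n)
        mask = np.ones(n, dtype=bool)
        clf = LogisticRegression(C=1e12, solver="newton-cholesky", max_iter=200)
        for i in range(n):
            mask[i] = False
            clf.fit(X[mask], y[mask])
            probs[i] = clf.predict_proba(X[i][None, :])[0, 1]
            mask[i] = True
        aucs[r] = auc_rank(probs, y)
    return aucs
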