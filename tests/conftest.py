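import numpy as np
import pytest

from mrcomplexity.records import MedicationOrder, PatientRecord
from mrcomplexity.simulate import GeneratorConfig, generate_cohort
from mrcomplexity.weights import WeightTable, default_weight_tables


@pytest.fixture(scope="session")
def tables():
    return default_weight_tables()


@pytest.fixture(scope="session")
def fixture_tables():
    """Small hand-built weight tables with easily summed weights."""
    return {
        "MRCI_A": WeightTable("MRCI_A", {"tablet": 1.0, "liquid": 2.0,
                                         "iv_infusion": 4.0, "injection": 3.0},
                              version="test"),
        "MRCI_B": WeightTable("MRCI_B", {"once_daily": 1.0, "twice_daily": 2.0,
                                         "q6h": 4.5, "continuous": 2.0,
                                         "q6h_prn": 2.5},
                              version="test"),
        "MRCI_C": WeightTable("MRCI_C", {"with_food": 1.0, "taper": 2.0},
                              version="test"),
        "MRC_ICU": WeightTable("MRC_ICU", {"vancomycin": 3.0,
                                           "continuous_iv_saline": 1.0,
                                           "heparin_infusion": 2.0},
                               version="test"),
    }


def make_order(pid="P1", drug="acetaminophen", drug_class="analgesics_sedatives",
               form="tablet", freq="once_daily", start=0.0, stop=24.0,
               directions=(), item=None, prn=False, continuous=False):
    return MedicationOrder(
        patient_id=pid, drug_name=drug, drug_class=drug_class,
        dosage_form=form, frequency_code=freq, prn=prn,
        continuous_infusion=continuous, additional_directions=tuple(directions),
        mrc_icu_item=item, start_time=start, stop_time=stop,
    )


def make_patient(pid="P1", age=60.0, los_hours=100.0, died=False, mv_hours=0.0,
                 labs=None, vitals=None, diagnoses=(), **kw):
    defaults = dict(
        sex="male", race_ethnicity="White", height=175.0, weight=80.0, bmi=26.1,
        apache2=15, saps2=14, cci=2, gcs=14,
    )
    defaults.update(kw)
    return PatientRecord(
        patient_id=pid, age=age,
        icu_admission=0.0, icu_discharge=los_hours,
        died_in_icu=died, mv_hours=mv_hours,
        vitals=vitals if vitals is not None else
               {"sbp": 120.0, "dbp": 75.0, "map": 90.0, "hr": 80.0},
        labs=labs if labs is not None else
             {"bun": 18.0, "scr": 1.0, "sodium": 138.0, "potassium": 4.0},
        diagnoses=frozenset(diagnoses),
        **defaults,
    )


@pytest.fixture(scope="session")
def small_cohort(tables):
    """A compact generated cohort shared by the slower integration tests."""
    config = GeneratorConfig(n_patients=150)
    patients, orders, truth = generate_cohort(config, seed=11, weight_tables=tables)
    return patients, orders, truth


@pytest.fixture(scope="session")
def pipeline_result():
    from mrcomplexity.pipeline import run_pipeline

    return run_pipeline(seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
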