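import numpy as np
import pytest

from hfoutcomes.cohort import EchoIndices, FollowUpRecord, PatientRecord
from hfoutcomes.simulate import TruthParams, generate_cohort


def make_patient(pid="p1", arm="integrative", nyha_discharge="III", **kw):
    """Hand-built patient with sensible defaults for unit tests."""
    defaults = dict(
        patient_id=pid,
        arm=arm,
        age=64.0,
        gender="male",
        height_cm=170.0,
        weight_kg=70.0,
        comorbidities={
            "hypertension": True, "coronary_artery_disease": False,
            "arrhythmia": False, "heart_valve_disease": False,
            "diabetes": True, "renal_insufficiency": False,
        },
        medications={"diuretics": True, "acei_arb": True,
                     "beta_blocker": True, "mra": False},
        smoking=False,
        labs={"hb": 128.0, "cr": 92.3, "tg": 1.67, "ldl_c": 2.41,
              "hs_crp": 6.71, "nt_probnp": 2455.0, "hcy": 17.98,
              "k": 4.06, "na": 139.7, "cl": 103.1, "mg": 0.88},
        echo=EchoIndices.from_measurements(47.5, 5.0, 1.0, 1.0, 170.0, 70.0),
        nyha_admission="III",
        nyha_discharge=nyha_discharge,
        died_in_hospital=False,
        hospital_days=9.0,
        entry_month=0,
    )
    defaults.update(kw)
    return PatientRecord(**defaults)


@pytest.fixture
def hand_cohort():
    """Five patients (both arms) with simple follow-up paths."""
    patients = [
        make_patient("a1", "integrative", nyha_discharge="II"),
        make_patient("a2", "integrative", nyha_discharge="III"),
        make_patient("a3", "conventional", nyha_discharge="III"),
        make_patient("a4", "conventional", nyha_discharge="IV", gender="female"),
        make_patient("a5", "conventional", nyha_discharge="II", age=55.0),
    ]
    followups = [
        FollowUpRecord("a1", 6, "II", False),
        FollowUpRecord("a1", 12, "CVE", False),
        FollowUpRecord("a2", 6, "III", False),
        FollowUpRecord("a2", 12, "III", False),
        FollowUpRecord("a2", 18, "II", True),
        FollowUpRecord("a3", 6, "CVE", False),
        FollowUpRecord("a4", 6, "IV", False),
        FollowUpRecord("a4", 12, "CVE", False),
        FollowUpRecord("a5", 6, "II", True),
    ]
    return patients, followups


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(TruthParams(seed=11))


@pytest.fixture(scope="session")
def hazard_cohort():
    params = TruthParams(seed=23, n_per_arm=(400, 400), cve_mode="hazard",
                         inhospital_death_rate={})
    return generate_cohort(params)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
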