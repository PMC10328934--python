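"""Shared fixtures: small simulated cohorts and hand-built toy tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from multidx import SimConfig, TrainConfig, generate
from multidx.pipeline import run_experiment, simulate_and_prepare
from multidx.synthetic import EventTables


def make_tables(patients, encounters, diagnoses, labs=None) -> EventTables:
    """Build EventTables from plain tuples (test helper).

    patients: (patient_id, birth_date, sex)
    encounters: (encounter_id, patient_id, date, type, status)
    diagnoses: (encounter_id, patient_id, date, icd10_code)
    labs: (patient_id, date, lab_name, raw_value, unit)
    """
    t = EventTables(
        patients=pd.DataFrame(patients, columns=["patient_id", "birth_date", "sex"]),
        encounters=pd.DataFrame(
            encounters, columns=["encounter_id", "patient_id", "date", "type", "status"]
        ),
        diagnoses=pd.DataFrame(
            diagnoses, columns=["encounter_id", "patient_id", "date", "icd10_code"]
        ),
        labs=pd.DataFrame(
            labs or [], columns=["patient_id", "date", "lab_name", "raw_value", "unit"]
        ),
    )
    for df, col in ((t.patients, "birth_date"), (t.encounters, "date"),
                    (t.diagnoses, "date"), (t.labs, "date")):
        df[col] = pd.to_datetime(df[col])
    return t


@pytest.fixture(scope="session")
def sim_small():
    """A small simulated cohort shared across read-only tests."""
    return generate(SimConfig(n_patients=300, seed=11))


@pytest.fixture(scope="session")
def prepared_small():
    """Prepared matrices for a small, clearly-signalled cohort."""
    data, truth, tables = simulate_and_prepare(
        SimConfig(n_patients=600, seed=5, signal_strength=1.5), min_patients=15
    )
    return data, truth, tables


@pytest.fixture(scope="session")
def lr_experiment(prepared_small):
    """A calibrated logistic-regression run on the small cohort."""
    data, truth, tables = prepared_small
    result = run_experiment(data, TrainConfig(base="LR", seed=5), with_calibration=True)
    return data, truth, result
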