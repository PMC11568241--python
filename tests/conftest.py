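from datetime import date

import pytest

from claims2tx import (
    ContingencyTable,
    PatientProfile,
    default_code_map,
    default_regimen_table,
)


@pytest.fixture(scope="session")
def code_map():
    return default_code_map()


@pytest.fixture(scope="session")
def regimens():
    return default_regimen_table()


@pytest.fixture
def profile():
    return PatientProfile(
        patient_id="P1",
        diagnosis_date=date(2013, 3, 1),
        age_at_diagnosis=50.0,
        height_cm=180.0,
        weight_kg=80.0,
        serum_creatinine_mg_dl=0.8,
    )


@pytest.fixture
def cyclophosphamide_table():
    """Published cyclophosphamide quadrants: 96 neither, 16 abstraction-only,
    12 claims-only, 62 both (n = 186)."""
    return ContingencyTable(both=62, gold_only=16, claims_only=12, neither=96)
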