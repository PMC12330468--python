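import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from suicidality_psm.case_definition import CodeSet


def make_encounters(rows):
    """Build an encounter frame from (pid, eid, date, age, sex, race, codes, notes)."""
    return pd.DataFrame(
        [
            {
                "patient_id": pid,
                "encounter_id": eid,
                "date": pd.Timestamp(date),
                "age_at_visit": age,
                "sex": sex,
                "race": race,
                "icd10_codes": tuple(codes),
                "note_types": tuple(notes),
            }
            for pid, eid, date, age, sex, race, codes, notes in rows
        ]
    )


@pytest.fixture(scope="session")
def codeset():
    return CodeSet.default()
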