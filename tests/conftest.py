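import random
from datetime import datetime

import pytest

from cohortforge.facts import ObservationFact
from cohortforge.store import PatientStore


@pytest.fixture
def store():
    s = PatientStore()
    yield s
    s.close()


def lab(pid, value, when, code="LOINC:2345-7", unit="mg/dL"):
    return ObservationFact(
        patient_id=pid,
        concept_code=code,
        start_datetime=when if isinstance(when, datetime) else datetime.fromisoformat(when),
        value_kind="numeric",
        numeric_value=float(value),
        unit=unit,
    )


def dx(pid, code, when):
    return ObservationFact(
        patient_id=pid,
        concept_code=code,
        start_datetime=when if isinstance(when, datetime) else datetime.fromisoformat(when),
        value_kind="flag",
    )


@pytest.fixture
def rng():
    return random.Random(20260920)
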