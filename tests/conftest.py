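from datetime import datetime, timedelta

import pytest
from hypothesis import settings

import clinicflow as cf

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def reference_ledgers():
    return cf.reference_ledgers()


@pytest.fixture(scope="session")
def june_ledger(reference_ledgers):
    return reference_ledgers[0]


@pytest.fixture(scope="session")
def small_population():
    cfg = cf.PopulationConfig(n_patients=2000, seed=1)
    return cf.generate_population(cfg)


@pytest.fixture
def make_record():
    base = datetime(2024, 3, 1, 9, 0)

    def _make(patient_id="p0", status="booked", role="primary", lead=None, slot_offset=0):
        return cf.AppointmentRecord(
            patient_id=patient_id,
            slot_time=base + timedelta(minutes=slot_offset),
            booking_time=base - timedelta(days=2),
            role=role,
            status=status,
            cancel_lead_min=lead,
        )

    return _make


@pytest.fixture
def make_candidate():
    def _make(patient_id="c0", p_attend=0.8, travel=30.0, order=0):
        p_rest = 1.0 - p_attend
        risk = cf.RiskProfile(
            patient_id=patient_id,
            p_attend=p_attend,
            p_cancel=p_rest * 0.7,
            p_noshow=p_rest * 0.3,
            high_risk=p_attend < 0.6,
        )
        return cf.ReserveCandidate(
            patient_id=patient_id,
            risk=risk,
            travel_time_min=travel,
            booking_order=order,
        )

    return _make
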