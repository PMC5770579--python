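from datetime import date

import pytest

from sbirtkit.cohort import pilot_fixture, simulate_patient, PatientProfile
from sbirtkit.content import load_library
from sbirtkit.screening import ScoringWeights
from sbirtkit.substances import Substance
from sbirtkit.tailoring import Stage, TailoringConfig, build_session

REFERENCE_DATE = date(2020, 6, 1)


@pytest.fixture(scope="session")
def weights():
    return ScoringWeights.default()


@pytest.fixture(scope="session")
def config():
    return TailoringConfig.default()


@pytest.fixture(scope="session")
def library():
    return load_library()


@pytest.fixture(scope="session")
def pilot_patients(weights):
    return pilot_fixture(weights)


@pytest.fixture(scope="session")
def pilot_sessions(pilot_patients, weights, config):
    return [
        build_session(
            p.interview,
            p.quit_answers,
            p.treatment_answers,
            weights=weights,
            config=config,
            patient_name=p.profile.name,
            date_of_birth=p.profile.date_of_birth,
        )
        for p in pilot_patients
    ]


def make_session(
    weights,
    config,
    *,
    target=Substance.OPIOIDS,
    score=21,
    quit_stage=Stage.CONTEMPLATION,
    treatment_stage=Stage.CONTEMPLATION,
    name=None,
    dob=None,
):
    """Convenience builder for a single-substance synthetic session."""
    profile = PatientProfile(
        name=name or "Test Patient",
        date_of_birth=dob or date(1980, 1, 1),
        target_scores={target: score},
        quit_stage=quit_stage,
        treatment_stage=treatment_stage if score >= 27 else None,
    )
    patient = simulate_patient(profile, weights, seed=11)
    return build_session(
        patient.interview,
        patient.quit_answers,
        patient.treatment_answers,
        weights=weights,
        config=config,
        patient_name=profile.name,
        date_of_birth=profile.date_of_birth,
    )


@pytest.fixture()
def session_factory(weights, config):
    def factory(**kwargs):
        return make_session(weights, config, **kwargs)

    return factory
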