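import numpy as np
import pytest

from cogbattery import (
    RespondentParams,
    SimulatedRespondent,
    generate_arrow_sequence,
    run_session,
    schedule_trials,
    simulate_cohort,
)
from cogbattery.session import correct_choice


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def omniscient():
    """Responder that always answers correctly after 300 ms."""

    def responder(stimulus, layout, condition):
        return correct_choice(stimulus), 300.0

    return responder


@pytest.fixture
def silent():
    """Responder that never answers."""

    def responder(stimulus, layout, condition):
        return None

    return responder


@pytest.fixture
def arrow_session():
    """One simulated 40-trial arrow session with default respondent params."""
    stimuli = generate_arrow_sequence(40, 7)
    specs = schedule_trials(stimuli, "arrow", 7)
    return run_session(
        specs,
        SimulatedRespondent(RespondentParams(), 7),
        participant_id="p000",
        test="arrow",
        platform="watch",
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study():
    """A seeded 8-participant balanced study, shared across tests."""
    return simulate_cohort(8, seed=11)
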