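import numpy as np
import pytest

from tinassay.behavior import AnimalState, Protocol, build_protocol, simulate_session


@pytest.fixture(scope="session")
def default_schedule():
    return build_protocol(Protocol(), seed=123)


@pytest.fixture()
def animal():
    return AnimalState("E01", exposed=True, tau=0.8, lambda_bg=20.0, c_off=0.9)


@pytest.fixture()
def control_animal():
    return AnimalState("U01", exposed=False, tau=0.0, lambda_bg=20.0, c_off=0.9)


@pytest.fixture(scope="session")
def example_session():
    state = AnimalState("E01", exposed=True, tau=0.6, lambda_bg=18.0)
    return simulate_session(state, Protocol(), seed=7)


def random_session(rng: np.random.Generator, n_presses: int = 500):
    """A session with uniformly random press times over a random schedule."""
    schedule = build_protocol(Protocol(), seed=rng)
    times = np.sort(rng.uniform(0.0, 3600.0 - 1e-9, size=n_presses))
    from tinassay.behavior import SessionLog

    return SessionLog(animal_id="rand", press_times=times, schedule=schedule)
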