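import numpy as np
import pandas as pd
import pytest

import aalearn as a


@pytest.fixture(scope="session")
def design():
    return a.TaskDesign()


@pytest.fixture(scope="session")
def control_design():
    return a.TaskDesign(arm=a.SOCIAL_CONTROL)


@pytest.fixture
def worked_example_trials():
    """Two out-group trials: y = (0.6, 0.5), outcomes (reward, punishment)."""
    return pd.DataFrame({
        "symbol": [a.SYMBOL_OUT, a.SYMBOL_OUT],
        "y_value": [0.6, 0.5],
        "outcome_r": [1, 0],
    })


@pytest.fixture(scope="session")
def noiseless_participant(design):
    """Deterministic valence-split agent: no response noise, no invalid trials."""
    agent = a.AgentConfig(noise_sd=0.0, p_invalid=0.0)
    out = a.simulate_participant(agent, design, seed=2024)
    return agent, out


@pytest.fixture(scope="session")
def small_cohort(design):
    """Six conflict-arm agents, default generator, fixed seed."""
    return a.simulate_cohort(arm=a.SOCIAL_CONFLICT, n_participants=6, seed=77,
                             design=design)


def random_histories(rng, n_trials=30):
    """One synthetic valid-trial frame with random responses and outcomes."""
    half = n_trials // 2
    symbols = np.array([a.SYMBOL_IN] * half + [a.SYMBOL_OUT] * (n_trials - half))
    rng.shuffle(symbols)
    return pd.DataFrame({
        "symbol": symbols,
        "y_value": rng.uniform(0, 1, n_trials),
        "outcome_r": rng.integers(0, 2, n_trials),
    })
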