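from __future__ import annotations

import numpy as np
import pytest

from decadd import simulate, stimuli


@pytest.fixture(scope="session")
def study1_sets():
    """One batch of 21 study-1 stimulus sets, shared across tests."""
    rng = np.random.default_rng(2024)
    return [stimuli.generate_set(1, rng) for _ in range(21)]


@pytest.fixture(scope="session")
def study1_log(study1_sets):
    """A default-parameter study-1 simulation (21 participants)."""
    return simulate.simulate_experiment(
        n_participants=21, study=1, stimulus_sets=study1_sets, seed=314
    )


@pytest.fixture(scope="session")
def study2_log():
    return simulate.simulate_experiment(n_participants=21, study=2, seed=2718)


@pytest.fixture
def noise_free_params():
    """Deterministic behaviour: no noise, no errors, no participant spread."""
    return simulate.SimParams(
        addend_slope=0.0,
        participant_sd=0.0,
        residual_cv=0.0,
        error_hazard={"POST": 0.0, "SUB": 0.0, "COMP": 0.0, "SUPER": 0.0},
        late_prob=0.0,
    )
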