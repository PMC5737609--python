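import numpy as np
import pandas as pd
import pytest

from mpramars import PWMatrix, ScenarioSpec, simulate_dataset


@pytest.fixture
def ac_pwm() -> PWMatrix:
    """Two-position motif with consensus AC (deterministic frequencies)."""
    return PWMatrix("AC", np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0]]), cutoff=0.9)


@pytest.fixture
def mixed_pwm() -> PWMatrix:
    """Three-position motif with non-trivial frequencies for score checks."""
    freqs = np.array(
        [
            [0.7, 0.1, 0.1, 0.1],
            [0.25, 0.25, 0.25, 0.25],
            [0.05, 0.05, 0.5, 0.4],
        ]
    )
    return PWMatrix("MIX", freqs)


def small_scenario(seed: int = 0, n: int = 300, **kwargs) -> ScenarioSpec:
    """A scaled-down scenario for fast unit tests (single cluster by sizing)."""
    return ScenarioSpec(seed=seed, n_sequences=n, **kwargs)


@pytest.fixture(scope="session")
def default_dataset():
    """One realisation of the reference scenario, shared across tests."""
    return simulate_dataset(ScenarioSpec(seed=7))


def random_design(rng: np.random.Generator, n: int, p: int):
    """Plain numeric feature frame + response helpers for tree/MARS tests."""
    X = pd.DataFrame(rng.random((n, p)), columns=[f"x{j}" for j in range(p)])
    return X
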