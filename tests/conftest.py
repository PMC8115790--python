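import numpy as np
import pytest

from rigwatch.experiments import run_experiment, simulate_labeled_series


@pytest.fixture(scope="session")
def small_session():
    """A short choker-setter session shared by fast pipeline tests."""
    series, log = simulate_labeled_series("choker_setter", n_cycles=8, seed=11)
    return series, log


@pytest.fixture(scope="session")
def reduced_sweep_separable():
    """Reduced-grid experiment at full separability (150 cycles).

    Session-scoped: the same run backs the learnability, ordering and
    acceptance checks.
    """
    return run_experiment("choker_setter", n_cycles=150, seed=7, separability=1.0)


@pytest.fixture(scope="session")
def reduced_sweep_null():
    """Reduced-grid experiment on the no-signal null (grouped split)."""
    return run_experiment(
        "choker_setter", n_cycles=100, seed=7, separability=0.0,
        split_mode="episode",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
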