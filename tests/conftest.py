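import numpy as np
import pytest

from betwheel import ObserverParams, simulate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_sampling_dataset():
    """A small sampling-observer cohort shared across analysis tests."""
    return simulate_dataset(
        n_participants=6, n_trials=50, seed=101,
        base_params=ObserverParams(kind="sampling"),
    )


@pytest.fixture(scope="session")
def small_undo_dataset():
    """Undo-enabled cohort with an elevated lapse rate so undos are plentiful."""
    return simulate_dataset(
        n_participants=4, n_trials=80, seed=202,
        base_params=ObserverParams(
            kind="sampling", lapse_rate=0.1, undo_enabled=True
        ),
        heterogeneous=False,
    )
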