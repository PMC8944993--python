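import numpy as np
import pytest

from sgann import (CohortConfig, NetworkParams, generate_table1_cohort,
                   table1_panel)
from sgann.pipeline import run_recovery_experiment


@pytest.fixture(scope="session")
def panel():
    return table1_panel()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def study_cohort():
    """A cohort at the published size: 14 SGA + 63 AGA."""
    return generate_table1_cohort(CohortConfig(n_sga=14, n_aga=63, seed=7))


@pytest.fixture(scope="session")
def recovery():
    """The oracle-recovery experiment at study conditions: n = 154 in the
    14:63 mixture, seeded 14-2-1 truth, output noise sd 0.02, 70/15/15
    split, h = 2 with 20 Levenberg-Marquardt restarts."""
    return run_recovery_experiment(seed=1)


def random_network(rng, h=None, n_inputs=14, scale=1.0):
    """Random finite network for property tests."""
    h = h or int(rng.integers(1, 5))
    return NetworkParams(
        Wi=rng.uniform(-scale, scale, size=(h, n_inputs)),
        b1=rng.uniform(-scale, scale, size=h),
        Wo=rng.uniform(-scale, scale, size=h),
        b2=float(rng.uniform(-scale, scale)),
    )
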