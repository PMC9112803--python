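import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import foldkin as fk

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def wt():
    return fk.WT_PARAMS


@pytest.fixture(scope="session")
def fixture_table():
    return fk.load_table1()


@pytest.fixture(scope="session")
def small_ensemble():
    """8 mutants + wt, 21-point chevrons, 2% log-noise (shared m-values)."""
    spec = fk.EnsembleSpec(
        n_variants=8, urea_grid=np.linspace(0.0, 9.0, 21), noise_sd_log=0.02, seed=424242
    )
    return fk.simulate_ensemble(spec)


@pytest.fixture(scope="session")
def small_global_fit(small_ensemble):
    datasets, _ = small_ensemble
    return fk.global_fit(datasets, "shared_all_m", seed=0)
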