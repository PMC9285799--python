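import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import feiso

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def standard_run():
    """Converged 50-year standard-experiment column run (full 31 levels)."""
    return feiso.run_experiment("standard", years=50)


@pytest.fixture(scope="session")
def endmembers_only_shelf_run():
    """Endmembers-only experiment in a sediment-dominated shelf column.

    19 levels (seafloor at 430 m) with strong sediment and weak dust input,
    so the source mixture is dominated by the light reductive endmember.
    """
    return feiso.run_experiment(
        "endmembers_only",
        years=20,
        n_levels=19,
        sediment_f_max=5e-11,
        dust_flux=5e-13,
    )


@pytest.fixture(scope="session")
def fractionation_only_run():
    """Fractionation-only experiment (all endmembers 0 permil), 40 years."""
    return feiso.run_experiment("fractionation_only", years=40)


@pytest.fixture(scope="session")
def quick_run():
    """Short shallow run for I/O, CLI, and observation-pipeline tests."""
    return feiso.run_experiment("standard", years=3, n_levels=22)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
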