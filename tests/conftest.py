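import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from admixclock.tract_io import WindowRecord

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[
        HealthCheck.too_slow,
        HealthCheck.function_scoped_fixture,
    ],
    deadline=None,
)
settings.load_profile("ci")


def make_windows(rates, n_per_rate=10, width=100_000, rho=1.0):
    """One chromosome per rate group, tiled with fixed-width windows."""
    windows = []
    for gi, r in enumerate(rates):
        for j in range(n_per_rate):
            windows.append(
                WindowRecord(
                    chromosome=f"chr{gi}",
                    start=j * width,
                    end=(j + 1) * width,
                    rho_per_kb=rho,
                    r_morgans_per_bp=r,
                )
            )
    return windows


@pytest.fixture
def uniform_windows():
    """30 windows on one chromosome at a single recombination rate."""
    return make_windows([1e-8], n_per_rate=30)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
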