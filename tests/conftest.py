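import numpy as np
import pytest

from hybridlv import (
    DistributionState,
    EncounterRates,
    gaussian_profile,
    make_grid,
    truncated_gaussian_density,
)


@pytest.fixture(scope="session")
def default_grid():
    """Production-resolution activity grid (spacing 0.05)."""
    return make_grid(-6.0, 6.0, 241)


@pytest.fixture(scope="session")
def coarse_grid():
    """61-node grid used for dense-kernel (O(n^3)) computations."""
    return make_grid(-6.0, 6.0, 61)


@pytest.fixture(scope="session")
def small_grid():
    return make_grid(-6.0, 6.0, 41)


@pytest.fixture
def gaussian_split(default_grid):
    """Initial density pair whose difference is the canonical Gaussian profile."""
    d0 = gaussian_profile(default_grid)
    f2 = truncated_gaussian_density(default_grid, 0.0, 1.0)
    f1 = DistributionState(default_grid, f2.values + d0.values)
    return f1, f2, d0


@pytest.fixture
def equal_rates_quarter():
    return EncounterRates.constant(0.25)
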