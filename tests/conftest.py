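import numpy as np
import pytest

from ssmri.kspace_sim import generate_cartesian_mask
from ssmri.phantom_gen import PhantomSpec, generate_slice, scenario_specs
from ssmri.ssconv import ConvFilterBank, RowFactors, SSFactors


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_bank(rng):
    """A 4-filter, 3-channel, 3x3 float64 bank with random weights."""
    return ConvFilterBank(
        rng.normal(size=(4, 3, 3, 3)), rng.normal(size=4)
    )


@pytest.fixture
def small_input(rng):
    return rng.normal(size=(3, 10, 12))


@pytest.fixture
def random_factors(rng, small_bank):
    n, m = small_bank.n_filters, small_bank.n_channels
    return SSFactors(rng.normal(size=(n, m)), rng.normal(size=(n, m)))


@pytest.fixture
def random_row_factors(rng, small_bank):
    n, m = small_bank.n_filters, small_bank.n_channels
    kh = small_bank.kernel_size[0]
    return RowFactors(rng.normal(size=(n, m, kh)), rng.normal(size=(n, m)))


@pytest.fixture(scope="session")
def phantom64():
    """One deterministic 64x64 T1-like brain slice."""
    spec = PhantomSpec(size=64, seed=3)
    return generate_slice(spec, 0).image


@pytest.fixture(scope="session")
def mask64_r03():
    return generate_cartesian_mask(64, 0.3, seed=7)


@pytest.fixture(scope="session")
def contrast_pair64():
    return scenario_specs("contrast", size=64, seed=17)
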