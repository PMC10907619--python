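import numpy as np
import pytest

from esvopt.synthetic import (SyntheticConfig, generate_factor_stack,
                              generate_lulc_pair, generate_socio_series)


@pytest.fixture(scope="session")
def small_cfg():
    return SyntheticConfig(grid_rows=80, grid_cols=80, seed=11)


@pytest.fixture(scope="session")
def lulc_pair(small_cfg):
    return generate_lulc_pair(small_cfg)


@pytest.fixture(scope="session")
def factor_stack(small_cfg, lulc_pair):
    return generate_factor_stack(small_cfg, lulc_pair).normalized()


@pytest.fixture(scope="session")
def socio_series(small_cfg):
    return generate_socio_series(small_cfg)


@pytest.fixture(scope="session")
def signal_cfg():
    """Larger region with strong, known factor→transition links."""
    return SyntheticConfig(grid_rows=150, grid_cols=150, seed=23)


@pytest.fixture(scope="session")
def signal_pair(signal_cfg):
    return generate_lulc_pair(signal_cfg)


@pytest.fixture(scope="session")
def signal_factors(signal_cfg, signal_pair):
    return generate_factor_stack(signal_cfg, signal_pair).normalized()


@pytest.fixture
def rng():
    return np.random.default_rng(7)
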