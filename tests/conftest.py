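import numpy as np
import pytest

from ramanquant.synthetic import SyntheticConfig, generate_dataset

#: small, fast study-condition stand-in used by most preprocessing tests:
#: coarse axis keeps the Whittaker solves cheap while preserving both
#: fingerprint windows.
SMALL_CFG = SyntheticConfig(axis_step=4.0, n_samples=12, seed=11)


@pytest.fixture(scope="session")
def small_synthetic():
    return generate_dataset(SMALL_CFG)


@pytest.fixture(scope="session")
def default_synthetic():
    """The full 51-sample study-condition dataset (shared: generation is cheap,
    airPLS on the full axis is not, so tests correct lazily as needed)."""
    return generate_dataset(SyntheticConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
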