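import numpy as np
import pytest

from raf_paradox import ModelVariant, Parameters

ALL_VARIANTS = list(ModelVariant)


@pytest.fixture
def defaults() -> Parameters:
    """The reference parameter set of the descriptive simulations."""
    return Parameters.defaults()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_parameters(rng: np.random.Generator, with_totals: bool = False) -> Parameters:
    """Log-uniform random parameter draw over the documented sweep ranges."""
    kwargs = dict(
        K_A=10.0 ** rng.uniform(-1, 3),
        K_d=10.0 ** rng.uniform(-3, 1),
        K_dim=10.0 ** rng.uniform(-3, 1),
        K_Smon=10.0 ** rng.uniform(-3, 1),
        K_Sdim=10.0 ** rng.uniform(-3, 1),
        R_total=10.0 ** rng.uniform(-3, 1),
    )
    if with_totals:
        kwargs["S_total"] = 10.0 ** rng.uniform(-3, 2)
        kwargs["D_total"] = 10.0 ** rng.uniform(-4, 2)
    return Parameters(**kwargs)
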