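import numpy as np
import pytest

from boldcomplexity import EntropyParams, PhantomSpec, Region, UniformTimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def default_entropy_params():
    return EntropyParams()  # m=2, k=0.25, tau=1


@pytest.fixture
def gaussian_series(rng):
    return UniformTimeSeries(rng.standard_normal(245), dt=2.0)


@pytest.fixture(scope="session")
def tiny_phantom_spec():
    """Small, fast phantom: one region over near-zero background."""
    return PhantomSpec(
        shape=(8, 8, 2),
        n_volumes=60,
        regions=(Region("core", ((2, 6), (2, 6), (0, 2)), "white", 0.0,
                        mean_intensity=1000.0, amplitude=10.0),),
        seed=11,
    )
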