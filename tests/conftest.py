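import numpy as np
import pytest

from fibronet import (
    FixtureSpec,
    TractographyParams,
    generate_tract_set,
    make_fixture,
)


@pytest.fixture(scope="session")
def slab():
    """40x30x4 uniform-fibre slab: the baseline geometry."""
    return make_fixture(FixtureSpec("slab", (40, 30, 4), thickness=4, seed=0))


@pytest.fixture(scope="session")
def slab_tracts(slab):
    geom, field = slab
    return generate_tract_set(
        geom, field, TractographyParams(seed=1), np.random.default_rng(1)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
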