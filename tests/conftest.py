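import numpy as np
import pytest

from nxmxkit.synth import (
    HierarchicalFixtureParams,
    RotationFixtureParams,
    make_hierarchical_fixture,
    make_rotation_fixture,
)


@pytest.fixture
def rotation_ds():
    return make_rotation_fixture(RotationFixtureParams(seed=7))


@pytest.fixture(scope="session")
def hierarchical_ds():
    # session-scoped: 256 panels are cheap to build but reused by many tests
    return make_hierarchical_fixture(HierarchicalFixtureParams(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
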