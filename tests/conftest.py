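import numpy as np
import pytest

from rangeshift import GridSpec, make_climate_stack


@pytest.fixture(scope="session")
def spec20() -> GridSpec:
    return GridSpec(20, 20)


@pytest.fixture(scope="session")
def stack20(spec20):
    return make_climate_stack(spec20, seed=42)


@pytest.fixture(scope="session")
def spec10() -> GridSpec:
    return GridSpec(10, 10)
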