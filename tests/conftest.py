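import numpy as np
import pytest

import naivesampling as ns


@pytest.fixture(scope="session")
def exposure_set() -> ns.StimulusSet:
    return ns.generate_uniform_set(seed=101)


@pytest.fixture(scope="session")
def test_set(exposure_set) -> ns.StimulusSet:
    return ns.generate_uniform_set(seed=202, exclude=exposure_set.values)


@pytest.fixture(scope="session")
def halves(exposure_set):
    return ns.partition_unimodal_bimodal(exposure_set, seed=303)


@pytest.fixture(scope="session")
def prototypes():
    return ns.generate_prototypes()


@pytest.fixture(scope="session")
def matrices(exposure_set, test_set):
    return ns.generate_matrices(exposure_set, test_set, seed=404)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def naive_shape_index(x, p, signs):
    """Independent loop-summation oracle for the Shape Index."""
    total = 0.0
    for i in range(10):
        total += signs[i] * (x[i] - p[i])
    return total
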