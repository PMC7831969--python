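import math

import numpy as np
import pytest

from thermochain import (chain_coefficients, discretize_measure, make_ohmic,
                         thermalize)


@pytest.fixture(scope="session")
def ohmic_weak():
    """Ohmic density with the standard weak-coupling study parameters."""
    return make_ohmic(0.1, 1, 1.0)


@pytest.fixture(scope="session")
def measure_zero_t(ohmic_weak):
    return discretize_measure(thermalize(ohmic_weak, math.inf), 600)


@pytest.fixture(scope="session")
def measure_beta1(ohmic_weak):
    return discretize_measure(thermalize(ohmic_weak, 1.0), 600)


@pytest.fixture(scope="session")
def coeffs_zero_t(measure_zero_t):
    return chain_coefficients(measure_zero_t, 50)


def random_hermitian_2x2(rng):
    v = rng.normal(size=4)
    return np.array([[v[0], v[1] + 1j * v[2]],
                     [v[1] - 1j * v[2], v[3]]], dtype=complex)
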