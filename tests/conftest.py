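import numpy as np
import pytest

from cryodsd import RateModel, basic_reaction_crn, fixture_circuit

#: k(4)*C0 in /s at the 50 nM operating concentration, used by analytic oracles
K_C0 = 5.3e3 * 50e-9


@pytest.fixture(scope="session")
def model():
    return RateModel()


@pytest.fixture()
def basic_crn():
    """Basic 4-nt displacement reaction at 50 nM, no reporter."""
    return basic_reaction_crn(4, 50.0, with_reporter=False)


@pytest.fixture(params=["or", "and", "and_or", "or_and_or"])
def benchmark_circuit(request):
    return request.param, fixture_circuit(request.param)


def second_order_conversion(t, k_c0=K_C0):
    """Closed-form conversion of an equal-concentration irreversible
    bimolecular reaction: x(t) = k C0 t / (1 + k C0 t)."""
    return k_c0 * np.asarray(t) / (1.0 + k_c0 * np.asarray(t))
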