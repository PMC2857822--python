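import numpy as np
import pytest

from halotaxis import ModelSpec, apply_labeling, build_model, pre_equilibrate, simulate
from halotaxis.scenarios import standard_protocol


@pytest.fixture(scope="session")
def model6_run():
    """Model 6 wildtype, standard orange+blue protocol, pre-equilibrated."""
    model = build_model(ModelSpec(6))
    y0, converged = pre_equilibrate(model)
    assert converged
    y0 = apply_labeling(model, y0)
    res = simulate(model, standard_protocol(True), (0.0, 2600.0), y0=y0)
    return model, res


@pytest.fixture(scope="session")
def model3_run():
    """Model 3 (quadratic), standard orange protocol, pre-equilibrated."""
    model = build_model(ModelSpec(3))
    y0, converged = pre_equilibrate(model)
    assert converged
    res = simulate(model, standard_protocol(False), (0.0, 1400.0), y0=y0)
    return model, res


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
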