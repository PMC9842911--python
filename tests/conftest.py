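import pytest

from cortivasc import build_vascular_unit
from cortivasc.datasets import best_fit_params


@pytest.fixture(scope="session")
def unit_dd():
    """Default unit with the depth-dependent laminar baseline."""
    return build_vascular_unit()


@pytest.fixture(scope="session")
def unit_const():
    """Unit with the flat 2.3% laminar baseline."""
    return build_vascular_unit(baseline_mode="constant")


@pytest.fixture(scope="session")
def params_best():
    """Published best-fit hemodynamics, depth-dependent scenario."""
    return best_fit_params("depth_dependent")


@pytest.fixture(scope="session")
def params_const():
    """Published best-fit hemodynamics, constant-baseline scenario."""
    return best_fit_params("constant")
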