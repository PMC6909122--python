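import numpy as np
import pytest

import gpqa


@pytest.fixture(scope="session")
def lib():
    """Default synthetic kernel library (distorting engine)."""
    return gpqa.make_synthetic_library()


@pytest.fixture(scope="session")
def lib0():
    """Distortion-free library: the engine equals the central kernel."""
    return gpqa.make_synthetic_library(gpqa.LibraryParams(alpha=0.0))


@pytest.fixture(scope="session")
def plan():
    return gpqa.generate_synthetic_plan(seed=1)


@pytest.fixture(scope="session")
def small_plan_spec():
    """Reduced control-point count / small target for fast orchestration tests."""
    return gpqa.PlanGeneratorSpec(
        gtv_cc=(2.9, 3.5, 4.5),
        ptv_cc=(21.7, 24.0, 28.0),
        breast_cc=(722.0, 800.0, 900.0),
        n_control_points=(50.0, 60.0, 70.0),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
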