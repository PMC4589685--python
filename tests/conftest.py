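import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def aligned_field():
    """Strongly aligned synthetic fiber image (kappa 16) with ground truth."""
    from ecmkit import FiberFieldParams, generate_fiber_image

    params = FiberFieldParams(image_size_px=(192, 192), n_fibers=120,
                              orientation_kappa=16.0, seed=11)
    return generate_fiber_image(params)


@pytest.fixture(scope="session")
def isotropic_field():
    """Isotropic synthetic fiber image (kappa 0) with ground truth."""
    from ecmkit import FiberFieldParams, generate_fiber_image

    params = FiberFieldParams(image_size_px=(192, 192), n_fibers=120,
                              orientation_kappa=0.0, seed=11)
    return generate_fiber_image(params)
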