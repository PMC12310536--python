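import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_tree():
    from flysim.body import build_default_fly

    return build_default_fly()


@pytest.fixture(scope="session")
def sites_tree(default_tree):
    from flysim.body import attach_keypoint_sites, default_walking_sites

    return attach_keypoint_sites(default_tree, default_walking_sites())


@pytest.fixture(scope="session")
def hover_pattern():
    from flysim.wpg import WingBeatPattern

    return WingBeatPattern.synthetic_hover()


@pytest.fixture(scope="session")
def tuned_servo(hover_pattern):
    """Wing servo meeting the 5%-of-amplitude tracking tolerance."""
    from flysim.flight import tune_wing_actuator

    return tune_wing_actuator(hover_pattern, tolerance=0.05)


@pytest.fixture(scope="session")
def calibrated_coeffs(hover_pattern, tuned_servo):
    """Fluid coefficients whose mean lift balances body weight."""
    from flysim.flight import calibrate_fluidcoef
    from flysim.fluid import FluidCoefficients

    return calibrate_fluidcoef(
        FluidCoefficients(), hover_pattern, tuned_servo, tolerance=0.05
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
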