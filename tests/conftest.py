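import numpy as np
import pytest

from pingpongfit import (
    Calibration,
    NoiseModel,
    RateParamsHill,
    RateParamsPingPong,
    design_default_grid,
    simulate_progress_curves,
    simulate_velocities,
)

# Published global-fit constants used as simulation ground truth; the Hill
# exponent is the midpoint of the reported 1.7-2 cooperativity range.
C8_TRUTH = RateParamsHill(kcat=0.09, Kp_XCoA=139.0, Kp_ACP=16.0, h_XCoA=1.85, h_ACP=1.85)
C14_TRUTH = RateParamsHill(kcat=0.05, Kp_XCoA=111.0, Kp_ACP=8.0, h_XCoA=1.85, h_ACP=1.85)


@pytest.fixture(scope="session")
def c8_design():
    return design_default_grid("C8-CoA")


@pytest.fixture(scope="session")
def c14_design():
    return design_default_grid("C14-CoA")


@pytest.fixture(scope="session")
def c8_noiseless_velocities(c8_design):
    return simulate_velocities(C8_TRUTH, c8_design, NoiseModel(velocity_cv=0.0, seed=0))


@pytest.fixture(scope="session")
def c8_noisy_velocities(c8_design):
    return simulate_velocities(C8_TRUTH, c8_design, NoiseModel(velocity_cv=0.03, seed=1))


@pytest.fixture(scope="session")
def calibration():
    return Calibration(slope=100.0, intercept=50.0, valid_range=(0.0, 8.0))


@pytest.fixture(scope="session")
def noiseless_plate(c8_noiseless_velocities, calibration):
    quiet = NoiseModel(velocity_cv=0.0, read_sd=0.0, background_level=200.0, seed=0)
    return simulate_progress_curves(
        c8_noiseless_velocities, calibration, noise=quiet, hydrolysis_rate=6.1e-3
    )
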