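import numpy as np
import pytest
from hypothesis import settings

from torquepuck import channel_hydro as ch
from torquepuck.puck_model import PuckState, TorqueDipoleSpec

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

#: Transmission constant used as a *known input* by the analytic-layer and
#: inference tests (the solver's own convergence is tested separately).
LAMBDA_REF = 0.195


@pytest.fixture(scope="session")
def bact():
    return TorqueDipoleSpec(
        motor_torque=2.0, body_length=5.0, dipole_ratio=1.5, swim_speed=20.0
    )


@pytest.fixture(scope="session")
def puck():
    return PuckState(radius=10.0, rotational_diffusivity=6.0e-5)


@pytest.fixture(scope="session")
def geo_short():
    """Short-truncation duct for fast boundary-element tests."""
    return ch.ChannelGeometry(half_width=1.0, truncation_length=10.0,
                              panel_size=0.25, viscosity=1.0)


@pytest.fixture(scope="session")
def sol_unit_rotlet(geo_short):
    """Unit axial rotlet on the centerline of the short duct, solved once."""
    return ch.solve_channel_flow(
        geo_short, [ch.Rotlet((0.0, 0.0, 0.0), (1.0, 0.0, 0.0))]
    )


@pytest.fixture(scope="session")
def fd_oracle():
    """Independent staggered-grid Stokes solve of the same rotlet problem."""
    from stokes_fd_oracle import solve_duct_fd

    return solve_duct_fd(nx=48, n=12, Lx=8.0, mu=1.0, gamma=1.0)


@pytest.fixture(scope="session")
def lambda_converged():
    """Richardson-extrapolated Lambda on the production-scale duct (L = 20 W)."""
    geo = ch.ChannelGeometry(half_width=1.0, truncation_length=20.0)
    return ch.compute_lambda(geo, refinement_levels=[1 / 4, 1 / 5])


def lambda_single_level(solution):
    """Transmission constant read off one solved panel level."""
    top = solution.panel_wall_id == ch.WALL_TOP
    f_y = np.sum(-solution.densities[top, 1] * solution.panel_areas[top])
    return -solution.geometry.half_width * f_y
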