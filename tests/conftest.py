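import numpy as np
import pytest

from thermosteer import behavior_analysis as ba
from thermosteer import neural_circuit as nc
from thermosteer import plate_simulator as ps
from thermosteer import synthetic_data as sd


@pytest.fixture(scope="session")
def plate():
    return ps.ThermalPlate()


@pytest.fixture(scope="session")
def positive_tables():
    return sd.make_behavior_tables("positive", seed=0)


@pytest.fixture(scope="session")
def gradient_free_tables():
    return sd.make_behavior_tables("gradient_free", seed=0)


@pytest.fixture(scope="session")
def genome():
    return nc.default_genome()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def straight_trajectory(
    heading_deg=0.0, speed_cm_s=0.02, duration=60.0, dt=0.1,
    x0=3.0, y0=4.8, plate=None,
):
    """Analytic constant-velocity trajectory (no turns)."""
    plate = plate or ps.ThermalPlate()
    t = np.arange(0.0, duration + dt / 2, dt)
    x = x0 + speed_cm_s * np.cos(np.deg2rad(heading_deg)) * t
    y = y0 + speed_cm_s * np.sin(np.deg2rad(heading_deg)) * t
    return _wrap_trajectory(t, x, y, plate)


def circle_trajectory(radius_cm=0.5, speed_cm_s=0.02, duration=200.0, dt=0.1,
                      center=(6.8, 4.8), plate=None):
    """Analytic circular trajectory of given radius and speed."""
    plate = plate or ps.ThermalPlate()
    t = np.arange(0.0, duration + dt / 2, dt)
    omega = speed_cm_s / radius_cm  # rad/s
    x = center[0] + radius_cm * np.cos(omega * t)
    y = center[1] + radius_cm * np.sin(omega * t)
    return _wrap_trajectory(t, x, y, plate)


def _wrap_trajectory(t, x, y, plate, labels=None):
    from thermosteer._utils import wrap_angle

    heading = np.zeros_like(t)
    heading[:-1] = np.rad2deg(np.arctan2(np.diff(y), np.diff(x)))
    heading[-1] = heading[-2]
    theta = wrap_angle(heading - plate.warm_axis_deg)
    if labels is None:
        labels = np.full(t.size, ps.CURVE_CODE, dtype=np.int8)
    temp = plate.T_left + (plate.T_right - plate.T_left) * np.clip(
        x, 0, plate.Lx
    ) / plate.Lx
    return ps.Trajectory(
        worm_id=0, times=t, x=x, y=y, heading_deg=heading,
        theta_signed=theta, dv=np.ones(t.size, dtype=np.int8),
        labels=labels, temperature=temp, handedness=1,
    )


@pytest.fixture(scope="session")
def analysis_config():
    return ba.AnalysisConfig()
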