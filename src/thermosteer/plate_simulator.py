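"""Agent-based thermotaxis assay on a rectangular thermal-gradient plate.

Worms are dimensionless points on a 13.6 cm x 9.6 cm plate carrying a linear
temperature field along x.  At every update step a worm either executes a
stereotyped turn (omega turn, shallow turn, reversal, reversal turn), drawn
from per-second event tables, or performs a steering (curve) step in which
its heading rotates at a curving rate supplied by one of three policies:

``data``
    the curving bias is read from the empirical-style bias profile
    phi(theta) (plus Gaussian steering noise), rotating the heading toward
    the warm side at the tabulated rate;
``circuit``
    the neuroanatomical model converts the sensed temperature history into
    a curving rate psi, applied with the dorsoventral sign of the worm's
    body (d theta = DV x psi dt in the gradient-relative convention);
``profile``
    the curvature magnitude is looked up in a steering-curvature profile
    Psi(T, theta) and the steering direction is chosen uniformly at random
    each step -- curvature modulation without any directed component.

Worms reflect specularly off the plate border.  The moving direction theta
is reported relative to the vector pointing at the warm side, so theta = 0
means moving straight up the gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from thermosteer import neural_circuit as nc
from thermosteer import synthetic_data as sd
from thermosteer._utils import substream, wrap_angle

N_FRACTIONS = 8


@dataclass(frozen=True)
class ThermalPlate:
    """Rectangular arena with a linear temperature field along x.

    The plate is divided into 8 equal fractions along x for occupancy
    analysis.  The standard assays use 14-20 degC (center 17, positive
    taxis toward x = Lx) or 20-26 degC (center 23).
    """

    Lx: float = 13.6  # cm
    Ly: float = 9.6  # cm
    T_left: float = 14.0  # degC at x = 0
    T_right: float = 20.0  # degC at x = Lx

    def temperature_at(self, x):
        """Affine temperature at position x (cm); raises off-plate."""
        x = np.asarray(x, dtype=float)
        if np.any(x < 0.0) or np.any(x > self.Lx):
            raise ValueError("position outside the plate; reflect first")
        out = self.T_left + (self.T_right - self.T_left) * x / self.Lx
        return float(out) if out.ndim == 0 else out

    def fraction_of(self, x):
        """1-based fraction index of x; x = Lx maps into fraction 8."""
        x = np.asarray(x, dtype=float)
        idx = np.minimum((N_FRACTIONS * x / self.Lx).astype(int), N_FRACTIONS - 1) + 1
        return int(idx) if idx.ndim == 0 else idx

    @property
    def gradient(self) -> float:
        """Temperature gradient dT/dx in degC/cm (signed)."""
        return (self.T_right - self.T_left) / self.Lx

    @property
    def warm_sign(self) -> int:
        """+1 if the warm side is at x = Lx, -1 if at x = 0."""
        return 1 if self.T_right >= self.T_left else -1

    @property
    def warm_axis_deg(self) -> float:
        """Absolute heading (deg) of the warm-pointing vector."""
        return 0.0 if self.warm_sign > 0 else 180.0

    @property
    def default_speed_mm_s(self) -> float:
        """Locomotion speed: 0.2 mm/s near 17 degC, 0.3 near 23 degC."""
        center = self.temperature_at(self.Lx / 2.0)
        return 0.2 if center <= 20.0 else 0.3


def temperature_at(plate: ThermalPlate, x):
    return plate.temperature_at(x)


@dataclass
class AgentState:
    """Scalar worm state used by the single-step operations."""

    x: float
    y: float
    heading_deg: float  # absolute, lab frame
    handedness: int = 1  # +1 dorsal-left, -1 dorsal-right
    behavior: str = "curve"

    def theta(self, plate: ThermalPlate) -> float:
        """Unsigned moving direction relative to the warm vector, [0, 180]."""
        return abs(wrap_angle(self.heading_deg - plate.warm_axis_deg))


# ---------------------------------------------------------------------------
# steering policies


@dataclass
class DataPolicy:
    """Steering from the tabulated curving-bias profile phi(theta)."""

    tables: sd.BehaviorTables
    noise_sd: float = 3.0  # deg/s Gaussian spread around the tabulated bias
    kind: str = field(default="data", init=False)
    default_dt: float = field(default=1.0, init=False)


@dataclass
class CircuitPolicy:
    """Steering via the neuroanatomical circuit (closed or open loop)."""

    genome: nc.CircuitGenome
    kernel_spec: sd.SensoryKernelSpec = field(default_factory=sd.SensoryKernelSpec)
    tau: float = nc.DEFAULT_TAU
    ablations: tuple = ()
    noise: nc.NoiseSpec | None = None
    clamp_y1: float | None = None
    kind: str = field(default="circuit", init=False)
    default_dt: float = field(default=nc.CIRCUIT_DT, init=False)


@dataclass
class ProfilePolicy:
    """Steering magnitude from a curvature profile, sign drawn at random.

    ``profile`` is either a callable ``Psi(T, theta) -> deg/s`` accepting
    arrays, or an object exposing ``psi_at(T, theta)``.
    """

    profile: object
    kind: str = field(default="profile", init=False)
    default_dt: float = field(default=1.0, init=False)

    def psi_at(self, T, theta):
        if hasattr(self.profile, "psi_at"):
            return np.asarray(self.profile.psi_at(T, theta), dtype=float)
        return np.asarray(self.profile(T, theta), dtype=float)


# ---------------------------------------------------------------------------
# single-step operations (scalar API; the assay loop uses the same vector
# helpers internally)


def _theta_bins(theta_unsigned):
    b = (np.asarray(theta_unsigned) / 180.0 * sd.N_THETA_BINS).astype(int)
    return np.clip(b, 0, sd.N_THETA_BINS - 1)


def _region_of_fraction(frac):
    """Plate fraction 1..8 -> data region 0 (1-2), 1 (3-6), 2 (7-8)."""
    frac = np.asarray(frac)
    return np.where(frac <= 2, 0, np.where(frac <= 6, 1, 2))


def _time_bin(t: float) -> int:
    return min(int(t // 600.0), sd.N_TIMEBINS - 1)


def _sample_events(tables, theta_bin, region, time_bin, rng, dt):
    """Vectorized categorical draw; returns event index, 4 = no turn."""
    p = tables.turn_probs[:, theta_bin, region, time_bin] * dt  # (4, n)
    c = np.cumsum(p, axis=0)
    u = rng.uniform(size=theta_bin.shape)
    return (u[None, :] >= c).sum(axis=0)


def sample_turn_event(
    tables: sd.BehaviorTables,
    theta: float,
    region: int,
    time_bin: int,
    rng: np.random.Generator,
    dt: float = 1.0,
) -> str:
    """Draw one behavioral event; returns a turn-class name or 'none'.

    'none' means the step is a steering (curve) step.  Probabilities are
    per-second and rescaled by dt so rates are cadence-invariant.
    """
    if not (0 <= region < sd.N_REGIONS and 0 <= time_bin < sd.N_TIMEBINS):
        raise KeyError(f"no table row for region {region}, time bin {time_bin}")
    ev = _sample_events(
        tables, np.atleast_1d(_theta_bins(theta)), np.full(1, region, int),
        np.full(1, time_bin, int), rng, dt,
    )[0]
    return "none" if ev == len(sd.TURN_CLASSES) else sd.TURN_CLASSES[ev]


def _sample_exit_phi(dists, rng):
    """Sample exit angles Phi (deg in [0, 180]) from distribution rows."""
    c = np.cumsum(dists, axis=1)
    u = rng.uniform(size=dists.shape[0])
    bins = np.minimum((u[:, None] >= c).sum(axis=1), sd.N_PHI_BINS - 1)
    width = 180.0 / sd.N_PHI_BINS
    return bins * width + rng.uniform(0.0, width, size=dists.shape[0])


def apply_turn(
    state: AgentState,
    event: str,
    tables: sd.BehaviorTables,
    rng: np.random.Generator,
    plate: ThermalPlate | None = None,
    region: int = 1,
    time_bin: int = 0,
    dt: float = 1.0,
) -> AgentState:
    """Execute a turn: displace by the class mean (dx, dy) and redraw theta
    from the exit-direction distribution Phi."""
    if event == "none":
        raise ValueError("apply_turn requires an actual turn event")
    plate = plate or ThermalPlate()
    ci = sd.TURN_CLASSES.index(event)
    tb = _theta_bins(state.theta(plate))
    dist = tables.exit_dists[ci, tb, region, time_bin][None, :]
    phi = _sample_exit_phi(dist, rng)[0]
    sign = 1.0 if rng.uniform() < 0.5 else -1.0
    dx_mm, dy_mm = tables.displacements_mm[ci]
    new = AgentState(
        x=state.x + plate.warm_sign * dx_mm / 10.0 * dt,
        y=state.y + dy_mm / 10.0 * dt,
        heading_deg=wrap_angle(plate.warm_axis_deg + sign * phi),
        handedness=state.handedness,
        behavior=event,
    )
    new.x, new.y, new.heading_deg = reflect_at_boundary(
        (new.x, new.y), new.heading_deg, plate
    )
    return new


def reflect_at_boundary(position, heading_deg, plate: ThermalPlate):
    """Specular reflection of an off-plate proposal; returns (x, y, heading).

    Both the position overshoot and the heading are mirrored about the
    violated wall; a corner double-violation reflects in both axes.
    """
    x, y = (np.asarray(v, dtype=float) for v in position)
    a = np.asarray(heading_deg, dtype=float)
    scalar = x.ndim == 0
    x, y, a = np.atleast_1d(x.copy(), y.copy(), a.copy())
    for _ in range(2):  # twice: a large overshoot may cross again
        m = x < 0.0
        x[m] = -x[m]; a[m] = 180.0 - a[m]
        m = x > plate.Lx
        x[m] = 2.0 * plate.Lx - x[m]; a[m] = 180.0 - a[m]
        m = y < 0.0
        y[m] = -y[m]; a[m] = -a[m]
        m = y > plate.Ly
        y[m] = 2.0 * plate.Ly - y[m]; a[m] = -a[m]
    np.clip(x, 0.0, plate.Lx, out=x)
    np.clip(y, 0.0, plate.Ly, out=y)
    a = wrap_angle(a)
    if scalar:
        return float(x[0]), float(y[0]), float(a[0])
    return x, y, a


def steering_step(
    state: AgentState,
    policy,
    plate: ThermalPlate,
    dt: float,
    rng: np.random.Generator,
    psi: float | None = None,
) -> AgentState:
    """One steering (curve) update of a scalar agent.

    For the circuit policy the caller supplies the instantaneous curving
    rate ``psi`` (deg/s) from the motor neurons; the heading then changes by
    the dorsoventral-signed amount and the agent advances at speed v.
    """
    theta_rel = wrap_angle(state.heading_deg - plate.warm_axis_deg)
    if policy.kind == "circuit":
        if psi is None:
            raise ValueError("circuit policy requires psi")
        dalpha = state.handedness * psi * dt
        v_mm = policy.genome.v if policy.genome.v is not None else plate.default_speed_mm_s
    elif policy.kind == "data":
        tb = _theta_bins(abs(theta_rel))
        phi = policy.tables.bias_at(tb) + policy.noise_sd * rng.normal()
        s = 1.0 if theta_rel >= 0 else -1.0
        dalpha = -s * phi * dt
        region = int(_region_of_fraction(plate.fraction_of(state.x)))
        v_mm = float(policy.tables.speed_mm_s[region])
    elif policy.kind == "profile":
        T = plate.temperature_at(state.x)
        mag = float(policy.psi_at(T, abs(theta_rel)))
        s = 1.0 if rng.uniform() < 0.5 else -1.0
        dalpha = s * mag * dt
        v_mm = plate.default_speed_mm_s
    else:
        raise ValueError(f"unknown policy kind {policy.kind!r}")
    alpha = wrap_angle(state.heading_deg + dalpha)
    v_cm = v_mm / 10.0
    x = state.x + v_cm * np.cos(np.deg2rad(alpha)) * dt
    y = state.y + v_cm * np.sin(np.deg2rad(alpha)) * dt
    x, y, alpha = reflect_at_boundary((x, y), alpha, plate)
    return AgentState(x=x, y=y, heading_deg=alpha,
                      handedness=state.handedness, behavior="curve")


# ---------------------------------------------------------------------------
# trajectories


LABEL_CODES = {name: i for i, name in enumerate(sd.BEHAVIOR_LABELS)}
CURVE_CODE = LABEL_CODES["curve"]


@dataclass
class Trajectory:
    """Uniformly sampled record of one simulated worm."""

    worm_id: int
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    heading_deg: np.ndarray  # absolute heading, lab frame
    theta_signed: np.ndarray  # heading relative to the warm vector
    dv: np.ndarray
    labels: np.ndarray  # int codes into BEHAVIOR_LABELS
    temperature: np.ndarray
    handedness: int
    psi: np.ndarray | None = None  # circuit curving rate per step
    neural: np.ndarray | None = None  # (n, 6) potentials y1..y6

    @property
    def theta(self) -> np.ndarray:
        """Unsigned moving direction vs the warm vector, degrees [0, 180]."""
        return np.abs(self.theta_signed)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        data = {
            "worm": np.full(self.times.size, self.worm_id),
            "t": self.times,
            "x": self.x,
            "y": self.y,
            "heading": self.heading_deg,
            "theta": self.theta_signed,
            "dv": self.dv,
            "label": [sd.BEHAVIOR_LABELS[c] for c in self.labels],
            "temperature": self.temperature,
        }
        if self.psi is not None:
            data["psi"] = self.psi
        if self.neural is not None:
            for k in range(6):
                data[f"y{k + 1}"] = self.neural[:, k]
        return pd.DataFrame(data)


def save_trajectories(trajectories, path) -> None:
    frames = [tr.to_frame() for tr in trajectories]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


def load_trajectories(path, handedness: int = 1) -> list:
    df = pd.read_csv(path)
    out = []
    for wid, g in df.groupby("worm", sort=True):
        neural = None
        if "y1" in g.columns:
            neural = g[[f"y{k + 1}" for k in range(6)]].to_numpy()
        out.append(
            Trajectory(
                worm_id=int(wid),
                times=g["t"].to_numpy(),
                x=g["x"].to_numpy(),
                y=g["y"].to_numpy(),
                heading_deg=g["heading"].to_numpy(),
                theta_signed=g["theta"].to_numpy(),
                dv=g["dv"].to_numpy(),
                labels=np.array([LABEL_CODES[s] for s in g["label"]]),
                temperature=g["temperature"].to_numpy(),
                handedness=handedness,
                psi=g["psi"].to_numpy() if "psi" in g.columns else None,
                neural=neural,
            )
        )
    return out


# ---------------------------------------------------------------------------
# the assay


def run_assay(
    policy,
    plate: ThermalPlate | None = None,
    tables: sd.BehaviorTables | None = None,
    n_worms: int = 100,
    duration: float = 1800.0,
    dt: float | None = None,
    seed: int = 0,
    open_loop=None,
    turning: bool = True,
    record_every: int = 1,
    record_neural: bool = False,
) -> list:
    """Simulate ``n_worms`` independent worms and record their trajectories.

    Worms start at x = Lx/2 with random y, heading, and dorsoventral
    handedness.  ``open_loop`` (a callable T(t)) feeds a prescribed
    temperature to the circuit while the position evolves on an unbounded
    plane with turning disabled -- the simplified stimulation protocols.
    ``record_every`` thins the recorded samples by an integer stride.
    """
    plate = plate or ThermalPlate()
    if dt is None:
        dt = policy.default_dt
    if dt <= 0:
        raise ValueError("dt must be positive")
    if open_loop is not None:
        turning = False
    if turning and tables is None:
        if policy.kind == "data":
            tables = policy.tables
        else:
            raise ValueError("turning requires behavior tables")
    rng = substream(seed, "assay", policy.kind)

    n_steps = int(round(duration / dt))
    n = int(n_worms)
    if n == 0:
        return []

    x = np.full(n, plate.Lx / 2.0)
    y = rng.uniform(0.0, plate.Ly, size=n)
    alpha = rng.uniform(-180.0, 180.0, size=n)
    hand = np.where(rng.uniform(size=n) < 0.5, 1, -1)

    if policy.kind == "circuit":
        return _run_circuit_assay(
            policy, plate, tables, n_steps, dt, rng, x, y, alpha, hand,
            open_loop, turning, record_every, record_neural,
        )
    if policy.kind == "data":
        noise_sd = policy.noise_sd
    elif policy.kind != "profile":
        raise ValueError(f"unknown policy kind {policy.kind!r}")

    rec_idx = np.arange(0, n_steps + 1, record_every)
    R = _Records(rec_idx, dt, n, with_circuit=False)
    T_now = (
        float(open_loop(0.0)) * np.ones(n) if open_loop is not None
        else plate.temperature_at(x)
    )
    R.store(0, x, y, alpha, hand, plate, T_now,
            np.full(n, CURVE_CODE, np.int8))
    rec_map = {s: i for i, s in enumerate(rec_idx)}

    labels = np.full(n, CURVE_CODE, dtype=np.int8)
    for step in range(n_steps):
        t = step * dt
        if open_loop is not None:
            T_now = float(open_loop(t)) * np.ones(n)
        else:
            T_now = plate.temperature_at(x)

        # -- behavioral event
        theta_rel = wrap_angle(alpha - plate.warm_axis_deg)
        theta_u = np.abs(theta_rel)
        tb = _theta_bins(theta_u)
        if turning or policy.kind == "data":
            region = _region_of_fraction(plate.fraction_of(np.clip(x, 0, plate.Lx)))
        if turning:
            tbin = _time_bin(t)
            ev = _sample_events(tables, tb, region, np.full(n, tbin), rng, dt)
        else:
            ev = np.full(n, len(sd.TURN_CLASSES))
        curve = ev == len(sd.TURN_CLASSES)
        labels[:] = np.where(curve, CURVE_CODE, ev).astype(np.int8)

        # -- turning worms: displace and redraw heading from Phi
        ti = np.nonzero(~curve)[0]
        if ti.size:
            ci = ev[ti]
            dists = tables.exit_dists[ci, tb[ti], region[ti], tbin]
            phi_exit = _sample_exit_phi(dists, rng)
            sgn = np.where(rng.uniform(size=ti.size) < 0.5, 1.0, -1.0)
            alpha[ti] = wrap_angle(plate.warm_axis_deg + sgn * phi_exit)
            disp = tables.displacements_mm[ci] / 10.0 * dt
            x[ti] += plate.warm_sign * disp[:, 0]
            y[ti] += disp[:, 1]

        # -- steering worms
        si = np.nonzero(curve)[0]
        if si.size:
            if policy.kind == "data":
                phi = tables.bias_at(tb[si]) + noise_sd * rng.normal(size=si.size)
                s = np.where(theta_rel[si] >= 0, 1.0, -1.0)
                dalpha = -s * phi * dt
                v_step = tables.speed_mm_s[region[si]] / 10.0
            else:  # profile
                mag = policy.psi_at(T_now[si], theta_u[si])
                s = np.where(rng.uniform(size=si.size) < 0.5, 1.0, -1.0)
                dalpha = s * mag * dt
                v_step = plate.default_speed_mm_s / 10.0
            alpha[si] = wrap_angle(alpha[si] + dalpha)
            rad = np.deg2rad(alpha[si])
            x[si] += v_step * np.cos(rad) * dt
            y[si] += v_step * np.sin(rad) * dt

        if open_loop is None:
            x, y, alpha = reflect_at_boundary((x, y), alpha, plate)

        slot = rec_map.get(step + 1)
        if slot is not None:
            if open_loop is None:
                T_now = plate.temperature_at(x)
            R.store(slot, x, y, alpha, hand, plate, T_now, labels)

    return R.to_trajectories(plate, hand, record_neural=False)


class _Records:
    """Sample buffers shared by the interpreted and compiled assay paths."""

    def __init__(self, rec_idx, dt, n, with_circuit):
        n_rec = rec_idx.size
        self.times = rec_idx * dt
        self.x = np.empty((n_rec, n)); self.y = np.empty((n_rec, n))
        self.a = np.empty((n_rec, n))
        self.dv = np.empty((n_rec, n), dtype=np.int8)
        self.lab = np.full((n_rec, n), CURVE_CODE, dtype=np.int8)
        self.T = np.empty((n_rec, n))
        self.psi = np.zeros((n_rec, n)) if with_circuit else None
        self.y1 = np.zeros((n_rec, n)) if with_circuit else None
        self.neu = np.zeros((n_rec, n, 5)) if with_circuit else None

    def store(self, slot, x, y, alpha, hand, plate, T_now, labels):
        self.x[slot] = x; self.y[slot] = y; self.a[slot] = alpha
        theta_rel = wrap_angle(alpha - plate.warm_axis_deg)
        self.dv[slot] = np.where(
            hand * np.sin(np.deg2rad(theta_rel)) > 0, 1, -1
        ).astype(np.int8)
        self.T[slot] = T_now
        self.lab[slot] = labels

    def to_trajectories(self, plate, hand, record_neural):
        theta_all = wrap_angle(self.a - plate.warm_axis_deg)
        out = []
        for w in range(self.x.shape[1]):
            neural = None
            if record_neural and self.neu is not None:
                neural = np.column_stack([self.y1[:, w], self.neu[:, w, :]])
            out.append(
                Trajectory(
                    worm_id=w,
                    times=self.times.copy(),
                    x=self.x[:, w].copy(),
                    y=self.y[:, w].copy(),
                    heading_deg=self.a[:, w].copy(),
                    theta_signed=theta_all[:, w].copy(),
                    dv=self.dv[:, w].copy(),
                    labels=self.lab[:, w].copy(),
                    temperature=self.T[:, w].copy(),
                    handedness=int(hand[w]),
                    psi=self.psi[:, w].copy() if self.psi is not None else None,
                    neural=neural,
                )
            )
        return out


def _run_circuit_assay(
    policy, plate, tables, n_steps, dt, rng, x, y, alpha, hand,
    open_loop, turning, record_every, record_neural,
):
    """Closed/open-loop circuit assay via the compiled per-worm core."""
    from thermosteer import _engine

    genome = policy.genome
    dyn = nc.CircuitDynamics(
        genome, tau=policy.tau, ablations=policy.ablations, noise=policy.noise
    )
    kernel = sd.make_sensory_kernel(policy.kernel_spec)
    if abs(policy.kernel_spec.step - dt) > 1e-12:
        raise ValueError("kernel sample step must equal the simulation dt")
    kr = kernel[::-1] * dt  # history is stored oldest-first
    n = x.size
    hill = genome.hill

    if open_loop is not None:
        T_series = np.array([float(open_loop(s * dt)) for s in range(n_steps + 1)])
        T0 = np.full(n, T_series[0])
    else:
        T_series = np.zeros(1)
        T0 = plate.temperature_at(x)
    hist = np.tile(
        np.atleast_1d(nc.hill_transform(T0, hill)).astype(float)[:, None],
        (1, kernel.size),
    )
    ycirc = dyn.initial_state(n)

    if turning:
        turn_probs = tables.turn_probs
        exit_cum = np.cumsum(tables.exit_dists, axis=-1)
        disp_cm = tables.displacements_mm / 10.0
    else:
        turn_probs = np.zeros((4, sd.N_THETA_BINS, sd.N_REGIONS, sd.N_TIMEBINS))
        exit_cum = np.ones(
            (4, sd.N_THETA_BINS, sd.N_REGIONS, sd.N_TIMEBINS, sd.N_PHI_BINS)
        )
        disp_cm = np.zeros((4, 2))

    u_event = rng.uniform(size=(n_steps, n))
    u_exit = rng.uniform(size=(n_steps, n))
    u_exitbin = rng.uniform(size=(n_steps, n))
    u_sign = rng.uniform(size=(n_steps, n))

    rec_idx = np.arange(0, n_steps + 1, record_every)
    R = _Records(rec_idx, dt, n, with_circuit=True)

    clamp_nodes = np.zeros(5, dtype=np.bool_)
    for a in policy.ablations:
        if a != "AFD":
            clamp_nodes[nc.CircuitDynamics.STATE_NODES.index(a)] = True
    noise_col = -1
    noise_amp = noise_period = 1.0
    if policy.noise is not None:
        noise_col = nc.CircuitDynamics.STATE_NODES.index(policy.noise.target)
        noise_amp = policy.noise.amplitude
        noise_period = policy.noise.period

    v_mm = genome.v if genome.v is not None else plate.default_speed_mm_s
    _engine.circuit_assay_core(
        n_steps, dt, record_every,
        x, y, alpha, hand.astype(np.int64),
        hist, kr, ycirc,
        dyn._W, dyn._G, dyn._gsum, dyn._beta,
        genome.w_cpg, genome.w_nmj, dyn.t_osc, policy.tau,
        noise_col, noise_amp, noise_period,
        clamp_nodes, "AFD" in policy.ablations,
        policy.clamp_y1 is not None,
        policy.clamp_y1 if policy.clamp_y1 is not None else 0.0,
        hill.T_thr, hill.K_d, hill.n,
        plate.Lx, plate.Ly, plate.T_left, plate.T_right,
        plate.warm_axis_deg, float(plate.warm_sign), v_mm / 10.0,
        turning, turn_probs, exit_cum, disp_cm,
        open_loop is not None, T_series,
        u_event, u_exit, u_exitbin, u_sign,
        R.x, R.y, R.a, R.dv, R.lab, R.T, R.psi, R.y1, R.neu,
    )
    return R.to_trajectories(plate, hand, record_neural=record_neural)
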