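"""Synthetic stand-ins for the empirical inputs of the thermotaxis pipeline.

The simulator consumes three kinds of empirical data that are not part of
this package: tables of turning statistics measured on thermal-gradient
plates, the temperature-response kernel of the AFD (or AWC) sensory neuron,
and the reference behavior that the evolutionary search tries to match.
This module generates parametric, seeded surrogates for all three.  The
tables are sinusoidal-in-theta modulations around baseline per-second event
rates -- enough statistical structure to express the empirical regularities
(turning is more frequent when moving away from the warm side; exit
directions and curving bias favor the warm side) without fitting any real
tracker dataset.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from thermosteer._utils import substream

TURN_CLASSES = ("omega", "shallow", "reversal", "reversal_turn")
#: behavior labels recorded in trajectories: the four turn classes + curve
BEHAVIOR_LABELS = TURN_CLASSES + ("curve",)

N_THETA_BINS = 18  # 10-degree bins over [0, 180]
N_PHI_BINS = 18  # exit-direction bins, same resolution
N_REGIONS = 3  # plate fractions 1-2, 3-6, 7-8
N_TIMEBINS = 3  # 0-10, 10-20, 20-30 min

THETA_EDGES = np.linspace(0.0, 180.0, N_THETA_BINS + 1)
THETA_CENTERS = 0.5 * (THETA_EDGES[:-1] + THETA_EDGES[1:])
PHI_EDGES = np.linspace(0.0, 180.0, N_PHI_BINS + 1)
PHI_CENTERS = 0.5 * (PHI_EDGES[:-1] + PHI_EDGES[1:])

MODES = ("positive", "negative", "gradient_free")


@dataclass(frozen=True)
class TableParams:
    """Knobs of the synthetic turning statistics.

    Rates are per second.  ``base_rates`` apply when moving straight toward
    the destination; ``rate_amplitudes`` are the extra rate accrued when
    moving straight away, ramped in between as (1 - cos theta)/2.
    ``exit_bias`` sets how strongly each turn class re-orients toward the
    destination (0 = uniform exit).  ``bias_amplitude`` scales the curving
    bias profile phi(theta) = A sin(theta) in deg/s.
    """

    base_rates: tuple = (0.003, 0.004, 0.003, 0.002)
    rate_amplitudes: tuple = (0.015, 0.010, 0.010, 0.005)
    exit_bias: tuple = (0.6, 0.3, 0.2, 0.4)
    bias_amplitude: float = 1.5  # deg/s
    speed_mm_s: tuple = (0.2, 0.2, 0.2)
    region_factors: tuple = (1.0, 1.0, 1.1)
    time_factors: tuple = (1.0, 0.9, 0.8)
    jitter: float = 0.05  # multiplicative spread across region/time cells
    turn_displacements_mm: tuple = ((0.0, 0.0),) * 4


@dataclass
class BehaviorTables:
    """Per-second turning statistics and steering targets for the simulator.

    Arrays are indexed ``[class, theta_bin, region, time_bin(, phi_bin)]``.
    ``turn_probs`` holds the per-second probability of each of the four turn
    classes; the complement of their sum is the probability of a curve
    (steering) step.  ``exit_dists`` are discrete distributions over the
    exit direction Phi.  ``bias_profile`` is the empirical-style curving
    bias phi(theta) in deg/s on the theta bin centers.
    """

    mode: str
    turn_probs: np.ndarray
    exit_dists: np.ndarray
    displacements_mm: np.ndarray  # (class, 2) mean (dx, dy) in mm
    speed_mm_s: np.ndarray  # per region
    bias_profile: np.ndarray  # deg/s per theta bin
    gradient_free: bool
    seed: int
    params: TableParams = field(default_factory=TableParams)

    def validate(self) -> None:
        p = self.turn_probs
        if p.shape != (len(TURN_CLASSES), N_THETA_BINS, N_REGIONS, N_TIMEBINS):
            raise ValueError(f"bad turn_probs shape {p.shape}")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("turn probabilities outside [0, 1]")
        if np.any(p.sum(axis=0) > 1.0 + 1e-12):
            raise ValueError("turn probabilities sum above 1")
        sums = self.exit_dists.sum(axis=-1)
        if not np.allclose(sums, 1.0):
            raise ValueError("exit-direction distributions must sum to 1")
        if np.any(self.exit_dists < 0):
            raise ValueError("negative exit-direction probability")
        if self.gradient_free:
            if not np.allclose(p, p[:, ::-1]):
                raise ValueError("gradient-free tables must be theta-symmetric")

    @property
    def curve_probs(self) -> np.ndarray:
        """Per-second probability of a steering (curve) step, by index."""
        return 1.0 - self.turn_probs.sum(axis=0)

    def bias_at(self, theta_bin) -> np.ndarray:
        return self.bias_profile[np.asarray(theta_bin, dtype=int)]

    # ---- serialization ----------------------------------------------------
    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        idx = pd.MultiIndex.from_product(
            [TURN_CLASSES, range(N_THETA_BINS), range(N_REGIONS), range(N_TIMEBINS)],
            names=["turn_class", "theta_bin", "region", "time_bin"],
        )
        pd.DataFrame(
            {"probability": self.turn_probs.ravel()}, index=idx
        ).reset_index().to_csv(path / "turn_probabilities.csv", index=False)
        idx2 = pd.MultiIndex.from_product(
            [TURN_CLASSES, range(N_THETA_BINS), range(N_REGIONS),
             range(N_TIMEBINS), range(N_PHI_BINS)],
            names=["turn_class", "theta_bin", "region", "time_bin", "phi_bin"],
        )
        pd.DataFrame(
            {"probability": self.exit_dists.ravel()}, index=idx2
        ).reset_index().to_csv(path / "exit_directions.csv", index=False)
        pd.DataFrame(
            self.displacements_mm, index=list(TURN_CLASSES), columns=["dx_mm", "dy_mm"]
        ).rename_axis("turn_class").reset_index().to_csv(
            path / "turn_displacements.csv", index=False
        )
        pd.DataFrame(
            {"theta_center_deg": THETA_CENTERS, "phi_deg_per_s": self.bias_profile}
        ).to_csv(path / "bias_profile.csv", index=False)
        sidecar = {
            "mode": self.mode,
            "seed": int(self.seed),
            "gradient_free": bool(self.gradient_free),
            "speed_mm_s": [float(v) for v in self.speed_mm_s],
            "params": asdict(self.params),
        }
        with open(path / "tables.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_dir(cls, path) -> "BehaviorTables":
        path = Path(path)
        with open(path / "tables.json") as fh:
            meta = json.load(fh)
        tp = pd.read_csv(path / "turn_probabilities.csv")
        probs = tp.sort_values(["turn_class", "theta_bin", "region", "time_bin"],
                               key=_class_sort_key)
        turn_probs = probs["probability"].to_numpy().reshape(
            len(TURN_CLASSES), N_THETA_BINS, N_REGIONS, N_TIMEBINS
        )
        ed = pd.read_csv(path / "exit_directions.csv")
        ed = ed.sort_values(
            ["turn_class", "theta_bin", "region", "time_bin", "phi_bin"],
            key=_class_sort_key,
        )
        exit_dists = ed["probability"].to_numpy().reshape(
            len(TURN_CLASSES), N_THETA_BINS, N_REGIONS, N_TIMEBINS, N_PHI_BINS
        )
        disp = pd.read_csv(path / "turn_displacements.csv")
        disp = disp.set_index("turn_class").loc[list(TURN_CLASSES)]
        bias = pd.read_csv(path / "bias_profile.csv")["phi_deg_per_s"].to_numpy()
        params = meta.get("params", {})
        for k in ("base_rates", "rate_amplitudes", "exit_bias", "speed_mm_s",
                  "region_factors", "time_factors"):
            if k in params:
                params[k] = tuple(params[k])
        if "turn_displacements_mm" in params:
            params["turn_displacements_mm"] = tuple(
                tuple(d) for d in params["turn_displacements_mm"]
            )
        tables = cls(
            mode=meta["mode"],
            turn_probs=turn_probs,
            exit_dists=exit_dists,
            displacements_mm=disp[["dx_mm", "dy_mm"]].to_numpy(),
            speed_mm_s=np.asarray(meta["speed_mm_s"]),
            bias_profile=bias,
            gradient_free=meta["gradient_free"],
            seed=meta["seed"],
            params=TableParams(**params),
        )
        tables.validate()
        return tables


def _class_sort_key(col: pd.Series) -> pd.Series:
    if col.name == "turn_class":
        order = {c: i for i, c in enumerate(TURN_CLASSES)}
        return col.map(order)
    return col


def make_behavior_tables(
    mode: str, seed: int, params: TableParams | None = None
) -> BehaviorTables:
    """Generate seeded synthetic turning statistics.

    ``mode='positive'`` yields tables for worms migrating up the gradient:
    turn rates rise monotonically with theta (moving away from warm), exit
    directions and the curving-bias profile favor the warm side.
    ``'negative'`` is the mirror image under theta -> 180 - theta, and
    ``'gradient_free'`` is the direction-independent control.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if seed < 0:
        raise ValueError("seed must be non-negative")
    params = params or TableParams()
    rng = substream(seed, "behavior-tables", mode)

    theta = np.deg2rad(THETA_CENTERS)
    if mode == "positive":
        shape = (1.0 - np.cos(theta)) / 2.0  # 0 at theta=0, 1 at theta=180
    elif mode == "negative":
        shape = (1.0 + np.cos(theta)) / 2.0
    else:
        shape = np.full(N_THETA_BINS, 0.5)

    base = np.asarray(params.base_rates)[:, None]
    amp = np.asarray(params.rate_amplitudes)[:, None]
    rate_theta = base + amp * shape[None, :]  # (class, theta)

    factors = (
        np.asarray(params.region_factors)[:, None]
        * np.asarray(params.time_factors)[None, :]
    )  # (region, time)
    jitter = 1.0 + params.jitter * rng.uniform(
        -1.0, 1.0, size=(len(TURN_CLASSES), N_REGIONS, N_TIMEBINS)
    )
    turn_probs = (
        rate_theta[:, :, None, None]
        * factors[None, None, :, :]
        * jitter[:, None, :, :]
    )
    turn_probs = np.clip(turn_probs, 0.0, 1.0)

    phi = np.deg2rad(PHI_CENTERS)
    kappa = np.asarray(params.exit_bias)
    if mode == "gradient_free":
        kappa = np.zeros_like(kappa)
    sign = -1.0 if mode == "negative" else 1.0
    weights = 1.0 + sign * kappa[:, None] * np.cos(phi)[None, :]  # (class, phi)
    weights = np.clip(weights, 1e-9, None)
    dists = weights / weights.sum(axis=1, keepdims=True)
    exit_dists = np.broadcast_to(
        dists[:, None, None, None, :],
        (len(TURN_CLASSES), N_THETA_BINS, N_REGIONS, N_TIMEBINS, N_PHI_BINS),
    ).copy()

    if mode == "positive":
        bias = params.bias_amplitude * np.sin(theta)
    elif mode == "negative":
        bias = -params.bias_amplitude * np.sin(theta)
    else:
        bias = np.zeros(N_THETA_BINS)

    tables = BehaviorTables(
        mode=mode,
        turn_probs=turn_probs,
        exit_dists=exit_dists,
        displacements_mm=np.asarray(params.turn_displacements_mm, dtype=float),
        speed_mm_s=np.asarray(params.speed_mm_s, dtype=float),
        bias_profile=bias,
        gradient_free=(mode == "gradient_free"),
        seed=int(seed),
        params=params,
    )
    tables.validate()
    return tables


# ---------------------------------------------------------------------------
# sensory kernels


@dataclass(frozen=True)
class SensoryKernelSpec:
    """Parametric stand-in for a thermosensory response kernel.

    Both families are differences/sums of two exponential lobes sampled on
    the AFD history window.  The AFD-like kernel is biphasic (fast positive
    lobe, slow negative lobe) and is normalized so its discrete integral is
    ~0: it behaves as a differentiator, responding to temperature change and
    ignoring constant offsets.  The AWC-like variant flips the slow lobe's
    sign, producing a same-sign, integrator-like kernel.
    """

    family: str = "AFD"  # or "AWC"
    duration: float = 100.0  # s
    step: float = 0.1  # s
    fast_amplitude: float = 1.0
    fast_tau: float = 2.0  # s
    slow_amplitude: float = 1.0
    slow_tau: float = 25.0  # s

    def __post_init__(self):
        if self.family not in ("AFD", "AWC"):
            raise ValueError(f"kernel family must be AFD or AWC, got {self.family}")
        if self.step <= 0:
            raise ValueError("sample step must be positive")
        if self.fast_tau <= 0 or self.slow_tau <= 0:
            raise ValueError("time constants must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration / self.step)) + 1


def make_sensory_kernel(spec: SensoryKernelSpec) -> np.ndarray:
    """Sample the kernel r(t) on [0, duration], lag 0 first.

    For the AFD-like family the slow (negative) lobe is rescaled so that the
    discrete quadrature ``sum(r) * step`` vanishes exactly; convolution with
    a constant input then returns (numerically) zero.
    """
    t = np.arange(spec.n_samples) * spec.step
    fast = (spec.fast_amplitude / spec.fast_tau) * np.exp(-t / spec.fast_tau)
    slow = (spec.slow_amplitude / spec.slow_tau) * np.exp(-t / spec.slow_tau)
    if spec.family == "AFD":
        ssum = slow.sum()
        if ssum > 0 and spec.fast_amplitude != 0:
            slow = slow * (fast.sum() / ssum)
        kernel = fast - slow
    else:
        kernel = fast + slow
    return kernel


# ---------------------------------------------------------------------------
# reference targets


@dataclass
class ReferenceTargets:
    """Targets the evolutionary search scores genomes against.

    ``ttx_times``/``ttx_reference`` hold the thermotaxis-index time course
    produced by a data-based plate simulation; ``bias_reference`` is the
    curving-bias profile phi(theta) the tables encode, on the same theta
    bins as :class:`BehaviorTables`.
    """

    ttx_times: np.ndarray
    ttx_reference: np.ndarray
    bias_reference: np.ndarray
    theta_centers: np.ndarray
    n_worms: int
    seed: int

    def validate(self) -> None:
        if np.any(np.abs(self.ttx_reference) > 1.0 + 1e-9):
            raise ValueError("TTX reference outside [-1, 1]")
        if self.bias_reference.shape != self.theta_centers.shape:
            raise ValueError("bias profile and theta grid mismatch")

    def to_csv(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"time_s": self.ttx_times, "ttx_index": self.ttx_reference}
        ).to_csv(path / "ttx_reference.csv", index=False)
        pd.DataFrame(
            {"theta_center_deg": self.theta_centers,
             "phi_deg_per_s": self.bias_reference}
        ).to_csv(path / "bias_reference.csv", index=False)

    @classmethod
    def from_csv(cls, path, n_worms: int = 0, seed: int = 0) -> "ReferenceTargets":
        path = Path(path)
        ttx = pd.read_csv(path / "ttx_reference.csv")
        bias = pd.read_csv(path / "bias_reference.csv")
        return cls(
            ttx_times=ttx["time_s"].to_numpy(),
            ttx_reference=ttx["ttx_index"].to_numpy(),
            bias_reference=bias["phi_deg_per_s"].to_numpy(),
            theta_centers=bias["theta_center_deg"].to_numpy(),
            n_worms=n_worms,
            seed=seed,
        )


def make_reference_targets(
    tables: BehaviorTables,
    plate=None,
    n_worms: int = 100,
    duration: float = 1800.0,
    seed: int = 0,
    ttx_interval: float = 10.0,
) -> ReferenceTargets:
    """Run the data-based simulation and collect its TTX time course.

    The reference curving-bias profile is taken directly from the tables
    (it is the quantity the data-based steering reproduces by construction).
    """
    from thermosteer import plate_simulator as ps
    from thermosteer.behavior_analysis import ttx_index

    tables.validate()
    plate = plate or ps.ThermalPlate()
    trajs = ps.run_assay(
        policy=ps.DataPolicy(tables),
        plate=plate,
        tables=tables,
        n_worms=n_worms,
        duration=duration,
        dt=1.0,
        seed=seed,
    )
    times = np.arange(0.0, duration + 0.5 * ttx_interval, ttx_interval)
    series = ttx_index(trajs, plate, times=times)
    targets = ReferenceTargets(
        ttx_times=series.times,
        ttx_reference=series.values,
        bias_reference=tables.bias_profile.copy(),
        theta_centers=THETA_CENTERS.copy(),
        n_worms=n_worms,
        seed=int(seed),
    )
    targets.validate()
    return targets
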