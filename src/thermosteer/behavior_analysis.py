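"""Behavioral statistics computed from simulated trajectories.

The analysis mirrors what multi-worm tracker pipelines do to empirical
plates: positions are smoothed with a 4.2 s moving-mean filter (one
undulation period, so the sinusoidal body wiggle cancels), the moving
direction theta is the angle of the vector from the current centroid to the
centroid 1 s later, the steering curvature Psi is the unsigned angle between
successive 1 s directions, and the curving bias phi signs Psi by whether the
heading rotated toward the warm side.  Frames within +-4.2 s of a turn are
excluded from curvature statistics.  The thermotaxis (TTX) index summarizes
population migration as a weighted occupancy over the plate's 8 fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from thermosteer import neural_circuit as nc
from thermosteer import plate_simulator as ps
from thermosteer import synthetic_data as sd
from thermosteer._utils import wrap_angle


@dataclass(frozen=True)
class AnalysisConfig:
    smoothing_window: float = 4.2  # s, moving-mean width
    direction_step: float = 1.0  # s between centroids defining theta
    turn_margin: float = 4.2  # s excluded on each side of a turn
    theta_bin_width: float = 10.0  # deg, profile resolution
    temp_bin_width: float = 1.0  # degC, profile resolution
    #: frames this close (cm) to a plate wall are excluded from curvature
    #: statistics -- boundary reflections corrupt the heading there
    border_margin_cm: float = 0.3

    def __post_init__(self):
        if self.smoothing_window <= 0 or self.turn_margin < 0:
            raise ValueError("window and margin must be positive")


@dataclass
class HeadingSeries:
    """Smoothed centroid track with per-frame moving directions.

    ``dir_deg`` is NaN on the trailing frames where no 1-s-later centroid
    exists; ``turn_excluded`` flags frames within the +-margin of any turn.
    """

    times: np.ndarray
    cx: np.ndarray
    cy: np.ndarray
    dir_deg: np.ndarray
    theta_signed: np.ndarray  # direction relative to the warm vector
    turn_excluded: np.ndarray
    dt: float
    step: int  # samples per direction_step

    @property
    def theta(self) -> np.ndarray:
        return np.abs(self.theta_signed)


def smooth_and_heading(
    trajectory: ps.Trajectory,
    config: AnalysisConfig | None = None,
    plate: ps.ThermalPlate | None = None,
) -> HeadingSeries:
    """Moving-mean centroid plus 1-s moving directions for one worm.

    The smoothing window shrinks at the series ends (truncated mean) so no
    frames are discarded.  Returns an empty series if the trajectory is
    shorter than the smoothing window.
    """
    config = config or AnalysisConfig()
    plate = plate or ps.ThermalPlate()
    dt = trajectory.dt
    n = trajectory.times.size
    if dt <= 0 or n * dt < config.smoothing_window:
        return HeadingSeries(*(np.empty(0),) * 6, dt=dt, step=0)
    if dt > config.direction_step + 1e-12:
        raise ValueError("trajectory must be sampled at <= the direction step")

    # window spans exactly the configured duration; when that is one
    # undulation period the boxcar nulls the oscillation exactly
    w = max(1, int(round(config.smoothing_window / dt)))
    cx = pd.Series(trajectory.x).rolling(w, center=True, min_periods=1).mean().to_numpy()
    cy = pd.Series(trajectory.y).rolling(w, center=True, min_periods=1).mean().to_numpy()

    step = int(round(config.direction_step / dt))
    dir_deg = np.full(n, np.nan)
    dx = cx[step:] - cx[:-step]
    dy = cy[step:] - cy[:-step]
    dir_deg[: n - step] = np.rad2deg(np.arctan2(dy, dx))
    still = (dx == 0) & (dy == 0)
    dir_deg[: n - step][still] = np.nan

    theta_signed = wrap_angle(dir_deg - plate.warm_axis_deg)

    is_turn = trajectory.labels != ps.CURVE_CODE
    m = int(round(config.turn_margin / dt))
    if m > 0 and is_turn.any():
        kernel = np.ones(2 * m + 1)
        excluded = np.convolve(is_turn.astype(float), kernel, mode="same") > 0
    else:
        excluded = is_turn.copy()
    b = config.border_margin_cm
    if b > 0:
        excluded = excluded | (
            (trajectory.x < b) | (trajectory.x > plate.Lx - b)
            | (trajectory.y < b) | (trajectory.y > plate.Ly - b)
        )

    return HeadingSeries(
        times=trajectory.times.copy(),
        cx=cx,
        cy=cy,
        dir_deg=dir_deg,
        theta_signed=theta_signed,
        turn_excluded=excluded,
        dt=dt,
        step=step,
    )


@dataclass
class CurvatureSeries:
    """Steering curvature Psi (deg/s) with its validity mask."""

    times: np.ndarray
    psi: np.ndarray  # NaN where undefined
    valid: np.ndarray  # finite and outside turn margins


def curvature_series(heading: HeadingSeries) -> CurvatureSeries:
    """Psi(t): unsigned angle between the directions 1 s apart.

    Frames within the turn-exclusion margin, or whose defining directions
    are undefined, are marked invalid (their Psi is NaN).
    """
    n = heading.times.size
    psi = np.full(n, np.nan)
    step = heading.step
    if n == 0 or step == 0:
        return CurvatureSeries(heading.times, psi, np.zeros(n, dtype=bool))
    prev = heading.dir_deg[: n - step]
    cur = heading.dir_deg[step:]
    d = np.abs(wrap_angle(cur - prev)) / (step * heading.dt)
    psi[step:] = d
    valid = np.isfinite(psi) & ~heading.turn_excluded
    psi[~valid] = np.nan
    return CurvatureSeries(heading.times.copy(), psi, valid)


def curving_bias_series(
    curvature: CurvatureSeries, heading: HeadingSeries
) -> np.ndarray:
    """phi(t): +Psi when the heading rotated toward the warm side, -Psi away.

    A frame whose unsigned theta did not change (or whose Psi is invalid)
    gets phi = 0 / NaN respectively.
    """
    n = heading.times.size
    phi = np.full(n, np.nan)
    step = heading.step
    if n == 0 or step == 0:
        return phi
    th = np.abs(heading.theta_signed)
    dth = th[step:] - th[: n - step]
    sign = np.sign(-dth)
    phi[step:] = sign * curvature.psi[step:]
    phi[~curvature.valid] = np.nan
    return phi


@dataclass
class TTXSeries:
    """Thermotaxis-index time course with its fraction weighting."""

    times: np.ndarray
    values: np.ndarray
    weights: np.ndarray

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "ttx_index": self.values}).to_csv(
            path, index=False
        )


def default_ttx_weights() -> np.ndarray:
    """Linear antisymmetric weights c_k = (2k - 9)/7 for fractions 1..8.

    The coldest fraction scores -1 and the warmest +1 (warm side at the
    high-fraction end), so the index of a population lies in [-1, 1].
    """
    k = np.arange(1, ps.N_FRACTIONS + 1)
    return (2 * k - 9) / 7.0


def ttx_index(
    trajectories,
    plate: ps.ThermalPlate | None = None,
    weighting=None,
    times=None,
) -> TTXSeries:
    """Weighted fraction-occupancy index over time for a set of worms."""
    if len(trajectories) == 0:
        raise ValueError("TTX index requires at least one trajectory")
    plate = plate or ps.ThermalPlate()
    w = np.asarray(weighting if weighting is not None else default_ttx_weights())
    if plate.warm_sign < 0:
        w = w[::-1]  # warm side at x = 0: mirror the weighting
    t0 = trajectories[0].times
    if times is None:
        times = t0
    times = np.asarray(times, dtype=float)
    dt = trajectories[0].dt
    idx = np.clip(np.round(times / dt).astype(int) if dt > 0 else np.zeros_like(times, int),
                  0, t0.size - 1)
    xs = np.stack([tr.x[idx] for tr in trajectories])  # (worms, times)
    frac = np.minimum((ps.N_FRACTIONS * xs / plate.Lx).astype(int),
                      ps.N_FRACTIONS - 1)
    values = w[frac].mean(axis=0)
    return TTXSeries(times=times, values=values, weights=w)


@dataclass
class CurvatureProfile:
    """Mean steering curvature Psi on a temperature x theta grid."""

    temp_edges: np.ndarray
    theta_edges: np.ndarray
    mean_psi: np.ndarray  # (n_temp, n_theta), NaN where empty
    counts: np.ndarray

    @property
    def temp_centers(self) -> np.ndarray:
        return 0.5 * (self.temp_edges[:-1] + self.temp_edges[1:])

    @property
    def theta_centers(self) -> np.ndarray:
        return 0.5 * (self.theta_edges[:-1] + self.theta_edges[1:])

    def __post_init__(self):
        # lookup table with empty cells filled from the theta-column mean,
        # then the global mean, so psi_at is a total function
        occ = self.counts > 0
        vals = np.where(occ, np.nan_to_num(self.mean_psi), 0.0)
        n_col = occ.sum(axis=0)
        overall = vals.sum() / occ.sum() if occ.any() else 0.0
        col = np.where(n_col > 0, vals.sum(axis=0) / np.maximum(n_col, 1), overall)
        self._lookup = np.where(occ, np.nan_to_num(self.mean_psi), col[None, :])

    def psi_at(self, T, theta):
        """Nearest-cell profile lookup, defined for any (T, theta)."""
        ti = np.clip(
            np.searchsorted(self.temp_edges, np.asarray(T, float), "right") - 1,
            0, self.temp_edges.size - 2,
        )
        hi = np.clip(
            np.searchsorted(self.theta_edges, np.asarray(theta, float), "right") - 1,
            0, self.theta_edges.size - 2,
        )
        return self._lookup[ti, hi]

    def marginal_theta(self) -> np.ndarray:
        """Count-weighted mean Psi per theta bin over occupied cells."""
        with np.errstate(invalid="ignore"):
            num = np.nansum(self.mean_psi * self.counts, axis=0)
        den = self.counts.sum(axis=0)
        return np.where(den > 0, num / np.maximum(den, 1), np.nan)

    @classmethod
    def from_function(cls, fn, temp_edges, theta_edges) -> "CurvatureProfile":
        """Build a synthetic profile by evaluating Psi(T, theta) at centers."""
        temp_edges = np.asarray(temp_edges, float)
        theta_edges = np.asarray(theta_edges, float)
        tc = 0.5 * (temp_edges[:-1] + temp_edges[1:])
        hc = 0.5 * (theta_edges[:-1] + theta_edges[1:])
        grid = np.broadcast_to(
            np.asarray(fn(tc[:, None], hc[None, :]), dtype=float),
            (tc.size, hc.size),
        ).copy()
        return cls(temp_edges, theta_edges, grid, np.ones_like(grid, dtype=int))

    def to_csv(self, path) -> None:
        rows = []
        for i, T in enumerate(self.temp_centers):
            for j, th in enumerate(self.theta_centers):
                rows.append(
                    {"temp_center": T, "theta_center": th,
                     "mean_psi": self.mean_psi[i, j], "count": self.counts[i, j]}
                )
        pd.DataFrame(rows).to_csv(path, index=False)


def curvature_profile(
    trajectories,
    plate: ps.ThermalPlate | None = None,
    config: AnalysisConfig | None = None,
    temp_edges=None,
    theta_edges=None,
) -> CurvatureProfile:
    """Accumulate mean Psi on the (temperature, theta) grid over worms."""
    plate = plate or ps.ThermalPlate()
    config = config or AnalysisConfig()
    lo, hi = sorted((plate.T_left, plate.T_right))
    if temp_edges is None:
        temp_edges = np.arange(lo, hi + config.temp_bin_width / 2, config.temp_bin_width)
    if theta_edges is None:
        theta_edges = np.arange(0.0, 180.0 + config.theta_bin_width / 2,
                                config.theta_bin_width)
    temp_edges = np.asarray(temp_edges, float)
    theta_edges = np.asarray(theta_edges, float)
    nT, nH = temp_edges.size - 1, theta_edges.size - 1
    s = np.zeros((nT, nH))
    c = np.zeros((nT, nH), dtype=int)
    for tr in trajectories:
        head = smooth_and_heading(tr, config, plate)
        if head.times.size == 0:
            continue
        curv = curvature_series(head)
        v = curv.valid
        if not v.any():
            continue
        T = tr.temperature[v]
        th = head.theta[v]
        psi = curv.psi[v]
        ti = np.clip(np.searchsorted(temp_edges, T, "right") - 1, 0, nT - 1)
        hi_ = np.clip(np.searchsorted(theta_edges, th, "right") - 1, 0, nH - 1)
        np.add.at(s, (ti, hi_), psi)
        np.add.at(c, (ti, hi_), 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(c > 0, s / np.maximum(c, 1), np.nan)
    return CurvatureProfile(temp_edges, theta_edges, mean, c)


def bias_profile_from_trajectories(
    trajectories,
    plate: ps.ThermalPlate | None = None,
    config: AnalysisConfig | None = None,
    theta_edges=None,
):
    """Mean curving bias phi per theta bin (the Fig-1E-style profile).

    theta is taken at the frame's *previous* direction (the entry direction
    of the rotation).  Returns (theta_centers, mean_phi, counts); bins with
    no valid frames hold NaN.
    """
    plate = plate or ps.ThermalPlate()
    config = config or AnalysisConfig()
    if theta_edges is None:
        theta_edges = np.arange(0.0, 180.0 + config.theta_bin_width / 2,
                                config.theta_bin_width)
    theta_edges = np.asarray(theta_edges, float)
    nH = theta_edges.size - 1
    s = np.zeros(nH)
    c = np.zeros(nH, dtype=int)
    for tr in trajectories:
        head = smooth_and_heading(tr, config, plate)
        if head.times.size == 0:
            continue
        curv = curvature_series(head)
        phi = curving_bias_series(curv, head)
        n = head.times.size
        step = head.step
        entry = np.full(n, np.nan)
        entry[step:] = head.theta[: n - step]
        v = np.isfinite(phi) & np.isfinite(entry)
        if not v.any():
            continue
        hi_ = np.clip(np.searchsorted(theta_edges, entry[v], "right") - 1, 0, nH - 1)
        np.add.at(s, hi_, phi[v])
        np.add.at(c, hi_, 1)
    centers = 0.5 * (theta_edges[:-1] + theta_edges[1:])
    mean = np.where(c > 0, s / np.maximum(c, 1), np.nan)
    return centers, mean, c


# ---------------------------------------------------------------------------
# simplified stimulation protocols


PROTOCOLS = ("constant", "sinusoid", "ramp_up", "ramp_down", "afd_clamp")


@dataclass
class ProtocolSettings:
    """Open-loop stimulation parameters (the simplified assays).

    The sinusoid emulates the thermal oscillation sensed through head swings
    on a 0.5 degC/cm gradient (amplitude 0.01 degC at the undulation
    period); the ramps emulate steady up/down-gradient movement at
    0.2 mm/s, i.e. +-0.01 degC/s, clipped to the plate's range.
    """

    T0: float = 17.0  # degC starting / constant temperature
    amplitude: float = 0.01  # degC, sinusoid
    period: float = nc.DEFAULT_T_OSC  # s, sinusoid
    rate: float = 0.01  # degC/s, ramps
    T_range: tuple = (14.0, 20.0)
    clamp_y1: float = 0.0  # AFD clamp value
    duration: float = 300.0  # s
    n_worms: int = 10
    dt: float = nc.CIRCUIT_DT
    kernel_spec: sd.SensoryKernelSpec = field(default_factory=sd.SensoryKernelSpec)


@dataclass
class ProtocolResult:
    protocol: str
    trajectories: list
    mean_psi: float
    psi_values: np.ndarray
    settings: ProtocolSettings


def open_loop_temperature(protocol: str, settings: ProtocolSettings):
    """The prescribed T(t) for each open-loop protocol."""
    lo, hi = settings.T_range
    if protocol in ("constant", "afd_clamp"):
        return lambda t: settings.T0
    if protocol == "sinusoid":
        return lambda t: settings.T0 + settings.amplitude * np.sin(
            2.0 * np.pi * t / settings.period
        )
    if protocol == "ramp_up":
        return lambda t: min(settings.T0 + settings.rate * t, hi)
    if protocol == "ramp_down":
        return lambda t: max(settings.T0 - settings.rate * t, lo)
    raise ValueError(f"unknown protocol {protocol!r}; expected one of {PROTOCOLS}")


def protocol_run(
    genome: nc.CircuitGenome,
    protocol: str,
    settings: ProtocolSettings | None = None,
    seed: int = 0,
    config: AnalysisConfig | None = None,
) -> ProtocolResult:
    """Run one simplified protocol: open-loop stimulus, turning disabled.

    Temperature is fed to the circuit as the prescribed T(t) (or AFD is
    clamped to a fixed y1) while the worm's position evolves freely; the
    returned summary is the mean steering curvature Psi over all valid
    frames of all worms.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; expected one of {PROTOCOLS}")
    settings = settings or ProtocolSettings()
    stim = open_loop_temperature(protocol, settings)
    policy = ps.CircuitPolicy(
        genome=genome,
        kernel_spec=settings.kernel_spec,
        clamp_y1=settings.clamp_y1 if protocol == "afd_clamp" else None,
    )
    plate = ps.ThermalPlate(T_left=settings.T_range[0], T_right=settings.T_range[1])
    trajs = ps.run_assay(
        policy=policy,
        plate=plate,
        tables=None,
        n_worms=settings.n_worms,
        duration=settings.duration,
        dt=settings.dt,
        seed=seed,
        open_loop=stim,
        record_neural=True,
    )
    config = config or AnalysisConfig()
    values = []
    for tr in trajs:
        head = smooth_and_heading(tr, config, plate)
        if head.times.size == 0:
            continue
        curv = curvature_series(head)
        values.append(curv.psi[curv.valid])
    psi_values = np.concatenate(values) if values else np.empty(0)
    mean_psi = float(np.mean(psi_values)) if psi_values.size else float("nan")
    return ProtocolResult(
        protocol=protocol,
        trajectories=trajs,
        mean_psi=mean_psi,
        psi_values=psi_values,
        settings=settings,
    )
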