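"""Experiment configuration, manifests, and the pipeline entry points.

Every runnable stage (table synthesis, assays, evolution, protocols,
analysis, decomposition, dependence measures) is driven by one
:class:`ExperimentConfig` and writes its outputs next to a ``manifest.json``
recording the seed, the effective configuration, its hash, and the package
version -- enough to re-run the stage bit-for-bit.  All randomness flows
from the single top-level seed through named substreams.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from thermosteer import __version__
from thermosteer import behavior_analysis as ba
from thermosteer import evolutionary_search as es
from thermosteer import infotheory as it
from thermosteer import plate_simulator as ps
from thermosteer import ssa_decomposition as ssa_mod
from thermosteer import synthetic_data as sd
from thermosteer.neural_circuit import CircuitGenome, default_genome


class ConfigError(ValueError):
    """Invalid or inconsistent experiment configuration."""


@dataclass
class ExperimentConfig:
    """Flat bundle of the knobs shared by the pipeline stages."""

    seed: int = 0
    mode: str = "positive"  # table mode: positive / negative / gradient_free
    kernel_family: str = "AFD"  # or AWC
    extended_genome: bool = False
    ablations: tuple = ()
    # plate
    T_left: float = 14.0
    T_right: float = 20.0
    # assay
    policy: str = "data"  # data / circuit / profile
    n_worms: int = 100
    duration: float = 1800.0
    genome_file: str | None = None
    tables_dir: str | None = None
    # evolution
    population_size: int = 16
    generations: int = 30
    assay_n_worms: int = 12
    assay_duration: float = 240.0
    # protocol
    protocol: str = "constant"
    # analysis / decomposition
    trajectories_file: str | None = None
    ssa_window_s: float = ssa_mod.DEFAULT_WINDOW_S
    ssa_channel: str = "y5"
    info_x: str = "y1"
    info_y: str = "psi"
    worm: int = 0

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "ExperimentConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**payload)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        problems = []
        if self.mode not in sd.MODES:
            problems.append(f"mode must be one of {sd.MODES}, got {self.mode!r}")
        if self.kernel_family not in ("AFD", "AWC"):
            problems.append(f"kernel_family must be AFD or AWC, got {self.kernel_family!r}")
        if self.policy not in ("data", "circuit", "profile"):
            problems.append(f"policy must be data/circuit/profile, got {self.policy!r}")
        if self.n_worms < 0 or self.duration <= 0:
            problems.append("n_worms must be >= 0 and duration positive")
        for name in ("genome_file", "tables_dir", "trajectories_file"):
            val = getattr(self, name)
            if val is not None and not Path(val).exists():
                problems.append(f"{name} does not exist: {val}")
        if self.protocol not in ba.PROTOCOLS:
            problems.append(f"protocol must be one of {ba.PROTOCOLS}")
        if problems:
            raise ConfigError("; ".join(problems))

    def plate(self) -> ps.ThermalPlate:
        return ps.ThermalPlate(T_left=self.T_left, T_right=self.T_right)

    def kernel_spec(self, step: float | None = None) -> sd.SensoryKernelSpec:
        kwargs = {"family": self.kernel_family}
        if step is not None:
            kwargs["step"] = step
        return sd.SensoryKernelSpec(**kwargs)


def config_hash(config: ExperimentConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_manifest(out_dir, command: str, config: ExperimentConfig, extra=None):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "seed": int(config.seed),
        "config": asdict(config),
        "config_hash": config_hash(config),
        "version": __version__,
    }
    if extra:
        manifest.update(extra)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return manifest


# ---------------------------------------------------------------------------
# stage runners


def _load_tables(config: ExperimentConfig) -> sd.BehaviorTables:
    if config.tables_dir is not None:
        return sd.BehaviorTables.from_dir(config.tables_dir)
    return sd.make_behavior_tables(config.mode, config.seed)


def _load_genome(config: ExperimentConfig) -> CircuitGenome:
    if config.genome_file is not None:
        return CircuitGenome.from_json(config.genome_file)
    return default_genome()


def run_synth(config: ExperimentConfig, out_dir) -> dict:
    out_dir = Path(out_dir)
    tables = sd.make_behavior_tables(config.mode, config.seed)
    tables.to_dir(out_dir / "tables")
    spec = config.kernel_spec()
    kernel = sd.make_sensory_kernel(spec)
    pd.DataFrame(
        {"lag_s": np.arange(spec.n_samples) * spec.step, "r": kernel}
    ).to_csv(out_dir / "kernel.csv", index=False)
    refs = sd.make_reference_targets(
        tables, config.plate(), n_worms=config.n_worms,
        duration=config.duration, seed=config.seed,
    )
    refs.to_csv(out_dir / "references")
    return {"tables": str(out_dir / "tables"), "kernel": str(out_dir / "kernel.csv"),
            "references": str(out_dir / "references")}


def run_simulate(config: ExperimentConfig, out_dir) -> dict:
    out_dir = Path(out_dir)
    tables = _load_tables(config)
    plate = config.plate()
    if config.policy == "circuit":
        if config.genome_file is None:
            raise ConfigError("circuit policy requires genome_file")
        policy = ps.CircuitPolicy(
            genome=_load_genome(config), kernel_spec=config.kernel_spec(),
            ablations=tuple(config.ablations),
        )
    elif config.policy == "data":
        policy = ps.DataPolicy(tables)
    else:
        raise ConfigError("profile simulations are driven via the library API")
    trajs = ps.run_assay(
        policy, plate, tables, n_worms=config.n_worms,
        duration=config.duration, seed=config.seed,
        record_neural=(config.policy == "circuit"),
    )
    path = out_dir / "trajectories.csv"
    ps.save_trajectories(trajs, path)
    return {"trajectories": str(path), "n_worms": config.n_worms}


def run_evolve(config: ExperimentConfig, out_dir) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = _load_tables(config)
    plate = config.plate()
    search = es.SearchConfig(
        population_size=config.population_size,
        generations=config.generations,
        extended=config.extended_genome,
        assay_n_worms=config.assay_n_worms,
        assay_duration=config.assay_duration,
    )
    refs = sd.make_reference_targets(
        tables, plate, n_worms=100, duration=search.assay_duration,
        seed=config.seed, ttx_interval=search.ttx_interval,
    )
    result = es.ga_run(
        search, refs, tables, plate, seed=config.seed,
        kernel_spec=config.kernel_spec(),
    )
    result.log.to_csv(out_dir / "evolution_log.csv", index=False)
    result.best_genome.to_json(out_dir / "best_genome.json")
    return {"best_fitness": result.best_fitness,
            "log": str(out_dir / "evolution_log.csv"),
            "best_genome": str(out_dir / "best_genome.json")}


def run_protocol(config: ExperimentConfig, out_dir) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    settings = ba.ProtocolSettings(
        T_range=(min(config.T_left, config.T_right),
                 max(config.T_left, config.T_right)),
        kernel_spec=config.kernel_spec(),
    )
    result = ba.protocol_run(
        _load_genome(config), config.protocol, settings, seed=config.seed
    )
    ps.save_trajectories(result.trajectories, out_dir / "trajectories.csv")
    with open(out_dir / "psi_summary.json", "w") as fh:
        json.dump({"protocol": config.protocol, "mean_psi": result.mean_psi,
                   "n_frames": int(result.psi_values.size)}, fh, indent=2)
        fh.write("\n")
    return {"protocol": config.protocol, "mean_psi": result.mean_psi}


def run_analyze(config: ExperimentConfig, out_dir) -> dict:
    if config.trajectories_file is None:
        raise ConfigError("analyze requires trajectories_file")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plate = config.plate()
    trajs = ps.load_trajectories(config.trajectories_file)
    ba.ttx_index(trajs, plate).to_csv(out_dir / "ttx_index.csv")
    centers, phi, counts = ba.bias_profile_from_trajectories(trajs, plate)
    pd.DataFrame(
        {"theta_center_deg": centers, "phi_deg_per_s": phi, "count": counts}
    ).to_csv(out_dir / "bias_profile.csv", index=False)
    ba.curvature_profile(trajs, plate).to_csv(out_dir / "curvature_profile.csv")
    return {"out": str(out_dir)}


def run_ssa(config: ExperimentConfig, out_dir) -> dict:
    if config.trajectories_file is None:
        raise ConfigError("ssa requires trajectories_file")
    trajs = ps.load_trajectories(config.trajectories_file)
    tr = trajs[config.worm]
    if tr.neural is None:
        raise ConfigError("trajectories carry no neural channels")
    channels = {f"y{k + 1}": k for k in range(6)}
    if config.ssa_channel not in channels:
        raise ConfigError(f"ssa_channel must be one of {sorted(channels)}")
    series = tr.neural[:, channels[config.ssa_channel]]
    q = max(2, int(round(config.ssa_window_s / tr.dt)))
    result = ssa_mod.ssa(series, q, dt=tr.dt, t0=float(tr.times[0]))
    result.to_dir(Path(out_dir) / "ssa", channel=config.ssa_channel)
    return {"q": q, "n_components": result.n_components,
            "flattest": int(np.argmin(result.flatness))}


def run_info(config: ExperimentConfig, out_dir) -> dict:
    if config.trajectories_file is None:
        raise ConfigError("info requires trajectories_file")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trajs = ps.load_trajectories(config.trajectories_file)
    tr = trajs[config.worm]
    frame = tr.to_frame()
    for name in (config.info_x, config.info_y):
        if name not in frame.columns:
            raise ConfigError(f"column {name!r} not in trajectory")
    x = frame[config.info_x].to_numpy(dtype=float)
    y = frame[config.info_y].to_numpy(dtype=float)
    table = it.dependence_table([(f"{config.info_x}~{config.info_y}", x, y)])
    table.to_csv(out_dir / "dependence.csv", index=False)
    return {"R": float(table["R"].iloc[0]), "I_bits": float(table["I_bits"].iloc[0])}


RUNNERS = {
    "synth": run_synth,
    "simulate": run_simulate,
    "evolve": run_evolve,
    "protocol": run_protocol,
    "analyze": run_analyze,
    "ssa": run_ssa,
    "info": run_info,
}


def run_command(subcommand: str, config: ExperimentConfig, out_dir) -> dict:
    """Execute one pipeline stage and persist its manifest."""
    if subcommand not in RUNNERS:
        raise ConfigError(f"unknown subcommand {subcommand!r}")
    config.validate()
    result = RUNNERS[subcommand](config, out_dir)
    write_manifest(out_dir, subcommand, config, extra={"outputs": result})
    return result
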