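"""Genetic-algorithm optimization of the steering-circuit genome.

A genome is scored by running the mixed assay -- turning drawn from the
behavior tables, steering produced by the circuit -- and comparing two
summaries against reference targets: the thermotaxis-index time course from
the data-based simulation, and the curving-bias profile phi(theta).  Each
term is a normalized absolute deviation mapped to [0, 1] (negative values
clipped to zero) and the total fitness is their product, so a genome must
reproduce both the migration and the steering bias to score well.

The search itself is a standard real-coded generational GA: tournament
selection, uniform crossover, per-gene Gaussian mutation, elitism of one,
with every gene clamped to its declared box constraint.  Fitness assays
within one generation share a seed so individuals are compared on the same
realization of the assay noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from thermosteer import behavior_analysis as ba
from thermosteer import plate_simulator as ps
from thermosteer import synthetic_data as sd
from thermosteer._utils import substream
from thermosteer.neural_circuit import CircuitGenome, CircuitTopology, default_topology


@dataclass(frozen=True)
class SearchConfig:
    """Desk-scale defaults; the full-campaign scale is 96 x 300."""

    population_size: int = 16
    generations: int = 30
    extended: bool = False  # evolve v and t_osc as well (25 genes)
    tournament_size: int = 3
    crossover_rate: float = 0.5  # per-gene exchange probability
    mutation_rate: float = 0.1  # per-gene mutation probability
    mutation_sd_frac: float = 0.05  # Gaussian sd as a fraction of the range
    elitism: int = 1
    good_model_threshold: float = 0.6
    # fitness assay settings
    assay_n_worms: int = 12
    assay_duration: float = 240.0  # s
    ttx_interval: float = 10.0  # s between index samples
    ttx_scale: float = 2.0  # normalizer S_ttx: the full index range

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population size must be at least 2")
        if self.generations < 1:
            raise ValueError("need at least one generation")


@dataclass
class FitnessReport:
    """Decomposed fitness: total = F_ttx * F_bias, each in [0, 1]."""

    f_ttx: float
    f_bias: float
    ttx_deviation: float  # mean |I_model - I_ref| before normalization
    bias_deviation: float  # mean |phi_model - phi_ref| before normalization

    @property
    def total(self) -> float:
        return self.f_ttx * self.f_bias


def evaluate_fitness(
    genome: CircuitGenome,
    references: sd.ReferenceTargets,
    tables: sd.BehaviorTables,
    plate: ps.ThermalPlate | None = None,
    config: SearchConfig | None = None,
    seed: int = 0,
    kernel_spec: sd.SensoryKernelSpec | None = None,
) -> FitnessReport:
    """Score one genome with a circuit-policy assay against the references.

    F_ttx = max(0, 1 - mean_t |I_model - I_ref| / S_ttx) and
    F_bias = max(0, 1 - mean_theta |phi_model - phi_ref| / S_bias) with
    S_bias = 2 max|phi_ref|; only theta bins visited by the model worms
    enter the bias mean.  A failed simulation scores 0.
    """
    plate = plate or ps.ThermalPlate()
    config = config or SearchConfig()
    policy = ps.CircuitPolicy(
        genome=genome, kernel_spec=kernel_spec or sd.SensoryKernelSpec()
    )
    try:
        trajs = ps.run_assay(
            policy=policy,
            plate=plate,
            tables=tables,
            n_worms=config.assay_n_worms,
            duration=config.assay_duration,
            dt=policy.default_dt,
            seed=seed,
        )
    except (ValueError, FloatingPointError) as err:  # diagnostic zero
        report = FitnessReport(0.0, 0.0, float("inf"), float("inf"))
        report.error = str(err)
        return report

    times = references.ttx_times[references.ttx_times <= config.assay_duration + 1e-9]
    series = ba.ttx_index(trajs, plate, times=times)
    ttx_dev = float(np.mean(np.abs(series.values - references.ttx_reference[: times.size])))
    f_ttx = max(0.0, 1.0 - ttx_dev / config.ttx_scale)

    _, phi_model, counts = ba.bias_profile_from_trajectories(trajs, plate)
    ref = references.bias_reference
    s_bias = 2.0 * float(np.max(np.abs(ref))) if np.any(ref) else 1.0
    valid = (counts > 0) & np.isfinite(phi_model)
    if valid.any():
        bias_dev = float(np.mean(np.abs(phi_model[valid] - ref[valid])))
        f_bias = max(0.0, 1.0 - bias_dev / s_bias)
    else:
        bias_dev, f_bias = float("inf"), 0.0
    return FitnessReport(f_ttx=f_ttx, f_bias=f_bias,
                         ttx_deviation=ttx_dev, bias_deviation=bias_dev)


@dataclass
class EvolutionResult:
    """Per-generation log plus the final population."""

    log: pd.DataFrame  # generation, best/mean fitness, best-so-far
    best_genome: CircuitGenome
    best_fitness: float
    best_per_generation: list
    population: np.ndarray  # final genomes as vectors
    fitnesses: np.ndarray
    config: SearchConfig
    seed: int

    @property
    def good(self) -> bool:
        return self.best_fitness >= self.config.good_model_threshold


def ga_run(
    config: SearchConfig,
    references: sd.ReferenceTargets,
    tables: sd.BehaviorTables,
    plate: ps.ThermalPlate | None = None,
    seed: int = 0,
    topology: CircuitTopology | None = None,
    kernel_spec: sd.SensoryKernelSpec | None = None,
) -> EvolutionResult:
    """Generational GA over the genome box; returns the evolution log.

    All randomness (initialization, operators, assay noise) derives from
    ``seed``; reruns with the same arguments are bitwise identical.
    """
    topology = topology or default_topology()
    plate = plate or ps.ThermalPlate()
    rng = substream(seed, "ga")
    lo, hi = CircuitGenome.vector_bounds(topology, config.extended)
    span = hi - lo
    npop, ngene = config.population_size, lo.size

    pop = rng.uniform(lo, hi, size=(npop, ngene))

    def evaluate(vectors, gen):
        assay_seed = int(substream(seed, "fitness", gen).integers(2**31))
        fits = np.empty(len(vectors))
        for i, vec in enumerate(vectors):
            genome = CircuitGenome.from_vector(vec, topology, config.extended)
            fits[i] = evaluate_fitness(
                genome, references, tables, plate, config,
                seed=assay_seed, kernel_spec=kernel_spec,
            ).total
        return fits

    rows = []
    best_per_generation = []
    best_so_far = -np.inf
    best_vec = pop[0].copy()
    fits = evaluate(pop, 0)
    for gen in range(config.generations + 1):
        ibest = int(np.argmax(fits))
        gen_best = float(fits[ibest])
        if gen_best > best_so_far:
            best_so_far = gen_best
            best_vec = pop[ibest].copy()
        best_per_generation.append(
            CircuitGenome.from_vector(pop[ibest], topology, config.extended)
        )
        rows.append(
            {"generation": gen, "best_fitness": gen_best,
             "mean_fitness": float(fits.mean()), "best_so_far": best_so_far}
        )
        if gen == config.generations:
            break

        elite_idx = np.argsort(fits)[::-1][: config.elitism]
        children = [pop[i].copy() for i in elite_idx]
        while len(children) < npop:
            pa = _tournament(fits, rng, config.tournament_size)
            pb = _tournament(fits, rng, config.tournament_size)
            c1, c2 = pop[pa].copy(), pop[pb].copy()
            swap = rng.uniform(size=ngene) < config.crossover_rate
            c1[swap], c2[swap] = c2[swap], c1[swap].copy()
            for child in (c1, c2):
                mut = rng.uniform(size=ngene) < config.mutation_rate
                child[mut] += rng.normal(
                    0.0, config.mutation_sd_frac, size=mut.sum()
                ) * span[mut]
                np.clip(child, lo, hi, out=child)
                if len(children) < npop:
                    children.append(child)
        pop = np.stack(children)
        fits = evaluate(pop, gen + 1)

    return EvolutionResult(
        log=pd.DataFrame(rows),
        best_genome=CircuitGenome.from_vector(best_vec, topology, config.extended),
        best_fitness=float(best_so_far),
        best_per_generation=best_per_generation,
        population=pop,
        fitnesses=fits,
        config=config,
        seed=int(seed),
    )


def _tournament(fits, rng, k) -> int:
    idx = rng.integers(0, fits.size, size=k)
    return int(idx[np.argmax(fits[idx])])
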