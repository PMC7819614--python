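"""The seven-node thermotactic steering circuit.

The circuit follows the neuroanatomy implicated in *C. elegans* thermotactic
steering: the thermosensory neuron AFD (node 1), amphid interneurons AIB,
AIY, AIZ (nodes 2-4), dorsal and ventral neck motor neurons DMN/VMN
(nodes 5-6), and a central pattern generator CPG (node 7) that models
dorsoventral body undulation as a fixed sinusoid.

AFD activity is a linear convolution of a Hill-transformed temperature
history with a biphasic response kernel, so AFD effectively reports the
recent history (up to 100 s) of temperature change.  Inter- and motor
neurons are passive isopotential nodes with first-order nonlinear dynamics

    tau dy_i/dt = -y_i + sum_j w_ji sigmoid(y_j + beta_j)
                        + sum_k g_ki (y_k - y_i)

integrated with the forward Euler method at 0.1 s.  The curving rate of
locomotion is proportional to the difference in dorsal/ventral motor-neuron
output, bounded by the neuromuscular weight.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

#: canonical node order; indices are 1-based in the field's notation
NODE_NAMES = ("AFD", "AIB", "AIY", "AIZ", "DMN", "VMN", "CPG")

#: oscillation period of dorsoventral body undulation on agar plates (s)
DEFAULT_T_OSC = 4.2

#: membrane time constant (s); not part of the evolvable parameter set
DEFAULT_TAU = 1.0

#: integration time step for the circuit (s)
CIRCUIT_DT = 0.1

#: temperature-history horizon feeding the AFD convolution (s)
AFD_HISTORY = 100.0


def sigmoid(x):
    """Logistic output function sigma(x) = 1 / (1 + exp(-x))."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class HillParams:
    """Operating range of the AFD temperature transduction.

    ``h(T) = (T - T_thr)^n / (K_d + (T - T_thr)^n)`` for T >= T_thr, else 0.

    Parameters
    ----------
    T_thr : threshold temperature in degrees Celsius.
    K_d : dissociation constant, in units of (T - T_thr)^n; must be > 0.
    n : Hill coefficient, >= 1.
    """

    T_thr: float = 15.0
    K_d: float = 100.0
    n: float = 2.0

    def __post_init__(self):
        if self.K_d <= 0:
            raise ValueError(f"K_d must be positive, got {self.K_d}")
        if self.n < 1:
            raise ValueError(f"Hill coefficient must be >= 1, got {self.n}")


def hill_transform(T, params: HillParams):
    """Hill-saturated thermal drive h(T) in [0, 1); 0 below threshold."""
    T = np.asarray(T, dtype=float)
    dT = np.maximum(T - params.T_thr, 0.0)
    x = dT**params.n
    out = x / (params.K_d + x)
    if np.isscalar(T) or out.ndim == 0:
        return float(out)
    return out


def cpg_value(t, t_osc: float = DEFAULT_T_OSC, phase_shift: float = 0.0):
    """CPG output y7(t) = sin(2 pi (t + shift) / t_osc).

    ``phase_shift = t_osc / 2`` yields the anti-phase copy delivered to the
    ventral motor neuron (equal to the sign-inverted in-phase output).
    """
    if t_osc <= 0:
        raise ValueError(f"t_osc must be positive, got {t_osc}")
    return np.sin(2.0 * np.pi * (np.asarray(t, dtype=float) + phase_shift) / t_osc)


@dataclass(frozen=True)
class CircuitTopology:
    """Wiring diagram of the steering circuit.

    ``chem_edges`` are directed (source, target) chemical synapses and
    ``gap_edges`` undirected gap junctions, both on node names.  The CPG
    always projects to DMN (in phase) and VMN (anti-phase) through a single
    shared weight, and the motor difference reaches the muscles through one
    neuromuscular weight, so the default diagram carries 12 evolvable
    chemical/gap weights plus those two, 14 connection parameters in all.
    """

    chem_edges: tuple = (
        ("AFD", "AIB"),
        ("AFD", "AIY"),
        ("AIB", "AIY"),
        ("AIY", "AIZ"),
        ("AIZ", "AIY"),
        ("AIB", "AIZ"),
        ("AIZ", "DMN"),
        ("AIZ", "VMN"),
        ("AIB", "DMN"),
        ("AIB", "VMN"),
    )
    gap_edges: tuple = (("AIB", "AIY"), ("AIY", "AIZ"))

    def __post_init__(self):
        for s, t in self.chem_edges:
            if s == t:
                raise ValueError(f"self chemical synapse on {s}")
            if s not in NODE_NAMES or t not in NODE_NAMES:
                raise ValueError(f"unknown node in edge {s}->{t}")
            if t in ("AFD", "CPG"):
                raise ValueError(f"{t} does not receive chemical synapses here")
        for a, b in self.gap_edges:
            if a == b:
                raise ValueError(f"self gap junction on {a}")
            if a not in NODE_NAMES or b not in NODE_NAMES:
                raise ValueError(f"unknown node in gap {a}~{b}")

    @property
    def n_connection_weights(self) -> int:
        """Evolvable chemical + gap weights (excludes CPG and NMJ weights)."""
        return len(self.chem_edges) + len(self.gap_edges)

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = [{"source": s, "target": t, "type": "chem"} for s, t in self.chem_edges]
        rows += [{"source": a, "target": b, "type": "gap"} for a, b in self.gap_edges]
        rows += [
            {"source": "CPG", "target": "DMN", "type": "cpg"},
            {"source": "CPG", "target": "VMN", "type": "cpg"},
            {"source": "DMN", "target": "muscle", "type": "nmj"},
            {"source": "VMN", "target": "muscle", "type": "nmj"},
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def default_topology() -> CircuitTopology:
    """The default wiring with exactly 12 evolvable chemical/gap weights."""
    return CircuitTopology()


# box constraints for each genome field
GENOME_RANGES = {
    "beta": (-15.0, 15.0),
    "w": (-15.0, 15.0),
    "g": (0.0, 3.0),
    "w_cpg": (-15.0, 15.0),
    "w_nmj": (0.0, 90.0),
    "T_thr": (14.0, 26.0),
    "K_d": (10.0, 1000.0),
    "n": (1.0, 10.0),
    "v": (0.01, 1.0),
    "t_osc": (0.5, 50.0),
}


@dataclass(frozen=True)
class CircuitGenome:
    """The evolvable parameter vector of the steering circuit.

    Default mode carries 23 free parameters: 6 bias terms (AFD through VMN),
    12 chemical/gap weights, the shared CPG->motor weight, the neuromuscular
    weight (deg/s), and the three Hill terms.  Extended mode additionally
    evolves locomotion speed ``v`` (mm/s) and the CPG period ``t_osc`` (s),
    25 parameters in all.
    """

    beta: tuple  # 6 biases for nodes AFD..VMN
    w: tuple  # chemical weights, aligned with topology.chem_edges
    g: tuple  # gap conductances, aligned with topology.gap_edges
    w_cpg: float
    w_nmj: float
    hill: HillParams
    v: float | None = None  # mm/s; only set in extended mode
    t_osc: float | None = None  # s; only set in extended mode
    topology: CircuitTopology = field(default_factory=default_topology)

    def __post_init__(self):
        object.__setattr__(self, "beta", tuple(float(b) for b in self.beta))
        object.__setattr__(self, "w", tuple(float(x) for x in self.w))
        object.__setattr__(self, "g", tuple(float(x) for x in self.g))
        if len(self.beta) != 6:
            raise ValueError(f"expected 6 bias terms, got {len(self.beta)}")
        if len(self.w) != len(self.topology.chem_edges):
            raise ValueError("chemical weight count does not match topology")
        if len(self.g) != len(self.topology.gap_edges):
            raise ValueError("gap conductance count does not match topology")
        self._check_range("beta", self.beta)
        self._check_range("w", self.w)
        self._check_range("g", self.g)
        self._check_range("w_cpg", (self.w_cpg,))
        self._check_range("w_nmj", (self.w_nmj,))
        self._check_range("T_thr", (self.hill.T_thr,))
        self._check_range("K_d", (self.hill.K_d,))
        self._check_range("n", (self.hill.n,))
        if (self.v is None) != (self.t_osc is None):
            raise ValueError("extended mode requires both v and t_osc")
        if self.v is not None:
            self._check_range("v", (self.v,))
            self._check_range("t_osc", (self.t_osc,))

    @staticmethod
    def _check_range(name, values):
        lo, hi = GENOME_RANGES[name]
        for x in values:
            if not (lo <= x <= hi):
                raise ValueError(f"{name}={x} outside [{lo}, {hi}]")

    @property
    def extended(self) -> bool:
        return self.v is not None

    @property
    def n_parameters(self) -> int:
        base = 6 + len(self.w) + len(self.g) + 2 + 3
        return base + 2 if self.extended else base

    # ---- flat-vector view used by the genetic algorithm -------------------
    def to_vector(self) -> np.ndarray:
        vec = list(self.beta) + list(self.w) + list(self.g)
        vec += [self.w_cpg, self.w_nmj, self.hill.T_thr, self.hill.K_d, self.hill.n]
        if self.extended:
            vec += [self.v, self.t_osc]
        return np.asarray(vec, dtype=float)

    @classmethod
    def from_vector(
        cls,
        vec,
        topology: CircuitTopology | None = None,
        extended: bool = False,
    ) -> "CircuitGenome":
        topology = topology or default_topology()
        nw = len(topology.chem_edges)
        ng = len(topology.gap_edges)
        expected = 6 + nw + ng + 5 + (2 if extended else 0)
        vec = np.asarray(vec, dtype=float)
        if vec.size != expected:
            raise ValueError(f"expected genome length {expected}, got {vec.size}")
        i = 0
        beta = tuple(vec[i : i + 6]); i += 6
        w = tuple(vec[i : i + nw]); i += nw
        g = tuple(vec[i : i + ng]); i += ng
        w_cpg, w_nmj, t_thr, k_d, n = vec[i : i + 5]; i += 5
        v = t_osc = None
        if extended:
            v, t_osc = vec[i], vec[i + 1]
        return cls(
            beta=beta, w=w, g=g, w_cpg=float(w_cpg), w_nmj=float(w_nmj),
            hill=HillParams(float(t_thr), float(k_d), float(n)),
            v=v if v is None else float(v),
            t_osc=t_osc if t_osc is None else float(t_osc),
            topology=topology,
        )

    @classmethod
    def vector_bounds(
        cls, topology: CircuitTopology | None = None, extended: bool = False
    ) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) box constraints aligned with :meth:`to_vector`."""
        topology = topology or default_topology()
        names = (
            ["beta"] * 6
            + ["w"] * len(topology.chem_edges)
            + ["g"] * len(topology.gap_edges)
            + ["w_cpg", "w_nmj", "T_thr", "K_d", "n"]
        )
        if extended:
            names += ["v", "t_osc"]
        lo = np.array([GENOME_RANGES[n][0] for n in names])
        hi = np.array([GENOME_RANGES[n][1] for n in names])
        return lo, hi

    @classmethod
    def random(
        cls,
        rng: np.random.Generator,
        topology: CircuitTopology | None = None,
        extended: bool = False,
    ) -> "CircuitGenome":
        """Uniform random genome within the declared box constraints."""
        lo, hi = cls.vector_bounds(topology, extended)
        return cls.from_vector(rng.uniform(lo, hi), topology, extended)

    # ---- serialization ----------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "beta": list(self.beta),
            "w": list(self.w),
            "g": list(self.g),
            "w_cpg": self.w_cpg,
            "w_nmj": self.w_nmj,
            "hill": {"T_thr": self.hill.T_thr, "K_d": self.hill.K_d, "n": self.hill.n},
            "v": self.v,
            "t_osc": self.t_osc,
            "chem_edges": [list(e) for e in self.topology.chem_edges],
            "gap_edges": [list(e) for e in self.topology.gap_edges],
            "ranges": {k: list(v) for k, v in GENOME_RANGES.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "CircuitGenome":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        topo = CircuitTopology(
            chem_edges=tuple(tuple(e) for e in payload["chem_edges"]),
            gap_edges=tuple(tuple(e) for e in payload["gap_edges"]),
        )
        return cls(
            beta=payload["beta"], w=payload["w"], g=payload["g"],
            w_cpg=payload["w_cpg"], w_nmj=payload["w_nmj"],
            hill=HillParams(**payload["hill"]),
            v=payload.get("v"), t_osc=payload.get("t_osc"), topology=topo,
        )


def afd_response(history, kernel, params: HillParams, dt: float) -> float:
    """AFD activity y1(t) from a sampled temperature history.

    ``history`` holds T(delta) on the trailing window [t - 100 s, t], oldest
    first; ``kernel`` holds r sampled on the same step, lag 0 first.  The
    return value is the discrete approximation of

        y1(t) = integral_{t-100}^{t} r(t - delta) h(T(delta)) d delta

    i.e. ``sum_k r[k] h(T(t - k dt)) dt``.
    """
    history = np.asarray(history, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if history.shape[-1] != kernel.shape[0]:
        raise ValueError(
            f"history length {history.shape[-1]} does not match kernel length "
            f"{kernel.shape[0]}; both must be sampled on the same step"
        )
    h = hill_transform(history, params)
    h = np.atleast_1d(np.asarray(h, dtype=float))
    # history is oldest-first; kernel is lag-0 first
    out = h @ kernel[::-1] * dt
    if out.ndim == 0:
        return float(out)
    return out


def curving_rate(y5, y6, beta5, beta6, w_nmj):
    """Instantaneous curving rate psi = w_nmj (sigma(y5+b5) - sigma(y6+b6)).

    Positive psi bends toward the dorsal side; the magnitude is bounded by
    the neuromuscular weight ``w_nmj`` (deg/s).
    """
    return w_nmj * (sigmoid(np.asarray(y5) + beta5) - sigmoid(np.asarray(y6) + beta6))


@dataclass
class NoiseSpec:
    """Additive sinusoidal input injected into one node (perturbation mode).

    ``period`` defaults to 10x the CPG period, the slow regime that degrades
    steering; ``target`` is AIY or DMN.
    """

    target: str = "AIY"
    amplitude: float = 1.0
    period: float = 10.0 * DEFAULT_T_OSC

    def __post_init__(self):
        if self.target not in ("AIY", "DMN"):
            raise ValueError(f"noise target must be AIY or DMN, got {self.target}")
        if self.period <= 0:
            raise ValueError("noise period must be positive")


class CircuitDynamics:
    """Vectorized integrator for nodes 2-6 across a batch of worms.

    Precomputes dense weight matrices from the genome and topology once, and
    exposes a single Euler ``step``.  ``y`` has shape (batch, 5) holding
    AIB, AIY, AIZ, DMN, VMN potentials; AFD activity ``y1`` is supplied by
    the caller (convolution or clamp), and the CPG value is computed from
    time.  Ablated nodes are clamped to 0 and their outgoing chemical and
    gap influences removed.
    """

    #: indices of the integrated nodes within NODE_NAMES
    STATE_NODES = ("AIB", "AIY", "AIZ", "DMN", "VMN")

    def __init__(
        self,
        genome: CircuitGenome,
        tau: float = DEFAULT_TAU,
        ablations: tuple = (),
        noise: NoiseSpec | None = None,
    ):
        self.genome = genome
        self.tau = float(tau)
        self.ablations = tuple(ablations)
        self.noise = noise
        for a in self.ablations:
            if a not in ("AFD",) + self.STATE_NODES:
                raise ValueError(f"cannot ablate unknown node {a}")

        idx = {name: k for k, name in enumerate(self.STATE_NODES)}
        topo = genome.topology
        # chemical weights: W[i, j] drives state node i from presynaptic j,
        # where j runs over AFD (col 0) then the five state nodes (cols 1-5)
        W = np.zeros((5, 6))
        for (src, dst), wval in zip(topo.chem_edges, genome.w):
            col = 0 if src == "AFD" else 1 + idx[src]
            W[idx[dst], col] = wval
        G = np.zeros((5, 5))
        for (a, b), gval in zip(topo.gap_edges, genome.g):
            G[idx[a], idx[b]] += gval
            G[idx[b], idx[a]] += gval
        # remove outgoing influence of ablated nodes
        for a in self.ablations:
            if a == "AFD":
                W[:, 0] = 0.0
            else:
                W[:, 1 + idx[a]] = 0.0
                G[idx[a], :] = 0.0
                G[:, idx[a]] = 0.0
        self._W = W
        self._G = G
        self._gsum = G.sum(axis=1)
        self._beta = np.asarray(genome.beta, dtype=float)  # AFD..VMN
        self._clamp_idx = np.array(
            [idx[a] for a in self.ablations if a != "AFD"], dtype=int
        )
        self._t_osc = genome.t_osc if genome.t_osc is not None else DEFAULT_T_OSC
        self._noise_col = None
        if noise is not None:
            self._noise_col = idx[noise.target]

    @property
    def t_osc(self) -> float:
        return self._t_osc

    def initial_state(self, batch: int) -> np.ndarray:
        y = np.zeros((batch, 5))
        return y

    def step(self, y: np.ndarray, y1, t: float, dt: float = CIRCUIT_DT) -> np.ndarray:
        """One forward-Euler update of the five integrated potentials."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        y1 = np.zeros(y.shape[0]) if "AFD" in self.ablations else np.asarray(y1, float)
        s = np.empty((y.shape[0], 6))
        s[:, 0] = sigmoid(y1 + self._beta[0])
        s[:, 1:] = sigmoid(y + self._beta[1:])
        drive = s @ self._W.T
        y7 = cpg_value(t, self._t_osc)
        # DMN gets the in-phase CPG output, VMN the half-period-shifted copy
        drive[:, 3] += self.genome.w_cpg * sigmoid(y7)
        drive[:, 4] += self.genome.w_cpg * sigmoid(-y7)
        if self._noise_col is not None:
            drive[:, self._noise_col] += self.noise.amplitude * np.sin(
                2.0 * np.pi * t / self.noise.period
            )
        gap = y @ self._G.T - y * self._gsum
        y_new = y + (dt / self.tau) * (-y + drive + gap)
        if self._clamp_idx.size:
            y_new[:, self._clamp_idx] = 0.0
        return y_new

    def psi(self, y: np.ndarray) -> np.ndarray:
        """Curving rate (deg/s) for each batch member from motor potentials."""
        return curving_rate(y[:, 3], y[:, 4], self._beta[4], self._beta[5],
                            self.genome.w_nmj)


def circuit_step(
    y: np.ndarray,
    genome: CircuitGenome,
    y1: float,
    t: float,
    dt: float = CIRCUIT_DT,
    tau: float = DEFAULT_TAU,
    ablations: tuple = (),
    noise: NoiseSpec | None = None,
) -> np.ndarray:
    """Single-worm convenience wrapper around :class:`CircuitDynamics`.

    ``y`` is the length-5 potential vector (AIB, AIY, AIZ, DMN, VMN).
    Repeated stepping should build one ``CircuitDynamics`` and reuse it.
    """
    dyn = CircuitDynamics(genome, tau=tau, ablations=ablations, noise=noise)
    return dyn.step(np.asarray(y, dtype=float)[None, :], y1, t, dt)[0]


def default_genome(topology: CircuitTopology | None = None) -> CircuitGenome:
    """A hand-set, biologically plausible genome used as a fixture/default.

    Not an evolved optimum: AFD excites AIY, inhibits AIB; AIZ relays to the
    motor pair with opposite signs so AFD activity shifts the dorsoventral
    balance, and the CPG drives the canonical oscillation.
    """
    topology = topology or default_topology()
    w_by_edge = {
        ("AFD", "AIB"): -4.0,
        ("AFD", "AIY"): 6.0,
        ("AIB", "AIY"): -2.0,
        ("AIY", "AIZ"): 5.0,
        ("AIZ", "AIY"): -1.0,
        ("AIB", "AIZ"): -2.0,
        ("AIZ", "DMN"): 4.0,
        ("AIZ", "VMN"): -4.0,
        ("AIB", "DMN"): 1.0,
        ("AIB", "VMN"): 1.0,
    }
    w = tuple(w_by_edge.get(e, 0.0) for e in topology.chem_edges)
    g = tuple(0.5 for _ in topology.gap_edges)
    return CircuitGenome(
        beta=(0.0, 0.0, -1.0, 0.0, 0.0, 0.0),
        w=w,
        g=g,
        w_cpg=5.0,
        w_nmj=20.0,
        hill=HillParams(T_thr=15.0, K_d=50.0, n=2.0),
        topology=topology,
    )
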