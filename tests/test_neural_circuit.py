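"""Steering-circuit building blocks: Hill transduction, AFD convolution,
CPG, node dynamics, and the neuromuscular readout."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermosteer import neural_circuit as nc
from thermosteer import synthetic_data as sd


class TestHill:
    @pytest.mark.parametrize(
        "T, expected",
        [
            (15.0, 0.0),  # at threshold
            (10.0, 0.0),  # below threshold
            (15.0 + 10.0, 0.5),  # (T - T_thr)^n = K_d -> half saturation
        ],
    )
    def test_anchor_points(self, T, expected):
        params = nc.HillParams(T_thr=15.0, K_d=100.0, n=2.0)
        assert nc.hill_transform(T, params) == pytest.approx(expected)

    @given(st.floats(min_value=-20, max_value=60), st.floats(min_value=0.01, max_value=20))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, T, dT):
        params = nc.HillParams(T_thr=15.0, K_d=50.0, n=3.0)
        h0 = nc.hill_transform(T, params)
        h1 = nc.hill_transform(T + dT, params)
        assert 0.0 <= h0 < 1.0
        assert h1 >= h0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            nc.HillParams(K_d=0.0)
        with pytest.raises(ValueError):
            nc.HillParams(n=0.5)


class TestSigmoid:
    def test_anchor_values(self):
        assert nc.sigmoid(0.0) == pytest.approx(0.5)
        assert nc.sigmoid(np.log(3.0)) == pytest.approx(0.75)

    def test_symmetry(self):
        x = np.linspace(-10, 10, 21)
        assert np.allclose(nc.sigmoid(x) + nc.sigmoid(-x), 1.0)


class TestCPG:
    def test_starts_at_zero_and_antiphase_negates(self):
        assert nc.cpg_value(0.0) == pytest.approx(0.0)
        t = np.linspace(0, 20, 401)
        shifted = nc.cpg_value(t, phase_shift=nc.DEFAULT_T_OSC / 2)
        assert np.allclose(shifted, -nc.cpg_value(t), atol=1e-12)

    def test_period_from_upward_zero_crossings(self):
        t = np.arange(0, 60, 0.1)
        y = nc.cpg_value(t)
        s = np.sign(y)
        up = np.nonzero((s[:-1] <= 0) & (s[1:] > 0))[0]
        crossings = t[up] - y[up] * (t[up + 1] - t[up]) / (y[up + 1] - y[up])
        assert np.diff(crossings).mean() == pytest.approx(4.2, abs=1e-9)

    def test_nonpositive_period_rejected(self):
        with pytest.raises(ValueError):
            nc.cpg_value(1.0, t_osc=0.0)


class TestAfdResponse:
    def setup_method(self):
        self.params = nc.HillParams(T_thr=15.0, K_d=100.0, n=2.0)
        self.dt = 0.1
        self.kernel = sd.make_sensory_kernel(sd.SensoryKernelSpec(step=self.dt))

    def test_zero_kernel_gives_zero_response(self):
        hist = np.linspace(15, 25, self.kernel.size)
        assert nc.afd_response(hist, np.zeros_like(self.kernel), self.params, self.dt) == 0.0

    def test_constant_history_closed_form(self):
        hist = np.full(self.kernel.size, 22.0)
        expected = nc.hill_transform(22.0, self.params) * self.kernel.sum() * self.dt
        got = nc.afd_response(hist, self.kernel, self.params, self.dt)
        assert got == pytest.approx(expected, abs=1e-12)
        # the normalized AFD kernel makes the constant response ~0
        assert abs(got) < 1e-10

    def test_unit_impulse_at_lag_zero_reads_current_temperature(self):
        kernel = np.zeros(101)
        kernel[0] = 1.0
        hist = np.linspace(16, 24, 101)  # oldest first; current T = 24
        got = nc.afd_response(hist, kernel, self.params, self.dt)
        assert got == pytest.approx(nc.hill_transform(24.0, self.params) * self.dt)

    def test_linear_in_kernel(self, rng):
        hist = 18 + 2 * rng.standard_normal(201)
        k1 = rng.standard_normal(201)
        k2 = rng.standard_normal(201)
        combo = nc.afd_response(hist, 2.0 * k1 - 0.5 * k2, self.params, self.dt)
        parts = 2.0 * nc.afd_response(hist, k1, self.params, self.dt) - 0.5 * nc.afd_response(
            hist, k2, self.params, self.dt
        )
        assert combo == pytest.approx(parts, rel=1e-12)

    def test_mismatched_sampling_rejected(self):
        with pytest.raises(ValueError, match="match"):
            nc.afd_response(np.zeros(100), np.zeros(101), self.params, self.dt)


class TestCircuitDynamics:
    def test_zero_coupling_euler_decay(self, genome):
        bare = nc.CircuitGenome(
            beta=(0.0,) * 6,
            w=(0.0,) * len(genome.topology.chem_edges),
            g=(0.0,) * len(genome.topology.gap_edges),
            w_cpg=0.0, w_nmj=0.0, hill=genome.hill,
        )
        # sigmoid(0) = 0.5 inputs vanish only if weights are zero
        y = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
        out = nc.circuit_step(y, bare, y1=0.0, t=0.0, dt=0.1)
        assert out[0] == pytest.approx(0.9)
        # long-run decay matches exp(-t/tau) within Euler error O(dt)
        dyn = nc.CircuitDynamics(bare)
        state = np.array([[1.0, 0.0, 0.0, 0.0, 0.0]])
        for k in range(50):
            state = dyn.step(state, 0.0, k * 0.1, 0.1)
        assert state[0, 0] == pytest.approx(np.exp(-5.0), abs=0.05)

    def test_gap_junction_equilibration(self, genome):
        # two nodes coupled only by a gap: the difference decays at rate
        # (1 + 2g)/tau, after which both potentials equal the decayed
        # midpoint exp(-t/tau) (a + b)/2 of the full linear system
        gval = 3.0
        topo = genome.topology
        gen = nc.CircuitGenome(
            beta=(0.0,) * 6,
            w=(0.0,) * len(topo.chem_edges),
            g=tuple(gval if e == ("AIB", "AIY") else 0.0 for e in topo.gap_edges),
            w_cpg=0.0, w_nmj=0.0, hill=genome.hill,
        )
        dyn = nc.CircuitDynamics(gen)
        a, b = 2.0, -1.0
        state = np.array([[a, b, 0.0, 0.0, 0.0]])
        dt, t_end = 0.001, 3.0
        for k in range(int(t_end / dt)):
            state = dyn.step(state, 0.0, k * dt, dt)
        mid = np.exp(-t_end) * (a + b) / 2.0
        assert state[0, 0] == pytest.approx(state[0, 1], abs=1e-6)
        assert state[0, 0] == pytest.approx(mid, rel=1e-2)

    def test_ablated_node_stays_clamped(self, genome, rng):
        dyn = nc.CircuitDynamics(genome, ablations=("AIY",))
        state = dyn.initial_state(1)
        for k in range(100):
            state = dyn.step(state, rng.uniform(-1, 1), k * 0.1, 0.1)
        assert state[0, 1] == 0.0  # AIY is the second integrated node
        assert np.any(state[0, [0, 2, 3, 4]] != 0.0)

    def test_fixed_point_under_constant_input(self, rng):
        # with constant AFD drive and no CPG, small random circuits settle
        # to a state satisfying y = W sigma(y + beta) + gap terms
        topo = nc.default_topology()
        for _ in range(5):
            gen = nc.CircuitGenome(
                beta=tuple(rng.uniform(-1, 1, 6)),
                w=tuple(rng.uniform(-1, 1, len(topo.chem_edges))),
                g=tuple(rng.uniform(0, 1, len(topo.gap_edges))),
                w_cpg=0.0,
                w_nmj=10.0,
                hill=nc.HillParams(),
            )
            dyn = nc.CircuitDynamics(gen)
            y1 = float(rng.uniform(-0.5, 0.5))
            state = dyn.initial_state(1)
            for k in range(2000):
                state = dyn.step(state, y1, k * 0.1, 0.1)
            # residual of the fixed-point equation
            nxt = dyn.step(state.copy(), y1, 0.0, 0.1)
            residual = np.abs(nxt - state).max() / 0.1
            assert residual < 1e-6

    def test_noise_injection_targets_one_node(self, genome):
        noise = nc.NoiseSpec(target="AIY", amplitude=2.0, period=42.0)
        dyn = nc.CircuitDynamics(genome, noise=noise)
        quiet = nc.CircuitDynamics(genome)
        s1 = s2 = np.zeros((1, 5))
        s1 = dyn.step(s1, 0.0, 10.0, 0.1)
        s2 = quiet.step(s2, 0.0, 10.0, 0.1)
        assert s1[0, 1] != s2[0, 1]
        with pytest.raises(ValueError):
            nc.NoiseSpec(target="CPG")


class TestCurvingRate:
    def test_symmetric_motors_give_zero(self):
        assert nc.curving_rate(1.3, 1.3, -0.2, -0.2, 50.0) == 0.0

    def test_antisymmetry_under_motor_swap(self, rng):
        y5, y6, b5, b6 = rng.uniform(-3, 3, 4)
        a = nc.curving_rate(y5, y6, b5, b6, 30.0)
        b = nc.curving_rate(y6, y5, b6, b5, 30.0)
        assert a == pytest.approx(-b)

    def test_bounded_by_neuromuscular_weight(self):
        almost = nc.curving_rate(20.0, -20.0, 0.0, 0.0, 90.0)
        assert almost == pytest.approx(90.0, abs=1e-6)
        assert abs(almost) <= 90.0

    def test_invariant_under_compensated_shift(self):
        # shifting y and beta so sigma(y + beta) is unchanged leaves psi fixed
        a = nc.curving_rate(1.0, -1.0, 0.5, 0.2, 40.0)
        b = nc.curving_rate(1.5, -0.3, 0.0, -0.5, 40.0)
        assert a == pytest.approx(b)


class TestGenome:
    def test_default_genome_has_23_parameters(self, genome):
        assert genome.n_parameters == 23
        assert genome.to_vector().size == 23
        assert genome.topology.n_connection_weights == 12

    def test_extended_genome_has_25_parameters(self):
        rng = np.random.default_rng(0)
        g = nc.CircuitGenome.random(rng, extended=True)
        assert g.n_parameters == 25
        assert g.to_vector().size == 25
        assert 0.01 <= g.v <= 1.0
        assert 0.5 <= g.t_osc <= 50.0

    def test_vector_roundtrip(self, rng):
        g = nc.CircuitGenome.random(rng)
        back = nc.CircuitGenome.from_vector(g.to_vector())
        assert np.allclose(back.to_vector(), g.to_vector())

    def test_out_of_range_rejected(self, genome):
        with pytest.raises(ValueError, match="outside"):
            nc.CircuitGenome(
                beta=(99.0,) + genome.beta[1:], w=genome.w, g=genome.g,
                w_cpg=genome.w_cpg, w_nmj=genome.w_nmj, hill=genome.hill,
            )

    def test_json_roundtrip(self, genome, tmp_path):
        path = tmp_path / "genome.json"
        genome.to_json(path)
        back = nc.CircuitGenome.from_json(path)
        assert np.allclose(back.to_vector(), genome.to_vector())
        assert back.topology == genome.topology

    def test_topology_rejects_self_edges(self):
        with pytest.raises(ValueError):
            nc.CircuitTopology(chem_edges=(("AIB", "AIB"),))
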