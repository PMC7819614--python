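"""Thermal plate geometry, event sampling, steering kinematics, and the
full assay loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermosteer import neural_circuit as nc
from thermosteer import plate_simulator as ps
from thermosteer import synthetic_data as sd


class TestThermalPlate:
    @pytest.mark.parametrize(
        "plate_kw, x, expected",
        [
            ({}, 0.0, 14.0),
            ({}, 13.6, 20.0),
            ({}, 6.8, 17.0),  # plate center of the 14-20 assay
            ({"T_left": 20.0, "T_right": 26.0}, 6.8, 23.0),
        ],
    )
    def test_linear_field(self, plate_kw, x, expected):
        plate = ps.ThermalPlate(**plate_kw)
        assert plate.temperature_at(x) == pytest.approx(expected)

    def test_off_plate_position_rejected(self, plate):
        with pytest.raises(ValueError, match="reflect"):
            plate.temperature_at(-0.1)

    def test_fraction_index(self, plate):
        assert plate.fraction_of(0.0) == 1
        assert plate.fraction_of(plate.Lx / 2) == 5  # center boundary -> 5
        assert plate.fraction_of(plate.Lx) == 8

    def test_gradient_of_standard_plate(self, plate):
        assert plate.gradient == pytest.approx(6.0 / 13.6)

    def test_speed_depends_on_center_temperature(self):
        assert ps.ThermalPlate().default_speed_mm_s == 0.2
        assert ps.ThermalPlate(T_left=20, T_right=26).default_speed_mm_s == 0.3


class TestSampleTurnEvent:
    def test_zero_probabilities_always_curve(self, gradient_free_tables, rng):
        tables = sd.make_behavior_tables("gradient_free", 0)
        tables.turn_probs = np.zeros_like(tables.turn_probs)
        for _ in range(50):
            assert ps.sample_turn_event(tables, 90.0, 1, 0, rng) == "none"

    def test_event_rate_matches_table_probability(self, rng):
        tables = sd.make_behavior_tables("gradient_free", 0)
        tables.turn_probs = np.zeros_like(tables.turn_probs)
        tables.turn_probs[0] = 0.5  # omega at 0.5/s, rest 0
        draws = [ps.sample_turn_event(tables, 90.0, 1, 0, rng) for _ in range(10_000)]
        frac = np.mean([d == "omega" for d in draws])
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 10_000)

    def test_gradient_free_rates_are_theta_independent(self, gradient_free_tables, rng):
        from scipy.stats import chi2_contingency

        thetas = [5.0, 65.0, 125.0, 175.0]
        counts = []
        for th in thetas:
            evs = ps._sample_events(
                gradient_free_tables,
                np.full(25_000, int(th // 10)),
                np.full(25_000, 1), np.full(25_000, 0),
                rng, 1.0,
            )
            turned = int((evs < 4).sum())
            counts.append([turned, 25_000 - turned])
        _, p, _, _ = chi2_contingency(np.array(counts))
        assert p > 0.01

    def test_missing_row_rejected(self, gradient_free_tables, rng):
        with pytest.raises(KeyError):
            ps.sample_turn_event(gradient_free_tables, 90.0, 7, 0, rng)


class TestApplyTurn:
    def test_zero_displacement_redraws_heading_only(self, positive_tables, rng, plate):
        state = ps.AgentState(x=5.0, y=4.0, heading_deg=120.0)
        new = ps.apply_turn(state, "omega", positive_tables, rng, plate)
        assert (new.x, new.y) == (5.0, 4.0)
        assert new.behavior == "omega"

    def test_degenerate_exit_distribution_hits_its_bin(self, positive_tables, rng, plate):
        tables = sd.make_behavior_tables("positive", 0)
        dists = np.zeros_like(tables.exit_dists)
        dists[..., 9] = 1.0  # Phi in [90, 100)
        tables.exit_dists = dists
        state = ps.AgentState(x=5.0, y=4.0, heading_deg=0.0)
        for _ in range(20):
            new = ps.apply_turn(state, "reversal", tables, rng, plate)
            assert 90.0 <= new.theta(plate) < 100.0

    def test_uniform_exit_gives_zero_mean_cos(self, gradient_free_tables, rng, plate):
        state = ps.AgentState(x=6.8, y=4.8, heading_deg=30.0)
        cos_sum = n = 0
        for _ in range(5000):
            new = ps.apply_turn(state, "shallow", gradient_free_tables, rng, plate)
            cos_sum += np.cos(np.deg2rad(new.theta(plate)))
            n += 1
        assert abs(cos_sum / n) < 0.03


class TestReflection:
    def test_mirror_rule_left_wall(self, plate):
        x, y, a = ps.reflect_at_boundary((-0.1, 4.0), 170.0, plate)
        assert (x, y) == (pytest.approx(0.1), 4.0)
        assert a == pytest.approx(10.0)

    def test_interior_unchanged(self, plate):
        x, y, a = ps.reflect_at_boundary((5.0, 4.0), 33.0, plate)
        assert (x, y, a) == (5.0, 4.0, 33.0)

    def test_corner_double_reflection(self, plate):
        x, y, a = ps.reflect_at_boundary((-0.2, -0.3), -135.0, plate)
        assert (x, y) == (pytest.approx(0.2), pytest.approx(0.3))
        assert a == pytest.approx(45.0)

    @given(
        st.floats(min_value=-2.0, max_value=15.6),
        st.floats(min_value=-2.0, max_value=11.6),
        st.floats(min_value=-180.0, max_value=180.0),
    )
    @settings(max_examples=300, deadline=None)
    def test_result_always_inside(self, x, y, a):
        plate = ps.ThermalPlate()
        nx, ny, _ = ps.reflect_at_boundary((x, y), a, plate)
        assert 0.0 <= nx <= plate.Lx
        assert 0.0 <= ny <= plate.Ly


class TestSteeringStep:
    def test_zero_psi_moves_straight(self, plate, genome):
        policy = ps.CircuitPolicy(genome=genome)
        state = ps.AgentState(x=5.0, y=4.0, heading_deg=30.0)
        rng = np.random.default_rng(0)
        new = ps.steering_step(state, policy, plate, dt=1.0, rng=rng, psi=0.0)
        v = plate.default_speed_mm_s / 10.0
        assert new.x == pytest.approx(5.0 + v * np.cos(np.deg2rad(30.0)))
        assert new.y == pytest.approx(4.0 + v * np.sin(np.deg2rad(30.0)))
        assert new.heading_deg == pytest.approx(30.0)

    def test_constant_psi_traces_circle_of_radius_v_over_psi(self, plate, genome):
        policy = ps.CircuitPolicy(genome=genome)
        psi = 10.0  # deg/s
        dt = 0.01
        state = ps.AgentState(x=6.8, y=4.8, heading_deg=0.0, handedness=1)
        xs, ys = [state.x], [state.y]
        rng = np.random.default_rng(0)
        for _ in range(int(36.0 / psi / dt)):  # one tenth of a turn
            state = ps.steering_step(state, policy, plate, dt, rng, psi=psi)
            xs.append(state.x); ys.append(state.y)
        pts = np.column_stack([xs, ys])
        v = plate.default_speed_mm_s / 10.0
        r_expected = v * (180.0 / np.pi) / psi
        # fit circle radius from the chord of the swept arc
        center = pts[0] + r_expected * np.array([0.0, 1.0])
        radii = np.linalg.norm(pts - center, axis=1)
        assert np.allclose(radii, r_expected, rtol=0.02)

    def test_handedness_flip_mirrors_trajectory(self, plate, genome):
        policy = ps.CircuitPolicy(genome=genome)
        rng = np.random.default_rng(1)
        psis = rng.uniform(-20, 20, 50)
        a = ps.AgentState(x=6.8, y=4.8, heading_deg=0.0, handedness=1)
        b = ps.AgentState(x=6.8, y=4.8, heading_deg=0.0, handedness=-1)
        for p in psis:
            a = ps.steering_step(a, policy, plate, 0.5, rng, psi=p)
            b = ps.steering_step(b, policy, plate, 0.5, rng, psi=p)
        assert a.x == pytest.approx(b.x)
        assert a.y - 4.8 == pytest.approx(-(b.y - 4.8))
        assert a.heading_deg == pytest.approx(-b.heading_deg)


class TestRunAssay:
    def test_no_worms_gives_empty_result(self, positive_tables):
        assert ps.run_assay(ps.DataPolicy(positive_tables), n_worms=0) == []

    def test_sample_count_arithmetic(self, positive_tables):
        trajs = ps.run_assay(
            ps.DataPolicy(positive_tables), n_worms=2, duration=1800.0, dt=1.0, seed=0
        )
        assert all(tr.times.size == 1801 for tr in trajs)

    def test_same_seed_reproduces_trajectories(self, positive_tables, genome):
        for policy in (
            ps.DataPolicy(positive_tables),
            ps.CircuitPolicy(genome=genome),
        ):
            a = ps.run_assay(policy, tables=positive_tables, n_worms=3,
                             duration=60.0, seed=7)
            b = ps.run_assay(policy, tables=positive_tables, n_worms=3,
                             duration=60.0, seed=7)
            for ta, tb in zip(a, b):
                assert np.array_equal(ta.x, tb.x)
                assert np.array_equal(ta.heading_deg, tb.heading_deg)
                assert np.array_equal(ta.labels, tb.labels)

    def test_containment_all_policies(self, positive_tables, genome, plate):
        for policy in (
            ps.DataPolicy(positive_tables),
            ps.CircuitPolicy(genome=genome),
        ):
            trajs = ps.run_assay(policy, tables=positive_tables, n_worms=5,
                                 duration=300.0, seed=3)
            for tr in trajs:
                assert tr.x.min() >= 0 and tr.x.max() <= plate.Lx
                assert tr.y.min() >= 0 and tr.y.max() <= plate.Ly

    def test_speed_contract_between_turns(self, positive_tables):
        trajs = ps.run_assay(ps.DataPolicy(positive_tables), n_worms=3,
                             duration=300.0, seed=2)
        v = 0.02  # 0.2 mm/s in cm/s
        for tr in trajs:
            step = np.hypot(np.diff(tr.x), np.diff(tr.y))
            # steps ending in a curve, not adjacent to a wall reflection
            interior = (
                (tr.x > 0.1) & (tr.x < 13.5) & (tr.y > 0.1) & (tr.y < 9.5)
            )
            curve = tr.labels[1:] == ps.CURVE_CODE
            ok = curve & interior[1:] & interior[:-1]
            assert np.allclose(step[ok], v, atol=1e-12)

    def test_neural_recording_shape(self, positive_tables, genome):
        trajs = ps.run_assay(
            ps.CircuitPolicy(genome=genome), tables=positive_tables,
            n_worms=2, duration=30.0, seed=1, record_neural=True,
        )
        assert trajs[0].neural.shape == (301, 6)
        assert trajs[0].psi is not None

    def test_open_loop_feeds_prescribed_temperature(self, genome):
        stim = lambda t: 17.0 + 0.5 * np.sin(t)
        trajs = ps.run_assay(
            ps.CircuitPolicy(genome=genome), n_worms=1, duration=20.0,
            seed=0, open_loop=stim,
        )
        tr = trajs[0]
        # recorded temperature follows the stimulus, not the position
        expected = np.array([stim(max(0.0, t - 0.1)) for t in tr.times])
        assert np.allclose(tr.temperature[1:], expected[1:], atol=1e-9)
        assert np.all(tr.labels == ps.CURVE_CODE)  # turning disabled

    def test_csv_roundtrip(self, positive_tables, tmp_path):
        trajs = ps.run_assay(ps.DataPolicy(positive_tables), n_worms=2,
                             duration=30.0, seed=0)
        path = tmp_path / "traj.csv"
        ps.save_trajectories(trajs, path)
        back = ps.load_trajectories(path)
        assert len(back) == 2
        assert np.allclose(back[0].x, trajs[0].x)
        assert np.array_equal(back[0].labels, trajs[0].labels)
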