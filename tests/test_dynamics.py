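"""Node/unit equations, couplings, delays and the Euler stepper.

Derivative operations are checked against independent straight-line
re-implementations of the printed formulas; the vectorized stepper is checked
against scalar hand computation on tiny instances.
"""

import math

import numpy as np
import pytest

from taskbrain.connectome import Connectome
from taskbrain.dynamics import (
    CompiledNetwork,
    connectome_node_derivative,
    long_range_coupling,
    lsnm_inputs,
    lsnm_unit_derivative,
    sigmoid_response,
    step_network,
    uniform_fixed_point,
)
from taskbrain.embedding import LsnmModuleSpec, build_embedding
from taskbrain.params import LsnmParams, TvbNodeParams
from taskbrain.templates import LsnmWeightSet, default_module_params


class TestSigmoid:
    def test_midpoint_is_half_ceiling(self):
        assert sigmoid_response(2.8, a=1.2, b=2.8, c=1.0) == pytest.approx(0.5)
        assert sigmoid_response(0.0, a=3.0, b=0.0, c=0.7) == pytest.approx(0.35)

    def test_known_value(self):
        # 1 / (1 + e^-2)
        assert sigmoid_response(2.0, 1.0, 0.0, 1.0) == pytest.approx(0.880797, abs=1e-6)

    def test_saturation_limits(self):
        assert sigmoid_response(-1e3, 1.0, 0.0, 1.0) == pytest.approx(0.0, abs=1e-12)
        assert sigmoid_response(1e3, 1.0, 0.0, 0.8) == pytest.approx(0.8, abs=1e-12)

    def test_strictly_increasing(self):
        f = np.linspace(-5, 5, 101)
        y = sigmoid_response(f, 1.2, 0.5, 1.0)
        assert np.all(np.diff(y) > 0)

    def test_nonpositive_ceiling_rejected(self):
        with pytest.raises(ValueError):
            sigmoid_response(0.0, 1.0, 0.0, 0.0)


class TestLongRangeCoupling:
    def test_zero_activity_gives_zero(self):
        assert long_range_coupling(np.zeros(5), np.ones(5), 2.0) == 0.0

    def test_single_edge_hand_value(self):
        assert long_range_coupling([0.4], [0.5], 2.0) == pytest.approx(0.4)

    def test_linear_in_coupling_scale(self):
        rng = np.random.default_rng(0)
        E, u = rng.random(7), rng.random(7)
        assert long_range_coupling(E, u, 3.0) == pytest.approx(
            3.0 * long_range_coupling(E, u, 1.0)
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            long_range_coupling([1.0, 2.0], [1.0], 1.0)


def _node_derivative_oracle(E, I, p, G):
    """Independent re-implementation of the node equations."""
    sE = p.sigmoid_E.c / (1 + math.exp(-p.sigmoid_E.a * (p.alpha_E * (p.c_EE * E - p.c_IE * I - p.theta_E + G) - p.sigmoid_E.b)))
    sI = p.sigmoid_I.c / (1 + math.exp(-p.sigmoid_I.a * (p.alpha_I * (p.c_EI * E - p.c_II * I - p.theta_I + G) - p.sigmoid_I.b)))
    return (
        (1.0 / p.tau_E) * (-E + (p.k_E - p.r_E * E) * sE),
        (1.0 / p.tau_I) * (-I + (p.k_I - p.r_I * I) * sI),
    )


class TestNodeDerivative:
    @pytest.mark.parametrize("E,I,G", [(0.1, 0.05, 0.0), (0.4, 0.3, 0.7), (0.9, 0.8, -0.2)])
    def test_matches_independent_formula(self, E, I, G):
        p = TvbNodeParams()
        dE, dI = connectome_node_derivative((E, I), p, G)
        oE, oI = _node_derivative_oracle(E, I, p, G)
        assert dE == pytest.approx(oE, rel=1e-12)
        assert dI == pytest.approx(oI, rel=1e-12)

    def test_doubling_tau_halves_rate(self):
        p1 = TvbNodeParams(tau_E=10.0)
        p2 = TvbNodeParams(tau_E=20.0)
        d1, _ = connectome_node_derivative((0.3, 0.2), p1, 0.5)
        d2, _ = connectome_node_derivative((0.3, 0.2), p2, 0.5)
        assert d2 == pytest.approx(d1 / 2)

    def test_saturation_factor_zero_leaves_leak_only(self):
        # at E = k_E / r_E the gain term vanishes: dE = -E / tau for any input
        p = TvbNodeParams()
        E = p.k_E / p.r_E
        dE, _ = connectome_node_derivative((E, 0.1), p, 50.0)
        assert dE == pytest.approx(-E / p.tau_E, rel=1e-9)


class TestUnitDerivative:
    def test_zero_rate_of_change_leaves_decay(self):
        p = LsnmParams(Delta=1e-12, delta=0.4)
        dE, dI = lsnm_unit_derivative((0.6, 0.2), p, (0.0, 0.0))
        assert dE == pytest.approx(-0.4 * 0.6, abs=1e-9)
        assert dI == pytest.approx(-0.4 * 0.2, abs=1e-9)

    def test_matches_independent_formula(self):
        p = LsnmParams()
        E, I, in_E, in_I, N = 0.4, 0.3, 0.25, 0.1, 0.02
        dE, dI = lsnm_unit_derivative((E, I), p, (in_E, in_I), N)
        oE = p.Delta / (1 + math.exp(-p.K_E * (p.w_EE * E + p.w_IE * I + in_E - p.phi_E + N))) - p.delta * E
        oI = p.Delta / (1 + math.exp(-p.K_I * (p.w_EI * E + in_I - p.phi_I + N))) - p.delta * I
        assert dE == pytest.approx(oE, rel=1e-12)
        assert dI == pytest.approx(oI, rel=1e-12)

    def test_logistic_floor(self):
        p = LsnmParams()
        dE, _ = lsnm_unit_derivative((0.5, 0.0), p, (-100.0, 0.0))
        assert dE == pytest.approx(-p.delta * 0.5, abs=1e-6)


class TestLsnmInputs:
    def _tiny_hybrid(self):
        coords = np.array([[0, 0, 0], [30, 0, 0]], dtype=float)
        w = np.array([[0.0, 0.0], [1.5, 0.0]])  # node 1 -> node 0
        conn = Connectome(weights=w, coords=coords)
        specs = [LsnmModuleSpec("A", (0.0, 0.0, 0.0)), LsnmModuleSpec("B", (30.0, 0.0, 0.0))]
        return build_embedding(conn, specs, G=0.15, rng=np.random.default_rng(0))

    def test_hand_computed_sum(self):
        hyb = self._tiny_hybrid()
        m_e = np.zeros((81, 81))
        m_e[0, 0] = 0.3  # B.E0 -> A.E0
        m_i = np.zeros((81, 81))
        m_i[0, 0] = -0.1  # B.I0 -> A.E0
        ws = LsnmWeightSet([
            __import__("taskbrain.templates", fromlist=["Template"]).Template("B", "A", m_e),
            __import__("taskbrain.templates", fromlist=["Template"]).Template("B", "A", m_i, source_pop="I"),
        ])
        states = {
            "A": (np.zeros(81), np.zeros(81)),
            "B": (np.full(81, 0.5), np.full(81, 0.2)),
        }
        # overwrite the placement's coupling so c * z = 0.002 * 1.5 exactly
        p = hyb.placements["A"]
        p.coupling_samples[:] = 0.002
        delayed = np.array([0.0, 0.4])
        in_E, in_I = lsnm_inputs(("A", 0), hyb, states, delayed, weights=ws)
        assert in_E == pytest.approx(0.3 * 0.5 - 0.1 * 0.2 + 0.002 * 1.5 * 0.4)
        assert in_I == 0.0

    def test_no_afferents_no_drive_is_zero(self):
        hyb = self._tiny_hybrid()
        states = {"A": (np.zeros(81),) * 2, "B": (np.zeros(81),) * 2}
        in_E, in_I = lsnm_inputs(("B", 40), hyb, states, np.zeros(2), weights=LsnmWeightSet([]))
        # B's host has no in-edges, so only (empty) template sums remain
        assert (in_E, in_I) == (0.0, 0.0)

    def test_connectome_never_reaches_inhibitory_input(self):
        hyb = self._tiny_hybrid()
        states = {"A": (np.zeros(81),) * 2, "B": (np.zeros(81),) * 2}
        _, in_I_a = lsnm_inputs(("A", 0), hyb, states, np.array([0.0, 5.0]), weights=LsnmWeightSet([]))
        assert in_I_a == 0.0  # perturbing node activity only enters in_E


class TestStepNetwork:
    def _net(self, n_nodes=2, noise=0.0, speed=3.0, tract=True, G=0.15):
        rng = np.random.default_rng(0)
        coords = np.array([[0, 0, 0], [30, 0, 0], [0, 40, 0]], dtype=float)[:n_nodes]
        w = np.array([[0, 0.5, 0.2], [0.5, 0, 0.1], [0.2, 0.1, 0]])[:n_nodes, :n_nodes]
        tl = np.linalg.norm(coords[:, None] - coords[None], axis=-1) if tract else None
        conn = Connectome(weights=w, coords=coords, tract_lengths=tl)
        hyb = build_embedding(conn, [], G, rng)
        tvb = TvbNodeParams(noise_sd=noise, conduction_speed=speed)
        return CompiledNetwork.compile(hyb, tvb_params=tvb, weight_set=LsnmWeightSet([]))

    def test_uniform_fixed_point_is_stationary(self):
        # fully-connected uniform weights: every node sees the same coupling
        coords = np.zeros((3, 3))
        coords[:, 0] = [0, 1, 2]
        w = np.ones((3, 3)) * 0.4
        np.fill_diagonal(w, 0)
        conn = Connectome(weights=w, coords=coords)
        hyb = build_embedding(conn, [], 0.15, np.random.default_rng(0))
        tvb = TvbNodeParams(noise_sd=0.0, conduction_speed=math.inf)
        net = CompiledNetwork.compile(hyb, tvb_params=tvb, weight_set=LsnmWeightSet([]))
        E0, I0 = uniform_fixed_point(tvb, total_in_weight=0.8, a_Gamma=0.15)
        state = net.init_state(E0, I0)
        before = (state.tvb_E.copy(), state.tvb_I.copy())
        for _ in range(50):
            step_network(net, state)
        np.testing.assert_allclose(state.tvb_E, before[0], atol=1e-9)
        np.testing.assert_allclose(state.tvb_I, before[1], atol=1e-9)

    def test_single_step_matches_scalar_euler(self):
        net = self._net(n_nodes=2)
        state = net.init_state(0.2, 0.1)
        E, I = state.tvb_E.copy(), state.tvb_I.copy()
        step_network(net, state)
        p = net.tvb
        for i in range(2):
            # delayed values all equal the initial state (uniform history)
            G = 0.15 * float(net.Win[i] @ E)
            dE, dI = connectome_node_derivative((E[i], I[i]), p, G)
            assert state.tvb_E[i] == pytest.approx(E[i] + 5.0 * dE, rel=1e-12)
            assert state.tvb_I[i] == pytest.approx(I[i] + 5.0 * dI, rel=1e-12)

    def test_infinite_speed_equals_no_tract_lengths(self):
        net_inf = self._net(n_nodes=3, speed=math.inf, tract=True)
        net_none = self._net(n_nodes=3, speed=3.0, tract=False)
        s1, s2 = net_inf.init_state(0.2, 0.1), net_none.init_state(0.2, 0.1)
        for _ in range(100):
            step_network(net_inf, s1)
            step_network(net_none, s2)
        np.testing.assert_array_equal(s1.tvb_E, s2.tvb_E)

    def test_delay_lag_is_at_least_one_step(self):
        net = self._net(n_nodes=3)
        assert net.lag_in.min() >= 1
        # 30 mm at 3 mm/ms and 5 ms steps -> 2 steps
        assert net.lag_in[0, 1] == 2

    def test_identical_seeds_give_identical_trajectories(self, hybrid):
        net = CompiledNetwork.compile(hybrid)
        results = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            state = net.init_state()
            for _ in range(40):
                step_network(net, state, rng)
            results.append((state.tvb_E.copy(), state.lsnm_E.copy()))
        np.testing.assert_array_equal(results[0][0], results[1][0])
        np.testing.assert_array_equal(results[0][1], results[1][1])

    def test_unit_activities_stay_in_unit_interval(self, hybrid):
        net = CompiledNetwork.compile(hybrid)
        rng = np.random.default_rng(1)
        state = net.init_state()
        drive = np.ones(net.U) * 2.0  # strong drive
        for _ in range(200):
            step_network(net, state, rng, unit_drive=drive)
            assert np.all(state.lsnm_E >= 0) and np.all(state.lsnm_E <= 1)
            assert np.all(state.lsnm_I >= 0) and np.all(state.lsnm_I <= 1)

    def test_halving_dt_stays_smooth(self):
        # same 1-second horizon at dt=5 and dt=2.5 must land close together
        finals = []
        for dt in (5.0, 2.5):
            coords = np.array([[0, 0, 0], [30, 0, 0]], dtype=float)
            w = np.array([[0, 0.5], [0.5, 0]])
            conn = Connectome(weights=w, coords=coords)
            hyb = build_embedding(conn, [], 0.15, np.random.default_rng(0))
            net = CompiledNetwork.compile(
                hyb, tvb_params=TvbNodeParams(noise_sd=0.0, conduction_speed=math.inf),
                weight_set=LsnmWeightSet([]), dt_ms=dt,
            )
            state = net.init_state(0.4, 0.3)
            for _ in range(int(1000 / dt)):
                step_network(net, state)
            finals.append(state.tvb_E.copy())
        assert np.all(np.isfinite(finals[0])) and np.all(np.isfinite(finals[1]))
        np.testing.assert_allclose(finals[0], finals[1], atol=0.02)

    def test_nonpositive_dt_rejected(self, hybrid):
        with pytest.raises(ValueError):
            CompiledNetwork.compile(hybrid, dt_ms=0.0)
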