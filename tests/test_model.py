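"""Core neural-mass types, transfer function, expansion, integration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rwwfit as rf
from rwwfit.constants import ModelConstants
from rwwfit.model import (MIN_REGIONAL_WEIGHT, Connectome, FreeParams, MapSet,
                          RegionalWeights, SimConfig, coefficient_bounds,
                          delay_matrix, expand_regional_params, simulate,
                          simulate_with_delay, transfer_rate)

C = ModelConstants()


class TestTransferRate:
    def test_removable_singularity_returns_inverse_curvature(self):
        assert transfer_rate(C.b_E, "E") == pytest.approx(1 / C.d_E)  # 6.25 Hz
        assert transfer_rate(C.b_I, "I") == pytest.approx(1 / C.d_I)

    @pytest.mark.parametrize("eps", [1e-9, -1e-9])
    def test_continuity_at_threshold(self, eps):
        r = transfer_rate(C.b_E + eps / C.a_E, "E")
        assert abs(r - 1 / C.d_E) < 1e-6

    def test_asymptotic_linearity(self):
        I = 1.5  # far above threshold
        assert transfer_rate(I, "E") == pytest.approx(C.a_E * (I - C.b_E), rel=1e-12)

    def test_value_at_fic_target_current(self):
        # frozen from direct evaluation of x/(1-exp(-d x)) at x = a(I-b)
        assert transfer_rate(0.37738, "E") == pytest.approx(3.0981482, abs=1e-6)

    @given(st.floats(-0.5, 1.5))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_nonnegative_everywhere(self, I):
        assert transfer_rate(I, "E") >= 0
        assert transfer_rate(I, "I") >= 0


class TestCoefficientBounds:
    @pytest.mark.parametrize("mmax, mmin, expected", [
        (2.0, -2.0, (-0.5, 0.5)),
        (1.0, -1.0, (-1.0, 1.0)),
    ])
    def test_formula(self, mmax, mmin, expected):
        m = np.array([mmax, 0.1, mmin])
        assert coefficient_bounds(m) == pytest.approx(expected)

    def test_consistent_with_reported_two_decimal_ranges(self):
        # a map with extremes 2.083 / -1.695 has bounds [-0.48, 0.59] at 2 d.p.
        lo, hi = coefficient_bounds(np.array([2.083, 0.0, -1.695]))
        assert round(lo, 2) == -0.48
        assert round(hi, 2) == 0.59

    def test_one_sided_map_rejected(self):
        with pytest.raises(ValueError):
            coefficient_bounds(np.array([0.5, 1.0]))

    def test_interior_coefficient_keeps_weight_positive(self, maps):
        for m in maps.maps:
            lo, hi = coefficient_bounds(m)
            for c in (lo + 1e-9, hi - 1e-9):
                assert np.all(1 + c * m > -1e-9)


class TestExpandRegionalParams:
    def test_zero_coefficients_identity(self, maps):
        theta = FreeParams(1.0, 0.3, 0.4, np.zeros(maps.k), np.zeros(maps.k))
        w = expand_regional_params(theta, maps)
        assert np.allclose(w.w_EE, 0.3)
        assert np.allclose(w.w_EI, 0.4)

    def test_hand_evaluated_two_node_example(self):
        maps2 = MapSet(np.array([[1.0, -1.0]]))
        theta = FreeParams(1.0, 0.2, 0.2, [0.5], [0.5])
        w = expand_regional_params(theta, maps2)
        assert w.w_EE == pytest.approx([0.3, 0.1])

    def test_min_shift_preserves_pairwise_differences(self):
        maps2 = MapSet(np.array([[1.0, -1.0]]))
        # wb*(1 + c*M) = 0.05*(1 -+ 2) -> (-0.05, 0.15): min below floor
        theta = FreeParams(1.0, 0.05, 0.3, [-2.0], [0.0])
        w = expand_regional_params(theta, maps2)
        assert w.w_EE.min() == pytest.approx(MIN_REGIONAL_WEIGHT)
        assert np.ptp(w.w_EE) == pytest.approx(0.2)  # differences preserved

    def test_dimension_mismatch_rejected(self, maps):
        theta = FreeParams(1.0, 0.3, 0.4, np.zeros(2), np.zeros(2))
        with pytest.raises(ValueError, match="maps"):
            expand_regional_params(theta, maps)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_floor_always_respected(self, seed):
        rng = np.random.default_rng(seed)
        maps_r = MapSet.from_raw(rng.normal(size=(3, 8)))
        bounds = FreeParams.default_bounds(maps_r)
        lo, hi = bounds[:, 0], bounds[:, 1]
        v = lo + rng.random(bounds.shape[0]) * (hi - lo)
        w = expand_regional_params(FreeParams.from_vector(v, 3), maps_r)
        assert w.w_EE.min() >= MIN_REGIONAL_WEIGHT - 1e-12
        assert w.w_EI.min() >= MIN_REGIONAL_WEIGHT - 1e-12


class TestTypes:
    def test_connectome_diagonal_forced_zero(self):
        conn = Connectome(weights=np.ones((3, 3)))
        assert np.all(np.diag(conn.weights) == 0)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            Connectome(weights=np.array([[0, -1.0], [1.0, 0]]))

    def test_mapset_requires_zscore(self):
        with pytest.raises(ValueError, match="z-scored"):
            MapSet(np.array([[1.0, 2.0, 3.0]]))

    def test_freeparams_vector_round_trip(self, maps):
        theta = FreeParams(1.2, 0.3, 0.4, np.arange(maps.k) * 0.01,
                           -np.arange(maps.k) * 0.01)
        back = FreeParams.from_vector(theta.to_vector(), maps.k)
        assert np.array_equal(back.to_vector(), theta.to_vector())
        assert theta.dim == 3 + 2 * maps.k

    def test_default_bounds_fifteen_parameters_for_six_maps(self, maps):
        b = FreeParams.default_bounds(maps)
        assert b.shape == (15, 2)
        assert tuple(b[0]) == (0.5, 4.0)
        assert tuple(b[1]) == (0.05, 0.75)

    def test_sim_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(duration=10.0, burn_in=30.0)
        with pytest.raises(ValueError):
            SimConfig(TR=0.0025)  # not a multiple of dt_bold
        assert SimConfig(TR=3.0, duration=450.0, burn_in=30.0).n_volumes == 140


class TestSimulate:
    def test_isolated_node_baseline_currents(self, single_node):
        """With zero gating and no noise the currents equal the baselines."""
        c0 = ModelConstants(sigma_noise=1e-300)
        cfg = SimConfig(TR=1e-3, duration=1e-3, burn_in=0.0, dt_bold=1e-4,
                        dt_neuronal=1e-4)
        w = RegionalWeights([1.0], [1.0], [1.0])
        out = simulate(single_node, w, 0.0, cfg, constants=c0,
                       record_bold=False, init_S_E=np.zeros(1),
                       init_S_I=np.zeros(1))
        # averages over the 10 steps include state drift; the first-step
        # current is the dominant term and the average stays near W_E
        assert out.mean_I_E[0] == pytest.approx(C.W_E, abs=5e-3)

    def test_symmetric_nodes_stay_identical_without_noise(self):
        conn = Connectome(weights=np.array([[0.0, 0.01], [0.01, 0.0]]))
        c0 = ModelConstants(sigma_noise=1e-300)
        cfg = SimConfig(TR=0.5, duration=2.0, burn_in=1.0)
        w = RegionalWeights([0.5, 0.5], [0.5, 0.5], [1.0, 1.0])
        out = simulate(conn, w, 1.0, cfg, constants=c0, record_bold=False)
        assert out.mean_S_E[0] == out.mean_S_E[1]
        assert out.mean_I_E[0] == out.mean_I_E[1]

    def test_inhibitory_gating_tracks_rate_times_tau(self, single_node):
        """Noise-off steady state satisfies S_I = H_I(I_I) * tau_I."""
        c0 = ModelConstants(sigma_noise=1e-300)
        cfg = SimConfig(TR=0.5, duration=4.0, burn_in=3.0)
        w = RegionalWeights([1.0], [1.0], [1.236])
        out = simulate(single_node, w, 0.0, cfg, constants=c0, record_bold=False)
        I_I = C.W_I + 1.0 * out.mean_S_E[0] - C.w_II * out.mean_S_I[0]
        assert out.mean_S_I[0] == pytest.approx(
            transfer_rate(I_I, "I") * C.tau_I, abs=1e-3)

    def test_bit_exact_reproducibility(self, connectome, balanced_weights,
                                       theta_true, short_cfg):
        a = simulate(connectome, balanced_weights, theta_true.G, short_cfg)
        b = simulate(connectome, balanced_weights, theta_true.G, short_cfg)
        assert np.array_equal(a.bold, b.bold)
        assert np.array_equal(a.mean_I_E, b.mean_I_E)

    def test_volume_count_and_shape(self, connectome, balanced_weights,
                                    theta_true, short_cfg):
        out = simulate(connectome, balanced_weights, theta_true.G, short_cfg)
        assert out.bold.shape == (10, short_cfg.n_volumes)
        assert short_cfg.n_volumes == 10  # floor((60-30)/3)

    def test_gating_record_stays_in_unit_interval(self, connectome,
                                                  balanced_weights, theta_true):
        """Even with 100x noise the clamped gating never leaves [0, 1]."""
        from rwwfit import _kernels
        big = ModelConstants(sigma_noise=1.0)
        n = connectome.n_nodes
        D = np.zeros((n, n), np.int64)
        se, *_ , ok = _kernels.integrate_neuronal(
            connectome.weights, D, 1, balanced_weights.w_EE,
            balanced_weights.w_EI, balanced_weights.w_IE, theta_true.G,
            1e-4, 20000, 0, 10, np.full(n, 0.001), np.full(n, 0.001),
            big.sigma_noise, 3, big.W_E, big.W_I, big.J_NMDA, big.w_II,
            big.a_E, big.b_E, big.d_E, big.a_I, big.b_I, big.d_I,
            big.tau_E, big.tau_I, big.gamma_kin)
        assert ok
        assert se.min() >= 0.0 and se.max() <= 1.0

    def test_zero_coupling_decouples_nodes(self):
        """At G=0 a two-node network reproduces two independent single-node
        runs exactly (noise off)."""
        c0 = ModelConstants(sigma_noise=1e-300)
        cfg = SimConfig(TR=0.5, duration=2.0, burn_in=1.0)
        conn2 = Connectome(weights=np.array([[0.0, 0.5], [0.5, 0.0]]))
        w2 = RegionalWeights([0.4, 0.7], [0.3, 0.6], [1.0, 1.5])
        out2 = simulate(conn2, w2, 0.0, cfg, constants=c0, record_bold=False)
        single = Connectome(weights=np.zeros((1, 1)))
        for i in range(2):
            w1 = RegionalWeights([w2.w_EE[i]], [w2.w_EI[i]], [w2.w_IE[i]])
            out1 = simulate(single, w1, 0.0, cfg, constants=c0,
                            record_bold=False)
            assert out1.mean_S_E[0] == pytest.approx(out2.mean_S_E[i], abs=1e-12)


class TestDelays:
    def test_uniform_lengths_give_uniform_delay(self):
        n = 3
        L = np.full((n, n), 60.0)
        np.fill_diagonal(L, 0.0)
        conn = Connectome(weights=np.full((n, n), 0.01), lengths=L)
        D = delay_matrix(conn, velocity=3.0, interval=1e-3)
        off = ~np.eye(n, dtype=bool)
        # 60 mm at 3 m/s = 20 ms = 20 intervals
        assert np.all(D[off] == 20)

    def test_velocity_must_be_positive_and_lengths_present(self, connectome):
        cfg = SimConfig(TR=0.5, duration=1.0, burn_in=0.5, velocity=-1.0)
        with pytest.raises(ValueError):
            delay_matrix(connectome, -1.0, 1e-3)
        bare = Connectome(weights=connectome.weights)
        with pytest.raises(ValueError, match="lengths"):
            delay_matrix(bare, 2.0, 1e-3)

    def test_two_node_cross_term_matches_explicit_buffer(self):
        """Delayed network input equals a hand-rolled Euler loop with an
        explicit delay line (noise off)."""
        c0 = ModelConstants(sigma_noise=1e-300)
        L = np.array([[0.0, 12.0], [12.0, 0.0]])
        W = np.array([[0.0, 0.02], [0.02, 0.0]])
        conn = Connectome(weights=W, lengths=L)
        cfg = SimConfig(TR=0.1, duration=0.5, burn_in=0.4, velocity=2.0,
                        dt_bold=1e-3)
        w = RegionalWeights([0.6, 0.2], [0.4, 0.5], [1.0, 1.2])
        out = simulate_with_delay(conn, w, 1.5, cfg, constants=c0,
                                  record_bold=False)

        # oracle: explicit ring buffer at the 1 ms global-input interval
        dt, gi = 1e-4, 10
        d_steps = int(round(12.0e-3 / 2.0 / 1e-3))   # 6 ms -> 6 intervals
        n_steps = int(0.5 / dt)
        S_E = np.full(2, cfg.s_init)
        S_I = np.full(2, cfg.s_init)
        hist = [np.full(2, cfg.s_init)] * (d_steps + 1)
        net = np.zeros(2)
        sums = np.zeros(2)
        burn = int(0.4 / dt)
        count = 0
        for step in range(n_steps):
            if step % gi == 0:
                hist.append(S_E.copy())
                delayed = hist[-1 - d_steps]
                net = np.array([W[0, 1] * delayed[1], W[1, 0] * delayed[0]])
            I_E = c0.W_E + w.w_EE * S_E + 1.5 * c0.J_NMDA * net - w.w_IE * S_I
            I_I = c0.W_I + w.w_EI * S_E - c0.w_II * S_I
            r_E = np.array([transfer_rate(v, "E", c0) for v in I_E])
            r_I = np.array([transfer_rate(v, "I", c0) for v in I_I])
            if step >= burn:
                sums += I_E
                count += 1
            S_E = np.clip(S_E + dt * (-S_E / c0.tau_E
                                      + (1 - S_E) * c0.gamma_kin * r_E), 0, 1)
            S_I = np.clip(S_I + dt * (-S_I / c0.tau_I + r_I), 0, 1)
        assert out.mean_I_E == pytest.approx(sums / count, abs=1e-9)

    def test_large_velocity_limit_equals_plain_one_ms_interval(
            self, connectome, balanced_weights, theta_true):
        """Zero-delay limit: huge velocity reproduces the delay-free
        integrator at the same 1 ms global-input interval, bit-exactly."""
        cfg_d = SimConfig(TR=1.0, duration=5.0, burn_in=2.0, noise_seed=9,
                          velocity=1e9)
        cfg_p = SimConfig(TR=1.0, duration=5.0, burn_in=2.0, noise_seed=9,
                          global_input_interval=1e-3)
        a = simulate_with_delay(connectome, balanced_weights, theta_true.G, cfg_d)
        b = simulate(connectome, balanced_weights, theta_true.G, cfg_p)
        assert np.array_equal(a.bold, b.bold)
        assert np.array_equal(a.mean_I_E, b.mean_I_E)
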