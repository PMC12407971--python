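"""Unit and property tests for the node model and network integrator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import fsolve

import jansenrit as jr
from jansenrit.params import NodeState


SP = jr.SigmoidParams()


class TestSigmoid:
    def test_midpoint_is_half_max(self):
        assert jr.sigmoid(6.0, SP) == pytest.approx(2.5)

    def test_saturation(self):
        assert jr.sigmoid(60.0, SP) == pytest.approx(5.0, abs=1e-6)

    def test_value_at_zero(self):
        assert jr.sigmoid(0.0, SP) == pytest.approx(5.0 / (1.0 + np.exp(0.56 * 6.0)))

    @given(st.floats(-30, 30), st.floats(-30, 30))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_increasing(self, v1, v2):
        # bounds are strict away from float saturation (|v| < ~70 mV)
        s1, s2 = jr.sigmoid(v1, SP), jr.sigmoid(v2, SP)
        assert 0.0 < s1 < 5.0
        if v1 + 1e-9 < v2:
            assert s1 < s2


class TestPSPKernel:
    def test_peak_at_inverse_time_constant(self):
        assert jr.psp_impulse_response(3.9, 120.0, 1.0 / 120.0) == pytest.approx(3.9 / np.e)

    @pytest.mark.parametrize("A,a", [(3.9, 120.0), (26.4, 60.0), (21.45, 660.0)])
    def test_boundary_and_decay(self, A, a):
        assert jr.psp_impulse_response(A, a, 0.0) == 0.0
        assert jr.psp_impulse_response(A, a, -0.5) == 0.0
        assert jr.psp_impulse_response(A, a, 100.0) == pytest.approx(0.0, abs=1e-12)
        t = np.linspace(0, 0.5, 1000)
        h = jr.psp_impulse_response(A, a, t)
        assert h.max() <= A / np.e + 1e-12


class TestGammaGains:
    def test_printed_formulas(self):
        A, B = jr.resolve_gamma_gains(660.0, 330.0)
        assert A == pytest.approx(21.45)
        assert B == pytest.approx(145.2)

    def test_recovers_alpha_gains_at_alpha_constants(self):
        assert jr.resolve_gamma_gains(120.0, 60.0) == pytest.approx((3.9, 26.4))

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            jr.resolve_gamma_gains(-1.0, 330.0)


class TestCombinedOutputs:
    def _state(self, va, vg, n=1):
        st_ = NodeState.initial(n, 33.75)
        st_.x1_a += va
        st_.x1_g += vg
        return st_

    def test_pure_alpha_and_gamma(self):
        s = self._state(2.0, 4.0)
        assert jr.combined_output(s, 1.0) == pytest.approx(2.0)
        assert jr.combined_output(s, 0.0) == pytest.approx(4.0)

    def test_midpoint_mixture(self):
        assert jr.combined_output(self._state(2.0, 4.0), 0.5) == pytest.approx(3.0)

    def test_rate_midpoint(self):
        s = self._state(6.0, 6.0)
        assert jr.combined_pyramidal_rate(s, 1.0, SP) == pytest.approx(2.5)
        # equal PSPs: mixture collapses to the single-population rate
        assert jr.combined_pyramidal_rate(s, 0.37, SP) == pytest.approx(2.5)

    def test_rate_mixture_weights(self):
        s = self._state(0.0, 60.0)
        expected = 0.3 * jr.sigmoid(0.0, SP) + 0.7 * jr.sigmoid(60.0, SP)
        assert jr.combined_pyramidal_rate(s, 0.3, SP) == pytest.approx(expected)


class TestNodeDerivatives:
    def test_origin_values(self, base_config):
        cfg = base_config
        st_ = NodeState.initial(1, cfg.circuit.C4_init, zeta0=float(jr.sigmoid(0.0, SP)))
        d = jr.node_derivatives(st_, 0.0, 0.0, cfg)
        s0 = jr.sigmoid(0.0, SP)
        cc = cfg.circuit
        for sub, tag in ((cfg.alpha, "a"), (cfg.gamma, "g")):
            assert getattr(d, f"y0_{tag}")[0] == pytest.approx(sub.A * sub.a * s0)
            assert getattr(d, f"y1_{tag}")[0] == pytest.approx(sub.A * sub.a * cc.C2 * s0)
            assert getattr(d, f"y2_{tag}")[0] == pytest.approx(
                sub.B * sub.b * cc.C4_init * s0)
            assert getattr(d, f"x0_{tag}")[0] == 0.0

    def test_drive_enters_linearly_in_dy1_only(self, base_config):
        cfg = base_config
        st_ = NodeState.initial(1, 33.75, zeta0=0.2)
        d0 = jr.node_derivatives(st_, 220.0, 0.0, cfg)
        d1 = jr.node_derivatives(st_, 440.0, 0.0, cfg)
        assert d1.y1_a[0] - d0.y1_a[0] == pytest.approx(cfg.alpha.A * cfg.alpha.a * 220.0)
        assert d1.y1_g[0] - d0.y1_g[0] == pytest.approx(cfg.gamma.A * cfg.gamma.a * 220.0)
        for f in NodeState._FIELDS:
            if not f.startswith("y1"):
                assert np.allclose(getattr(d0, f), getattr(d1, f))

    def test_vanishes_at_root_found_fixed_point(self, base_config):
        """Root-finding oracle: the derivative is ~0 at the numerically
        solved deterministic fixed point of each subpopulation."""
        cfg = base_config.with_(isp_enabled=False)
        cc, p = cfg.circuit, 220.0
        st_ = NodeState.initial(1, cc.C4_init, zeta0=0.0)
        for sub, tag in ((cfg.alpha, "a"), (cfg.gamma, "g")):
            def resid(x):
                x0, x1, x2 = x
                return [
                    sub.A / sub.a * jr.sigmoid(x1 - x2, SP) - x0,
                    sub.A / sub.a * (p + cc.C2 * jr.sigmoid(cc.C1 * x0, SP)) - x1,
                    sub.B / sub.b * cc.C4_init * jr.sigmoid(cc.C3 * x0, SP) - x2,
                ]
            x0, x1, x2 = fsolve(resid, [0.1, 4.0, 2.0], xtol=1e-13)
            getattr(st_, f"x0_{tag}")[0] = x0
            getattr(st_, f"x1_{tag}")[0] = x1
            getattr(st_, f"x2_{tag}")[0] = x2
            getattr(st_, f"zp_{tag}")[0] = jr.sigmoid(x1 - x2, SP)
            getattr(st_, f"zi_{tag}")[0] = jr.sigmoid(cc.C3 * x0, SP)
        d = jr.node_derivatives(st_, p, 0.0, cfg)
        norm = np.sqrt(sum(float(getattr(d, f)[0]) ** 2 for f in NodeState._FIELDS))
        assert norm < 1e-8


class TestISPDerivative:
    PP = jr.PlasticityParams(rho=2.5, tau=2.0, beta=1.0, C4_min=0.0)

    def test_zero_at_target_rate(self):
        assert jr.isp_derivative(30.0, 1.0, 2.5, self.PP, 135.0) == 0.0

    def test_zero_at_soft_bound(self):
        pp = jr.PlasticityParams(rho=2.5, C4_min=5.0)
        assert jr.isp_derivative(5.0, 1.0, 4.0, pp, 135.0) == 0.0

    def test_hand_value(self):
        # (1/2) * 1 * (3.5 - 2.5) * (33.75/135)^1 = 0.125
        val = jr.isp_derivative(0.25 * 135.0, 1.0, 3.5, self.PP, 135.0)
        assert val == pytest.approx(0.5 * 1.0 * 1.0 * 0.25)

    def test_sign_follows_rate_error(self):
        assert jr.isp_derivative(30.0, 1.0, 3.0, self.PP, 135.0) > 0
        assert jr.isp_derivative(30.0, 1.0, 2.0, self.PP, 135.0) < 0


class TestCouplingDrive:
    def test_decoupled_at_k_zero(self, base_config):
        st_ = NodeState.initial(3, 33.75)
        st_.x1_a += np.array([1.0, 5.0, -2.0])
        M = np.ones((3, 3)) - np.eye(3)
        assert np.all(jr.coupling_drive(st_, M, 0.0, 135.0, 0.5, SP) == 0.0)

    def test_two_node_midpoint(self):
        st_ = NodeState.initial(2, 33.75)
        st_.x1_a[1] = 6.0  # node 2 combined PSP at threshold (r_alpha = 1)
        M = np.array([[0.0, 1.0], [1.0, 0.0]])
        drive = jr.coupling_drive(st_, M, 0.7, 135.0, 1.0, SP)
        assert drive[0] == pytest.approx(0.7 * 135.0 * 2.5)

    def test_matches_bruteforce_double_loop(self, rng):
        n, K, C, ra = 5, 0.8, 135.0, 0.3
        st_ = NodeState.initial(n, 33.75)
        for f in ("x1_a", "x2_a", "x1_g", "x2_g"):
            setattr(st_, f, rng.normal(0, 5, n))
        M = rng.uniform(0, 1, (n, n))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0.0)
        expected = np.zeros(n)
        for i in range(n):
            for j in range(n):
                if i != j:
                    vj = ra * (st_.x1_a[j] - st_.x2_a[j]) + (1 - ra) * (st_.x1_g[j] - st_.x2_g[j])
                    expected[i] += K * C * M[i, j] * jr.sigmoid(vj, SP)
        assert np.allclose(jr.coupling_drive(st_, M, K, C, ra, SP), expected)

    def test_dimension_mismatch(self):
        st_ = NodeState.initial(2, 33.75)
        with pytest.raises(ValueError):
            jr.coupling_drive(st_, np.zeros((3, 3)), 1.0, 135.0, 0.5, SP)


class TestEMStep:
    def test_noise_free_reduces_to_euler(self, base_config):
        cfg = base_config.with_(p_sd=0.0, K=0.2)
        M = np.array([[0.0, 0.5], [0.5, 0.0]])
        st_ = NodeState.initial(2, cfg.circuit.C4_init, zeta0=0.17)
        st_.x1_a += 1.0
        net = jr.coupling_drive(st_, M, cfg.K, cfg.circuit.C, cfg.circuit.r_alpha, SP)
        d = jr.node_derivatives(st_, cfg.drive.p_mean, net, cfg)
        new = jr.em_step(st_, cfg, M, 1e-3)
        for f in NodeState._FIELDS:
            assert np.allclose(getattr(new, f), getattr(st_, f) + 1e-3 * getattr(d, f))

    def test_diffusion_noise_variance_scaling(self, base_config):
        """Monte-Carlo check of the Euler-Maruyama increment variance
        against the stated (A a sigma_p)^2 dt scaling."""
        cfg = base_config.with_(noise_mode="diffusion", K=0.0)
        M = np.zeros((1, 1))
        st_ = NodeState.initial(1, cfg.circuit.C4_init, zeta0=0.17)
        rng_ = np.random.default_rng(7)
        dt = 1e-3
        base = jr.em_step(st_, cfg.with_(p_sd=0.0), M, dt).y1_a[0]
        incs = np.array([jr.em_step(st_, cfg, M, dt, rng_).y1_a[0] - base
                         for _ in range(4000)])
        expected_var = (cfg.alpha.A * cfg.alpha.a * cfg.drive.p_sd) ** 2 * dt
        assert np.var(incs) == pytest.approx(expected_var, rel=0.1)
        assert np.mean(incs) == pytest.approx(0.0, abs=3 * np.sqrt(expected_var / 4000))


class TestSimulate:
    def test_kernel_matches_reference_steps(self, base_config):
        """The compiled network kernel reproduces repeated reference
        Euler steps (noise-free, ISP on, coupled nodes)."""
        cfg = base_config.with_(K=0.5, r_alpha=0.5, isp_enabled=True, p_sd=0.0)
        M = np.array([[0.0, 1.0], [1.0, 0.0]])
        prot = jr.SimulationProtocol(t_sim=0.4, t_discard=0.0, out_fs=1000.0)
        res = jr.simulate(cfg, prot, M=M)
        st_ = NodeState.initial(2, cfg.circuit.C4_init,
                                zeta0=float(jr.sigmoid(0.0, SP)))
        for k in range(res.eeg.shape[0] - 1):
            assert np.allclose(res.eeg[k], jr.combined_output(st_, 0.5), atol=1e-9)
            st_ = jr.em_step(st_, cfg, M, prot.dt)

    def test_seeded_determinism_bit_identical(self, base_config, short_protocol):
        r1 = jr.simulate(base_config, short_protocol, seed=42)
        r2 = jr.simulate(base_config, short_protocol, seed=42)
        assert np.array_equal(r1.eeg, r2.eeg)
        assert np.array_equal(r1.rate_pyr, r2.rate_pyr)
        assert np.array_equal(r1.c4, r2.c4)
        r3 = jr.simulate(base_config, short_protocol, seed=43)
        assert not np.array_equal(r1.eeg, r3.eeg)

    def test_output_shapes_and_rate_bounds(self, base_config, short_protocol):
        res = jr.simulate(base_config, short_protocol, seed=1)
        n_expected = int(round((16.0 - 6.0) * 200.0))
        assert res.eeg.shape == (n_expected, 1)
        assert res.rate_pyr.min() >= 0.0
        assert res.rate_pyr.max() <= SP.zeta_max

    def test_c4_respects_floor(self, base_config):
        cfg = base_config.with_(isp_enabled=True, C4_min=20.0, rho=4.5)
        prot = jr.SimulationProtocol(t_sim=30.0, t_discard=1.0, out_fs=200.0)
        res = jr.simulate(cfg, prot, seed=0)
        assert res.c4.min() >= 20.0 - 1e-12

    def test_blowup_raises_with_diagnostic(self, base_config):
        # dt far beyond the gamma kernel stability limit forces divergence
        cfg = base_config.with_(p_sd=0.0)
        prot = jr.SimulationProtocol(dt=0.05, t_sim=100.0, t_discard=1.0, out_fs=20.0)
        with pytest.raises(jr.SimulationError, match="non-finite"):
            jr.simulate(cfg, prot)

    def test_classical_jansen_rit_regression(self):
        """With r_alpha=1, no ISP and the classical constants, the model
        reduces to the classical Jansen-Rit system; compare one noise-free
        trajectory against an independently coded Euler integrator."""
        A, B, a, b = 3.25, 22.0, 100.0, 50.0
        C = 135.0
        C1, C2, C3, C4 = C, 0.8 * C, 0.25 * C, 0.25 * C
        p, dt, n_steps = 220.0, 1e-3, 3000

        def S(v):
            return 5.0 / (1.0 + np.exp(0.56 * (6.0 - v)))

        y = np.zeros(6)
        trace = np.empty(n_steps)
        for k in range(n_steps):
            trace[k] = y[2] - y[4]
            x0, v0, x1, v1, x2, v2 = y
            dy = np.array([
                v0, A * a * S(x1 - x2) - 2 * a * v0 - a * a * x0,
                v1, A * a * (p + C2 * S(C1 * x0)) - 2 * a * v1 - a * a * x1,
                v2, B * b * C4 * S(C3 * x0) - 2 * b * v2 - b * b * x2,
            ])
            y = y + dt * dy

        cfg = jr.ModelConfig().with_(A_alpha=A, B_alpha=B, a_alpha=a, b_alpha=b,
                                     r_alpha=1.0, isp_enabled=False, p_sd=0.0, K=0.0)
        prot = jr.SimulationProtocol(t_sim=3.0, t_discard=0.0, out_fs=1000.0)
        res = jr.simulate(cfg, prot)
        assert np.allclose(res.eeg[:n_steps, 0], trace, atol=1e-9)


class TestAttractorScan:
    def test_infinite_threshold_flags_nothing(self, base_config):
        cfg = base_config.with_(r_alpha=1.0, p_sd=0.0, isp_enabled=False)
        prot = jr.SimulationProtocol(t_sim=8.0, t_discard=4.0, out_fs=200.0)
        tab = jr.attractor_scan([150.0, 250.0], cfg, prot, amplitude_threshold=np.inf)
        assert not tab["oscillating"].any()

    def test_rejects_unsorted(self, base_config):
        with pytest.raises(ValueError):
            jr.attractor_scan([300.0, 100.0], base_config)

    def test_fixed_point_below_oscillatory_range(self, base_config):
        cfg = base_config.with_(r_alpha=1.0, p_sd=0.0, isp_enabled=False)
        prot = jr.SimulationProtocol(t_sim=40.0, t_discard=30.0, out_fs=200.0)
        tab = jr.attractor_scan([50.0, 220.0], cfg, prot)
        assert not tab["oscillating"].iloc[0]
        assert tab["oscillating"].iloc[1]
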