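"""Mean-field dynamics: transfer function, Euler step, simulation contracts.

Noise-free trajectories are checked against an independent high-accuracy
ODE integration (scipy solve_ivp) of the same vector field, and the
compiled simulation loop is checked for exact agreement with the
transparent per-step reference on a shared noise stream.
"""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from lesionkit import (Connectome, DMFParams, DMFState, simulate, step,
                       transfer_rate)
from lesionkit.dmf import NetworkIntegrator


def three_node_connectome() -> Connectome:
    w = np.array([[0.0, 0.5, 0.2],
                  [0.5, 0.0, 0.8],
                  [0.2, 0.8, 0.0]])
    return Connectome(w, list("abc"))


def reference_rhs(t, y, w, p, J):
    """Independent (plain-python) evaluation of the deterministic field."""
    n = w.shape[0]
    S_E, S_I = y[:n], y[n:]
    out = np.empty_like(y)
    for i in range(n):
        I_E = (p.w_E * p.I_0 + p.w_plus * p.J_N * S_E[i]
               + p.G * p.J_N * sum(w[i, j] * S_E[j] for j in range(n))
               - J[i] * S_I[i])
        I_I = p.w_I * p.I_0 + p.J_N * S_E[i] - p.w_II * S_I[i]
        x_e = p.a_E * I_E - p.b_E
        x_i = p.a_I * I_I - p.b_I
        r_E = x_e / (1.0 - np.exp(-p.d_E * x_e))
        r_I = x_i / (1.0 - np.exp(-p.d_I * x_i))
        out[i] = -S_E[i] / (p.tau_E / 1000.0) + (1 - S_E[i]) * p.gamma * r_E
        out[n + i] = -S_I[i] / (p.tau_I / 1000.0) + r_I
    return out


class TestTransferRate:
    def test_removable_singularity(self):
        p = DMFParams()
        at_threshold = p.b_E / p.a_E
        assert transfer_rate(at_threshold, p.a_E, p.b_E, p.d_E) == pytest.approx(
            1.0 / p.d_E)  # 6.25 Hz for d_E = 0.16

    def test_value_at_default_drive(self):
        # direct high-precision evaluation of (aI-b)/(1-exp(-d(aI-b)))
        p = DMFParams()
        x = p.a_E * 0.382 - p.b_E
        expected = x / (1.0 - np.exp(-p.d_E * x))
        assert transfer_rate(0.382, p.a_E, p.b_E, p.d_E) == pytest.approx(
            expected, rel=1e-12)
        assert expected == pytest.approx(3.5269, abs=2e-4)

    def test_linear_asymptote(self):
        p = DMFParams()
        for I in (5.0, 50.0):
            x = p.a_E * I - p.b_E
            assert transfer_rate(I, p.a_E, p.b_E, p.d_E) / x == pytest.approx(1.0)

    def test_monotone_and_nonnegative(self):
        p = DMFParams()
        I = np.linspace(-1.0, 2.0, 400)
        r = transfer_rate(I, p.a_E, p.b_E, p.d_E)
        assert np.all(r >= 0)
        assert np.all(np.diff(r) > 0)

    def test_continuous_through_threshold(self):
        p = DMFParams()
        thr = p.b_E / p.a_E
        eps = 1e-9
        lo = transfer_rate(thr - eps, p.a_E, p.b_E, p.d_E)
        hi = transfer_rate(thr + eps, p.a_E, p.b_E, p.d_E)
        assert abs(hi - lo) < 1e-5


class TestStep:
    def test_fixed_point_is_stationary(self):
        """A noise-free single node placed at its own fixed point stays put."""
        p = DMFParams(sigma=0.0, G=0.0)
        c = Connectome(np.zeros((1, 1)), ["a"])
        J = 1.0

        def rhs(y):
            return reference_rhs(0.0, y, c.weights, p, [J])

        from scipy.optimize import fsolve
        y0 = fsolve(rhs, [0.16, 0.04], full_output=False)
        state = DMFState(S_E=np.array([y0[0]]), S_I=np.array([y0[1]]),
                         J=np.array([J]))
        out = step(state, c, p)
        assert abs(out.S_E[0] - y0[0]) < 1e-10
        assert abs(out.S_I[0] - y0[1]) < 1e-10

    def test_noise_free_matches_reference_integrator(self):
        """1 s of noise-free network dynamics vs high-accuracy solve_ivp."""
        c = three_node_connectome()
        p = DMFParams(sigma=0.0, G=0.8, dt=1.0)
        J = np.array([1.0, 1.2, 0.9])
        state = DMFState(S_E=np.full(3, 0.05), S_I=np.full(3, 0.05), J=J)
        for _ in range(1000):
            state = step(state, c, p)
        y0 = np.concatenate([np.full(3, 0.05), np.full(3, 0.05)])
        ref = solve_ivp(reference_rhs, (0.0, 1.0), y0, args=(c.weights, p, J),
                        method="Radau", rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(state.S_E, ref.y[:3, -1], atol=1e-4)
        np.testing.assert_allclose(state.S_I, ref.y[3:, -1], atol=1e-4)

    def test_clipping_contract(self):
        c = Connectome(np.zeros((2, 2)), ["a", "b"])
        p = DMFParams(sigma=1.0)
        state = DMFState.initial(2)
        big = np.full(2, 1e6)
        out = step(state, c, p, noise=(big, -big))
        assert np.all(out.S_E == 1.0)
        assert np.all(out.S_I == 0.0)

    def test_dimension_mismatch_raises(self):
        c = three_node_connectome()
        with pytest.raises(ValueError, match="regions"):
            step(DMFState.initial(2), c, DMFParams(sigma=0.0))


class TestSimulate:
    def test_deterministic_given_seed(self):
        c = three_node_connectome()
        p = DMFParams(G=0.5)
        a = simulate(c, p, J=1.0, duration=3.0, transient=1.0, seed=42)
        b = simulate(c, p, J=1.0, duration=3.0, transient=1.0, seed=42)
        np.testing.assert_array_equal(a.r_E, b.r_E)
        np.testing.assert_array_equal(a.I_E, b.I_E)

    def test_decoupled_identical_nodes_have_identical_rates(self):
        """With G=0 and no noise, identical nodes evolve identically."""
        c = Connectome(np.zeros((4, 4)), list("abcd"))
        p = DMFParams(sigma=0.0, G=0.0)
        res = simulate(c, p, J=1.0, duration=5.0, transient=2.0)
        assert np.ptp(res.r_E) < 1e-12
        assert np.ptp(res.I_E) < 1e-12

    def test_single_node_mean_rate_matches_root_finding_oracle(self):
        """Noise-free mean r_E equals the fixed-point rate of the
        two-population steady-state equations found independently."""
        p = DMFParams(sigma=0.0, G=0.0)
        c = Connectome(np.zeros((1, 1)), ["a"])
        J = 1.0

        tau_e = p.tau_E / 1000.0
        tau_i = p.tau_I / 1000.0

        def phi(I, a, b, d):
            x = a * I - b
            return x / (1.0 - np.exp(-d * x))

        def s_i_of_s_e(s_e):
            return brentq(lambda s_i: tau_i * phi(
                p.w_I * p.I_0 + p.J_N * s_e - p.w_II * s_i,
                p.a_I, p.b_I, p.d_I) - s_i, 0.0, 1.0)

        def g(s_e):
            s_i = s_i_of_s_e(s_e)
            r_e = phi(p.w_E * p.I_0 + p.w_plus * p.J_N * s_e - J * s_i,
                      p.a_E, p.b_E, p.d_E)
            return p.gamma * r_e * tau_e / (1.0 + p.gamma * r_e * tau_e) - s_e

        s_e_star = brentq(g, 0.0, 0.99)
        r_star = phi(p.w_E * p.I_0 + p.w_plus * p.J_N * s_e_star
                     - J * s_i_of_s_e(s_e_star), p.a_E, p.b_E, p.d_E)
        res = simulate(c, p, J=J, duration=20.0, transient=10.0)
        assert res.r_E[0] == pytest.approx(r_star, abs=1e-3)

    def test_gating_bounds_on_recorded_trace(self):
        c = three_node_connectome()
        p = DMFParams(G=0.5, sigma=0.05)
        res = simulate(c, p, J=1.0, duration=4.0, transient=1.0,
                       record_stride=5, seed=7)
        assert res.S_E_trace is not None
        assert res.S_E_trace.min() >= 0.0
        assert res.S_E_trace.max() <= 1.0

    def test_raising_J_lowers_firing(self):
        c = three_node_connectome()
        p = DMFParams(sigma=0.0, G=0.5)
        lo = simulate(c, p, J=np.array([1.0, 1.0, 1.0]), duration=5, transient=2)
        hi = simulate(c, p, J=np.array([1.5, 1.0, 1.0]), duration=5, transient=2)
        assert hi.r_E[0] < lo.r_E[0]

    def test_duration_must_exceed_transient(self):
        c = three_node_connectome()
        with pytest.raises(ValueError):
            simulate(c, DMFParams(), duration=1.0, transient=2.0)


class TestKernelEquivalence:
    def test_compiled_loop_matches_step_reference(self):
        """The numba loop and the python step agree to rounding error when
        fed the same noise increments (they share formulas and op order;
        only the matvec summation order may differ)."""
        c = three_node_connectome()
        p = DMFParams(G=0.7, sigma=0.02, seed=0)
        n_steps = 250
        rng = np.random.default_rng(99)
        eta_E = rng.standard_normal((n_steps, 3))
        eta_I = rng.standard_normal((n_steps, 3))

        state = DMFState.initial(3, J=1.1)
        for t in range(n_steps):
            state = step(state, c, p, noise=(eta_E[t], eta_I[t]))

        class _FixedNoise:
            def __init__(self, e, i):
                self.seq = [e, i]

            def standard_normal(self, shape):
                return self.seq.pop(0)

        integ = NetworkIntegrator(c, p, J=1.1)
        integ.run(n_steps, _FixedNoise(eta_E, eta_I))
        np.testing.assert_allclose(integ.state.S_E, state.S_E, atol=1e-13)
        np.testing.assert_allclose(integ.state.S_I, state.S_I, atol=1e-13)
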