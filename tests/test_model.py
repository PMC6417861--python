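"""Dynamics-core tests: force balance, reaction terms, stepping, conservation."""

import dataclasses

import numpy as np
import pytest

from parpolar import (
    CortexState,
    NumericalError,
    SolverOptions,
    default_params,
    homogeneous_steady_state,
    reaction_terms,
    run_to_steady_state,
    solve_force_balance,
    step,
)
from parpolar.scenarios import make_scenario


class TestForceBalance:
    def test_uniform_P_gives_zero_flow(self, params):
        v = solve_force_balance(np.full(64, 2.5), params, dx=0.5)
        assert np.allclose(v, 0.0, atol=1e-14)

    def test_single_fourier_mode_closed_form(self, params):
        # P = P0 + eps*cos(kx) on a ring  =>  v = eps*beta*k*sin(kx)/(eta k^2 + gamma)
        L, n = 127.5, 256
        x = np.arange(n) * (L / n)
        k = 2 * np.pi / L
        eps = 0.41
        P = params.scales.P0 + eps * np.cos(k * x)
        v = solve_force_balance(P, params, dx=L / n)
        v_exact = eps * params.beta * k * np.sin(k * x) / (params.eta * k**2 + params.gamma)
        assert np.max(np.abs(v - v_exact)) <= 1e-8 * np.max(np.abs(v_exact))

    def test_matches_dense_direct_solve(self, params, rng):
        # brute-force oracle: assemble the discretized operator as dense
        # matrices (spectral differentiation, built column by column from the
        # identity) and solve the linear system directly
        n, L = 64, 100.0
        dx = L / n
        P = rng.uniform(0.0, 3.0, n)
        v = solve_force_balance(P, params, dx)

        k = 2 * np.pi * np.fft.rfftfreq(n, dx)

        def spectral_matrix(symbol):
            cols = [
                np.fft.irfft(symbol * np.fft.rfft(col), n=n) for col in np.eye(n)
            ]
            return np.array(cols).T

        D1 = spectral_matrix(1j * k)
        D2 = spectral_matrix(-(k**2))
        Pi = params.pi_active_0 - params.beta * P + params.pi_passive
        A = params.gamma * np.eye(n) - params.eta * D2
        v_dense = np.linalg.solve(A, D1 @ Pi)
        assert np.max(np.abs(v - v_dense)) <= 1e-8 * max(np.max(np.abs(v_dense)), 1e-30)

    def test_zero_friction_uses_zero_mean_flow(self, params):
        p = dataclasses.replace(params, gamma=0.0)
        P = np.cos(2 * np.pi * np.arange(32) / 32) + 2.0
        v = solve_force_balance(P, p, dx=1.0)
        assert abs(v.mean()) < 1e-12

    def test_singular_and_bad_grid_rejected(self, params):
        with pytest.raises(ValueError):
            solve_force_balance(np.ones(4), params, dx=1.0)
        p = dataclasses.replace(params, eta=0.0, gamma=0.0)
        with pytest.raises(ValueError):
            solve_force_balance(np.ones(32), p, dx=1.0)


class TestReactionTerms:
    def test_pure_attachment_when_membrane_empty(self, params):
        n = 32
        konP = np.full(n, params.kon_P)
        dA, dP, dAc, dPc = reaction_terms(
            np.zeros(n), np.zeros(n), 1.0, 1.0, konP, params
        )
        assert np.allclose(dA, params.kon_A * 1.0)
        assert np.allclose(dP, params.kon_P * 1.0)
        assert dAc == pytest.approx(-params.psi * params.kon_A)

    def test_detailed_balance_fixed_point(self, params):
        p = dataclasses.replace(params, k_AP=0.0, k_PA=0.0)
        Ac, Pc = 0.8, 0.6
        A = p.kon_A * Ac / p.koff_A
        P = p.kon_P * Pc / p.koff_P
        n = 16
        dA, dP, dAc, dPc = reaction_terms(
            np.full(n, A), np.full(n, P), Ac, Pc, np.full(n, p.kon_P), p
        )
        assert np.allclose(dA, 0.0, atol=1e-15)
        assert np.allclose(dP, 0.0, atol=1e-15)

    def test_single_point_hand_computed(self, params):
        # direct arithmetic with the package's default rate constants
        p = params
        A, P, Ac, Pc = 1.5, 0.4, 1.1, 0.9
        dA, dP, _, _ = reaction_terms(
            np.array([A]), np.array([P]), Ac, Pc, np.array([p.kon_P]), p
        )
        want_dA = p.kon_A * Ac - p.koff_A * A - p.k_AP * P * A
        want_dP = p.kon_P * Pc - p.koff_P * P - p.k_PA * A**2 * P
        assert dA[0] == pytest.approx(want_dA, rel=1e-12)
        assert dP[0] == pytest.approx(want_dP, rel=1e-12)

    def test_negative_input_rejected(self, params):
        with pytest.raises(ValueError):
            reaction_terms(
                np.array([-0.1]), np.array([0.0]), 1.0, 1.0, np.array([0.05]), params
            )

    def test_mass_conservation_by_construction(self, params, rng):
        n = 64
        A = rng.uniform(0, 2, n)
        P = rng.uniform(0, 3, n)
        dA, dP, dAc, dPc = reaction_terms(A, P, 1.0, 0.7, np.full(n, params.kon_P), params)
        assert dAc + params.psi * dA.mean() == pytest.approx(0.0, abs=1e-15)
        assert dPc + params.psi * dP.mean() == pytest.approx(0.0, abs=1e-15)


def _uniform_state(params, n=64, L=127.5):
    A0, P0, Ac, Pc = homogeneous_steady_state(params)
    x = np.arange(n) * (L / n)
    return CortexState(
        x=x, A=np.full(n, A0), P=np.full(n, P0), v=np.zeros(n), A_cyto=Ac, P_cyto=Pc, t=0.0
    )


class TestStep:
    def test_homogeneous_fixed_point_stays_uniform(self, base_params):
        # alpha = 0, beta = 0, no trigger: uniform state is invariant
        p = base_params.with_nondim(0.0, 0.0)
        st = _uniform_state(p)
        for _ in range(50):
            st = step(st, None, p, dt=0.25)
        assert np.ptp(st.A) < 1e-12 and np.ptp(st.P) < 1e-12

    def test_mirror_symmetry_preserved(self, params):
        # mirror-symmetric initial data + mirror-symmetric attachment stay symmetric
        sc = make_scenario("no-trigger", "ellipse")
        st = sc.build(params, 64).initial_state(params)
        L = st.x.size * st.dx
        d = np.cos(2 * np.pi * st.x / L)  # even perturbation about the pole
        st.P = st.P + 0.05 * d - 0.05 * d.min()
        for _ in range(200):
            st = step(st, sc, params, dt=0.2)
        mirrored = np.concatenate(([st.P[0]], st.P[1:][::-1]))
        assert np.max(np.abs(st.P - mirrored)) < 1e-8 * max(st.P.max(), 1e-12)

    def test_step_converges_to_explicit_euler(self, params, rng):
        # one step equals explicit Euler of all terms up to O(dt^2)
        sc = make_scenario("no-trigger", "ellipse")
        prob = sc.build(params, 64)
        st = prob.initial_state(params)
        st.P = st.P + rng.uniform(0, 0.5, 64)
        st.A = st.A * rng.uniform(0.8, 1.0, 64)

        def one_step_error(dt):
            after = step(st, sc, params, dt)
            # explicit-Euler reference assembled from the elementary operators
            v = solve_force_balance(st.P, params, st.dx)
            dA, dP, dAc, dPc = reaction_terms(
                st.A, st.P, st.A_cyto, st.P_cyto, prob.kon_P_profile, params
            )

            def ddx(f):
                return (np.roll(f, -1) - np.roll(f, 1)) / (2 * st.dx)

            def lap(f):
                return (np.roll(f, -1) - 2 * f + np.roll(f, 1)) / st.dx**2

            euler_P = st.P + dt * (params.D_P * lap(st.P) - ddx(v * st.P) + dP)
            return np.max(np.abs(after.P - euler_P))

        e1 = one_step_error(0.2)
        e2 = one_step_error(0.1)
        e3 = one_step_error(0.05)
        assert e2 < 0.6 * e1 and e3 < 0.6 * e2  # vanishes faster than O(dt)

    def test_unstable_dt_raises(self, params):
        sc = make_scenario("wt", "ellipse")
        st = sc.build(params, 64).initial_state(params)
        st.P = st.P + 2.0 * np.exp(-((st.x - 30) ** 2) / 20.0)
        with pytest.raises(NumericalError):
            st2 = st
            for _ in range(50):
                st2 = step(st2, sc, params, dt=500.0)


class TestSteadyState:
    def test_mass_conserved_over_full_run(self, params):
        sc = make_scenario("wt", "ellipse")
        opts = SolverOptions(n=96, t_max=1500.0, record=False)
        st0 = sc.build(params, 96).initial_state(params)
        tot0 = st0.total_mass(params)
        res = run_to_steady_state(sc, params, opts)
        tot1 = res.state.total_mass(params)
        assert abs(tot1[0] - tot0[0]) / tot0[0] < 1e-6
        assert abs(tot1[1] - tot0[1]) / tot0[1] < 1e-6

    def test_quiescence_without_curvature_coupling(self, base_params):
        # alpha = 0, no trigger: no spurious symmetry breaking
        p = base_params.with_nondim(0.0, 100.0)
        sc = make_scenario("no-trigger", "ellipse")
        res = run_to_steady_state(sc, p, SolverOptions(n=96, t_max=1200.0, record=False))
        assert res.converged
        assert np.ptp(res.state.P) < 1e-9

    def test_nonconvergence_is_flagged(self, params):
        sc = make_scenario("no-trigger", "ellipse")
        res = run_to_steady_state(
            sc, params, SolverOptions(n=96, t_max=60.0, record=False)
        )
        assert not res.converged
        assert res.P_settled is not None

    def test_kymograph_recorded(self, params):
        sc = make_scenario("no-trigger", "ellipse")
        res = run_to_steady_state(
            sc, params, SolverOptions(n=64, t_max=300.0, record=True, save_dt=50.0)
        )
        k = res.kymograph
        assert k is not None
        assert k.values.shape == (k.times.size, k.positions.size)
        assert k.times[0] == 0.0
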