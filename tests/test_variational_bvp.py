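import numpy as np
import pytest

from varode.priors import fit_spline_prior
from varode.variational_bvp import (AugmentedSystem, augmented_rhs,
                                    continuous_chi2, eliminate_input,
                                    solve_augmented_bvp, stationarity_check,
                                    forward_solve)
from varode.model_core import extend_positive_input

from conftest import TOY_P, TOY_Y0, T_END, const_sigma_rep, zero_residual_system


def toy_reference_rhs(A, B, uA, uB, k1, k2, SA, SB, Sx, s2A, s2B, s2x):
    """The printed augmented toy system, coded independently as an oracle:
    x = Sx + Sσx²·k1·A·(uA−uB); Ȧ, Ḃ mass action; u̇ carries the misfit."""
    x = Sx + s2x * k1 * A * (uA - uB)
    dA = -k1 * A * x + k2 * B
    dB = k1 * A * x - k2 * B
    duA = k1 * x * (uA - uB) - (A - SA) / s2A
    duB = -k2 * (uA - uB) - (B - SB) / s2B
    return x, np.array([dA, dB, duA, duB])


class TestEliminateInput:
    def test_zero_adjoint_returns_prior(self, gaussian_zero_residual):
        system, course = gaussian_zero_residual
        x = eliminate_input(system, np.array([0.8, 0.2]), np.zeros(2), 1.3,
                            TOY_P)
        assert x[0] == pytest.approx(course(1.3), rel=1e-12)

    def test_printed_toy_relation_value(self, toy):
        # S_x=1, Sσx²=0.25, k1=2, A=1, u=(0.3,−0.1) → x = 1 + 0.25·2·1·0.4
        system = AugmentedSystem(
            toy,
            [const_sigma_rep(lambda t: np.ones_like(np.asarray(t, float)), 1.0)
             for _ in range(2)],
            [const_sigma_rep(lambda t: np.ones_like(np.asarray(t, float)), 0.25)])
        x = eliminate_input(system, np.array([1.0, 0.5]),
                            np.array([0.3, -0.1]), 0.0, np.array([2.0, 0.5]))
        assert x[0] == pytest.approx(1.2, abs=1e-14)

    def test_general_elimination_matches_toy_closed_form(self, toy):
        rng = np.random.default_rng(5)
        s2x = 0.37
        system = AugmentedSystem(
            toy,
            [const_sigma_rep(lambda t: np.full_like(np.asarray(t, float), 0.6), 0.8)
             for _ in range(2)],
            [const_sigma_rep(lambda t: np.full_like(np.asarray(t, float), 1.4), s2x)])
        for _ in range(20):
            y = rng.uniform(0.1, 2, 2)
            u = rng.uniform(-1, 1, 2)
            p = rng.uniform(0.1, 2, 2)
            x = eliminate_input(system, y, u, 2.0, p)
            x_ref = 1.4 + s2x * p[0] * y[0] * (u[0] - u[1])
            assert x[0] == pytest.approx(x_ref, rel=1e-12)


class TestAugmentedRHS:
    def _system(self, toy, SA=1.0, SB=0.0, Sx=1.5, s2=0.01, s2x=0.25):
        mk = lambda v, s: const_sigma_rep(
            lambda t: np.full_like(np.asarray(t, float), v), s)
        return AugmentedSystem(toy, [mk(SA, s2), mk(SB, s2)], [mk(Sx, s2x)])

    def test_zero_residual_state_is_stationary(self, toy):
        system = self._system(toy, SA=0.9, SB=0.3, Sx=1.5)
        state = np.array([0.9, 0.3, 0.0, 0.0])  # y = S_y, u = 0
        d = augmented_rhs(system, 0.7, state, TOY_P)
        f_expected = toy.f([0.9, 0.3], [1.5], TOY_P)
        np.testing.assert_allclose(d[:2], f_expected, rtol=1e-12)
        np.testing.assert_allclose(d[2:], 0.0, atol=1e-14)

    def test_adjoint_source_printed_values(self, toy):
        # (A,B) = (S_A,S_B) = (1,0), u = (0.3,−0.1): residual terms vanish,
        # u̇_A = k1·x·0.4, u̇_B = −k2·0.4 with x from the elimination
        system = self._system(toy, SA=1.0, SB=0.0, Sx=1.5, s2x=0.25)
        u = np.array([0.3, -0.1])
        state = np.array([1.0, 0.0, *u])
        x = eliminate_input(system, state[:2], u, 0.5, TOY_P)[0]
        d = augmented_rhs(system, 0.5, state, TOY_P)
        assert d[2] == pytest.approx(TOY_P[0] * x * 0.4, rel=1e-12)
        assert d[3] == pytest.approx(-TOY_P[1] * 0.4, rel=1e-12)

    def test_mass_conservation_any_adjoint(self, toy):
        system = self._system(toy, SA=0.7, SB=0.5, Sx=0.9)
        rng = np.random.default_rng(2)
        for _ in range(10):
            state = rng.uniform(-1, 2, 4)
            d = augmented_rhs(system, rng.uniform(0, 5), state, TOY_P)
            assert abs(d[0] + d[1]) < 1e-12

    def test_general_rhs_matches_printed_toy_system(self, toy):
        """Sign self-consistency: the generic adjoint assembly reduces to the
        printed two-species system on random states."""
        SA, SB, Sx = 0.8, 0.4, 1.1
        s2A, s2B, s2x = 0.02, 0.05, 0.3
        mk = lambda v, s: const_sigma_rep(
            lambda t: np.full_like(np.asarray(t, float), v), s)
        system = AugmentedSystem(toy, [mk(SA, s2A), mk(SB, s2B)],
                                 [mk(Sx, s2x)])
        rng = np.random.default_rng(8)
        for _ in range(30):
            A, B = rng.uniform(0.05, 2, 2)
            uA, uB = rng.uniform(-1, 1, 2)
            k1, k2 = rng.uniform(0.1, 3, 2)
            x_ref, d_ref = toy_reference_rhs(A, B, uA, uB, k1, k2,
                                             SA, SB, Sx, s2A, s2B, s2x)
            state = np.array([A, B, uA, uB])
            p = np.array([k1, k2])
            x = eliminate_input(system, state[:2], state[2:], 1.0, p)
            d = augmented_rhs(system, 1.0, state, p)
            assert x[0] == pytest.approx(x_ref, rel=1e-12)
            np.testing.assert_allclose(d, d_ref, rtol=1e-12, atol=1e-14)

    def test_nonfinite_state_reports_time(self, toy):
        system = self._system(toy)
        with pytest.raises(FloatingPointError, match="t="):
            augmented_rhs(system, 1.25, np.array([np.inf, 0, 0, 0]), TOY_P)


class TestBVPSolve:
    @pytest.mark.parametrize("family", ["exp_decay", "activation", "gaussian"])
    def test_zero_residual_fixture_recovered(self, toy, family):
        system, course = zero_residual_system(toy, family)
        traj = solve_augmented_bvp(system, TOY_P, TOY_Y0)
        assert np.max(np.abs(traj.u)) <= 1e-6
        for i, pr in enumerate(system.priors_y):
            assert np.max(np.abs(traj.y[i] - pr.S(traj.grid))) <= 1e-6
        assert np.max(np.abs(traj.x[0] - course(traj.grid))) <= 1e-6

    def test_boundary_conditions(self, toy, gaussian_zero_residual):
        system, _ = gaussian_zero_residual
        traj = solve_augmented_bvp(system, TOY_P * 1.3, TOY_Y0 + [0.1, 0.2])
        np.testing.assert_allclose(traj.y[:, 0], TOY_Y0 + [0.1, 0.2],
                                   atol=1e-8)
        assert np.max(np.abs(traj.u[:, -1])) <= 1e-5

    def test_y0_shape_checked(self, toy, gaussian_zero_residual):
        system, _ = gaussian_zero_residual
        with pytest.raises(ValueError, match="y0"):
            solve_augmented_bvp(system, TOY_P, np.array([1.0]))

    def test_bvp_improves_on_prior_input(self, toy):
        """With perturbed species priors the stationary input achieves a
        continuous χ² no worse than freezing x at its prior course."""
        system, course = zero_residual_system(toy, "gaussian")
        pert = [const_sigma_rep(
            lambda t, i=i, pr=pr: pr.S(t) + 0.05 * np.sin(3 * np.asarray(t, float) + i),
            0.01) for i, pr in enumerate(system.priors_y)]
        psys = AugmentedSystem(toy, pert, system.priors_x)
        traj = solve_augmented_bvp(psys, TOY_P, TOY_Y0)
        J_bvp = continuous_chi2(traj)
        J_frozen = continuous_chi2(
            lambda t: np.atleast_2d(course(t)), psys.priors_y, psys.priors_x,
            model=toy, p=TOY_P, y0=TOY_Y0)
        assert J_bvp <= J_frozen + 1e-9


class TestContinuousChi2:
    def test_zero_at_truth(self, gaussian_zero_residual):
        system, course = gaussian_zero_residual
        J = continuous_chi2(lambda t: np.atleast_2d(course(t)),
                            system.priors_y, system.priors_x,
                            model=system.model, p=TOY_P, y0=TOY_Y0)
        assert J == pytest.approx(0.0, abs=1e-10)

    def test_constant_offset_closed_form(self, toy):
        """Offsetting one species prior by c under constant weight w adds
        w·c²·T to the functional."""
        system, course = zero_residual_system(toy, "exp_decay")
        c, s2 = 0.2, 0.01
        off = [const_sigma_rep(
            lambda t, pr=system.priors_y[0]: pr.S(t) + c, s2),
            system.priors_y[1]]
        osys = AugmentedSystem(toy, off, system.priors_x)
        J = continuous_chi2(lambda t: np.atleast_2d(course(t)),
                            osys.priors_y, osys.priors_x,
                            model=toy, p=TOY_P, y0=TOY_Y0)
        assert J == pytest.approx(c ** 2 / s2 * T_END, rel=1e-6)

    def test_quadrature_converged(self, toy, gaussian_zero_residual):
        system, course = gaussian_zero_residual
        pert = lambda t: np.atleast_2d(course(t) + 0.1)
        kw = dict(model=toy, p=TOY_P, y0=TOY_Y0)
        J1 = continuous_chi2(pert, system.priors_y, system.priors_x,
                             grid=np.linspace(0, T_END, 401), **kw)
        J2 = continuous_chi2(pert, system.priors_y, system.priors_x,
                             grid=np.linspace(0, T_END, 801), **kw)
        assert abs(J2 - J1) <= 1e-6 * max(J1, 1.0)


class TestStationarity:
    def test_fixture_first_variation_vanishes(self, toy,
                                              gaussian_zero_residual):
        system, _ = gaussian_zero_residual
        traj = solve_augmented_bvp(system, TOY_P, TOY_Y0)
        assert stationarity_check(system, traj, n_directions=5) <= 1e-6

    def test_solution_is_stationary_on_misfit_priors(self, toy):
        """On perturbed priors the diagnostic at the BVP solution is orders
        of magnitude below its value at the non-stationary prior course."""
        system, course = zero_residual_system(toy, "gaussian")
        pert = [const_sigma_rep(
            lambda t, i=i, pr=pr: pr.S(t) + 0.05 * np.sin(3 * np.asarray(t, float) + i),
            0.01) for i, pr in enumerate(system.priors_y)]
        psys = AugmentedSystem(toy, pert, system.priors_x)
        traj = solve_augmented_bvp(psys, TOY_P, TOY_Y0)
        at_solution = stationarity_check(psys, traj, n_directions=5)

        # same diagnostic at x = S_x (not stationary here)
        from varode.variational_bvp import _bump_directions
        rng = np.random.default_rng(0)
        grid = np.linspace(0, T_END, 401)
        eps = 1e-2
        worst = 0.0
        for h in _bump_directions(0, T_END, 5, rng):
            Js = [continuous_chi2(
                lambda t, s=s: np.atleast_2d(course(t) + s * eps * h(t)),
                psys.priors_y, psys.priors_x, model=toy, p=TOY_P, y0=TOY_Y0,
                grid=grid) for s in (+1, -1)]
            worst = max(worst, abs(Js[0] - Js[1]) / (2 * eps))
        assert worst > 0.1
        assert at_solution <= 1e-3 * worst

    def test_perturbed_course_less_stationary(self, toy,
                                              gaussian_zero_residual):
        system, course = gaussian_zero_residual
        traj = solve_augmented_bvp(system, TOY_P, TOY_Y0)
        base = stationarity_check(system, traj, n_directions=3)

        class Shifted:
            """Trajectory stand-in whose input course is displaced."""
            p, y0 = traj.p, traj.y0
            grid, x = traj.grid, traj.x

            def x_at(self, t):
                return np.atleast_2d(traj.x_at(t)) + 0.1
        worse = stationarity_check(system, Shifted(), n_directions=3)
        assert worse > 10 * max(base, 1e-9)

    def test_local_minimality(self, toy):
        """J[x*+εh] ≥ J[x*] − 1e-9 for random smooth bumps at the solution."""
        system, _ = zero_residual_system(toy, "gaussian")
        pert = [const_sigma_rep(
            lambda t, i=i, pr=pr: pr.S(t) + 0.04 * np.cos(2 * np.asarray(t, float) + i),
            0.01) for i, pr in enumerate(system.priors_y)]
        psys = AugmentedSystem(toy, pert, system.priors_x)
        traj = solve_augmented_bvp(psys, TOY_P, TOY_Y0)
        grid = np.linspace(0, T_END, 401)
        J_star = continuous_chi2(traj, grid=grid)
        rng = np.random.default_rng(1)
        from varode.variational_bvp import _bump_directions
        for h in _bump_directions(0, T_END, 50, rng):
            eps = rng.uniform(0.002, 0.02)
            J_pert = continuous_chi2(
                lambda t: np.atleast_2d(traj.x_at(t)) + eps * h(t),
                psys.priors_y, psys.priors_x, model=toy, p=TOY_P, y0=TOY_Y0,
                grid=grid)
            assert J_pert >= J_star - 1e-9


class TestNonlinearInputRouting:
    def test_nonlinear_entry_rejected_at_construction(self, toy):
        from varode.model_core import ODEModel

        def f(y, x, p):
            v = p[0] * y[0] * x[0] ** 2
            return np.array([-v, v])

        nonlin = ODEModel(
            n=2, m=1, r=1, f=f,
            jac_y=lambda y, x, p: np.array([[-p[0] * x[0] ** 2, 0],
                                            [p[0] * x[0] ** 2, 0]]),
            jac_x=lambda y, x, p: np.array([[-2 * p[0] * y[0] * x[0]],
                                            [2 * p[0] * y[0] * x[0]]]),
            linear_input=False)
        mk = lambda v, s: const_sigma_rep(
            lambda t: np.full_like(np.asarray(t, float), v), s)
        with pytest.raises(ValueError, match="extend_positive_input"):
            AugmentedSystem(nonlin, [mk(1, 0.01), mk(0, 0.01)], [mk(1, 0.25)])

    def test_positivity_extension_is_accepted(self, toy):
        ext = extend_positive_input(toy)
        mk = lambda v, s: const_sigma_rep(
            lambda t: np.full_like(np.asarray(t, float), v), s)
        system = AugmentedSystem(
            ext, [mk(1, 0.01), mk(0, 0.01), mk(1, 0.25)], [mk(0, 1.0)])
        assert system.dimension == 6
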