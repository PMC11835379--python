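"""Tests for the factorized single-cell density model."""

import numpy as np
import pytest

from dtpdyn.grid import Grid
from dtpdyn.params import CellularParams, DoseSchedule, EpigeneticParams
from dtpdyn.population import PopulationState
from dtpdyn.singlecell import (
    DensityState,
    SingleCellSolver,
    cell_type_probabilities,
    density_from_population,
    evolve_g,
    initial_density,
    simulate_singlecell,
    stationary_g,
    step_g,
    step_h,
    survival_curve,
)


class TestDensityFromPopulation:
    def test_joint_density_normalized(self, ep, cp, small_grid, rng):
        state = PopulationState(
            rng.random((small_grid.nx, small_grid.ny)) + 0.1, 0.0, small_grid
        )
        ds = density_from_population(state)
        total = ds.f.sum() * small_grid.dx * small_grid.dy
        assert total == pytest.approx(1.0, abs=1e-8)
        assert ds.g.sum() * small_grid.dx == pytest.approx(1.0, abs=1e-6)
        h_mass = ds.h.sum(axis=1) * small_grid.dy
        np.testing.assert_allclose(h_mass, 1.0, atol=1e-6)

    def test_separable_state_has_x_independent_h(self, small_grid, rng):
        u = rng.random(small_grid.nx) + 0.5
        w = rng.random(small_grid.ny) + 0.5
        state = PopulationState(np.outer(u, w), 0.0, small_grid)
        ds = density_from_population(state)
        expected = np.tile(ds.h[0], (small_grid.nx, 1))
        np.testing.assert_allclose(ds.h, expected, rtol=1e-10)

    def test_round_trip(self, small_grid, rng):
        Q = rng.random((small_grid.nx, small_grid.ny))
        state = PopulationState(Q.copy(), 0.0, small_grid)
        ds = density_from_population(state)
        np.testing.assert_allclose(
            ds.f * state.Q_hat, Q, rtol=1e-12, atol=1e-15
        )

    def test_empty_rejected(self, small_grid):
        state = PopulationState(
            np.zeros((small_grid.nx, small_grid.ny)), 0.0, small_grid
        )
        with pytest.raises(ValueError):
            density_from_population(state)


class TestStepG:
    def test_conservation_1000_steps(self, ep, cp, small_grid):
        g = stationary_g(ep, cp, 0.0, small_grid)
        g = g + 0.2 * np.sin(2 * np.pi * small_grid.x)  # perturb
        g = np.clip(g, 0.0, None)
        g /= g.sum() * small_grid.dx
        out = g.copy()
        for _ in range(1000):
            out = step_g(out, ep, cp, 0.9, 0.01, small_grid)
        assert out.sum() * small_grid.dx == pytest.approx(1.0, abs=1e-5)

    def test_rhs_matches_quadrature_oracle(self, ep, cp, small_grid):
        # independent evaluation of the gain/loss integrals on a finer grid
        from dtpdyn import kernels

        g = np.exp(-0.5 * ((small_grid.x - 0.2) / 0.1) ** 2)
        g /= g.sum() * small_grid.dx
        out = step_g(g, ep, cp, 0.3, 1e-4, small_grid)
        rhs = (out - g) / 1e-4

        alpha = kernels.alpha_of_dose(ep, 0.3)
        b1 = np.asarray(kernels.beta1(small_grid.x, cp))
        P = kernels.inheritance_matrix(small_grid.x, alpha, ep, dx=small_grid.dx)
        mean_b1 = (b1 * g).sum() * small_grid.dx
        oracle = 2.0 * (P @ (b1 * g)) * small_grid.dx - g * (b1 + mean_b1)
        np.testing.assert_allclose(rhs, oracle, rtol=1e-6, atol=1e-9)

    def test_point_mass_at_fixed_point_is_stationary(self, small_grid):
        # near-faithful kernel: a point mass at the fixed point of the
        # daughter-mean map barely moves in one step
        from scipy.optimize import brentq

        from dtpdyn import kernels

        ep = EpigeneticParams(
            phi0=0.02, phi1=0.9, alpha0=5.0, k=1.0, n=1.0, eta0=50_000.0
        )
        cp = CellularParams(beta0=0.3, beta10=0.0)
        z_star = brentq(
            lambda z: kernels.phi(z, 5.0, ep) - z, 0.1, 0.99
        )
        i = np.argmin(np.abs(small_grid.x - z_star))
        g = np.zeros(small_grid.nx)
        g[i] = 1.0 / small_grid.dx
        out = step_g(g, ep, cp, 0.0, 0.01, small_grid)
        # relative L1 change per unit time is tiny for the faithful kernel
        drift = np.abs(out - g).sum() * small_grid.dx / 0.01
        assert drift < 0.05

    def test_drug_shifts_marginal_up(self, ep, cp, small_grid):
        g0 = stationary_g(ep, cp, 0.0, small_grid)
        g_drug = evolve_g(g0, ep, cp, 0.9, 7.0, grid=small_grid)
        mean0 = (g0 * small_grid.x).sum() * small_grid.dx
        mean1 = (g_drug * small_grid.x).sum() * small_grid.dx
        assert mean1 > mean0

    def test_stationary_point_is_fixed(self, ep, cp, small_grid):
        g = stationary_g(ep, cp, 0.0, small_grid)
        out = step_g(g, ep, cp, 0.0, 0.1, small_grid)
        assert np.abs(out - g).sum() * small_grid.dx < 1e-9

    def test_eig_matches_iterated_fixed_point(self, ep, cp, small_grid):
        # two independent routes to the stationary marginal agree
        g_eig = stationary_g(ep, cp, 0.3, small_grid, method="eig")
        g_it = stationary_g(
            ep, cp, 0.3, small_grid, method="iterate", tol=1e-9
        )
        assert np.abs(g_eig - g_it).sum() * small_grid.dx < 1e-6

    def test_expm_matches_stepper(self, ep, cp, small_grid):
        g0 = stationary_g(ep, cp, 0.0, small_grid)
        a = evolve_g(g0, ep, cp, 0.9, 5.0, grid=small_grid, method="expm")
        b = evolve_g(g0, ep, cp, 0.9, 5.0, dt=0.002, grid=small_grid)
        assert np.abs(a - b).sum() * small_grid.dx < 1e-3


class TestStepH:
    def test_constant_gamma_cancels(self, ep, small_grid):
        # gamma independent of y: death term exactly cancels
        cp = CellularParams(gamma0=0.4, gamma1=0.0, v0=0.0, sigma=0.002)
        ds = initial_density(ep, cp, small_grid)
        h_adv_diff = step_h(
            ds.h, ds.g, ep, cp, 0.0, 0.01, small_grid, renormalize=False
        )
        cp2 = CellularParams(gamma0=0.0, gamma1=0.0, v0=0.0, sigma=0.002)
        h_pure = step_h(
            ds.h, ds.g, ep, cp2, 0.0, 0.01, small_grid, renormalize=False
        )
        np.testing.assert_allclose(h_adv_diff, h_pure, rtol=1e-10, atol=1e-12)

    def test_diffusion_relaxes_to_uniform(self, ep, small_grid):
        cp = CellularParams(gamma0=0.0, gamma1=0.0, v0=0.0, sigma=0.004)
        g = np.full(small_grid.nx, 1.0)
        h = np.zeros((small_grid.nx, small_grid.ny))
        h[:, small_grid.ny // 2] = small_grid.ny  # delta-ish, integrates to 1
        for _ in range(4000):
            h = step_h(h, g, ep, cp, 0.0, 0.01, small_grid)
        np.testing.assert_allclose(h, 1.0, atol=0.05)

    def test_drug_concentrates_near_adapted_equilibrium(self, ep, cp):
        grid = Grid(nx=10, ny=100)
        ds = initial_density(ep, cp, grid)
        h = ds.h
        for _ in range(6000):  # 60 days
            h = step_h(h, ds.g, ep, cp, 0.9, 0.01, grid)
        # mass above the phenotype threshold at a mid trait node
        i = np.argmin(np.abs(grid.x - 0.55))
        above = h[i, grid.y > 0.5].sum() * grid.dy
        assert above > 0.9
        mean_y = (h[i] * grid.y).sum() * grid.dy
        assert mean_y == pytest.approx(cp.y0_on, abs=0.1)


class TestCellTypeProbabilities:
    def test_point_mass_is_dtp(self, small_grid):
        g = np.zeros(small_grid.nx)
        ix = np.argmin(np.abs(small_grid.x - 0.3))
        g[ix] = 1.0 / small_grid.dx
        h = np.zeros((small_grid.nx, small_grid.ny))
        iy = np.argmin(np.abs(small_grid.y - 0.8))
        h[:, iy] = 1.0 / small_grid.dy
        ds = DensityState(g, h, 0.0, small_grid)
        pn, pd, pr = cell_type_probabilities(ds)
        assert pd == pytest.approx(1.0)

    def test_probabilities_sum_to_one(self, ep, cp, small_grid):
        ds = initial_density(ep, cp, small_grid)
        probs = cell_type_probabilities(ds)
        assert sum(probs) == pytest.approx(1.0, abs=1e-8)

    def test_matches_population_classification(self, ep, cp, small_grid, rng):
        from dtpdyn.population import classify_fractions

        state = PopulationState(
            rng.random((small_grid.nx, small_grid.ny)) + 0.05, 0.0, small_grid
        )
        ds = density_from_population(state)
        probs = cell_type_probabilities(ds)
        fr = classify_fractions(state)
        np.testing.assert_allclose(probs, fr.as_tuple(), atol=1e-10)


class TestSolverConsistency:
    def test_probability_conservation_drift(self, ep, cp, small_grid):
        # discrete drift of the trait-marginal integral < 1e-5 per day
        solver = SingleCellSolver(
            ep, cp, small_grid, DoseSchedule.constant(0.9), dt=0.01
        )
        ds = initial_density(ep, cp, small_grid)
        for _ in range(100):  # one day
            ds = solver.step(ds)
        assert abs(ds.g.sum() * small_grid.dx - 1.0) < 1e-5

    def test_resistance_nondecreasing_early_high_dose(self, ep, cp, small_grid):
        probs = simulate_singlecell(
            ep,
            cp,
            DoseSchedule.constant(0.9),
            10.0,
            dt=0.01,
            grid=small_grid,
            record_every=1.0,
        )
        surviving = probs["P_dtp"] + probs["P_resistant"]
        assert np.all(np.diff(surviving) > -1e-6)

    def test_matches_population_model_low_crowding(self, ep, small_grid):
        # with Q_hat << K the two formulations must agree for a while
        from dtpdyn.population import simulate as simulate_pop

        cp = CellularParams(K=1e6)
        traj = simulate_pop(
            ep,
            cp,
            DoseSchedule.constant(0.3),
            20.0,
            dt=0.01,
            grid=small_grid,
            mass_frac=1e-8,
        )
        probs = simulate_singlecell(
            ep, cp, DoseSchedule.constant(0.3), 20.0, dt=0.01, grid=small_grid
        )
        for key, arr in (
            ("P_naive", traj.frac_naive),
            ("P_dtp", traj.frac_dtp),
            ("P_resistant", traj.frac_resistant),
        ):
            assert abs(probs[key].iloc[-1] - arr[-1]) < 0.05


class TestSurvivalCurve:
    def test_starts_at_one(self, ep, cp):
        df = survival_curve(0.3, ep, cp, dose=0.9, t_end=1.0)
        assert df["S"].iloc[0] == pytest.approx(1.0)

    def test_monotone_nonincreasing(self, ep, cp):
        df = survival_curve(0.3, ep, cp, dose=0.9, t_end=10.0)
        assert np.all(np.diff(df["S"]) <= 1e-12)

    def test_drug_free_is_exponential(self, ep, cp):
        df = survival_curve(0.3, ep, cp, dose=0.0, t_end=5.0)
        np.testing.assert_allclose(
            df["S"], np.exp(-cp.gamma0 * df["t"]), rtol=1e-6
        )

    def test_high_trait_survives_drug_better(self, ep, cp):
        s_hi = survival_curve(0.5, ep, cp, dose=0.9, t_end=30.0)
        s_lo = survival_curve(0.05, ep, cp, dose=0.9, t_end=30.0)
        assert s_hi["S"].iloc[-1] > s_lo["S"].iloc[-1]
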