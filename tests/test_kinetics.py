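"""Master-equation propagation, population bookkeeping and IRF convolution."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.special import erfc

from fretquench import (
    DecayKinetics,
    MolecularEnsemble,
    PhotophysicalParams,
    average_ensembles,
    build_rate_matrix,
    convolve_irf,
    fluorescent_population,
    initial_condition,
    pair_transfer_rate,
    solve_master_equation,
)
from fretquench.rates import TransferRateMatrix
from tests.conftest import random_ensemble


class TestInitialCondition:
    def test_uniform_over_fluorescent_only(self):
        ens = random_ensemble(2, 4, seed=0)
        np.testing.assert_allclose(initial_condition(ens), 0.25)
        ens_t = random_ensemble(2, 4, seed=0, trap_frac=0.25)
        p0 = initial_condition(ens_t)
        assert p0.sum() == pytest.approx(1.0)
        assert (p0[ens_t.trap_mask] == 0).all()
        np.testing.assert_allclose(p0[~ens_t.trap_mask], 1.0 / 3.0)

    def test_all_trap_ensemble_rejected(self):
        ens = MolecularEnsemble(2, [10, 10], [[5.0, 5.0]], [[1.0, 0.0]], [True], 1.0)
        with pytest.raises(ValueError):
            initial_condition(ens)


class TestSolver:
    def test_isolated_donor_decays_exponentially(self, params2d, time_grid):
        ens = MolecularEnsemble(2, [10, 10], [[5.0, 5.0]], [[1.0, 0.0]], [False], 1.0)
        m = build_rate_matrix(ens, params2d)
        probs = solve_master_equation(m, initial_condition(ens), time_grid)
        np.testing.assert_allclose(probs[:, 0], np.exp(-time_grid / 5.0), atol=1e-12)
        assert probs[time_grid == 5.0, 0] == pytest.approx(np.exp(-1.0))

    def test_donor_trap_pair_matches_two_state_closed_form(
        self, donor_trap_pair, params2d, time_grid
    ):
        m = build_rate_matrix(donor_trap_pair, params2d)
        probs = solve_master_equation(m, initial_condition(donor_trap_pair), time_grid)
        k = pair_transfer_rate(params2d, 3.0)
        donor_exact = np.exp(-(1.0 / 5.0 + k) * time_grid)
        trap_exact = k / (1.0 / 5.0 + k) * (1.0 - donor_exact)
        np.testing.assert_allclose(probs[:, 0], donor_exact, atol=1e-8)
        np.testing.assert_allclose(probs[:, 1], trap_exact, atol=1e-8)

    def test_zero_generator_is_identity_propagator(self, time_grid):
        m = TransferRateMatrix(np.zeros((3, 3)), np.zeros(3, bool), tau_total=5.0)
        p0 = np.array([0.5, 0.3, 0.2])
        probs = solve_master_equation(m, p0, time_grid)
        np.testing.assert_allclose(probs, np.tile(p0, (len(time_grid), 1)))

    def test_semigroup_property(self, params3d):
        ens = random_ensemble(3, 40, seed=4, trap_frac=0.2)
        m = build_rate_matrix(ens, params3d)
        p0 = initial_condition(ens)
        direct = solve_master_equation(m, p0, np.array([0.0, 1.5, 4.0]))
        relay = solve_master_equation(m, direct[1], np.array([0.0, 2.5]))
        np.testing.assert_allclose(relay[1], direct[2], atol=1e-8)

    def test_global_probability_bookkeeping(self, params3d):
        # d/dt (sum_all P) = -sum_fluor P / tau_total, checked by trapezoid
        ens = random_ensemble(3, 50, seed=8, trap_frac=0.2)
        m = build_rate_matrix(ens, params3d)
        t = np.linspace(0, 10, 2001)
        probs = solve_master_equation(m, initial_condition(ens), t)
        total = probs.sum(axis=1)
        fluor = probs[:, ~ens.trap_mask].sum(axis=1)
        assert (np.diff(total) <= 1e-12).all()
        loss = np.trapezoid(fluor / 5.0, t)
        assert total[0] - total[-1] == pytest.approx(loss, rel=1e-6)

    def test_matches_independent_ode_integration(self, params2d):
        ens = random_ensemble(2, 30, seed=6, trap_frac=0.2)
        m = build_rate_matrix(ens, params2d)
        p0 = initial_condition(ens)
        t = np.linspace(0, 10, 11)
        ours = solve_master_equation(m, p0, t)
        sol = solve_ivp(
            lambda _, p: m.rates @ p, (0, 10), p0, t_eval=t, rtol=1e-10, atol=1e-12
        )
        np.testing.assert_allclose(ours, sol.y.T, atol=1e-7)

    def test_generic_fallback_for_asymmetric_generator(self, time_grid):
        # irreversible 2-state conversion without absorbing-column structure
        k = np.array([[-1.0, 0.0], [1.0, -0.2]])
        m = TransferRateMatrix(k, np.zeros(2, bool), tau_total=5.0)
        probs = solve_master_equation(m, np.array([1.0, 0.0]), np.array([0.0, 1.0, 2.0]))
        np.testing.assert_allclose(probs[:, 0], np.exp([-0.0, -1.0, -2.0]), atol=1e-9)

    def test_non_finite_matrix_rejected(self):
        with pytest.raises(ValueError):
            TransferRateMatrix(np.array([[np.nan]]), np.zeros(1, bool), tau_total=5.0)


class TestPopulationAndAveraging:
    def test_trap_excluded_from_fluorescent_sum(self, donor_trap_pair, params2d, time_grid):
        m = build_rate_matrix(donor_trap_pair, params2d)
        probs = solve_master_equation(m, initial_condition(donor_trap_pair), time_grid)
        kin = fluorescent_population(probs, donor_trap_pair.trap_mask, time_grid)
        k = pair_transfer_rate(params2d, 3.0)
        np.testing.assert_allclose(kin.values, np.exp(-(0.2 + k) * time_grid), atol=1e-8)
        assert kin.values[0] == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(kin.values) <= 1e-12).all()
        assert ((kin.values >= 0) & (kin.values <= 1)).all()

    def test_average_of_identical_curves_is_unchanged(self, time_grid):
        kin = DecayKinetics(time_grid, np.exp(-time_grid))
        avg = average_ensembles([kin, kin, kin])
        np.testing.assert_allclose(avg.values, kin.values)
        assert avg.n_configs == 3

    def test_average_arithmetic(self):
        t = np.array([0.0, 1.0])
        a = DecayKinetics(t, np.exp(-t))
        b = DecayKinetics(t, np.ones_like(t))
        avg = average_ensembles([a, b])
        assert avg.values[1] == pytest.approx(0.5 * (np.exp(-1) + 1.0))

    def test_mismatched_grids_rejected(self):
        a = DecayKinetics(np.array([0.0, 1.0]), np.array([1.0, 0.5]))
        b = DecayKinetics(np.array([0.0, 2.0]), np.array([1.0, 0.5]))
        with pytest.raises(ValueError, match="grid"):
            average_ensembles([a, b])

    def test_sem_shrinks_with_more_configurations(self, params2d, time_grid):
        from fretquench import simulate_decay

        small = simulate_decay(2, 100.0, 0.01, params2d, trap_model="random",
                               trap_fraction_value=0.3, n_configs=8, master_seed=1)
        big = simulate_decay(2, 100.0, 0.01, params2d, trap_model="random",
                             trap_fraction_value=0.3, n_configs=32, master_seed=1)
        mid = slice(20, 200)  # away from t=0 where all curves pinch to 1
        assert np.median(big.sem[mid]) < np.median(small.sem[mid])


class TestIRF:
    def test_narrow_kernel_shifts_curve(self, time_grid):
        kin = DecayKinetics(time_grid, np.exp(-time_grid / 5.0))
        dt = time_grid[1] - time_grid[0]
        out = convolve_irf(kin, fwhm=dt / 10.0, center=3.5)
        shift = int(round(3.5 / dt))
        np.testing.assert_allclose(out.values[shift : shift + 400],
                                   kin.values[:400], atol=5e-3)

    def test_mass_conservation(self, time_grid):
        kin = DecayKinetics(time_grid, np.exp(-time_grid / 2.0))
        out = convolve_irf(kin, fwhm=0.1, center=3.5)
        dt = time_grid[1] - time_grid[0]
        assert out.values.sum() * dt == pytest.approx(kin.values.sum() * dt, rel=1e-3)

    def test_matches_exponential_gaussian_closed_form(self):
        # exp(-t/tau) (x) Gaussian(mu, sigma) =
        # 1/2 exp(sigma^2/2tau^2 - (t-mu)/tau) erfc((sigma/tau - (t-mu)/sigma)/sqrt 2)
        tau, mu, fwhm = 5.0, 3.5, 0.1
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        t = np.linspace(0, 25, 2501)
        kin = DecayKinetics(t, np.exp(-t / tau))
        out = convolve_irf(kin, fwhm=fwhm, center=mu)
        x = out.time_grid - mu
        exact = 0.5 * np.exp(sigma**2 / (2 * tau**2) - x / tau) * erfc(
            (sigma / tau - x / sigma) / np.sqrt(2.0)
        )
        # the only discretization error is O(dt), pinned to the signal's
        # t=0 step (which the kernel maps to t=mu); elsewhere the discrete
        # convolution agrees with the closed form to near machine precision
        dt = t[1] - t[0]
        sel = (out.time_grid > 1.0) & (out.time_grid < 24.0) & (np.abs(x) > 0.5)
        np.testing.assert_allclose(out.values[sel], exact[sel], atol=1e-8)
        rise = np.abs(x) <= 0.5
        peak = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
        assert np.abs(out.values[rise] - exact[rise]).max() < 0.6 * dt * peak

    def test_invalid_fwhm_rejected(self, time_grid):
        kin = DecayKinetics(time_grid, np.exp(-time_grid))
        with pytest.raises(ValueError):
            convolve_irf(kin, fwhm=0.0)
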