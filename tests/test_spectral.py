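"""Eigendecomposition, autocorrelation, modal spectra and coherence."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.linalg import expm

import promodyn as pmd


class TestDecompose:
    def test_two_state_eigenvalues(self, telegraph_gm):
        dec = pmd.decompose(telegraph_gm)
        np.testing.assert_allclose(sorted(dec.eigenvalues.real), [-4.0, 0.0], atol=1e-12)
        assert np.all(dec.eigenvalues.imag == 0)

    def test_zero_mode_is_stationary_and_ones(self, telegraph_gm):
        dec = pmd.decompose(telegraph_gm)
        np.testing.assert_allclose(dec.pi, [0.75, 0.25], rtol=1e-12)
        np.testing.assert_allclose(dec.left[0], 1.0, rtol=1e-12)

    def test_biorthonormality_and_reconstruction(self):
        gm = pmd.build_generator(pmd.random_system(3, seed=11))
        dec = pmd.decompose(gm)
        np.testing.assert_allclose(dec.left @ dec.right, np.eye(8), atol=1e-9)
        recon = (dec.right * dec.eigenvalues) @ dec.left
        assert np.abs(recon.real - gm.M).max() <= 1e-8 * np.abs(gm.M).max()
        assert dec.reconstruction_residual < 1e-8

    def test_irreversible_four_cycle(self):
        gm = pmd.build_generator(pmd.homogeneous_cycle(4, kf=1.0))
        got = sorted(pmd.decompose(gm).eigenvalues, key=lambda z: (z.real, z.imag))
        want = sorted(pmd.cycle_eigenvalues(4, 1.0), key=lambda z: (z.real, z.imag))
        np.testing.assert_allclose(got, want, atol=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_closed_systems_have_real_spectrum(self, seed):
        system, _ = pmd.random_closed_system(3, seed)
        dec = pmd.decompose(pmd.build_generator(system))
        assert np.abs(dec.eigenvalues.imag).max() < 1e-9

    def test_conjugate_pairs(self):
        dec = pmd.decompose(pmd.build_generator(pmd.homogeneous_cycle(5, 1.0)))
        vals = dec.eigenvalues[np.abs(dec.eigenvalues.imag) > 1e-12]
        for lam in vals:
            assert np.min(np.abs(vals - lam.conjugate())) < 1e-10


class TestAutocorrelation:
    def test_two_state_closed_form(self, telegraph_gm):
        dec = pmd.decompose(telegraph_gm)
        tau = np.linspace(0, 2, 9)
        got = pmd.autocorrelation(dec, [0.0, 1.0], tau)
        np.testing.assert_allclose(got, 0.1875 * np.exp(-4 * tau), rtol=1e-10)

    def test_matches_matrix_exponential_oracle(self):
        # C(tau) = sum_{s,s'} obs_{s'} [e^{M tau}]_{s',s} pi_s obs_s - mean^2
        gm = pmd.build_generator(pmd.random_system(2, seed=3))
        rho = pmd.random_system(2, seed=3).rho
        pi = pmd.stationary_distribution(gm)
        dec = pmd.decompose(gm)
        for tau in (0.0, 0.7, 3.0):
            oracle = rho @ expm(gm.M * tau) @ (pi * rho) - (pi @ rho) ** 2
            got = pmd.autocorrelation(dec, rho, [tau])[0]
            assert got == pytest.approx(oracle, rel=1e-8, abs=1e-12)

    def test_constant_observable_is_zero(self, telegraph_gm):
        dec = pmd.decompose(telegraph_gm)
        got = pmd.autocorrelation(dec, [5.0, 5.0], np.linspace(0, 3, 7))
        np.testing.assert_allclose(got, 0.0, atol=1e-10)

    def test_variance_at_zero_lag(self, telegraph_gm):
        dec = pmd.decompose(telegraph_gm)
        obs = np.array([1.0, 7.0])
        pi = dec.pi
        var = pi @ obs**2 - (pi @ obs) ** 2
        assert pmd.autocorrelation(dec, obs, [0.0])[0] == pytest.approx(var, rel=1e-10)


class TestPowerSpectrum:
    def test_two_state_lorentzian(self, telegraph_gm):
        dec = pmd.decompose(telegraph_gm)
        omega = np.array([0.0, 1.0, 4.0])
        s = pmd.power_spectrum(dec, [0.0, 1.0], omega)
        expected = 2 * 4 * 0.1875 / (16 + omega**2)
        np.testing.assert_allclose(s.values, expected, rtol=1e-10)
        assert s.values[0] == pytest.approx(0.09375)

    @pytest.mark.parametrize("seed", range(10))
    def test_spectra_real_nonnegative(self, seed):
        system = pmd.random_system(3, seed)
        dec = pmd.decompose(pmd.build_generator(system))
        s = pmd.power_spectrum(dec, system.rho)
        assert np.all(s.values >= 0)

    @pytest.mark.parametrize("seed", [0, 4, 7])
    def test_wiener_khinchin_variance(self, seed):
        # integral of S over the whole axis recovers the stationary variance
        system = pmd.random_system(3, seed)
        dec = pmd.decompose(pmd.build_generator(system))
        c = dec.mode_coefficients(system.rho)
        lams = dec.eigenvalues

        def density(w):
            acc = 0j
            for i in range(1, lams.size):
                acc += c[i] * (1 / (-lams[i] + 1j * w) + 1 / (-lams[i] - 1j * w))
            return acc.real

        cut = 100 * np.abs(lams).max()
        head, _ = quad(density, 0, cut, limit=400)
        tail, _ = quad(density, cut, np.inf, limit=200)
        var = dec.pi @ system.rho**2 - (dec.pi @ system.rho) ** 2
        assert (head + tail) / np.pi == pytest.approx(var, rel=1e-3)

    def test_closed_system_no_peak_above_dc(self):
        system, _ = pmd.random_closed_system(3, seed=8)
        dec = pmd.decompose(pmd.build_generator(system))
        s = pmd.power_spectrum(dec, system.rho)
        assert s.values.max() <= s.values[0] * (1 + 1e-9)


class TestCycleSpectrum:
    @pytest.mark.parametrize("n", [3, 5, 22])
    @pytest.mark.parametrize("ratio", [0.0, 0.1, 1.0])
    def test_closed_form_matches_eigensolver(self, n, ratio):
        kf, kb = 1.0, ratio

        def canon(z):
            # conjugate partners have equal real parts only up to roundoff;
            # round before lexicographic sort so pairs line up
            return z[np.lexsort((np.round(z.imag, 8), np.round(z.real, 8)))]

        analytic = canon(pmd.cycle_eigenvalues(n, kf, kb))
        gm = pmd.build_generator(pmd.homogeneous_cycle(n, kf, kb))
        numeric = canon(pmd.decompose(gm).eigenvalues)
        np.testing.assert_allclose(numeric, analytic, atol=1e-10)

    def test_irreversible_circle_geometry(self):
        lam = pmd.cycle_eigenvalues(22, kf=2.0)
        np.testing.assert_allclose(np.abs(lam + 2.0), 2.0, rtol=1e-12)

    def test_symmetric_cycle_real(self):
        lam = pmd.cycle_eigenvalues(7, 1.5, 1.5)
        np.testing.assert_allclose(lam.imag, 0.0, atol=1e-12)
        j = np.arange(7)
        np.testing.assert_allclose(
            np.sort(lam.real), np.sort(2 * 1.5 * (np.cos(2 * np.pi * j / 7) - 1)),
            atol=1e-12,
        )

    def test_coherence_grows_with_length_and_directionality(self):
        def z1(n, kf, kb):
            lam = pmd.cycle_eigenvalues(n, kf, kb)[1]
            return pmd.coherence_factor(lam)

        assert z1(10, 1, 0) < z1(22, 1, 0) < z1(100, 1, 0)
        assert z1(22, 1, 1.0) < z1(22, 1, 0.1) < z1(22, 1, 0.0)


class TestCoherenceFactor:
    def test_reference_value(self):
        assert pmd.coherence_factor(-0.01 + 0.628319j) == pytest.approx(10.0, rel=1e-4)

    def test_real_mode_zero(self):
        assert pmd.coherence_factor(-5.0 + 0j) == 0.0

    def test_growing_mode_rejected(self):
        with pytest.raises(ValueError):
            pmd.coherence_factor(0.1 + 1j)


class TestTrajectoriesAndRelaxation:
    def test_two_state_linear_path(self, telegraph):
        grid = np.logspace(-2, 2, 15)
        res = pmd.eigenvalue_trajectories(telegraph, "A", grid)
        lam = res["paths"][1]
        np.testing.assert_allclose(lam.real, -(0.2 * grid + 3.0), rtol=1e-10)
        np.testing.assert_allclose(lam.imag, 0.0, atol=1e-12)

    def test_conjugate_paths_stay_conjugate(self):
        system = pmd.random_system(3, seed=21)
        grid = np.logspace(-1, 1, 10)
        res = pmd.eigenvalue_trajectories(system, "A", grid)
        paths = res["paths"]
        for k in range(grid.size):
            vals = paths[:, k]
            for lam in vals[np.abs(vals.imag) > 1e-10]:
                assert np.min(np.abs(vals - lam.conjugate())) < 1e-8

    def test_population_relaxation_two_state(self, telegraph_gm):
        t = np.linspace(0, 2, 11)
        got = pmd.population_relaxation(telegraph_gm, [0.0, 1.0], 1, t)
        np.testing.assert_allclose(got, 0.25 + 0.75 * np.exp(-4 * t), rtol=1e-9)

    def test_cycle_relaxation_damped_oscillation(self):
        n, kf = 8, 1.0
        gm = pmd.build_generator(pmd.homogeneous_cycle(n, kf))
        obs = np.zeros(n)
        obs[0] = 1.0
        t = np.linspace(0, 30, 400)
        got = pmd.population_relaxation(gm, obs, 0, t)
        oracle = np.array([(expm(gm.M * ti) @ np.eye(n)[:, 0])[0] for ti in t])
        np.testing.assert_allclose(got, oracle, atol=1e-9)
        # damped oscillation around 1/n with period ~ n/kf
        assert got[0] == pytest.approx(1.0)
        assert abs(got[-1] - 1 / n) < 1e-3
        first_min = t[np.argmin(got)]
        assert 0.3 * n / kf < first_min < 0.9 * n / kf
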