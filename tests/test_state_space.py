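"""State enumeration, generator assembly and the kinetic/energetic duality."""

import numpy as np
import pytest

import promodyn as pmd
from promodyn.state_space import KB_KCAL_MOL_K


class TestEnumerateStates:
    def test_bitmask_order(self):
        states = pmd.enumerate_states(["A", "B"])
        assert states == [frozenset(), {"A"}, {"B"}, {"A", "B"}]

    def test_single_tf(self):
        assert pmd.enumerate_states(["A"]) == [frozenset(), {"A"}]

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            pmd.enumerate_states(["A", "A"])


class TestBuildGenerator:
    def test_two_state_concentration_weighting(self, telegraph_gm):
        # association 0.2 * 5 nM = 1/s, dissociation 3/s
        np.testing.assert_allclose(telegraph_gm.M, [[-1.0, 3.0], [1.0, -3.0]])

    def test_zero_kinetics_gives_zero_matrix(self):
        s = pmd.PromoterSystem(
            tf_names=("A", "B"),
            k0=np.zeros((2, 4)),
            concentrations=np.array([1.0, 1.0]),
            rho=np.zeros(4),
        )
        assert np.all(pmd.build_generator(s).M == 0)

    def test_raw_cycle_columns_conserve(self):
        cyc = pmd.homogeneous_cycle(4, kf=1.0, kb=0.0)
        M = pmd.build_generator(cyc).M
        np.testing.assert_allclose(M.sum(axis=0), 0.0, atol=1e-14)
        off = M - np.diag(np.diag(M))
        expected = np.zeros((4, 4))
        for s in range(4):
            expected[(s + 1) % 4, s] = 1.0
        np.testing.assert_allclose(off, expected)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            pmd.PromoterSystem(
                tf_names=("A",),
                k0=np.array([[-1.0, 1.0]]),
                concentrations=np.array([1.0]),
                rho=np.zeros(2),
            )

    def test_nonconservative_raw_rejected(self):
        bad = np.array([[0.0, 1.0], [1.0, 0.5]])
        with pytest.raises(ValueError, match="sum to 0"):
            pmd.PromoterSystem(tf_names=("A",), rho=np.zeros(2), raw_M=bad)

    @pytest.mark.parametrize("seed", range(5))
    def test_column_sums_zero_random(self, seed):
        M = pmd.build_generator(pmd.random_system(4, seed)).M
        np.testing.assert_allclose(M.sum(axis=0), 0.0, atol=1e-12 * np.abs(M).max())


class TestEnergetics:
    def test_flat_energies_unit_rates(self):
        em = pmd.EnergeticModel(G0=np.zeros(2), E0=np.zeros((1, 2)), prefactor=1.0)
        np.testing.assert_allclose(pmd.kinetics_from_energies(em), 1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_closed_two_state_ratio(self, seed):
        # k_on/k_off = exp((G0_empty - G0_bound)/kBT) for a shared barrier
        rng = np.random.default_rng(seed)
        G0 = rng.normal(0, 2, 2)
        barrier = rng.normal(3, 1)
        em = pmd.EnergeticModel(G0=G0, E0=np.full((1, 2), barrier))
        k0 = pmd.kinetics_from_energies(em)
        np.testing.assert_allclose(
            k0[0, 0] / k0[0, 1], np.exp((G0[0] - G0[1]) / em.kBT), rtol=1e-12
        )

    def test_concentration_enters_association_only(self):
        _, em = pmd.random_closed_system(2, seed=0)
        k0 = pmd.kinetics_from_energies(em)
        base = pmd.PromoterSystem(
            tf_names=("A", "B"), k0=k0, concentrations=np.array([1.0, 1.0]),
            rho=np.zeros(4),
        )
        doubled = base.with_concentration("A", 2.0)
        M1, M2 = pmd.build_generator(base).M, pmd.build_generator(doubled).M
        # association of A (states lacking A) doubles
        assert M2[1, 0] == pytest.approx(2 * M1[1, 0])
        assert M2[3, 2] == pytest.approx(2 * M1[3, 2])
        # dissociations and B transitions unchanged
        assert M2[0, 1] == M1[0, 1]
        assert M2[2, 0] == M1[2, 0]

    def test_prefactor_scales_generator_not_stationary(self):
        system, em = pmd.random_closed_system(2, seed=1)
        em2 = pmd.EnergeticModel(G0=em.G0, E0=em.E0, prefactor=2.0)
        s2 = pmd.PromoterSystem(
            tf_names=system.tf_names,
            k0=pmd.kinetics_from_energies(em2),
            concentrations=system.concentrations,
            rho=system.rho,
        )
        M1 = pmd.build_generator(system).M
        M2 = pmd.build_generator(s2).M
        np.testing.assert_allclose(M2, 2 * M1, rtol=1e-12)
        np.testing.assert_allclose(
            pmd.stationary_distribution(pmd.build_generator(system)),
            pmd.stationary_distribution(pmd.build_generator(s2)),
            atol=1e-12,
        )

    def test_is_closed_detects_asymmetry(self):
        _, em = pmd.random_closed_system(2, seed=2)
        assert pmd.is_closed_system(em)
        E0 = em.E0.copy()
        E0[0, 1] += 2.0  # one direction only
        assert not pmd.is_closed_system(
            pmd.EnergeticModel(G0=em.G0, E0=E0)
        )

    def test_kbt_constant(self):
        em = pmd.EnergeticModel(G0=np.zeros(2), E0=np.zeros((1, 2)))
        assert em.kBT == pytest.approx(KB_KCAL_MOL_K * 298.15)
        assert em.kBT == pytest.approx(0.5925, abs=5e-4)


class TestDetailedBalance:
    def test_two_state_never_cyclic(self, telegraph_gm):
        cyclic, witness = pmd.detect_directed_cycles(telegraph_gm)
        assert not cyclic and witness is None

    def test_three_cycle_detected(self):
        gm = pmd.build_generator(pmd.homogeneous_cycle(3, kf=2.0, kb=1.0))
        cyclic, witness = pmd.detect_directed_cycles(gm)
        assert cyclic
        assert sorted(witness) == [0, 1, 2]

    @pytest.mark.parametrize("seed", range(30))
    def test_closed_systems_satisfy_kolmogorov(self, seed):
        system, _ = pmd.random_closed_system(3, seed)
        cyclic, _ = pmd.detect_directed_cycles(pmd.build_generator(system))
        assert not cyclic


class TestStationaryDistribution:
    def test_two_state(self, telegraph_gm):
        np.testing.assert_allclose(
            pmd.stationary_distribution(telegraph_gm), [0.75, 0.25], rtol=1e-12
        )

    def test_irreversible_cycle_uniform(self):
        gm = pmd.build_generator(pmd.homogeneous_cycle(5, kf=1.0))
        np.testing.assert_allclose(pmd.stationary_distribution(gm), 0.2, rtol=1e-12)

    @pytest.mark.parametrize("seed", range(30))
    def test_closed_system_is_boltzmann(self, seed):
        system, em = pmd.random_closed_system(3, seed)
        pi = pmd.stationary_distribution(pmd.build_generator(system))
        G = em.state_energies(system.concentrations)
        boltz = np.exp(-(G - G.min()) / em.kBT)
        boltz /= boltz.sum()
        np.testing.assert_allclose(pi, boltz, rtol=1e-8)

    def test_reducible_chain_names_states(self):
        M = np.array([[0.0, 1.0], [0.0, -1.0]])  # state 1 leaks, never refills
        gm = pmd.GeneratorMatrix(M=M)
        with pytest.raises(ValueError, match=r"\[1\]"):
            pmd.stationary_distribution(gm)

    def test_energetic_and_kinetic_construction_commute(self):
        # build M from energies, then rebuild from the extracted k0: identical
        system, _ = pmd.random_closed_system(3, seed=5)
        M1 = pmd.build_generator(system).M
        system2 = pmd.PromoterSystem(
            tf_names=system.tf_names,
            k0=system.k0.copy(),
            concentrations=system.concentrations.copy(),
            rho=system.rho,
        )
        np.testing.assert_allclose(pmd.build_generator(system2).M, M1, rtol=1e-10)
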