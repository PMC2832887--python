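"""Builders for worked-example promoters, random fixtures and optimization.

Every recipe stores its biophysical parameters as module-level data (units in
comments), builds a validated :class:`~promodyn.state_space.PromoterSystem`,
and where the system is energetically specified also returns the
:class:`~promodyn.state_space.EnergeticModel` so barriers can be manipulated
independently of state energies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cascade import CascadeParams
from .distributions import energy_consumption_rate
from .spectral import coherence_factor, decompose
from .state_space import (
    KB_KCAL_MOL_K,
    EnergeticModel,
    PromoterSystem,
    build_generator,
    kinetics_from_energies,
)

__all__ = [
    "two_state",
    "homogeneous_cycle",
    "steric_hindrance_system",
    "HINDRANCE_PARAMS",
    "dna_looping_system",
    "looping_energetics",
    "LOOPING_PARAMS",
    "randomize_barriers",
    "random_system",
    "random_closed_system",
    "optimize_coherence",
    "OptimizationStep",
]

_KBT_298 = KB_KCAL_MOL_K * 298.15  # 0.5925 kcal/mol


# ---------------------------------------------------------------------------
# analytic minimal systems


def two_state(
    kon0: float,
    conc: float,
    koff: float,
    rho_off: float,
    rho_on: float,
) -> PromoterSystem:
    """Telegraph promoter: one TF, eigenvalues {0, -(kon0*conc + koff)}."""
    if min(kon0, conc, koff) <= 0:
        raise ValueError("rates and concentration must be positive")
    return PromoterSystem(
        tf_names=("A",),
        k0=np.array([[kon0, koff]]),
        concentrations=np.array([conc]),
        rho=np.array([rho_off, rho_on], dtype=float),
    )


def homogeneous_cycle(
    n: int, kf: float, kb: float = 0.0, rho: Optional[Sequence[float]] = None
) -> PromoterSystem:
    """Homogeneous ``n``-state directed cycle, supplied as a raw generator.

    The idealized model of sequential recruitment: forward rate ``kf`` around
    the cycle, optional uniform backward rate ``kb``.  Its spectrum is the
    circle/ellipse closed form of :func:`promodyn.spectral.cycle_eigenvalues`.
    A cycle of ``n`` states is not a subset lattice, so the generator is
    carried explicitly (``raw_M`` route) by a :class:`CyclePromoter`.
    """
    if n < 3:
        raise ValueError("need n >= 3 cycle states")
    M = np.zeros((n, n))
    for s in range(n):
        M[(s + 1) % n, s] = kf
        if kb > 0:
            M[(s - 1) % n, s] = kb
    np.fill_diagonal(M, -M.sum(axis=0))
    if rho is None:
        rho = np.zeros(n)
        rho[0] = 1.0
    return CyclePromoter(M=M, rho=np.asarray(rho, dtype=float), n=n, kf=kf, kb=kb)


@dataclass(frozen=True)
class CyclePromoter:
    """Cycle system exposing the PromoterSystem surface used downstream.

    A directed cycle has ``n`` states rather than ``2**N``; it bypasses the
    bitmask state space and carries its generator explicitly.
    """

    M: np.ndarray
    rho: np.ndarray
    n: int
    kf: float
    kb: float

    @property
    def n_states(self) -> int:
        return self.n

    @property
    def raw_M(self):
        return self.M


# ---------------------------------------------------------------------------
# minimal two-TF system: stochasticity induced by high activator concentration

#: Printed parameters of the minimal "hindrance" promoter: a factor A that
#: does not touch transcription but slows the binding/unbinding of the
#: transcription-gating factor B when bound (e.g. steric occlusion or a
#: remodeler competing for the B site).
HINDRANCE_PARAMS = {
    "koff_A_per_s": 1.0 / 30.0,     # A residence time 30 s
    "koff_B_per_s": 1.0 / 60.0,     # B residence time 60 s
    "K_A_nM": 0.5,                  # A equilibrium constant
    "K_B_nM": 5.0,                  # B equilibrium constant
    "conc_B_nM": 5.0,               # fixed B concentration
    "delta_E_kcal": 2.5,            # barrier shift on both B transitions when A bound
    "rna_lifetime_s": 300.0,        # 5 min
    "protein_lifetime_s": 1200.0,   # 20 min
    "rho_B_per_s": 0.2,             # calibrated: <R> ~ 30 at vanishing [A]
    "protein_per_rna": 1000.0,      # sets beta: <P> = 1000 <R>
}


def steric_hindrance_system(conc_a: float) -> tuple[PromoterSystem, CascadeParams]:
    """Two-TF promoter where high [A] *increases* expression noise.

    Transcription depends only on B; A's sole effect is to scale both B
    transition rates by ``exp(-dE/kBT)`` when bound.  B's equilibrium (hence
    every mean level) is independent of [A], but at saturating [A] the
    B switching slows ~70-fold, driving slow bursty dynamics and a bimodal
    RNA distribution.
    """
    p = HINDRANCE_PARAMS
    if not 0 < conc_a:
        raise ValueError("conc_a must be positive")
    h = math.exp(-p["delta_E_kcal"] / _KBT_298)
    kon_a = p["koff_A_per_s"] / p["K_A_nM"]
    kon_b = p["koff_B_per_s"] / p["K_B_nM"]
    koff_a, koff_b = p["koff_A_per_s"], p["koff_B_per_s"]
    # states (bit0=A, bit1=B): 0:empty 1:A 2:B 3:AB
    k0 = np.zeros((2, 4))
    k0[0, :] = [kon_a, koff_a, kon_a, koff_a]          # A unaffected by B
    k0[1, :] = [kon_b, kon_b * h, koff_b, koff_b * h]  # B slowed when A bound
    rho_b = p["rho_B_per_s"]
    system = PromoterSystem(
        tf_names=("A", "B"),
        k0=k0,
        concentrations=np.array([conc_a, p["conc_B_nM"]]),
        rho=np.array([0.0, 0.0, rho_b, rho_b]),
    )
    gamma = 1.0 / p["rna_lifetime_s"]
    gamma_p = 1.0 / p["protein_lifetime_s"]
    beta = p["protein_per_rna"] * gamma_p
    return system, CascadeParams(gamma=gamma, beta=beta, gamma_p=gamma_p)


# ---------------------------------------------------------------------------
# prokaryotic-like promoter: two activator sites, a competitor and DNA looping

#: Printed energies (kcal/mol) and kinetics of the looping promoter.  The
#: factor list is (A1, A2, C, loop); "loop" is a conformational pseudo-factor
#: at unit dimensionless concentration.
LOOPING_PARAMS = {
    "K_A_nM": 20.0,
    "K_C_nM": 1.0,
    "dG_AA_kcal": -2.0,        # A-A cooperativity when both sites occupied
    "dG_AC_kcal": 1.5,         # A/C competition at one A site
    "dG_loop_kcal": 9.0,       # cost of looping bare DNA
    "dG_loopA_kcal": -5.5,     # loop stabilization per occupied A site
    "dE_loopC_kcal": 2.5,      # barrier shift on C transitions when looped
    "koff_A_per_s": 1.0 / 20.0,
    "koff_C_per_s": 1.0 / 60.0,
    "k_close_per_s": 1.0,      # loop closing when both A sites occupied
    "rna_lifetime_s": 300.0,
    # transcription: promoted by the unlooped state, by C, slightly by one A
    "rho_unlooped_per_s": 0.06,
    "rho_C_bonus_per_s": 0.16,
    "rho_oneA_bonus_per_s": 0.02,
    "rho_looped_per_s": 0.035,
    "rho_looped_C_bonus_per_s": 0.015,
}

_A1, _A2, _C, _L = 1, 2, 4, 8  # bitmasks


def looping_energetics(competing_site: int = 2, temperature: float = 298.15) -> EnergeticModel:
    """Energetic model of the looping promoter (closed: shared barriers).

    ``competing_site`` selects which A site pays the A/C competition penalty
    (the biology does not pin it down; both choices are exposed).
    """
    if competing_site not in (1, 2):
        raise ValueError("competing_site must be 1 or 2")
    p = LOOPING_PARAMS
    kbt = KB_KCAL_MOL_K * temperature
    comp_mask = _A1 if competing_site == 1 else _A2
    G0 = np.zeros(16)
    for s in range(16):
        g = 0.0
        n_a = bool(s & _A1) + bool(s & _A2)
        g += n_a * kbt * math.log(p["K_A_nM"])
        if s & _C:
            g += kbt * math.log(p["K_C_nM"])
        if (s & _A1) and (s & _A2):
            g += p["dG_AA_kcal"]
        if (s & comp_mask) and (s & _C):
            g += p["dG_AC_kcal"]
        if s & _L:
            g += p["dG_loop_kcal"] + n_a * p["dG_loopA_kcal"]
        G0[s] = g
    E0 = np.full((4, 16), np.inf)

    def set_pair(f_bit, f_idx, s_bound, barrier):
        E0[f_idx, s_bound] = barrier
        E0[f_idx, s_bound ^ f_bit] = barrier

    for s in range(16):
        if s & _A1:
            set_pair(_A1, 0, s, G0[s] + kbt * math.log(1.0 / p["koff_A_per_s"]))
        if s & _A2:
            set_pair(_A2, 1, s, G0[s] + kbt * math.log(1.0 / p["koff_A_per_s"]))
        if s & _C:
            barrier = G0[s] + kbt * math.log(1.0 / p["koff_C_per_s"])
            if s & _L:
                barrier += p["dE_loopC_kcal"]
            set_pair(_C, 2, s, barrier)
        if s & _L and (s & _A1) and (s & _A2):
            # closing is fast and allowed only with both A bound; the barrier
            # is anchored on the unlooped side so 1/k_close = 1 s there
            s_open = s ^ _L
            set_pair(_L, 3, s, G0[s_open] + kbt * math.log(1.0 / p["k_close_per_s"]))
    return EnergeticModel(G0=G0, E0=E0, temperature=temperature, prefactor=1.0)


def _looping_rho() -> np.ndarray:
    p = LOOPING_PARAMS
    rho = np.zeros(16)
    for s in range(16):
        n_a = bool(s & _A1) + bool(s & _A2)
        if s & _L:
            rho[s] = p["rho_looped_per_s"]
            if s & _C:
                rho[s] += p["rho_looped_C_bonus_per_s"]
        else:
            rho[s] = p["rho_unlooped_per_s"]
            if s & _C:
                rho[s] += p["rho_C_bonus_per_s"]
            if n_a == 1:
                rho[s] += p["rho_oneA_bonus_per_s"]
    return rho


def dna_looping_system(
    conc_a: float,
    conc_c: float,
    em: Optional[EnergeticModel] = None,
    competing_site: int = 2,
) -> tuple[PromoterSystem, EnergeticModel, CascadeParams]:
    """16-state looping promoter (A at two sites, competitor C, DNA loop).

    Energy-independent (closed) by construction: randomizing barriers with
    :func:`randomize_barriers` leaves every mean untouched.  Pass ``em`` to
    rebuild the kinetics from a modified energetic model.
    """
    if conc_a <= 0 or conc_c <= 0:
        raise ValueError("concentrations must be positive")
    if em is None:
        em = looping_energetics(competing_site=competing_site)
    conc = np.array([conc_a, conc_a, conc_c, 1.0])
    k0 = kinetics_from_energies(em, conc)
    system = PromoterSystem(
        tf_names=("A1", "A2", "C", "loop"),
        k0=k0,
        concentrations=conc,
        rho=_looping_rho(),
    )
    gamma = 1.0 / LOOPING_PARAMS["rna_lifetime_s"]
    cascade = CascadeParams(gamma=gamma, beta=1000.0 / 1200.0, gamma_p=1.0 / 1200.0)
    return system, em, cascade


def randomize_barriers(em: EnergeticModel, sd_kcal: float, seed: int) -> EnergeticModel:
    """Add one Gaussian draw per reaction to its shared activation barrier.

    Both directions move together and ``G0`` is untouched, so the system stays
    closed and its stationary law (hence every mean) is exactly preserved;
    only the kinetics -- and with them all fluctuation properties -- change.
    """
    if sd_kcal < 0:
        raise ValueError("sd_kcal must be >= 0")
    rng = np.random.default_rng(seed)
    E0 = em.E0.copy()
    for f in range(em.n_tfs):
        bit = 1 << f
        for s in range(em.n_states):
            if s & bit and np.isfinite(E0[f, s]):
                d = rng.normal(0.0, sd_kcal)
                E0[f, s] += d
                E0[f, s ^ bit] += d
    return EnergeticModel(
        G0=em.G0.copy(), E0=E0, temperature=em.temperature, prefactor=em.prefactor
    )


# ---------------------------------------------------------------------------
# random fixtures


def random_system(N: int, seed: int, log_rate_sd: float = 1.0) -> PromoterSystem:
    """Reproducible random promoter with log-normal kinetics (irreducible)."""
    if not 1 <= N <= 8:
        raise ValueError("need 1 <= N <= 8")
    rng = np.random.default_rng(seed)
    n_states = 2**N
    k0 = np.exp(rng.normal(math.log(0.05), log_rate_sd, size=(N, n_states)))
    conc = np.exp(rng.normal(math.log(2.0), 0.5, size=N))
    rho = np.exp(rng.normal(math.log(0.05), 0.7, size=n_states))
    return PromoterSystem(
        tf_names=tuple("ABCDEFGH"[:N]), k0=k0, concentrations=conc, rho=rho
    )


def random_closed_system(
    N: int,
    seed: int,
    g_sd_kcal: float = 1.5,
    barrier_mean_kcal: float = 2.0,
    barrier_sd_kcal: float = 1.5,
) -> tuple[PromoterSystem, EnergeticModel]:
    """Random equilibrium promoter: shared barriers, Boltzmann steady state."""
    if not 1 <= N <= 8:
        raise ValueError("need 1 <= N <= 8")
    rng = np.random.default_rng(seed)
    n_states = 2**N
    G0 = rng.normal(0.0, g_sd_kcal, size=n_states)
    E0 = np.zeros((N, n_states))
    for f in range(N):
        bit = 1 << f
        for s in range(n_states):
            if s & bit:
                barrier = rng.normal(barrier_mean_kcal, barrier_sd_kcal)
                E0[f, s] = barrier
                E0[f, s ^ bit] = barrier
    em = EnergeticModel(G0=G0, E0=E0)
    conc = np.exp(rng.normal(0.0, 0.5, size=N))
    rho = np.exp(rng.normal(math.log(0.05), 0.7, size=n_states))
    system = PromoterSystem(
        tf_names=tuple("ABCDEFGH"[:N]),
        k0=kinetics_from_energies(em, conc),
        concentrations=conc,
        rho=rho,
    )
    return system, em


# ---------------------------------------------------------------------------
# stochastic search for coherent oscillations


@dataclass(frozen=True)
class OptimizationStep:
    """One accepted state of the coherence hill-climb."""

    iteration: int
    system: PromoterSystem
    coherence: float
    edot_kbt_per_s: float


def _coherence_objective(eigenvalues: np.ndarray) -> float:
    """Best coherence among slow oscillatory modes.

    A pair only counts fully when its oscillation period is at least ten times
    the fastest relaxation time of the chain (the slow-global-clock regime);
    faster oscillations are discounted proportionally.
    """
    nz = eigenvalues[np.abs(eigenvalues) > 1e-12]
    if nz.size == 0:
        return 0.0
    fastest = np.abs(nz.real).max()
    best = 0.0
    for lam in nz:
        if lam.imag <= 1e-12 or lam.real >= 0:
            continue
        period = 2.0 * np.pi / lam.imag
        gate = min(1.0, period * fastest / 10.0)
        best = max(best, coherence_factor(lam) * gate)
    return best


def optimize_coherence(
    initial: PromoterSystem,
    iterations: int,
    seed: int,
    move_sd: float = 0.4,
) -> list[OptimizationStep]:
    """Hill-climb log-kinetics toward a coherent slow oscillation.

    Proposes Gaussian perturbations of randomly chosen log-rate entries and
    accepts whenever the objective does not decrease, so the best coherence is
    non-decreasing along the returned trace.  The free-energy consumption rate
    is logged at every accepted step: directing a cycle costs energy, and the
    two quantities rise together.
    """
    if initial.raw_M is not None:
        raise ValueError("optimizer operates on k0-parameterized systems")
    rng = np.random.default_rng(seed)
    system = initial
    dec = decompose(build_generator(system))
    score = _coherence_objective(dec.eigenvalues)
    trace = [
        OptimizationStep(
            iteration=0,
            system=system,
            coherence=score,
            edot_kbt_per_s=energy_consumption_rate(build_generator(system)).kbt_per_s,
        )
    ]
    log_k0 = np.log(system.k0)
    for it in range(1, iterations + 1):
        proposal = log_k0.copy()
        n_moves = rng.integers(1, 4)
        for _ in range(n_moves):
            f = rng.integers(0, proposal.shape[0])
            s = rng.integers(0, proposal.shape[1])
            proposal[f, s] += rng.normal(0.0, move_sd)
        cand = PromoterSystem(
            tf_names=system.tf_names,
            k0=np.exp(proposal),
            concentrations=system.concentrations,
            rho=system.rho,
        )
        cand_score = _coherence_objective(decompose(build_generator(cand)).eigenvalues)
        if cand_score >= score:
            log_k0 = proposal
            system = cand
            score = cand_score
            trace.append(
                OptimizationStep(
                    iteration=it,
                    system=system,
                    coherence=score,
                    edot_kbt_per_s=energy_consumption_rate(
                        build_generator(system)
                    ).kbt_per_s,
                )
            )
    return trace
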