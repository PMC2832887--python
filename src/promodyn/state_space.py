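"""Promoter state space, generator matrix and the kinetic/energetic duality.

A promoter interacting with ``N`` transcription factors (TFs, or more generally
binary epigenetic marks, conformations such as a DNA loop, etc.) occupies one of
``2**N`` states: the subsets of bound factors.  State ``s`` is encoded as a
bitmask over the declared TF order, so state ``0`` is the empty promoter and
flipping factor ``f`` is the XOR ``s ^ (1 << f)``.

The continuous-time Markov chain over these states is generated by the
``2**N x 2**N`` matrix ``M`` with the *column-as-source* convention:
``M[s', s]`` is the rate of the transition ``s -> s'`` and the probability
vector evolves as ``dphi/dt = M phi`` (columns sum to zero).

Two equivalent parameterizations are supported:

* **kinetic** -- an ``N x 2**N`` matrix ``k0`` of standard-condition constants:
  for ``f`` not in ``s`` the entry is an association constant (nM^-1 s^-1,
  multiplied by the free concentration ``[f]`` to give a rate), for ``f`` in
  ``s`` it is a dissociation rate (s^-1);
* **energetic** -- per-state standard Gibbs energies ``G0`` (kcal/mol) plus
  per-reaction activation barriers ``E0`` and an attempt frequency ``nu``,
  with rates ``nu * exp(-(E0 - G0_s)/kBT)``.

A *closed* (equilibrium, energy-conserving) system shares the barrier between
the two directions of every reaction; this forces detailed balance, a Boltzmann
stationary law and a purely real relaxation spectrum.  Asymmetric barriers
model energy input (ATP-driven remodeling ...) and permit directed cycles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.linalg import lu_factor, lu_solve

__all__ = [
    "KB_KCAL_MOL_K",
    "PromoterSystem",
    "GeneratorMatrix",
    "EnergeticModel",
    "enumerate_states",
    "build_generator",
    "kinetics_from_energies",
    "is_closed_system",
    "detect_directed_cycles",
    "stationary_distribution",
]

#: Boltzmann constant in kcal/(mol K); kBT = 0.5925 kcal/mol at 298.15 K.
KB_KCAL_MOL_K = 0.0019872

_COLSUM_RTOL = 1e-12
_DB_RTOL = 1e-8
_STAT_RTOL = 1e-10


def enumerate_states(tf_names: Sequence[str]) -> list[frozenset]:
    """Enumerate all ``2**N`` promoter states in bitmask order.

    Index ``i`` corresponds to the subset of TFs whose bit is set in ``i``;
    index 0 is the empty promoter.
    """
    names = list(tf_names)
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate TF labels in {names}")
    n = len(names)
    if not 1 <= n <= 20:
        raise ValueError(f"need 1 <= N <= 20 TFs, got {n}")
    if n > 12:
        warnings.warn(f"N={n} gives {2**n} promoter states; expect heavy linear algebra")
    return [
        frozenset(names[f] for f in range(n) if s >> f & 1) for s in range(2**n)
    ]


@dataclass(frozen=True)
class PromoterSystem:
    """A combinatorial promoter: TFs, kinetics and transcriptional efficiency.

    Parameters
    ----------
    tf_names
        Ordered TF labels; the state index is the bitmask over this order.
    k0
        ``N x 2**N`` standard-condition constants; entry ``(f, s)`` governs the
        reaction ``s -> s XOR f``.  Ignored when ``raw_M`` is given.
    concentrations
        Free TF concentrations in nM (positive).
    rho
        Length ``2**N`` per-state transcription initiation rates (s^-1).
    raw_M
        Optional explicit generator (columns sum to zero); used verbatim, e.g.
        for multi-molecule transitions that single-TF kinetics cannot encode.
    """

    tf_names: tuple
    k0: Optional[np.ndarray] = None
    concentrations: Optional[np.ndarray] = None
    rho: np.ndarray = None
    raw_M: Optional[np.ndarray] = None

    def __post_init__(self):
        object.__setattr__(self, "tf_names", tuple(self.tf_names))
        enumerate_states(self.tf_names)  # validates labels
        n_states = 2 ** self.n_tfs
        if self.raw_M is not None:
            raw = np.asarray(self.raw_M, dtype=float)
            if raw.shape != (n_states, n_states):
                raise ValueError(f"raw_M must be {n_states}x{n_states}, got {raw.shape}")
            off = raw - np.diag(np.diag(raw))
            if np.any(off < 0):
                raise ValueError("raw_M off-diagonal entries must be >= 0")
            colsum = raw.sum(axis=0)
            scale = max(np.abs(raw).max(), 1.0)
            if np.any(np.abs(colsum) > _COLSUM_RTOL * scale * n_states):
                raise ValueError("raw_M columns must sum to 0 (non-conservative generator)")
            object.__setattr__(self, "raw_M", raw)
        else:
            if self.k0 is None or self.concentrations is None:
                raise ValueError("either raw_M or (k0, concentrations) is required")
            k0 = np.asarray(self.k0, dtype=float)
            if k0.shape != (self.n_tfs, n_states):
                raise ValueError(f"k0 must be {self.n_tfs}x{n_states}, got {k0.shape}")
            if np.any(k0 < 0) or not np.all(np.isfinite(k0)):
                raise ValueError("k0 entries must be finite and >= 0")
            conc = np.asarray(self.concentrations, dtype=float)
            if conc.shape != (self.n_tfs,) or np.any(conc <= 0):
                raise ValueError("concentrations must be positive, one per TF")
            object.__setattr__(self, "k0", k0)
            object.__setattr__(self, "concentrations", conc)
        if self.rho is None:
            raise ValueError("rho is required")
        rho = np.asarray(self.rho, dtype=float)
        if rho.shape != (n_states,):
            raise ValueError(f"rho must have length {n_states}, got {rho.shape}")
        if np.any(rho < 0):
            raise ValueError("rho entries must be >= 0")
        object.__setattr__(self, "rho", rho)

    @property
    def n_tfs(self) -> int:
        return len(self.tf_names)

    @property
    def n_states(self) -> int:
        return 2 ** self.n_tfs

    def states(self) -> list[frozenset]:
        return enumerate_states(self.tf_names)

    def with_concentration(self, tf: str, value: float) -> "PromoterSystem":
        """Copy of the system with one TF concentration replaced."""
        if self.raw_M is not None:
            raise ValueError("cannot sweep concentrations on a raw_M system")
        idx = self.tf_names.index(tf)
        conc = self.concentrations.copy()
        conc[idx] = value
        return replace(self, concentrations=conc)


@dataclass(frozen=True)
class GeneratorMatrix:
    """Column-conservative rate matrix with ``M[s', s] = rate(s -> s')``."""

    M: np.ndarray
    irreducible: bool = field(default=False)

    def __post_init__(self):
        M = np.asarray(self.M, dtype=float)
        off = M - np.diag(np.diag(M))
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        object.__setattr__(self, "M", M)
        object.__setattr__(self, "irreducible", _is_irreducible(M))

    @property
    def n_states(self) -> int:
        return self.M.shape[0]


def _is_irreducible(M: np.ndarray) -> bool:
    g = _support_digraph(M)
    return nx.number_strongly_connected_components(g) == 1


def _support_digraph(M: np.ndarray) -> nx.DiGraph:
    n = M.shape[0]
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    src, dst = np.nonzero((M.T > 0) & ~np.eye(n, dtype=bool))
    g.add_edges_from(zip(src, dst))
    return g


def build_generator(system: PromoterSystem) -> GeneratorMatrix:
    """Assemble the generator ``M`` from kinetics (or pass through ``raw_M``).

    In the single-TF-per-event version, ``M[s ^ f, s]`` is ``k0[f, s] * [f]``
    when ``f`` is free in ``s`` (association) and ``k0[f, s]`` when bound
    (dissociation); diagonals close the columns to zero.
    """
    if system.raw_M is not None:
        M = system.raw_M.copy()
        np.fill_diagonal(M, 0.0)
        np.fill_diagonal(M, -M.sum(axis=0))
        return GeneratorMatrix(M=M)
    n, n_states = system.n_tfs, system.n_states
    M = np.zeros((n_states, n_states))
    for s in range(n_states):
        for f in range(n):
            target = s ^ (1 << f)
            rate = system.k0[f, s]
            if not s >> f & 1:  # association: concentration-weighted
                rate *= system.concentrations[f]
            M[target, s] += rate
    np.fill_diagonal(M, -M.sum(axis=0))
    return GeneratorMatrix(M=M)


@dataclass(frozen=True)
class EnergeticModel:
    """Thermodynamic dual of the kinetics: state energies and barriers.

    ``G0`` are per-state standard Gibbs energies (kcal/mol, unit = 1 nM
    reference concentration); ``E0[f, s]`` is the absolute activation barrier
    of the reaction ``s -> s XOR f`` (``+inf`` forbids it).  At concentrations
    ``[f]`` the occupied-state law is Boltzmann in
    ``G_s = G0_s + kBT * sum_{f not in s} log [f]``.
    """

    G0: np.ndarray
    E0: np.ndarray
    temperature: float = 298.15
    prefactor: float = 1.0

    def __post_init__(self):
        G0 = np.asarray(self.G0, dtype=float)
        E0 = np.asarray(self.E0, dtype=float)
        if G0.ndim != 1:
            raise ValueError("G0 must be a vector of length 2**N")
        n_states = G0.shape[0]
        n = int(round(math.log2(n_states)))
        if 2**n != n_states:
            raise ValueError(f"len(G0)={n_states} is not a power of two")
        if E0.shape != (n, n_states):
            raise ValueError(f"E0 must be {n}x{n_states}, got {E0.shape}")
        if not np.all(np.isfinite(G0)):
            raise ValueError("G0 must be finite")
        if np.any(np.isnan(E0)):
            raise ValueError("E0 must not contain NaN")
        if self.temperature <= 0 or self.prefactor <= 0:
            raise ValueError("temperature and prefactor must be positive")
        object.__setattr__(self, "G0", G0)
        object.__setattr__(self, "E0", E0)

    @property
    def n_tfs(self) -> int:
        return self.E0.shape[0]

    @property
    def n_states(self) -> int:
        return self.G0.shape[0]

    @property
    def kBT(self) -> float:
        """Thermal energy in kcal/mol."""
        return KB_KCAL_MOL_K * self.temperature

    def state_energies(self, concentrations: np.ndarray) -> np.ndarray:
        """Concentration-corrected energies ``G_s`` (kcal/mol).

        Only *unbound* factors contribute their ``kBT log [f]`` term.
        """
        conc = np.asarray(concentrations, dtype=float)
        if np.any(conc <= 0):
            raise ValueError("concentrations must be positive")
        G = self.G0.copy()
        for s in range(self.n_states):
            for f in range(self.n_tfs):
                if not s >> f & 1:
                    G[s] += self.kBT * math.log(conc[f])
        return G


def kinetics_from_energies(
    em: EnergeticModel, concentrations: Optional[np.ndarray] = None
) -> np.ndarray:
    """Arrhenius-style rate constants from the energetic parameterization.

    Returns the standard-condition matrix ``k0`` with
    ``k0[f, s] = nu * exp(-(E0[f, s] - G0_s) / kBT)`` (an infinite barrier
    gives 0).  ``build_generator`` multiplies association entries by ``[f]``,
    which reproduces the Boltzmann law in the concentration-corrected ``G_s``:
    spectator-concentration terms cancel between barrier and state and only
    the binding factor's ``[f]`` survives.
    """
    if concentrations is not None:
        conc = np.asarray(concentrations, dtype=float)
        if np.any(conc <= 0):
            raise ValueError("concentrations must be positive")
    with np.errstate(over="raise"):
        k0 = em.prefactor * np.exp(-(em.E0 - em.G0[None, :]) / em.kBT)
    k0[np.isinf(em.E0)] = 0.0
    return k0


def is_closed_system(em: EnergeticModel, tol_kcal: float = 1e-9) -> bool:
    """True iff every reaction shares its barrier in both directions.

    Barrier symmetry (``E0[f, s] == E0[f, s XOR f]``) means no reaction pumps
    energy into the chain: detailed balance holds and the stationary law is
    Boltzmann.  Mutually forbidden reactions (both barriers infinite) count as
    symmetric.
    """
    for f in range(em.n_tfs):
        for s in range(em.n_states):
            a, b = em.E0[f, s], em.E0[f, s ^ (1 << f)]
            if np.isinf(a) and np.isinf(b):
                continue
            if np.isinf(a) != np.isinf(b) or abs(a - b) > tol_kcal:
                return False
    return True


def detect_directed_cycles(
    gm: GeneratorMatrix, rtol: float = _DB_RTOL
) -> tuple[bool, Optional[list[int]]]:
    """Kolmogorov criterion for broken detailed balance.

    Walks a cycle basis of the undirected support graph and compares the
    product of rates around each cycle in the two directions.  Returns
    ``(True, witness_cycle)`` if some ratio differs from 1 beyond ``rtol``
    (including one-way edges inside a cycle), else ``(False, None)``.
    Disconnected support graphs are evaluated per component.
    """
    M = gm.M
    n = M.shape[0]
    und = nx.Graph()
    und.add_nodes_from(range(n))
    for s in range(n):
        for t in range(s + 1, n):
            if M[t, s] > 0 or M[s, t] > 0:
                und.add_edge(s, t)
    for comp in nx.connected_components(und):
        for cycle in nx.cycle_basis(und.subgraph(comp)):
            log_fwd = 0.0
            log_bwd = 0.0
            one_way = False
            for a, b in zip(cycle, cycle[1:] + cycle[:1]):
                fwd, bwd = M[b, a], M[a, b]
                if fwd == 0 or bwd == 0:
                    one_way = True
                    break
                log_fwd += math.log(fwd)
                log_bwd += math.log(bwd)
            if one_way or abs(log_fwd - log_bwd) > rtol:
                return True, list(cycle)
    return False, None


def stationary_distribution(gm: GeneratorMatrix) -> np.ndarray:
    """Stationary probability vector ``pi`` with ``M pi = 0``.

    Raises on reducible chains, naming states unreachable from the largest
    recurrent class.
    """
    M = gm.M
    n = M.shape[0]
    if n == 1:
        return np.array([1.0])
    if not gm.irreducible:
        comps = sorted(
            nx.strongly_connected_components(_support_digraph(M)), key=len, reverse=True
        )
        outside = sorted(set(range(n)) - comps[0])
        raise ValueError(
            f"chain is reducible; states outside the largest strongly connected "
            f"component: {outside}"
        )
    A = M.copy()
    A[0, :] = 1.0  # replace one redundant balance equation with normalization
    b = np.zeros(n)
    b[0] = 1.0
    lu, piv = lu_factor(A)
    pi = lu_solve((lu, piv), b)
    for _ in range(2):  # iterative refinement: rates can span many decades
        r = b - A @ pi
        pi += lu_solve((lu, piv), r)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    resid = np.abs(M @ pi).max()
    scale = np.abs(M).max()
    if resid > _STAT_RTOL * max(scale, 1.0):
        raise ArithmeticError(f"stationary solve residual {resid:.3e} too large")
    return pi
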