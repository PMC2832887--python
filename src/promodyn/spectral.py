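"""Eigendecomposition of the promoter generator and modal noise spectra.

The relaxation of the promoter Markov chain is entirely encoded in the
eigenvalues of ``M``: a unique zero eigenvalue (the stationary state), real
negative eigenvalues (aperiodic modes with relaxation time ``-1/lambda``) and
complex-conjugate pairs (stochastic oscillations at frequency
``|Im lambda| / 2 pi`` damped at rate ``|Re lambda|``).  The autocorrelation of
any per-state observable (the transcriptional efficiency ``rho``, occupancy of
one TF, co-occurrence of two marks ...) is a sum of exponentials over these
modes, and its power spectrum a sum of Lorentzians / shifted peaks -- one
elementary component per mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .state_space import GeneratorMatrix, PromoterSystem, build_generator, stationary_distribution

__all__ = [
    "SpectralDecomposition",
    "Spectrum",
    "decompose",
    "autocorrelation",
    "power_spectrum",
    "coherence_factor",
    "cycle_eigenvalues",
    "eigenvalue_trajectories",
    "population_relaxation",
    "default_omega_grid",
]

_ZERO_EIG_TOL = 1e-9
_DEFECTIVE_COND = 1e8


@dataclass(frozen=True)
class SpectralDecomposition:
    """Biorthonormal eigensystem of a generator matrix.

    ``eigenvalues`` are sorted by ``|Re|`` ascending, the zero mode first.
    ``right[:, i]`` and ``left[i, :]`` satisfy ``left @ right = I``;
    ``right[:, 0]`` is the stationary distribution and ``left[0, :]`` the
    all-ones covector.  ``well_conditioned`` is False when the eigenvector
    matrix condition number suggests near-defectiveness (coefficients then
    unreliable, spectra still computable).
    """

    eigenvalues: np.ndarray
    right: np.ndarray
    left: np.ndarray
    well_conditioned: bool = True
    reconstruction_residual: float = 0.0

    @property
    def pi(self) -> np.ndarray:
        return self.right[:, 0].real

    @property
    def n_states(self) -> int:
        return self.eigenvalues.shape[0]

    def mode_coefficients(self, observable: np.ndarray) -> np.ndarray:
        """Modal weights ``c_i = (obs . R_i)(L_i . (pi * obs))`` for i >= 1.

        These are the coefficients of ``C(tau) = sum_i c_i exp(lambda_i tau)``
        for the stationary autocovariance of the observable.
        """
        obs = np.asarray(observable, dtype=float)
        w = self.pi * obs
        return (obs @ self.right) * (self.left @ w)


@dataclass(frozen=True)
class Spectrum:
    """One-sided sample of a two-sided power spectral density.

    ``omega`` is in rad/s; ``values`` carry observable^2 * s.  The underlying
    density is symmetric in omega and the stationary variance is
    ``(1/pi) * integral_0^inf S(omega) d omega``.
    """

    omega: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        omega = np.asarray(self.omega, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if omega.shape != values.shape:
            raise ValueError("omega and values must have equal shapes")
        if np.any(omega < 0):
            raise ValueError("spectra are stored for omega >= 0 only")
        floor = -1e-12 * max(values.max(initial=0.0), 1.0)
        if np.any(values < floor):
            raise ValueError("power spectral density must be nonnegative")
        object.__setattr__(self, "omega", omega)
        object.__setattr__(self, "values", np.clip(values, 0.0, None))


def decompose(gm: GeneratorMatrix) -> SpectralDecomposition:
    """Diagonalize ``M`` into a biorthonormal right/left eigensystem."""
    M = gm.M
    n = M.shape[0]
    if n == 1:
        return SpectralDecomposition(
            eigenvalues=np.zeros(1, complex),
            right=np.ones((1, 1), complex),
            left=np.ones((1, 1), complex),
        )
    if not gm.irreducible:
        raise ValueError("decompose requires an irreducible generator")
    vals, vecs = np.linalg.eig(M)
    order = np.argsort(np.abs(vals.real), kind="stable")
    vals, vecs = vals[order], vecs[:, order]
    cond = np.linalg.cond(vecs)
    well = cond < _DEFECTIVE_COND
    if not well:
        warnings.warn(
            f"eigenvector condition number {cond:.2e}: generator is nearly "
            "defective, modal coefficients may be unreliable"
        )
    left = np.linalg.inv(vecs)
    # pin the zero mode exactly: right_0 = pi, left_0 = 1
    vals[0] = 0.0
    scale = vecs[:, 0].sum()
    vecs[:, 0] /= scale
    left[0, :] *= scale
    recon = (vecs * vals) @ left
    resid = np.abs(recon - M).max() / max(np.abs(M).max(), 1.0)
    return SpectralDecomposition(
        eigenvalues=vals,
        right=vecs,
        left=left,
        well_conditioned=well,
        reconstruction_residual=float(resid),
    )


def autocorrelation(
    dec: SpectralDecomposition, observable: Sequence[float], tau_grid: Sequence[float]
) -> np.ndarray:
    """Stationary autocovariance ``C(tau)`` of a per-state observable.

    ``C(tau) = sum_{i>=1} c_i exp(lambda_i tau)``; ``C(0)`` is the stationary
    variance.  Imaginary parts cancel over conjugate pairs.
    """
    tau = np.asarray(tau_grid, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau_grid must be nonnegative")
    c = dec.mode_coefficients(observable)
    vals = dec.eigenvalues
    out = np.zeros_like(tau)
    acc = np.zeros(tau.shape, complex)
    for i in range(1, dec.n_states):
        acc += c[i] * np.exp(vals[i] * tau)
    scale = max(np.abs(acc).max(initial=0.0), 1e-300)
    if np.abs(acc.imag).max(initial=0.0) > 1e-8 * scale:
        warnings.warn("autocorrelation imaginary residue unexpectedly large")
    out = acc.real
    return out


def power_spectrum(
    dec: SpectralDecomposition,
    observable: Sequence[float],
    omega_grid: Optional[Sequence[float]] = None,
) -> Spectrum:
    """Modal power spectral density of a per-state observable.

    Each nonzero mode contributes
    ``c_i * (1/(-lambda_i + i omega) + 1/(-lambda_i - i omega))``: a Lorentzian
    of half-width ``-lambda_i`` for real modes, a peak near
    ``omega = |Im lambda_i|`` for conjugate pairs (combined so the density is
    real and nonnegative).
    """
    if omega_grid is None:
        omega_grid = default_omega_grid(dec)
    omega = np.asarray(omega_grid, dtype=float)
    c = dec.mode_coefficients(observable)
    acc = np.zeros(omega.shape, complex)
    for i in range(1, dec.n_states):
        lam = dec.eigenvalues[i]
        acc += c[i] * (1.0 / (-lam + 1j * omega) + 1.0 / (-lam - 1j * omega))
    values = acc.real
    # roundoff can leave tiny negatives on an exactly-zero spectrum
    tiny = 1e-12 * max(np.abs(values).max(initial=0.0), 1.0)
    values[np.abs(values) < tiny] = np.abs(values[np.abs(values) < tiny])
    return Spectrum(omega=omega, values=np.clip(values, 0.0, None))


def default_omega_grid(dec: SpectralDecomposition, points: int = 400) -> np.ndarray:
    """Log grid spanning all Lorentzian shoulders and oscillation peaks."""
    nz = dec.eigenvalues[np.abs(dec.eigenvalues) > _ZERO_EIG_TOL]
    if nz.size == 0:
        return np.logspace(-3, 1, points)
    lo = 1e-2 * np.abs(nz.real[np.abs(nz.real) > 0]).min(initial=1e-3)
    hi = 1e2 * np.abs(nz).max()
    return np.logspace(np.log10(max(lo, 1e-12)), np.log10(hi), points)


def coherence_factor(lam: complex) -> float:
    """Oscillation quality of one eigenvalue: ``|Im| / (2 pi |Re|)``.

    Counts how many oscillation periods fit in the damping time, i.e. how many
    cycles a synchronized promoter population completes before desynchronizing.
    Real eigenvalues have coherence 0.
    """
    if lam.real >= 0:
        raise ValueError("coherence is defined for decaying modes (Re lambda < 0)")
    return abs(lam.imag) / (2.0 * np.pi * abs(lam.real))


def cycle_eigenvalues(n: int, kf: float, kb: float = 0.0) -> np.ndarray:
    """Closed-form spectrum of the homogeneous ``n``-state directed cycle.

    ``lambda_j = kf (e^{2 pi i j / n} - 1) + kb (e^{-2 pi i j / n} - 1)``.
    For ``kb = 0`` the eigenvalues sit on the circle of radius ``kf`` tangent
    to the imaginary axis at 0; backward rates flatten it toward the real
    axis (fully symmetric: all real -- no oscillation without directionality).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if kf <= 0 or kb < 0:
        raise ValueError("need kf > 0 and kb >= 0")
    j = np.arange(n)
    z = np.exp(2j * np.pi * j / n)
    return kf * (z - 1.0) + kb * (np.conj(z) - 1.0)


def eigenvalue_trajectories(
    system: PromoterSystem,
    tf: str,
    conc_grid: Sequence[float],
) -> dict:
    """Track eigenvalue paths while sweeping one TF concentration.

    Rebuilds and decomposes ``M`` at each grid point and matches eigenvalues
    to the previous point by optimal assignment on complex-plane distances.
    Returns ``{"conc": grid, "paths": (n_states x n_grid) complex array,
    "coherence": ..., "frequency_hz": ..., "ambiguity": per-step margin}``.
    Near bifurcations path labels are heuristic; a small assignment margin is
    reported rather than resolved.
    """
    grid = np.asarray(conc_grid, dtype=float)
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("conc_grid must be positive and strictly increasing")
    n_states = system.n_states
    paths = np.empty((n_states, grid.size), complex)
    ambiguity = np.zeros(grid.size)
    prev = None
    for k, c in enumerate(grid):
        vals = decompose(build_generator(system.with_concentration(tf, c))).eigenvalues
        if prev is None:
            paths[:, k] = vals
        else:
            dist = np.abs(prev[:, None] - vals[None, :])
            rows, cols = linear_sum_assignment(dist)
            paths[:, k] = vals[cols[np.argsort(rows)]]
            # margin between chosen and best alternative assignment per row
            if n_states > 1:
                sorted_d = np.sort(dist, axis=1)
                gap = sorted_d[:, 1] - sorted_d[:, 0]
                ambiguity[k] = float(gap.min())
        prev = paths[:, k]
    if grid.size > 1 and np.any(ambiguity[1:] < 1e-12):
        warnings.warn("eigenvalue matching ambiguous at some sweep steps")
    lam_final = paths[:, -1]
    coh = np.array(
        [coherence_factor(l) if l.real < 0 else 0.0 for l in lam_final]
    )
    freq = np.abs(lam_final.imag) / (2.0 * np.pi)
    return {
        "conc": grid,
        "paths": paths,
        "coherence": coh,
        "frequency_hz": freq,
        "ambiguity": ambiguity,
    }


def population_relaxation(
    gm: GeneratorMatrix,
    observable: Sequence[float],
    initial_state: int,
    t_grid: Sequence[float],
) -> np.ndarray:
    """Ensemble-average observable after synchronous start in one state.

    ``value(t) = obs . exp(M t) . delta_init``, evaluated through the spectral
    decomposition; the damping of its oscillations is the population
    desynchronization seen in ChIP-style synchronized-induction experiments.
    Converges to the stationary mean as ``t -> inf``.
    """
    t = np.asarray(t_grid, dtype=float)
    dec = decompose(gm)
    obs = np.asarray(observable, dtype=float)
    if not 0 <= initial_state < dec.n_states:
        raise ValueError("initial_state out of range")
    amp = (obs @ dec.right) * dec.left[:, initial_state]
    acc = np.zeros(t.shape, complex)
    for i in range(dec.n_states):
        acc += amp[i] * np.exp(dec.eigenvalues[i] * t)
    return acc.real
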