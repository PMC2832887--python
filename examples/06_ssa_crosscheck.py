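"""Exact Gillespie simulation as an independent check of the analytics."""

import numpy as np
from scipy.stats import poisson

import promodyn as pmd
from promodyn.gillespie import time_average_histogram

# telegraph promoter occupancy vs stationary law
system = pmd.two_state(0.2, 5.0, 3.0, 0.0, 8.0)
traj = pmd.simulate(system, None, duration=2e5, seed=42)
occ = time_average_histogram(traj, traj.states, 1)
pi = pmd.stationary_distribution(pmd.build_generator(system))
print(f"SSA bound fraction {occ[1]:.4f} vs stationary {pi[1]:.4f} "
      f"({traj.times.size} events)")

# constant promoter: time-averaged RNA histogram vs Poisson
constant = pmd.PromoterSystem(
    tf_names=("A",), k0=np.array([[1e-12, 1e-12]]),
    concentrations=np.array([1.0]), rho=np.array([2.0, 2.0]),
)
cascade = pmd.CascadeParams(gamma=0.1, beta=1e-12, gamma_p=1.0)
traj = pmd.simulate(constant, cascade, 3e5, seed=1, burn_in=500, track_protein=False)
hist = time_average_histogram(traj, traj.rna, int(traj.rna.max()))
tv = 0.5 * np.abs(hist - poisson.pmf(np.arange(hist.size), 20.0)).sum()
print(f"RNA histogram vs Poisson(20): total variation {tv:.4f}")

# periodogram of the simulated efficiency path vs the modal spectrum
traj = pmd.simulate(system, None, 2e5, seed=7)
series = pmd.sampled_series(traj, dt=0.05)
sp = pmd.periodogram(system.rho[series["state"]], 0.05)
dec = pmd.decompose(pmd.build_generator(system))
ana = pmd.power_spectrum(dec, system.rho, sp.omega)
band = (sp.omega > 0.4) & (sp.omega < 8.0)
ratio = sp.values[band].mean() / ana.values[band].mean()
print(f"Welch periodogram / analytic Lorentzian, mid-band mean ratio: {ratio:.3f}")
print("-> simulation and spectral theory agree; the SSA is the ground truth the")
print("   eigendecomposition route is checked against")
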