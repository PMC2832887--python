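"""A 16-state energy-independent promoter: cooperative binding, competition,
DNA looping -- Hill-like means hiding kinetic complexity.

A binds at two sites (cooperatively, -2 kcal/mol), competes with C at one
site (+1.5 kcal/mol), and two bound A's pay for a repressive DNA loop
(9 - 2*5.5 kcal/mol).  All barriers are shared between reaction directions:
the system is closed, dissipates nothing, and its stationary law is Boltzmann
in the assembled free energies.
"""

import numpy as np

import promodyn as pmd

em = pmd.looping_energetics()
print("closed (energy-independent)?", pmd.is_closed_system(em))

grid = np.logspace(-2, 3, 5)
cascade = pmd.dna_looping_system(1.0, 1.0)[2]
print("\nmean RNA over [A] (rows, nM down) x [C] (cols, nM across):")
for a in grid:
    row = []
    for c in grid:
        system, _, _ = pmd.dna_looping_system(a, c)
        pi = pmd.stationary_distribution(pmd.build_generator(system))
        row.append(pi @ system.rho / cascade.gamma)
    print("  " + "  ".join(f"{v:6.1f}" for v in row))
print("-> four Hill-like plateaus: C activates, A (via the loop) represses")

# randomizing barriers (G0 fixed) leaves this whole table untouched but
# reshapes the fluctuations
em2 = pmd.randomize_barriers(em, sd_kcal=3.0, seed=7)
a, c = 0.01, 0.178
s1, _, _ = pmd.dna_looping_system(a, c)
s2, _, _ = pmd.dna_looping_system(a, c, em=em2)
for label, s in (("printed barriers", s1), ("randomized barriers", s2)):
    dec = pmd.decompose(pmd.build_generator(s))
    m = float(dec.pi @ s.rho) / cascade.gamma
    _, vr, _ = pmd.analytic_variances(dec, s.rho, cascade)
    print(f"{label:22s} [A]={a}, [C]={c}: <R> = {m:.4f}, cv2_R = {vr/m**2:.4f}")
print("-> identical means, different noise: steady-state fluctuations reveal")
print("   the activation barriers that mean expression cannot")
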