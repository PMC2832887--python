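"""Noise induced by HIGH activator concentration, with the mean pinned.

Two TFs: B gates transcription; A merely slows B's binding and unbinding
(shared 2.5 kcal/mol barrier shift) when bound.  Since A changes no state
energy, B's occupancy -- and so every mean level -- is independent of [A].
But saturating [A] slows the transcription-gating events ~70-fold, producing
slow bursts and a bimodal RNA distribution.
"""

import promodyn as pmd

for conc_a in (0.01, 1.0, 1000.0):
    system, cascade = pmd.steric_hindrance_system(conc_a)
    _, mr, mp = pmd.mean_levels(system, cascade)
    _, cr, cp = pmd.normalized_variances(system, cascade)
    marg = pmd.rna_marginal(pmd.joint_steady_state(system, cascade.gamma))
    n_modes, locs = pmd.count_modes(marg, min_height=1e-4)
    print(f"[A] = {conc_a:7.2f} nM: <R> = {mr:5.2f}, <P> = {mp:8.1f}, "
          f"cv2_R = {cr:6.4f}, cv2_P = {cp:6.4f}, RNA modes = {n_modes} at {locs}")

print()
print("The mean is flat in [A] while cv2 rises ~20-fold and the distribution")
print("splits into an off mode at 0 and an on mode near 60 copies: raising a")
print("TF's concentration can CREATE expression noise rather than average it out.")
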