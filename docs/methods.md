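# Methods

## Model

The promoter is a continuous-time Markov chain on the `2^N` subsets of bound
factors, indexed as bitmasks over the declared factor order (state 0 = empty;
`s ⊖ f` is the XOR with factor `f`'s bit). The generator uses the
column-as-source convention `M[s', s] = rate(s → s')`, `dφ/dt = Mφ`, columns
summing to zero by construction. In the single-event version only one factor
binds or unbinds per transition; arbitrary multi-molecule transitions
(complex binding, concerted conformational changes) enter through an explicit
`raw_M` generator, after which every derivation is unchanged.

Assumptions inherited from the modeling tradition this package belongs to:
factors are well-mixed at fixed free concentration (no extrinsic noise, no
depletion), transcription and translation are instantaneous first-order
events, RNA and protein decay are exponential, and there is no autoregulation.
Non-exponential lifetimes, synthesis delays and feedback are out of scope.

## Kinetic–energetic duality

The energetic form assigns each state a standard Gibbs energy `G⁰_s`
(kcal/mol, reference concentration 1 nM) and each reaction an activation
barrier `E⁰[f, s]`, with rates `ν·exp(−(E⁰ − G⁰_s)/k_BT)`. We evaluate this
formula entirely at standard condition and let `build_generator` multiply
association entries by `[f]`: spectator-concentration terms cancel between
barrier and state, so the equilibrium ratio of any reaction is
`[f]·exp(−ΔG⁰/k_BT)`, reproducing the Boltzmann law in the
concentration-corrected energies `G_s = G⁰_s + k_BT Σ_{f∉s} log[f]`.
The attempt frequency `ν` (default 1 s⁻¹) is an explicit parameter: energies
alone fix only rate ratios, and doubling `ν` doubles `M` while leaving the
stationary law untouched. `k_B = 0.0019872 kcal/(mol·K)`; `T` defaults to
298.15 K (`k_BT = 0.5925 kcal/mol`).

Closedness is the barrier-symmetry predicate `E⁰[f, s] = E⁰[f, s ⊖ f]`
(tolerance 1e-9 kcal/mol; a pair of infinite barriers — a forbidden reaction —
counts as symmetric). Closed systems satisfy the Kolmogorov cycle criterion,
have Boltzmann stationary laws and purely real spectra; we test all three on
random ensembles. Detailed-balance violation is detected on a cycle basis of
the undirected support graph, comparing directed rate products at relative
tolerance 1e-8, one-way edges inside a cycle counting as violations.

## Spectral machinery

`decompose` diagonalizes `M` (dense `numpy.linalg.eig`), sorts by `|Re λ|`
with the zero mode first, pins `R₀ = π` and `L₀ = 1`, and takes left vectors
from the inverse eigenvector matrix so biorthonormality is exact by
construction. An eigenvector condition number above 1e8 flags
near-defectiveness (random parameter draws occasionally approach it); the
decomposition is still returned, with a warning, since spectra remain usable
even when individual coefficients are ill-determined.

For an observable `ρ`, modal coefficients `c_i = (ρ·R_i)(L_i·(π⊙ρ))` give the
stationary autocovariance `C(τ) = Σ_{i≥1} c_i e^{λ_i τ}` and the two-sided
spectral density `S(ω) = Σ_i c_i[1/(−λ_i+iω) + 1/(−λ_i−iω)]`; conjugate pairs
are summed in complex arithmetic and the real part taken, with a roundoff
floor clipped at 1e-12 of scale. Spectra are stored one-sided in `ω ≥ 0`
(default grid: 400 log-spaced points from `10⁻²·min|Re λ≠0|` to `10²·max|λ|`),
the variance being `(1/π)∫₀^∞ S dω`.

The coherence of an oscillatory mode is defined here as
`Z = |Im λ|/(2π|Re λ|)` — periods completed within one damping time, i.e. how
many oscillations a synchronized population shows before desynchronizing.
(The guide values Z = 0.5 and 1 are rays through the origin of the complex
plane; the ideal irreversible 22-step cycle has `Z₁ = 1.107`.) Other
normalizations differing by a constant appear in the literature; this one is
used consistently throughout.

Eigenvalue trajectories along a concentration sweep are matched between grid
points by optimal bipartite assignment on complex-plane distances
(`scipy.optimize.linear_sum_assignment`) — chosen over greedy nearest-neighbor
matching as strictly better at equal cost. Labels near bifurcations remain
heuristic; the assignment margin is reported, not resolved.

## Cascade and normalized variances

RNA and protein are birth–death stages driven by the promoter: each adds a
shot-noise floor `2·(decay)·(mean)` and a Lorentzian low-pass filter at its
decay rate. Variances are obtained by exact partial-fraction integration of
the filtered modal spectra:

- `Var(R) = ⟨R⟩ + Σ_i c_i/(γ(γ − λ_i))`
- `Var(P) = ⟨P⟩ + β²⟨R⟩/(γ̃(γ + γ̃)) + β² Σ_i c_i J(−λ_i; γ, γ̃)`

with `J` the three-pole partial-fraction integral. The result is smooth where
poles collide, so near-degenerate poles (within 1e-8 of scale) are nudged by
1e-5 rather than special-cased. Every call cross-checks the closed form
against adaptive quadrature of the assembled spectrum and raises beyond 0.1%
mismatch. A term-by-term Paulsson-style decomposition is *verified*
numerically (Poisson floors, time-averaging monotonicity, the classical
two-stage constant-promoter formula) rather than hard-coded, since the
integral definition is exact by construction.

## Joint promoter–RNA distribution

The joint steady state is one sparse linear solve over `(r, s)` blocks,
r-major ordering for small bandwidth, one redundant balance row replaced by
normalization. The birth flux out of the top level `rmax` is suppressed
(reflecting truncation) so the truncated generator remains conservative.
`rmax` starts at `ceil(mean + 12√mean + 20)` — generous enough for bimodal
mixtures whose upper mode sits well above the mean — and doubles until the
mass in the top three levels falls below 1e-8, erroring at `rmax = 1e5`.
Mode counting merges numerically-equal plateaus (a Poisson pmf with integer
mean has a two-point plateau) and ignores maxima below 1e-6 by default.
Protein distributions are not solved exactly (only RNA); protein histograms
are available from the simulator.

## Entropy production

`Ė = Σ_{s≠s'} π_s M[s',s] log(M[s',s]/M[s,s'])` in k_BT/s (the kcal/mol/s
conversion is explicit, `k_BT` outside the sum). It is nonnegative, zero
exactly on detailed balance, scales linearly under time rescaling of `M`, and
is reported as `+∞` with the offending edge when a reaction inside a cycle
has no reverse rate (the idealized irreversible cycle). The ATP-equivalent
helper divides `Ė × period` by 20 k_BT per hydrolysis by default.

## Simulator

Direct-method SSA — exactness is the point of an oracle, and the systems are
small — over promoter transitions, RNA birth/death and protein birth/death,
with the hot loop numba-compiled and driven by a single integer seed (chunked
runs derive sub-seeds below 2³¹; identical seeds give identical paths).
Sampling onto a regular grid takes the value set by the last event at or
before each grid time. The periodogram is Welch-averaged (Hann window, 16
segments, 50% overlap by default), halved and mapped to rad/s to match the
two-sided analytic convention. Zero-order-hold sampling aliases the
`ω⁻²` spectral tails near the Nyquist frequency, so comparisons against
analytic spectra are made in a mid-band at least a factor ~8 below Nyquist.

## Example systems

**Telegraph promoter** (`two_state`): kon⁰ = 0.2 nM⁻¹s⁻¹, [A] = 5 nM,
koff = 3 s⁻¹, ρ = (0, 8) s⁻¹ — every quantity has a closed form, used as the
primary oracle fixture.

**Hindrance promoter** (`steric_hindrance_system`): two factors; B gates
transcription (K_B = 5 nM, 60 s residence, [B] = 5 nM), A gates nothing
(K_A = 0.5 nM, 30 s residence) but adds a shared 2.5 kcal/mol barrier to both
B transitions when bound. RNA lifetime 5 min, protein 20 min. Because the
barrier shift is direction-symmetric the system is closed and B's occupancy
is independent of [A]: means are exactly flat while saturating [A] slows the
gating ~70-fold (`e^{−2.5/0.5925}`), raising CV² and splitting the RNA
distribution to bimodal. The transcription rate ρ_B = 0.2 s⁻¹ is this
package's calibration, set once so ⟨R⟩ ≈ 30 at vanishing [A]; the
translation rate is set so ⟨P⟩ = 1000·⟨R⟩, a typical protein/mRNA abundance
ratio in yeast.

**DNA-looping promoter** (`dna_looping_system`): 16 states over (A₁, A₂, C,
loop). State energies assemble additively: `k_BT·log K` per binding
(K_A = 20 nM, K_C = 1 nM), A–A cooperativity −2, A/C competition +1.5 at one
A site (which site is a flag; default site 2), loop cost +9 overcompensated by
−5.5 per bound A. Barriers are anchored on residence times (20 s at A sites,
60 s for C, +2.5 kcal/mol on C when looped) and loop closing takes 1 s when
both A sites are occupied; the loop transition is forbidden (infinite shared
barrier) otherwise, and the "loop" pseudo-factor has unit dimensionless
concentration so it contributes no concentration term. Everything is shared
between directions: the system is closed regardless of barrier choices, which
is what makes `randomize_barriers` (one Gaussian draw per reaction, both
directions, G⁰ untouched) preserve every mean exactly while reshaping the
noise. Per-state transcription rates (0.06 s⁻¹ unlooped baseline, +0.16 with
C, +0.02 with exactly one A, 0.035/0.05 looped) are this package's
calibration, chosen once to keep ⟨R⟩ inside the characteristic 10–70
copies-per-cell window across the swept concentration grid
([10⁻², 10³] nM both axes).

**Homogeneous cycle** (`homogeneous_cycle`): carries its generator explicitly
(a cycle of `n` states is not a subset lattice) and duck-types the promoter
interface downstream.

## Random fixtures and the optimizer

`random_system` draws log-normal kinetics (median 0.05 s⁻¹, σ = 1 log-unit),
concentrations (median 2 nM) and transcription rates (median 0.05 s⁻¹) —
second-to-minute promoter timescales against a 5-min RNA lifetime, the regime
the example systems inhabit. `random_closed_system` draws `G⁰` (σ = 1.5
kcal/mol) and shared barriers (2 ± 1.5 kcal/mol). All draws are seeded.

`optimize_coherence` hill-climbs log-kinetics: 1–3 entries perturbed per
iteration (σ = 0.4 log-units), accepted when the objective does not decrease.
The objective is the best modal coherence among oscillations slower than 10×
the fastest relaxation (faster ones discounted proportionally) — a slow
"global clock" emerging from fast molecular events. This is a deliberately
simple search: it demonstrates the qualitative coupling between coherence and
energy dissipation along accepted steps, and makes no claim to reproduce any
particular optimized system.

## What the synthetic generators do and do not show

The random and example systems exercise combinatorial state spaces, shared
vs. asymmetric barriers, slow/fast timescale separations and realistic
abundances, so passing tests demonstrate the internal consistency of the
spectral, distributional, thermodynamic and simulation routes and the claimed
qualitative phenomena. They do not capture extrinsic noise, concentration
depletion, non-exponential lifetimes, delays or autoregulation, so agreement
here does not by itself validate the model against measured promoters.

## Problem sizes and numerical choices

Default test and acceptance workloads use N ≤ 4 (16 states) for exhaustive
ensembles, 100-draw thermodynamic ensembles, 10⁶-second simulations for
oracle comparisons, and 300-iteration optimizer runs — sizes at which every
check is comfortably reproducible on a single core. Stationary solves use LU
with two steps of iterative refinement (barrier-randomized systems spread
rates over many decades); stationary residual tolerance 1e-10·max|M|, column
conservation 1e-12 relative, spectral reconstruction 1e-8.

## Known limitations

Defective or near-defective generators are flagged, not repaired; eigenvalue
path labels can swap at bifurcations; the coherence normalization is fixed up
to the documented constant; mode counting at default tolerance can be
sensitive for nearly-flat distributions; protein-level distributions are
simulation-only.
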