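# Methods

## The model

Excitation energy transfer in pigment–protein complexes is described by a
Frenkel-exciton Hamiltonian H = H_s + H_b + H_sb.  In the basis of locally
excited sites,

    H_s  = Σ_n ε_n |n⟩⟨n| + Σ_{n≠m} J_nm |n⟩⟨m|
    H_b  = Σ_{nk} ħω_k (b†_nk b_nk + ½)
    H_sb = Σ_{nk} ħω_k g_k (b†_nk + b_nk) |n⟩⟨n|

with site energies ε_n, intersite couplings J_nm, and identical independent
harmonic baths on every site, characterized by mode frequencies ω_k and
Huang–Rhys factors g_k².  All energies and frequencies are handled in cm⁻¹
(k_B = 0.69503476 cm⁻¹/K, so k_BT ≈ 208.5 cm⁻¹ at 300 K) and times in fs;
trajectory propagation internally converts to angular frequencies with
ω[rad/fs] = 2πc·ν[cm⁻¹].

The bath is specified as a `SpectralDensity`: a list of discrete
intramolecular modes plus smooth solvent components in parametric form
(Debye by default, ρ(ω) = (2/π) λ ω_c/(ω² + ω_c²), which integrates to the
solvent reorganization energy λ; a lognormal form is also available).  The
density of reorganization energies Λ(ω) is the working representation: its
integral is the total reorganization energy Λ, and for plotting each
discrete mode is broadened with a Brownian-oscillator lineshape
(2/π)·g_k²·ω_k²γω/[(ω_k²−ω²)² + ω²γ²] whose integral recovers
λ_k = ω_k g_k² (default γ = 10 cm⁻¹).

## Bath partition

The quantum-mechanically "interesting" window of the bath is
[k_BT, ħω_max], where ħω_max is the maximum gap between eigenvalues of
H_s: modes slower than k_BT are effectively classical, modes faster than
ħω_max cannot be resonant with any excitonic transition.  Discrete modes
are routed into low (ω < k_BT, strict), high (k_BT ≤ ω ≤ ω_max) and
nonresonant (ω > ω_max) classes; smooth solvent components are always low,
on the assumption that they are dominated by sub-thermal frequencies.
Nonresonant modes are excluded from the classical dynamics by default
(verified to leave populations unchanged); they are included in the
polaron transformation.

The *window fraction* — reorganization energy in [k_BT, ω_max] relative to
[0, ω_max] — is the single most predictive number for the size of nuclear
quantum effects on transfer rates: large fractions mean strong vibronic
coupling in the band of frequencies that are both quantized (ħω > k_BT)
and dynamically relevant (ħω < ħω_max).

## Solvent discretization

Smooth components are discretized into effective modes by equal-λ slicing
of the cumulative reorganization profile, cut at the frequency capturing
99.9% of λ, with each slice represented at its median frequency and
g_j² = (λ/n)/ω_j.  Two properties of this quadrature matter in practice:

* The Debye density has a slowly decaying ω⁻² tail, so the deepest slices
  sit at thousands of cm⁻¹ while carrying ≲1% of λ.  The correlation
  function of the discretized bath therefore matches the continuous one to
  about 2% of C(0) while C(t) is alive, and fluctuates within the
  dephasing noise floor λ/√(2n) afterwards.  Both bounds are asserted in
  the tests against direct quadrature.
* Equilibrium observables converge with the number of solvent modes
  roughly as 1/n (finite heat capacity and recurrences); n = 200 per
  component is used for equilibrium studies, n = 24 (the default) for
  transfer kinetics, which only probe the bath's short-time response.

## Multi-state MASH dynamics

Nuclear operators are replaced by mass-scaled classical variables,
b_nk = (ω_k q_nk + i p_nk)/√(2ħω_k), giving H(p,q) = p²/2 + V(q) with
V_nn(q) = ε_n + Σ_k κ_k q_nk (κ_k = √2 g_k ω_k^{3/2}, ħ = 1) and
V_nm = J_nm.  The excitonic coefficients c_n and the nuclei are propagated
together; the nuclei feel the Hellmann–Feynman force of the *most
populated* adiabatic state of V(q) (the active state).  When the active
state changes, the momentum is rescaled along the normalized
nonadiabatic-coupling direction d_nk ∝ κ_k U_{n,a}U_{n,b} so that total
energy is conserved exactly; if the quadratic rescaling equation has no
real root the momentum component along d is reversed instead (frustrated
hop, "bouncing off a wall").  With a degenerate (zero-norm) direction the
full momentum vector is rescaled uniformly; this is logged.

Populations are measured with the estimator
Φ_n = 1/N + α_N(|c_n|² − 1/N), α_N = (N−1)/(H_N−1), the linear estimator
consistent with the mixed quantum-classical equilibrium; ΣΦ_n = 1 holds
exactly.  Trajectories start from "focused" initial conditions
(c_n = r_n e^{iφ_n} with magnitudes making Φ a unit vector on the initial
site and independent uniform phases) and nuclei from the classical
Boltzmann distribution centered at q = 0 (vertical excitation); a Wigner
option with coth(βħω/2) widths is available for initial conditions only.

Integration uses velocity Verlet for the nuclei and, for the
coefficients, the split unitary exp(−iV(q')dt/2)·exp(−iV(q)dt/2) built
from the adiabatic decompositions at the step endpoints — exactly
norm-conserving and second-order accurate.  Hop detection runs once per
step.  The default timestep is a fortieth of the fastest *coupled* period
(excitonic bandwidth and the frequency below which 99% of bath
reorganization lies), capped at 0.5 fs, with a velocity-Verlet stability
bound ω_max·dt ≤ 1.2 guarding the weakly coupled discretization tail.
Energy drift between hops is bounded and shrinks as dt²; hops conserve
energy to machine precision by construction.

Ensembles are divided into batches (default 5); all standard errors,
including those of group populations, are computed from batch means.
Each trajectory's random stream derives from (seed, trajectory index), so
results are independent of batching and execution order.  The ensemble
kernel is compiled with numba; a plain-numpy single-trajectory reference
implementation of the identical algorithm is cross-checked against it in
the tests.

### Equilibrium protocol

Detailed balance — agreement of long-time MASH populations with the
phase-space average of the excitonic Boltzmann distribution (estimated
independently by importance-sampling Monte Carlo) — is the central
correctness test.  Two finite-simulation artifacts must be controlled:

* *Quasi-static solvent modes.*  The lowest equal-λ slices of a Debye
  solvent have periods far exceeding any affordable simulation, so a
  vertically excited ensemble relaxes toward equilibrium with a slow tail
  (several ps) carried by modes that cannot re-equilibrate.  Equilibrium
  runs therefore use a warm start (`initial_site="thermal"`): the focused
  site is drawn from the site-energy Boltzmann distribution and the
  occupied site's modes are displaced to their coupled minima
  (q → −κ_k/ω_k²).  This places the ensemble close to the true joint
  equilibrium; the dynamics then only has to *hold* it, which is the
  property being tested (a no-back-action propagator, for example, drifts
  to uniform populations and fails).
* *Timestep bias.*  The once-per-step hop handling leaves a small
  O(dt) bias in the uphill flux that is visible for donor-acceptor
  offsets of several k_BT; equilibrium runs for the steepest fixture use
  dt = 0.0625 fs, chosen by dt-halving until the change is below the
  ensemble standard error.

### No-back-action baseline

For reference, the dynamics can be run with the state-independent force
only (free harmonic nuclei).  The exciton subsystem then absorbs energy
without limit and all site populations tend to 1/N — for a two-ring
funnel with 8 of 12 sites in the acceptor ring, a long-time acceptor
yield of 2/3 regardless of energetics.  Populations for this variant are
reported as plain |c_n|², since the Φ estimator's consistency argument
presumes MASH dynamics.

## Variational polaron transformation

High-frequency modes are removed from the dynamical bath and folded into
the exciton Hamiltonian by the unitary dressing e^G with
G = Σ_nk f_nk(b†_nk − b_nk)|n⟩⟨n|.  The renormalized parameters are

    ε′_n = ε_n − Σ_k ω_k(2 f_nk g_k − f_nk²)
    J′_nm = J_nm ⟨B_nm⟩,  ⟨B_nm⟩ = exp(−½ Σ_k (f_nk² + f_mk²) coth(βω_k/2))

The displacements minimize the Bogoliubov bound F₀ on the free energy;
stationarity gives the self-consistency condition

    f_nk = ω_k g_k / (ω_k − coth(βω_k/2) Σ_{m≠n} J′_nm Γ_nm)

with Γ_nm = Σ_M P_M U_nM U_mM / Σ_M P_M U_nM² built from the
Boltzmann-weighted eigenstates of H′_s.  The fixed point is iterated from
the full-polaron guess f = g (tolerance 10⁻¹⁰ relative, mixing 0.5 only
if the update oscillates); on dimer fixtures it matches a dense-grid
minimization of F₀ to grid resolution, and the reported residual is the
finite-difference stationarity defect ∂F₀/∂f.  The limits behave
correctly: J = 0 gives the full polaron (f = g, J′ = 0), g = 0 gives the
identity, and β → ∞ turns ⟨B⟩ into the familiar exp(−Σ(f² + f′²)/2).

After the transformation the residual system-bath coupling (reduced
diagonal terms g_k − f_nk and fluctuating off-diagonal dressing) is
reported but *not* propagated: MASH then runs on (ε′, J′) with the
low-frequency bath only.  This captures the leading nuclear quantum
effect — thermal band narrowing by zero-point statistics via
coth(βω/2) = 2n̄+1 — while leaving the sub-thermal bath, which a
perturbative polaron master equation would handle badly, to the
nonperturbative trajectory dynamics.

## Equilibrium oracles

* `qc_equilibrium`: the mixed quantum-classical populations.  Since the
  linear coupling makes the site-energy shifts Gaussian under the
  uncoupled-bath proposal (variance 2Λk_BT per site, independent of the
  discretization), the phase-space integral reduces to a low-dimensional
  Gaussian average evaluated by importance sampling with the excitonic
  trace as weight; momenta integrate out analytically.  Standard errors
  come from block means; an effective-sample-size warning flags poor
  overlap at low temperature.
* `quantum_equilibrium_small`: exact diagonalization of H on the
  site ⊗ Fock product space for ≤3 sites and ≤2 modes per site, with
  truncation validated by halving the Fock size (tolerance 10⁻⁶).
* `system_boltzmann`: site projections of the excitonic Boltzmann state,
  the appropriate reference for a VPT-renormalized system whose residual
  bath has been dropped.

For small systems a fourth evaluator, `qc_equilibrium_quadrature`,
computes the phase-space average by exact Gauss–Hermite quadrature; the
importance-sampling estimator loses essentially all of its effective
sample size for strongly coupled single-mode fixtures, and the
quadrature is the oracle of record there.

A noteworthy (and deliberately documented) finding from these oracles:
for a dimer whose stiff mode (βħω ≈ 5) couples *identically* to both
sites, the polaron shift cancels in the site-energy gap and all three
equilibria nearly coincide (within ~0.02 over the physically sensible
parameter range), with the fixed ordering P_VPT ≤ P_classical ≤
P_quantum.  Zero-point band narrowing slightly underestimates the
thermally enhanced vibronic delocalization, which classical broadening
partially mimics, so for this observable the bare classical average is
marginally the closer of the two.  The polaron correction earns its keep
in the *dynamics* (transfer rates), not in the equilibrium site
populations of identical-bath dimers; the tests assert the verified
ordering rather than a presumed one.

## Kinetics

Group populations (sums of Φ_n over named site groups, with errors from
batch means of the summed quantity) are reduced to time constants by
nonlinear least squares: P(t) = P∞(1 − e^{−t/τ}) for single-step
transfer, P(t) = P∞ − A₁e^{−t/τ₁} − A₂e^{−t/τ₂} (τ₁ ≤ τ₂, amplitudes
non-negative, five τ-ratio multistarts) for funnels.  Initial guesses
are deterministic (P∞ from the final value, τ from the 1−1/e crossing),
weights uniform by default with SEM weighting optional, and fits start at
t = 0.  Rate-constant ratios carry errors propagated from the fit
covariances.  Nearly equal biexponential time constants (τ₂/τ₁ < 1.05)
are flagged as degenerate rather than rejected.

## Synthetic regimes

The generators produce models with the statistical structure of three
light-harvesting architectures, explicitly labelled synthetic — they are
test beds for the machinery, not reproductions of literature
Hamiltonians:

* **Two-ring funnel (LH2-like)**: a strongly coupled inner ring
  (nearest-neighbour coupling 300 cm⁻¹; 16 sites, or 8 in the desk-scale
  variant with 250 cm⁻¹) and a weakly coupled outer ring (4–8 sites,
  30 cm⁻¹) red-shifted relative to the donor ring by 800–850 cm⁻¹ so that
  the donor band sits at the upper edge of the acceptor exciton band —
  the structural feature that makes transfer depend on the bath's
  ability to absorb large energy quanta.  Each outer site couples to its
  two nearest inner sites (45 cm⁻¹).  Window fraction target 0.54.
* **Eight-site network (FMO-like)**: a chain-like funnel with
  nearest-neighbour couplings ~−80 cm⁻¹, small excitonic gaps
  (ω_max ≈ 550 cm⁻¹) and weak in-window vibronic coupling
  (fraction 0.11).
* **Two-group funnel (LHCII-like)**: 8 + 6 sites, offset 350 cm⁻¹,
  intermediate couplings, fraction 0.44.

Every bath is a Debye solvent (λ = 100 cm⁻¹, or 35 for the FMO-like
regime; ω_c = 50 cm⁻¹) plus 10–20 discrete modes in three bands
(sub-thermal, in-window, just-above-ω_max).  In-window Huang–Rhys factors
are rescaled in closed form so the realized window fraction equals the
regime target exactly (an error is raised if the solvent alone already
exceeds the target).  Generation is deterministic at fixed seed, to the
point of byte-identical model files.

Desk-scale choices: the acceptance runs use the 12-site two-ring funnel,
10⁴ (or 5×10³ in the acceptance script) trajectories, and 0.5–0.7 ps of
dynamics; these sizes resolve the factor-~1.3–1.5 rate discrimination
between variants at 5-batch standard errors of a few 10⁻³.

## What the synthetic tests do and do not show

Passing tests demonstrate that the machinery is internally consistent
(detailed balance against an independent oracle, exactness at g = 0,
variational optimality of the polaron displacement, estimator
identities) and that the qualitative mechanism — classical high-frequency
modes speed transfer up, polaron quantization slows it down, with the
effect growing with the window fraction — emerges on models with
light-harvesting-like structure.  They do not validate any specific
pigment assignment, energy, or coupling of a real complex; reproducing
published numbers for LH2, FMO or LHCII requires the corresponding
literature Hamiltonians and spectral densities as input model files.

## Known limitations

* The once-per-step hop handling leaves an O(dt) bias in steeply uphill
  equilibria; controlled by timestep refinement, not eliminated.
* Identical independent baths only; no static disorder by default, no
  correlated or site-specific spectral densities.
* The truncated-boson oracle is restricted to brute-force scale.
* No spectroscopy: absorption/fluorescence lineshapes and coherence
  observables are out of scope.
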