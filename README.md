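# excitonmash

Mixed quantum-classical simulation of excitation energy transfer in
light-harvesting-like pigment networks, with nuclear quantum effects of
high-frequency vibrations captured by a variational polaron
transformation.

## The problem

Energy transfer between chromophores in photosynthetic antenna complexes
is governed by a Frenkel-exciton Hamiltonian

    H = Σ_n ε_n|n⟩⟨n| + Σ_{n≠m} J_nm|n⟩⟨m|
      + Σ_{nk} ħω_k(b†_nk b_nk + ½) + Σ_{nk} ħω_k g_k(b†_nk + b_nk)|n⟩⟨n|

in which each site couples to an identical, independent bath of
vibrations (frequencies ω_k, Huang–Rhys factors g_k²).  Whether the
*quantum* character of the high-frequency intramolecular modes matters
for the transfer is a long-debated question.  Answering it requires a
classical reference that is actually consistent with the quantum-
classical equilibrium — naive "no back-action" dynamics drives all site
populations to 1/N, an infinite-temperature artifact.

This package provides the two ingredients needed for a clean comparison:

* **Multi-state MASH** (mapping approach to surface hopping): a
  deterministic trajectory method whose nuclei follow the most-populated
  adiabatic state of V(q), with energy-conserving momentum rescaling at
  state changes.  Its long-time populations reproduce the mixed
  quantum-classical Boltzmann average

      ⟨|n⟩⟨n|⟩_cl = ∫dp dq Tr_ex[e^{−βH(p,q)}|n⟩⟨n|] / ∫dp dq Tr_ex[e^{−βH(p,q)}]

  which the package verifies against an independent Monte-Carlo oracle.
  Populations use the equilibrium-consistent estimator
  Φ_n = 1/N + α_N(|c_n|² − 1/N), α_N = (N−1)/(H_N−1).
* **Variational polaron transformation (VPT)**: high-frequency modes
  (above k_BT, up to the maximum excitonic gap ħω_max) are removed from
  the dynamical bath and folded into renormalized parameters
  ε′_n = ε_n − Σ_k ω_k(2f_nk g_k − f_nk²) and J′_nm = J_nm⟨B_nm⟩ with the
  thermal band-narrowing factor
  ⟨B_nm⟩ = exp(−½Σ_k(f²_nk + f²_mk)coth(βħω_k/2)).  The displacements
  f_nk minimize the Bogoliubov free-energy bound and are found by a
  self-consistent fixed point validated against brute-force minimization.

Running MASH with all modes classical, with the VPT-renormalized
Hamiltonian, and with the low-frequency bath only isolates the nuclear
quantum effect on the transfer rate.

## Worked example

Generate a synthetic two-ring funnel (a B850/B800-like architecture with
54% of its in-window reorganization energy above k_BT), then compare the
classical and polaron-quantized transfer:

```python
import numpy as np
from excitonmash import (make_model, build_dynamical_bath, max_exciton_gap,
                         solve_vpt, MASHConfig, run_ensemble)
from excitonmash.kinetics import fit_mono

system, sd, spec = make_model("ring_funnel_LH2like_desk", seed=7)
wmax = max_exciton_gap(system)            # 1573 cm^-1
high = build_dynamical_bath(sd, 300.0, wmax, include=("high", "nonresonant"))
vpt = solve_vpt(system, high, 300.0)
print("band narrowing (mean, min):",
      tuple(round(x, 2) for x in vpt.narrowing_statistics(system.couplings)))

cfg = MASHConfig(t_max=700.0, n_traj=2000, seed=3,
                 initial_site=spec.n_inner)   # excite an outer-ring site
taus = {}
for name, bath, sol in (
        ("classical", build_dynamical_bath(sd, 300.0, wmax), None),
        ("quantum (VPT)", build_dynamical_bath(sd, 300.0, wmax,
                                               include=("low",)), vpt)):
    ts = run_ensemble(system, bath, cfg, vpt=sol)
    series, sem = ts.group_series("inner")
    fit = fit_mono(ts.times, series, sem,
                   fixed_p_inf=float(series[-12:].mean()))
    taus[name] = fit.tau
    print(f"{name}: tau = {fit.tau:.3f} ps")
print("quantum slowdown factor:",
      round(taus["quantum (VPT)"] / taus["classical"], 2))
```

Typical output:

```
band narrowing (mean, min): (0.92, 0.92)
classical: tau = 0.244 ps
quantum (VPT): tau = 0.297 ps
quantum slowdown factor: 1.22
```

The couplings are mildly narrowed (⟨B⟩ ≈ 0.9), yet the quantum treatment
slows the inter-ring transfer measurably; treating the same modes
classically *speeds it up* relative to omitting them, because their
classical fluctuations help bridge the donor-acceptor detuning.

A command-line interface mirrors the library
(`excitonmash generate|simulate|equilibrium|fit|pipeline`), e.g.

```bash
excitonmash generate --regime ring_funnel_LH2like_desk --seed 7 --out model.json
excitonmash pipeline --model model.json --outdir out/
```

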