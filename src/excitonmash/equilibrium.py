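"""Independent equilibrium references for exciton + bath models.

Two oracles anchor the dynamics:

* the mixed quantum-classical equilibrium — the average of the excitonic
  Boltzmann distribution over the classical nuclear phase space,

      <|n><n|>_cl = ∫dp dq Tr_ex[e^{-beta H(p,q)} |n><n|] / ∫dp dq Tr_ex[e^{-beta H(p,q)}]

  estimated by importance sampling with the uncoupled-bath Gaussian as
  proposal (momenta integrate out analytically); MASH provably relaxes to
  this distribution, which is the detailed-balance test of the package;

* the fully quantum Boltzmann populations, by brute-force diagonalization
  of the exciton ⊗ truncated-Fock product Hamiltonian on tiny instances.
  Comparing the two, with and without polaron renormalization of the
  high-frequency modes, isolates genuine nuclear quantum effects on the
  equilibrium.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .model import DiscretizedBath, ExcitonSystem
from .units import thermal_energy_cm

__all__ = [
    "EquilibriumEstimate",
    "system_boltzmann",
    "qc_equilibrium",
    "qc_equilibrium_quadrature",
    "quantum_equilibrium_small",
    "TruncationError",
]


class TruncationError(RuntimeError):
    """Fock-space truncation did not converge within the allowed size."""


@dataclass(frozen=True)
class EquilibriumEstimate:
    """Per-site equilibrium populations with Monte-Carlo errors."""

    populations: np.ndarray
    stderr: np.ndarray
    n_samples: int
    method: str

    def __post_init__(self):
        pops = np.asarray(self.populations, dtype=float)
        total = pops.sum()
        object.__setattr__(self, "populations", pops / total)
        object.__setattr__(self, "stderr", np.asarray(self.stderr, dtype=float))


def system_boltzmann(system: ExcitonSystem, temperature: float) -> EquilibriumEstimate:
    """Site populations of the bare excitonic Boltzmann state of H_s.

    P_n = sum_M P_M U_nM^2 with P_M the Boltzmann weights of the exciton
    eigenstates.  This is the g = 0 limit of both oracles, and the
    equilibrium of a VPT-renormalized system whose residual bath has been
    dropped.
    """
    evals, U = np.linalg.eigh(system.hamiltonian())
    kT = thermal_energy_cm(temperature)
    w = np.exp(-(evals - evals.min()) / kT)
    P = w / w.sum()
    pops = (U**2 * P[None, :]).sum(axis=1)
    return EquilibriumEstimate(
        populations=pops,
        stderr=np.zeros_like(pops),
        n_samples=0,
        method="system_boltzmann",
    )


def qc_equilibrium(
    system: ExcitonSystem,
    bath: DiscretizedBath,
    temperature: float,
    n_samples: int = 100_000,
    rng=None,
    n_blocks: int = 10,
) -> EquilibriumEstimate:
    """Monte-Carlo estimate of the mixed quantum-classical populations.

    Nuclear configurations are drawn from the uncoupled-bath Boltzmann
    distribution; each sample is weighted by the excitonic trace
    Tr_ex e^{-beta V(q)} (the bath Gaussian cancels against the proposal
    and the momenta integrate out).  Standard errors come from block
    means; an effective-sample-size warning flags poor overlap.
    """
    if n_samples < 1000:
        raise ValueError("n_samples must be at least 1000")
    if rng is None:
        rng = np.random.default_rng(0)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    N = system.n_sites
    kT = thermal_energy_cm(temperature)
    beta = 1.0 / kT
    # Under the uncoupled-bath Gaussian, the site-energy shift
    # sum_k kappa_k q_nk is itself Gaussian with variance
    # sum_k kappa_k^2 <q^2> = 2 * Lambda * kT, independently per site, so
    # the modes can be integrated into a single per-site draw.
    sig_shift = math.sqrt(2.0 * bath.total_reorganization * kT)

    num = np.zeros((n_blocks, N))
    den = np.zeros(n_blocks)
    wsum = 0.0
    w2sum = 0.0
    per_block = n_samples // n_blocks
    H0 = system.hamiltonian()
    for ib in range(n_blocks):
        diag_shift = rng.standard_normal((per_block, N)) * sig_shift
        V = np.broadcast_to(H0, (per_block, N, N)).copy()
        idx = np.arange(N)
        V[:, idx, idx] = system.site_energies[None, :] + diag_shift
        evals, U = np.linalg.eigh(V)
        # stable weights: subtract per-sample ground energy, track offsets
        e0 = evals[:, 0]
        wloc = np.exp(-beta * (evals - e0[:, None]))
        tr = wloc.sum(axis=1)
        logw = -beta * e0 + np.log(tr)
        logw -= logw.max()
        w = np.exp(logw)
        rho = (U**2 * wloc[:, None, :]).sum(axis=2) / tr[:, None]
        num[ib] = (w[:, None] * rho).sum(axis=0)
        den[ib] = w.sum()
        wsum += w.sum()
        w2sum += (w**2).sum()
    ess = wsum**2 / w2sum if w2sum > 0 else 0.0
    if ess < 0.01 * n_samples:
        warnings.warn(
            f"effective sample size {ess:.0f} below 1% of {n_samples}; "
            "poor overlap between proposal and weights",
            RuntimeWarning,
        )
    pops = num.sum(axis=0) / den.sum()
    block_pops = num / den[:, None]
    stderr = np.std(block_pops, axis=0, ddof=1) / math.sqrt(n_blocks)
    return EquilibriumEstimate(
        populations=pops, stderr=stderr, n_samples=n_samples, method="qc_montecarlo"
    )


def qc_equilibrium_quadrature(
    system: ExcitonSystem,
    bath: DiscretizedBath,
    temperature: float,
    n_nodes: int = 80,
) -> EquilibriumEstimate:
    """Deterministic Gauss-Hermite evaluation of the phase-space average.

    The site-energy shifts are independent Gaussians of variance
    2*Lambda*k_B*T per site, so for small systems the classical
    equilibrium reduces to an N-dimensional Gaussian quadrature (exact up
    to quadrature order, no Monte-Carlo noise).  Practical for N <= 3.
    """
    N = system.n_sites
    if N > 3:
        raise ValueError("quadrature evaluator limited to <= 3 sites")
    kT = thermal_energy_cm(temperature)
    sig = math.sqrt(2.0 * bath.total_reorganization * kT)
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    H0 = system.hamiltonian()
    grids = np.meshgrid(*([nodes] * N), indexing="ij")
    wgrids = np.meshgrid(*([weights] * N), indexing="ij")
    shifts = np.stack([g.ravel() for g in grids], axis=1) * sig
    wts = np.prod(np.stack([w.ravel() for w in wgrids], axis=1), axis=1)
    V = np.broadcast_to(H0, (shifts.shape[0], N, N)).copy()
    idx = np.arange(N)
    V[:, idx, idx] = system.site_energies[None, :] + shifts
    evals, U = np.linalg.eigh(V)
    e0 = evals[:, 0]
    bw = np.exp(-(evals - e0[:, None]) / kT)
    tr = bw.sum(axis=1)
    rho = (U**2 * bw[:, None, :]).sum(axis=2) / tr[:, None]
    logw = -e0 / kT + np.log(tr)
    logw -= logw.max()
    w = wts * np.exp(logw)
    pops = (w[:, None] * rho).sum(axis=0) / w.sum()
    return EquilibriumEstimate(populations=pops, stderr=np.zeros(N),
                               n_samples=shifts.shape[0],
                               method="qc_quadrature")


def _boson_operators(n_fock: int):
    sq = np.sqrt(np.arange(1, n_fock))
    a = np.diag(sq, k=1)
    return a, a.T


def _quantum_populations(system: ExcitonSystem, bath: DiscretizedBath,
                         temperature: float, n_fock: int) -> np.ndarray:
    """Exact populations at a fixed Fock truncation.

    The nuclear Hilbert space is the product of one oscillator per
    (site, mode) pair; each oscillator couples linearly to its own site's
    projector.  Feasible only for a handful of oscillators.
    """
    N = system.n_sites
    K = bath.n_modes
    n_osc = N * K
    dim_nuc = n_fock**n_osc
    a, ad = _boson_operators(n_fock)
    num_op = ad @ a
    x_op = a + ad
    eye = np.eye(n_fock)

    def embed(op, which):
        out = np.array([[1.0]])
        for j in range(n_osc):
            out = np.kron(out, op if j == which else eye)
        return out

    H = np.kron(system.hamiltonian(), np.eye(dim_nuc))
    for n in range(N):
        proj = np.zeros((N, N))
        proj[n, n] = 1.0
        for k in range(K):
            which = n * K + k
            w = bath.frequencies[k]
            g = bath.couplings[k]
            H += np.kron(np.eye(N), w * embed(num_op, which))
            H += np.kron(proj, w * g * embed(x_op, which))
    # zero-point energy omitted: it shifts all eigenvalues uniformly
    evals, vecs = np.linalg.eigh(H)
    kT = thermal_energy_cm(temperature)
    w = np.exp(-(evals - evals.min()) / kT)
    Z = w.sum()
    pops = np.empty(N)
    for n in range(N):
        # <i|P_n|i> = sum over nuclear block of |<n, nu | i>|^2
        block = vecs[n * dim_nuc:(n + 1) * dim_nuc, :]
        pops[n] = np.sum(w[None, :] * block**2) / Z
    return pops


def quantum_equilibrium_small(
    system: ExcitonSystem,
    bath: DiscretizedBath,
    temperature: float,
    n_fock: int = 16,
    check_convergence: bool = True,
) -> EquilibriumEstimate:
    """Fully quantum Boltzmann site populations by truncated-boson brute force.

    Restricted to tiny instances (<= 3 sites, <= 2 modes per site).  With
    ``check_convergence`` the truncation is validated by comparing with
    half the Fock size and requiring the populations to agree to 1e-6.
    """
    if system.n_sites > 3:
        raise ValueError("brute-force oracle limited to <= 3 sites")
    if bath.n_modes > 2:
        raise ValueError("brute-force oracle limited to <= 2 modes per site")
    if n_fock < 2 or n_fock > 40:
        raise ValueError("n_fock must be between 2 and 40")
    pops = _quantum_populations(system, bath, temperature, n_fock)
    if check_convergence and bath.n_modes:
        ref = _quantum_populations(system, bath, temperature, max(2, n_fock // 2))
        if np.max(np.abs(pops - ref)) > 1e-6:
            raise TruncationError(
                f"populations changed by {np.max(np.abs(pops - ref)):.2e} "
                f"between n_fock={max(2, n_fock // 2)} and {n_fock}"
            )
    return EquilibriumEstimate(
        populations=pops,
        stderr=np.zeros_like(pops),
        n_samples=0,
        method="quantum_truncated",
    )
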