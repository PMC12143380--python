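"""Variational polaron transformation (VPT) of high-frequency modes.

The VPT dresses each site excitation with displacements f_nk of the
high-frequency vibrations, chosen to minimize the Bogoliubov upper bound
F_0 on the free energy of the dressed system.  The transformed exciton
Hamiltonian has renormalized site energies and couplings

    eps'_n = eps_n - sum_k omega_k (2 f_nk g_k - f_nk^2)
    J'_nm  = J_nm * <B_nm>,
    <B_nm> = exp(-1/2 sum_k (f_nk^2 + f_mk^2) coth(beta omega_k / 2))

where <B_nm> is the thermal band-narrowing factor: the coth factor equals
2 n_k + 1 with n_k the Bose-Einstein occupation, so the narrowing encodes
quantum (zero-point plus thermal) vibrational statistics.  Stationarity
of F_0 with respect to f_nk gives the self-consistency condition

    f_nk = omega_k g_k / (omega_k - coth(beta omega_k/2) sum_{m != n} J'_nm Gamma_nm)

with Gamma_nm = sum_M P_M U_nM U_mM / sum_M P_M U_nM^2 built from the
Boltzmann-weighted eigenstates of the renormalized Hamiltonian.  The
fixed point interpolates between f = g (full polaron, J = 0 limit) and
f -> small (strong-coupling exciton limit).

After the transformation the high-frequency modes are dropped from the
dynamical bath entirely; the residual renormalized system-bath coupling
(g_k - f_nk on the diagonal) is reported but not propagated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import DiscretizedBath, ExcitonSystem
from .units import thermal_energy_cm

__all__ = [
    "VPTSolution",
    "VPTWorkspace",
    "band_narrowing",
    "renormalize",
    "gamma_matrix",
    "free_energy_system",
    "solve_vpt",
]


@dataclass(frozen=True)
class VPTWorkspace:
    """Eigen-decomposition of H'_s with Boltzmann weights and Gamma matrix."""

    eigvals: np.ndarray
    eigvecs: np.ndarray
    boltzmann: np.ndarray
    gamma: np.ndarray


@dataclass(frozen=True)
class VPTSolution:
    """Converged variational parameters and the renormalized exciton model."""

    f: np.ndarray
    mode_frequencies: np.ndarray
    mode_couplings: np.ndarray
    renorm_energies: np.ndarray
    renorm_couplings: np.ndarray
    narrowing: np.ndarray
    iterations: int
    converged: bool
    residual: float

    @property
    def residual_diagonal_couplings(self) -> np.ndarray:
        """Reduced diagonal couplings g_k - f_nk left in the transformed bath."""
        return self.mode_couplings[None, :] - self.f

    def renormalized_system(self, system: ExcitonSystem) -> ExcitonSystem:
        """The dressed exciton Hamiltonian as a new :class:`ExcitonSystem`."""
        return ExcitonSystem(
            site_energies=self.renorm_energies,
            couplings=self.renorm_couplings,
            site_labels=system.site_labels,
            groups=dict(system.groups),
        )

    def narrowing_statistics(self, couplings: np.ndarray, threshold: float = 1.0):
        """Mean and min of J'/J over distinct pairs with ``|J| > threshold`` cm^-1."""
        mask = np.triu(np.abs(couplings) > threshold, k=1)
        if not mask.any():
            return 1.0, 1.0
        vals = self.narrowing[mask]
        return float(vals.mean()), float(vals.min())

    def to_json_dict(self) -> dict:
        return {
            "f": self.f.tolist(),
            "mode_frequencies_cm1": self.mode_frequencies.tolist(),
            "mode_couplings": self.mode_couplings.tolist(),
            "renorm_energies_cm1": self.renorm_energies.tolist(),
            "renorm_couplings_cm1": self.renorm_couplings.tolist(),
            "narrowing": self.narrowing.tolist(),
            "iterations": self.iterations,
            "converged": self.converged,
            "residual_cm1": self.residual,
        }


def band_narrowing(f: np.ndarray, omegas: np.ndarray, temperature: float) -> np.ndarray:
    """Band-narrowing matrix <B_nm> for displacement matrix ``f`` (site x mode)."""
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    f = np.atleast_2d(np.asarray(f, dtype=float))
    omegas = np.asarray(omegas, dtype=float)
    beta = 1.0 / thermal_energy_cm(temperature)
    coth = 1.0 / np.tanh(0.5 * beta * omegas)
    s = (f**2 * coth[None, :]).sum(axis=1)  # per-site sum_k f_nk^2 coth
    return np.exp(-0.5 * (s[:, None] + s[None, :]))


def renormalize(system: ExcitonSystem, high_modes: DiscretizedBath, f: np.ndarray,
                temperature: float):
    """Renormalized site energies and couplings for displacements ``f``."""
    f = np.atleast_2d(np.asarray(f, dtype=float))
    w = high_modes.frequencies
    g = high_modes.couplings
    shift = (w[None, :] * (2.0 * f * g[None, :] - f**2)).sum(axis=1)
    eps_prime = system.site_energies - shift
    B = band_narrowing(f, w, temperature)
    J_prime = system.couplings * B
    np.fill_diagonal(J_prime, 0.0)
    return eps_prime, J_prime


def gamma_matrix(eps_prime: np.ndarray, J_prime: np.ndarray, temperature: float,
                 degeneracy_floor: float = 1e-300) -> VPTWorkspace:
    """Boltzmann-weighted eigenstructure of H'_s and the Gamma_nm matrix."""
    H = np.diag(np.asarray(eps_prime, dtype=float)) + np.asarray(J_prime, dtype=float)
    evals, U = np.linalg.eigh(H)
    beta = 1.0 / thermal_energy_cm(temperature)
    w = np.exp(-beta * (evals - evals.min()))
    P = w / w.sum()
    denom = (P[None, :] * U**2).sum(axis=1)  # sum_M P_M U_nM^2 per site n
    if np.any(denom < degeneracy_floor):
        raise FloatingPointError(
            "site weight sum_M P_M U_nM^2 underflowed; degenerate Gamma matrix"
        )
    numer = np.einsum("m,nm,km->nk", P, U, U)
    gamma = numer / denom[:, None]
    return VPTWorkspace(eigvals=evals, eigvecs=U, boltzmann=P, gamma=gamma)


def free_energy_system(eps_prime, J_prime, temperature: float) -> float:
    """System part of the Bogoliubov bound: F_0 = -kT ln sum_M exp(-beta eps_M).

    The bath free energy is independent of the displacements f, so this is
    the only piece that varies in the optimization.
    """
    H = np.diag(np.asarray(eps_prime, dtype=float)) + np.asarray(J_prime, dtype=float)
    evals = np.linalg.eigvalsh(H)
    kT = thermal_energy_cm(temperature)
    e0 = evals.min()
    return float(e0 - kT * np.log(np.sum(np.exp(-(evals - e0) / kT))))


def _stationarity_residual(system, high_modes, f, temperature, h=1e-6):
    """Max |dF0/df_nk| by central finite differences (cm^-1 per unit f)."""
    f = np.array(f, dtype=float)
    worst = 0.0
    for n in range(f.shape[0]):
        for k in range(f.shape[1]):
            for sgn, store in ((1, 0), (-1, 1)):
                fp = f.copy()
                fp[n, k] += sgn * h
                e, J = renormalize(system, high_modes, fp, temperature)
                if sgn == 1:
                    up = free_energy_system(e, J, temperature)
                else:
                    dn = free_energy_system(e, J, temperature)
            worst = max(worst, abs(up - dn) / (2 * h))
    return worst


def solve_vpt(
    system: ExcitonSystem,
    high_modes: DiscretizedBath,
    temperature: float,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> VPTSolution:
    """Self-consistent solution of the variational displacement equations.

    Fixed-point iteration started from the full-polaron guess f = g; each
    sweep recomputes J' and Gamma from the current f.  If the update
    oscillates (sign-alternating changes for three sweeps) a mixing factor
    of 0.5 is applied.  Non-convergence is flagged, not raised.
    """
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    n = system.n_sites
    K = high_modes.n_modes
    if K == 0:
        eps = system.site_energies.copy()
        J = system.couplings.copy()
        return VPTSolution(
            f=np.zeros((n, 0)),
            mode_frequencies=np.zeros(0),
            mode_couplings=np.zeros(0),
            renorm_energies=eps,
            renorm_couplings=J,
            narrowing=np.ones((n, n)),
            iterations=0,
            converged=True,
            residual=0.0,
        )
    w = high_modes.frequencies
    g = high_modes.couplings
    beta = 1.0 / thermal_energy_cm(temperature)
    coth = 1.0 / np.tanh(0.5 * beta * w)

    f = np.broadcast_to(g, (n, K)).astype(float).copy()
    mixing = 1.0
    osc_count = 0
    prev_delta = None
    converged = False
    iterations = 0
    for it in range(1, max_iter + 1):
        iterations = it
        eps_p, J_p = renormalize(system, high_modes, f, temperature)
        ws = gamma_matrix(eps_p, J_p, temperature)
        JG = J_p * ws.gamma  # J'_nm Gamma_nm; diagonal of J_p is zero
        coupling_term = JG.sum(axis=1)  # sum over m != n
        denom = w[None, :] - coth[None, :] * coupling_term[:, None]
        if np.any(np.abs(denom) < 1e-12 * w[None, :]):
            raise FloatingPointError(
                "vanishing denominator in the displacement update; "
                f"coupling term {coupling_term} vs mode frequencies {w}"
            )
        f_new = (w * g)[None, :] / denom
        delta = f_new - f
        if prev_delta is not None and np.all(delta * prev_delta <= 0) and np.any(delta != 0):
            osc_count += 1
            if osc_count >= 3:
                mixing = 0.5
        else:
            osc_count = 0
        prev_delta = delta
        f = f + mixing * delta
        scale = np.maximum(np.abs(f), 1e-30)
        if np.max(np.abs(delta) / scale) < tol:
            converged = True
            break

    eps_p, J_p = renormalize(system, high_modes, f, temperature)
    B = band_narrowing(f, w, temperature)
    residual = _stationarity_residual(system, high_modes, f, temperature)
    return VPTSolution(
        f=f,
        mode_frequencies=w.copy(),
        mode_couplings=g.copy(),
        renorm_energies=eps_p,
        renorm_couplings=J_p,
        narrowing=B,
        iterations=iterations,
        converged=converged,
        residual=residual,
    )
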