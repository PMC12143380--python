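"""Multi-state MASH trajectory dynamics for exciton + classical-bath models.

The mapping approach to surface hopping (MASH) propagates classical
nuclei on the adiabatic surface of the *most populated* local eigenstate
of the excitonic potential matrix V(q), alongside a complex coefficient
vector c for the excitonic wavefunction.  Whenever a different adiabatic
state becomes the most populated, the momentum is rescaled along a
nonadiabatic-coupling direction so that the total energy is exactly
conserved; if the kinetic energy along that direction is insufficient,
the momentum component is reversed instead (a frustrated hop).  The
dynamics is deterministic: all randomness lives in the initial conditions
(thermal nuclei, random excitonic phases).

Populations are measured with the estimator

    Phi_n = 1/N + alpha_N (|c_n|^2 - 1/N),   alpha_N = (N-1)/(H_N-1)

which is the unique linear function of |c_n|^2 consistent with the mixed
quantum-classical equilibrium distribution.  The "focused" initial
condition places Phi exactly at a unit vector on the initial site.

Two propagation paths are provided: a compiled (numba) ensemble kernel
used for production runs, and a plain-numpy single-trajectory reference
(`potential_matrix`, `step`, `hop_rescale`) that spells out the algorithm
and is cross-checked against the kernel in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .model import DiscretizedBath, ExcitonSystem
from .units import CM_TO_RADFS, thermal_energy_cm

__all__ = [
    "MASHConfig",
    "TrajectoryState",
    "PopulationTimeSeries",
    "harmonic_number",
    "alpha_coefficient",
    "population_estimator",
    "focused_init",
    "sample_nuclei",
    "potential_matrix",
    "step",
    "hop_rescale",
    "run_ensemble",
    "run_no_backaction",
    "default_timestep",
]


# ---------------------------------------------------------------------------
# configuration and containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MASHConfig:
    """Ensemble configuration.

    ``dt`` (fs) defaults to a fortieth of the fastest period in the
    problem (bath modes and excitonic bandwidth), capped at 0.5 fs.
    ``nuclear_sampling`` is ``classical_boltzmann`` (vertical excitation
    from the classical ground-state equilibrium) or ``wigner``.

    ``initial_site`` is a site index for transfer kinetics, or
    ``"thermal"`` for equilibrium studies: each trajectory is focused on
    a site drawn from the site-energy Boltzmann distribution, a warm
    start that removes the slow one-sided relaxation transient carried by
    quasi-static solvent modes (their periods exceed any affordable
    t_max) while leaving the dynamical fixed point untouched.
    """

    t_max: float
    n_traj: int
    seed: int
    temperature: float = 300.0
    initial_site: int | str = 0
    dt: float | None = None
    n_batches: int = 5
    out_dt: float = 4.0
    nuclear_sampling: str = "classical_boltzmann"
    backaction: str = "mash"

    def __post_init__(self):
        if self.dt is not None and not self.dt > 0:
            raise ValueError("dt must be positive")
        if isinstance(self.initial_site, str) and self.initial_site != "thermal":
            raise ValueError(f"unknown initial_site {self.initial_site!r}")
        if self.n_traj % self.n_batches != 0:
            raise ValueError("n_traj must be divisible by n_batches")
        if self.nuclear_sampling not in ("classical_boltzmann", "wigner"):
            raise ValueError(f"unknown nuclear_sampling {self.nuclear_sampling!r}")
        if self.backaction not in ("mash", "none"):
            raise ValueError(f"unknown backaction mode {self.backaction!r}")


@dataclass
class TrajectoryState:
    """Phase-space state of one trajectory (internal rad/fs units)."""

    q: np.ndarray  # (N, K) mass-scaled positions
    p: np.ndarray  # (N, K) momenta
    c: np.ndarray  # (N,) complex excitonic coefficients
    active: int
    eigvals: np.ndarray  # adiabatic energies at q
    eigvecs: np.ndarray  # columns |a(q)>

    def total_energy(self, omega2: np.ndarray) -> float:
        """Kinetic + state-independent bath potential + active adiabatic energy."""
        ke = 0.5 * float(np.sum(self.p**2))
        pe = 0.5 * float(np.sum(omega2[None, :] * self.q**2))
        return ke + pe + float(self.eigvals[self.active])

    def populations(self) -> np.ndarray:
        amps = self.eigvecs.T @ self.c
        return np.abs(amps) ** 2


@dataclass(frozen=True)
class PopulationTimeSeries:
    """Ensemble-averaged populations with per-batch means.

    ``phi`` is (n_sites, n_times); ``batch_phi`` is
    (n_batches, n_sites, n_times) and is the basis for all standard
    errors, including those of derived group populations.
    """

    times: np.ndarray
    phi: np.ndarray
    batch_phi: np.ndarray
    groups: dict = field(default_factory=dict)
    estimator: str = "phi"
    n_traj: int = 0
    n_discarded: int = 0

    @property
    def n_sites(self) -> int:
        return self.phi.shape[0]

    @property
    def sem(self) -> np.ndarray:
        nb = self.batch_phi.shape[0]
        return np.std(self.batch_phi, axis=0, ddof=1) / math.sqrt(nb)

    def group_series(self, group):
        """Summed population of a site group with its batch-derived SEM."""
        idx = self._resolve(group)
        series = self.phi[idx].sum(axis=0)
        batch = self.batch_phi[:, idx, :].sum(axis=1)
        nb = batch.shape[0]
        sem = np.std(batch, axis=0, ddof=1) / math.sqrt(nb)
        return series, sem

    def _resolve(self, group):
        if isinstance(group, str):
            if group not in self.groups:
                raise KeyError(f"unknown site group {group!r}")
            return np.asarray(self.groups[group], dtype=int)
        return np.asarray(list(group), dtype=int)

    def to_frame(self):
        import pandas as pd

        data = {"time_fs": self.times}
        sem = self.sem
        for n in range(self.n_sites):
            data[f"phi_{n}"] = self.phi[n]
            data[f"sem_{n}"] = sem[n]
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# estimator and initial conditions
# ---------------------------------------------------------------------------

def harmonic_number(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n + 1)))


def alpha_coefficient(n: int) -> float:
    """alpha_N = (N - 1)/(H_N - 1), the estimator scale factor."""
    if n < 2:
        raise ValueError("estimator requires at least two states")
    return (n - 1.0) / (harmonic_number(n) - 1.0)


def population_estimator(c: np.ndarray) -> np.ndarray:
    """Phi_n from the coefficient vector; requires ||c|| = 1."""
    c = np.asarray(c)
    pops = np.abs(c) ** 2
    norm = pops.sum()
    if abs(norm - 1.0) > 1e-8:
        raise ValueError(f"coefficient vector is not normalized (|c|^2 = {norm})")
    n = c.size
    alpha = alpha_coefficient(n)
    return 1.0 / n + alpha * (pops - 1.0 / n)


def focused_init(initial_site: int, n_sites: int, rng) -> np.ndarray:
    """Focused initial coefficients: Phi = 1 on the initial site, 0 elsewhere."""
    if n_sites < 2:
        raise ValueError("need at least two sites")
    if not 0 <= initial_site < n_sites:
        raise ValueError("initial_site out of range")
    alpha = alpha_coefficient(n_sites)
    r2 = np.full(n_sites, (alpha - 1.0) / (n_sites * alpha))
    r2[initial_site] = (n_sites + alpha - 1.0) / (n_sites * alpha)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_sites)
    return np.sqrt(r2) * np.exp(1j * phases)


def sample_nuclei(bath: DiscretizedBath, temperature: float, mode: str, rng,
                  n_sites: int = 1):
    """Thermal initial conditions for the bath (internal rad/fs units).

    ``classical_boltzmann``: q ~ N(0, kT/Omega^2), p ~ N(0, kT) — a
    vertical excitation from the classical ground-state equilibrium.
    ``wigner``: widths carry zero-point energy through coth(beta Omega/2).
    """
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    omega = CM_TO_RADFS * bath.frequencies
    kT = CM_TO_RADFS * thermal_energy_cm(temperature)
    if mode == "classical_boltzmann":
        var_q = kT / omega**2
        var_p = np.full_like(omega, kT)
    elif mode == "wigner":
        coth = 1.0 / np.tanh(0.5 * omega / kT)
        var_q = 0.5 * coth / omega
        var_p = 0.5 * coth * omega
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    shape = (n_sites, omega.size)
    q = rng.standard_normal(shape) * np.sqrt(var_q)[None, :]
    p = rng.standard_normal(shape) * np.sqrt(var_p)[None, :]
    return p, q


def default_timestep(system: ExcitonSystem, bath: DiscretizedBath) -> float:
    """Timestep resolving every dynamically relevant frequency.

    A fortieth of the period of the fastest *coupled* motion — the larger
    of the excitonic bandwidth and the frequency below which 99% of the
    bath reorganization energy lies — capped at 0.5 fs.  Discretized
    solvent tails can contain much faster, essentially decoupled modes;
    these only need the velocity-Verlet stability bound, enforced as
    Omega_max * dt <= 1.2.
    """
    evals = np.linalg.eigvalsh(system.hamiltonian())
    fastest_cm = max(float(evals[-1] - evals[0]), 1.0)
    stiffest_cm = fastest_cm
    if bath.n_modes:
        stiffest_cm = max(stiffest_cm, float(bath.frequencies.max()))
        lam = bath.reorganizations
        if lam.sum() > 0:
            order = np.argsort(bath.frequencies)
            cum = np.cumsum(lam[order]) / lam.sum()
            w99 = float(bath.frequencies[order][np.searchsorted(cum, 0.99)])
            fastest_cm = max(fastest_cm, w99)
    period_fs = 2.0 * np.pi / (CM_TO_RADFS * fastest_cm)
    dt = min(0.5, period_fs / 40.0)
    return min(dt, 1.2 / (CM_TO_RADFS * stiffest_cm))


# ---------------------------------------------------------------------------
# reference (single-trajectory, numpy) implementation
# ---------------------------------------------------------------------------

def potential_matrix(q: np.ndarray, system: ExcitonSystem, bath: DiscretizedBath,
                     internal_units: bool = True) -> np.ndarray:
    """Excitonic potential matrix V(q) at nuclear configuration ``q`` (N, K).

    V_nn = eps_n + sum_k kappa_k q_nk, V_nm = J_nm.  The state-independent
    bath potential sum 1/2 Omega_k^2 q_nk^2 is tracked separately in the
    energy bookkeeping.  With ``internal_units`` the result is in rad/fs
    (the units of the propagators); otherwise cm^-1.
    """
    q = np.asarray(q, dtype=float)
    scale = CM_TO_RADFS if internal_units else 1.0
    kappa = bath.coupling_coefficients if internal_units else (
        bath.coupling_coefficients / CM_TO_RADFS
    )
    V = scale * system.couplings.astype(float).copy()
    np.fill_diagonal(V, scale * system.site_energies + q @ kappa)
    return V


def init_state(system: ExcitonSystem, bath: DiscretizedBath, config: MASHConfig,
               rng) -> TrajectoryState:
    """Draw one trajectory's initial conditions."""
    p, q = sample_nuclei(bath, config.temperature, config.nuclear_sampling, rng,
                         n_sites=system.n_sites)
    c = focused_init(config.initial_site, system.n_sites, rng)
    V = potential_matrix(q, system, bath)
    evals, U = np.linalg.eigh(V)
    active = int(np.argmax(np.abs(U.T @ c) ** 2))
    return TrajectoryState(q=q, p=p, c=c, active=active, eigvals=evals, eigvecs=U)


def hop_rescale(state: TrajectoryState, old_active: int, new_active: int,
                bath: DiscretizedBath) -> TrajectoryState:
    """Energy-conserving momentum adjustment at an attempted hop.

    The momentum component along the normalized direction
    d_nk ∝ kappa_k <a_old|n><n|a_new> (the nonadiabatic-coupling direction
    for linear on-site coupling) is rescaled so the total energy is exactly
    conserved across the potential jump; with insufficient kinetic energy
    the component is reversed and the hop rejected.
    """
    if new_active == old_active:
        raise ValueError("hop requires distinct states")
    U = state.eigvecs
    kappa = bath.coupling_coefficients
    d = kappa[None, :] * (U[:, old_active] * U[:, new_active])[:, None]
    dnorm = float(np.linalg.norm(d))
    dV = float(state.eigvals[new_active] - state.eigvals[old_active])
    p = state.p
    if dnorm < 1e-15:
        # Degenerate direction: fall back to uniform rescaling of p.
        ke = 0.5 * float(np.sum(p**2))
        if ke - dV >= 0 and ke > 0:
            return replace(state, p=p * math.sqrt((ke - dV) / ke), active=new_active)
        return replace(state, p=-p)
    d = d / dnorm
    pd = float(np.sum(p * d))
    disc = pd * pd - 2.0 * dV
    if disc >= 0.0:
        s = math.sqrt(disc)
        eta = -pd + s if pd >= 0 else -pd - s
        return replace(state, p=p + eta * d, active=new_active)
    return replace(state, p=p - 2.0 * pd * d)  # frustrated: reflect


def step(state: TrajectoryState, dt: float, system: ExcitonSystem,
         bath: DiscretizedBath) -> TrajectoryState:
    """One velocity-Verlet + unitary-coefficient step (reference path).

    The nuclei feel the Hellmann-Feynman force of the active adiabatic
    state plus the harmonic bath force; the coefficients are advanced by
    the split unitary exp(-i V(q') dt/2) exp(-i V(q) dt/2) built from the
    adiabatic decompositions at the step endpoints (exact for frozen
    nuclei, second-order and exactly norm-preserving in general).  Hop
    detection runs once per step, after the coefficient update.
    """
    omega = CM_TO_RADFS * bath.frequencies
    omega2 = omega**2
    kappa = bath.coupling_coefficients
    a = state.active
    U, E = state.eigvecs, state.eigvals

    force = -omega2[None, :] * state.q - kappa[None, :] * (U[:, a] ** 2)[:, None]
    p_half = state.p + 0.5 * dt * force
    q_new = state.q + dt * p_half
    V_new = potential_matrix(q_new, system, bath)
    E2, U2 = np.linalg.eigh(V_new)
    force_new = -omega2[None, :] * q_new - kappa[None, :] * (U2[:, a] ** 2)[:, None]
    p_new = p_half + 0.5 * dt * force_new

    t1 = U.T @ state.c
    t1 = t1 * np.exp(-0.5j * E * dt)
    c_mid = U @ t1
    t2 = U2.T @ c_mid
    t2 = t2 * np.exp(-0.5j * E2 * dt)
    c_new = U2 @ t2

    new_state = TrajectoryState(q=q_new, p=p_new, c=c_new, active=a,
                                eigvals=E2, eigvecs=U2)
    pops = np.abs(t2) ** 2
    candidate = int(np.argmax(pops))
    if candidate != a and pops[candidate] > pops[a]:
        new_state = hop_rescale(new_state, a, candidate, bath)
    return new_state


# ---------------------------------------------------------------------------
# compiled ensemble kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _eigh_small(V):
    n = V.shape[0]
    if n == 2:
        a = V[0, 0]
        b = V[1, 1]
        cc = V[0, 1]
        E = np.empty(2)
        U = np.empty((2, 2))
        if cc == 0.0:
            if a <= b:
                E[0], E[1] = a, b
                U[0, 0], U[1, 0], U[0, 1], U[1, 1] = 1.0, 0.0, 0.0, 1.0
            else:
                E[0], E[1] = b, a
                U[0, 0], U[1, 0], U[0, 1], U[1, 1] = 0.0, 1.0, 1.0, 0.0
            return E, U
        m = 0.5 * (a + b)
        r = math.hypot(0.5 * (a - b), cc)
        E[0] = m - r
        E[1] = m + r
        v0 = cc
        v1 = E[1] - a
        nrm = math.hypot(v0, v1)
        v0 /= nrm
        v1 /= nrm
        U[0, 1] = v0
        U[1, 1] = v1
        U[0, 0] = -v1
        U[1, 0] = v0
        return E, U
    return np.linalg.eigh(V)


@njit(cache=True)
def _propagate_chunk(eps, J, omega2, kappa, q, p, c, dt, n_steps, out_stride,
                     backaction, pop_sum, stats):
    """Propagate a chunk of trajectories, accumulating site populations.

    ``pop_sum[t, n]`` accumulates |c_n|^2 at output time t over the clean
    trajectories of the chunk.  ``stats`` receives [n_ok, n_discarded,
    n_hops, n_frustrated, n_fallback, max_energy_drift].
    """
    B, N, K = q.shape
    n_out = pop_sum.shape[0]
    max_drift = 0.0
    n_hops = 0
    n_frust = 0
    n_fallback = 0
    n_ok = 0
    n_bad = 0
    for b in range(B):
        qb = q[b].copy()
        pb = p[b].copy()
        cb = c[b].copy()
        popbuf = np.zeros((n_out, N))
        V = np.empty((N, N))
        for n in range(N):
            for m in range(N):
                V[n, m] = J[n, m]
            acc = eps[n]
            for k in range(K):
                acc += kappa[k] * qb[n, k]
            V[n, n] = acc
        E, U = _eigh_small(V)
        # initial active state from adiabatic populations
        best = 0
        bestp = -1.0
        for a in range(N):
            re = 0.0
            im = 0.0
            for n in range(N):
                re += U[n, a] * cb[n].real
                im += U[n, a] * cb[n].imag
            pa = re * re + im * im
            if pa > bestp:
                bestp = pa
                best = a
        a = best
        e0 = 0.0
        for n in range(N):
            for k in range(K):
                e0 += 0.5 * pb[n, k] * pb[n, k] + 0.5 * omega2[k] * qb[n, k] * qb[n, k]
        e0 += E[a]
        for n in range(N):
            popbuf[0, n] = cb[n].real ** 2 + cb[n].imag ** 2
        out_idx = 1
        bad = False
        traj_drift = 0.0
        t1 = np.empty(N, dtype=np.complex128)
        cmid = np.empty(N, dtype=np.complex128)
        t2 = np.empty(N, dtype=np.complex128)
        for istep in range(n_steps):
            # half kick + drift
            for n in range(N):
                ua2 = U[n, a] * U[n, a]
                for k in range(K):
                    f = -omega2[k] * qb[n, k]
                    if backaction:
                        f -= kappa[k] * ua2
                    pb[n, k] += 0.5 * dt * f
                    qb[n, k] += dt * pb[n, k]
            # new potential and adiabatic basis
            for n in range(N):
                acc = eps[n]
                for k in range(K):
                    acc += kappa[k] * qb[n, k]
                V[n, n] = acc
            E2, U2 = _eigh_small(V)
            for n in range(N):
                ua2 = U2[n, a] * U2[n, a]
                for k in range(K):
                    f = -omega2[k] * qb[n, k]
                    if backaction:
                        f -= kappa[k] * ua2
                    pb[n, k] += 0.5 * dt * f
            # unitary coefficient update: U2 D2 U2^T U D1 U^T c
            for ai in range(N):
                amp = 0.0 + 0.0j
                for n in range(N):
                    amp += U[n, ai] * cb[n]
                ph = -0.5 * E[ai] * dt
                t1[ai] = amp * complex(math.cos(ph), math.sin(ph))
            for n in range(N):
                amp = 0.0 + 0.0j
                for ai in range(N):
                    amp += U[n, ai] * t1[ai]
                cmid[n] = amp
            for ai in range(N):
                amp = 0.0 + 0.0j
                for n in range(N):
                    amp += U2[n, ai] * cmid[n]
                ph = -0.5 * E2[ai] * dt
                t2[ai] = amp * complex(math.cos(ph), math.sin(ph))
            for n in range(N):
                amp = 0.0 + 0.0j
                for ai in range(N):
                    amp += U2[n, ai] * t2[ai]
                cb[n] = amp
            # hop detection (adiabatic populations from t2)
            if backaction:
                best = 0
                bestp = -1.0
                for ai in range(N):
                    pa = t2[ai].real ** 2 + t2[ai].imag ** 2
                    if pa > bestp:
                        bestp = pa
                        best = ai
                pa_cur = t2[a].real ** 2 + t2[a].imag ** 2
                if best != a and bestp > pa_cur:
                    dV = E2[best] - E2[a]
                    dnorm2 = 0.0
                    for n in range(N):
                        dn = U2[n, a] * U2[n, best]
                        for k in range(K):
                            dv = kappa[k] * dn
                            dnorm2 += dv * dv
                    if dnorm2 < 1e-30:
                        ke = 0.0
                        for n in range(N):
                            for k in range(K):
                                ke += 0.5 * pb[n, k] * pb[n, k]
                        n_fallback += 1
                        if ke - dV >= 0.0 and ke > 0.0:
                            scale = math.sqrt((ke - dV) / ke)
                            for n in range(N):
                                for k in range(K):
                                    pb[n, k] *= scale
                            a = best
                            n_hops += 1
                        else:
                            for n in range(N):
                                for k in range(K):
                                    pb[n, k] = -pb[n, k]
                            n_frust += 1
                    else:
                        dnorm = math.sqrt(dnorm2)
                        pd = 0.0
                        for n in range(N):
                            dn = U2[n, a] * U2[n, best]
                            for k in range(K):
                                pd += pb[n, k] * (kappa[k] * dn / dnorm)
                        disc = pd * pd - 2.0 * dV
                        if disc >= 0.0:
                            s = math.sqrt(disc)
                            eta = -pd + s if pd >= 0.0 else -pd - s
                            for n in range(N):
                                dn = U2[n, a] * U2[n, best]
                                for k in range(K):
                                    pb[n, k] += eta * kappa[k] * dn / dnorm
                            a = best
                            n_hops += 1
                        else:
                            for n in range(N):
                                dn = U2[n, a] * U2[n, best]
                                for k in range(K):
                                    pb[n, k] -= 2.0 * pd * kappa[k] * dn / dnorm
                            n_frust += 1
            E = E2
            U = U2
            # record
            if (istep + 1) % out_stride == 0:
                norm = 0.0
                for n in range(N):
                    w = cb[n].real ** 2 + cb[n].imag ** 2
                    popbuf[out_idx, n] = w
                    norm += w
                if not np.isfinite(norm):
                    bad = True
                    break
                if backaction:
                    etot = 0.0
                    for n in range(N):
                        for k in range(K):
                            etot += (0.5 * pb[n, k] * pb[n, k]
                                     + 0.5 * omega2[k] * qb[n, k] * qb[n, k])
                    etot += E[a]
                    drift = abs(etot - e0)
                    if drift > traj_drift:
                        traj_drift = drift
                out_idx += 1
        if bad:
            n_bad += 1
        else:
            n_ok += 1
            for t in range(n_out):
                for n in range(N):
                    pop_sum[t, n] += popbuf[t, n]
            if traj_drift > max_drift:
                max_drift = traj_drift
    stats[0] += n_ok
    stats[1] += n_bad
    stats[2] += n_hops
    stats[3] += n_frust
    stats[4] += n_fallback
    if max_drift > stats[5]:
        stats[5] = max_drift


# ---------------------------------------------------------------------------
# ensemble drivers
# ---------------------------------------------------------------------------

def _trajectory_rng(seed: int, index: int):
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def _draw_batch(system, bath, config, start, count):
    N = system.n_sites
    K = bath.n_modes
    q = np.empty((count, N, K))
    p = np.empty((count, N, K))
    c = np.empty((count, N), dtype=np.complex128)
    thermal = config.initial_site == "thermal"
    if thermal:
        kT = thermal_energy_cm(config.temperature)
        w = np.exp(-(system.site_energies - system.site_energies.min()) / kT)
        site_weights = w / w.sum()
        # polaron displacement of the occupied site's modes: centers the
        # bath on the coupled equilibrium rather than the vertical one
        omega = CM_TO_RADFS * bath.frequencies
        shift = bath.coupling_coefficients / omega**2 if bath.n_modes else omega
    for j in range(count):
        rng = _trajectory_rng(config.seed, start + j)
        pj, qj = sample_nuclei(bath, config.temperature, config.nuclear_sampling,
                               rng, n_sites=N)
        if thermal:
            site = int(rng.choice(N, p=site_weights))
            qj[site] -= shift
        else:
            site = config.initial_site
        p[j] = pj
        q[j] = qj
        c[j] = focused_init(site, N, rng)
    return q, p, c


def run_ensemble(system: ExcitonSystem, bath: DiscretizedBath, config: MASHConfig,
                 vpt=None, return_stats: bool = False):
    """Propagate a MASH ensemble and return a :class:`PopulationTimeSeries`.

    If a VPT solution is supplied, the dynamics runs on the renormalized
    exciton Hamiltonian (the caller passes the low-frequency bath).  Each
    trajectory's random stream is derived from ``(config.seed, index)``,
    so results are independent of batch layout and execution order.
    """
    if not isinstance(config.initial_site, str) and not (
            0 <= config.initial_site < system.n_sites):
        raise ValueError("initial_site out of range")
    dyn_system = vpt.renormalized_system(system) if vpt is not None else system
    N = dyn_system.n_sites
    eps = CM_TO_RADFS * dyn_system.site_energies
    J = CM_TO_RADFS * dyn_system.couplings
    omega = CM_TO_RADFS * bath.frequencies
    omega2 = omega**2
    kappa = bath.coupling_coefficients
    dt = config.dt if config.dt is not None else default_timestep(dyn_system, bath)
    n_steps = max(1, int(round(config.t_max / dt)))
    out_stride = max(1, int(round(config.out_dt / dt)))
    n_out = n_steps // out_stride + 1
    times = np.arange(n_out) * (out_stride * dt)
    backaction = config.backaction == "mash"

    per_batch = config.n_traj // config.n_batches
    batch_pop = np.zeros((config.n_batches, n_out, N))
    stats = np.zeros(6)
    for ib in range(config.n_batches):
        q, p, c = _draw_batch(dyn_system, bath, config, ib * per_batch, per_batch)
        pop_sum = np.zeros((n_out, N))
        bstats = np.zeros(6)
        _propagate_chunk(eps, J, omega2, kappa, q, p, c, dt, n_steps, out_stride,
                         backaction, pop_sum, bstats)
        n_ok = int(bstats[0])
        if n_ok == 0:
            raise FloatingPointError("all trajectories in a batch diverged")
        batch_pop[ib] = pop_sum / n_ok
        stats[:5] += bstats[:5]
        stats[5] = max(stats[5], bstats[5])
    n_discarded = int(stats[1])
    if n_discarded > 1e-3 * config.n_traj:
        import warnings

        warnings.warn(
            f"{n_discarded} of {config.n_traj} trajectories discarded (NaN)",
            RuntimeWarning,
        )

    if backaction:
        alpha = alpha_coefficient(N)
        batch_phi = 1.0 / N + alpha * (batch_pop - 1.0 / N)
        estimator = "phi"
    else:
        batch_phi = batch_pop
        estimator = "coefficient"
    batch_phi = np.transpose(batch_phi, (0, 2, 1))  # (batch, site, time)
    phi = batch_phi.mean(axis=0)
    ts = PopulationTimeSeries(
        times=times,
        phi=phi,
        batch_phi=batch_phi,
        groups=dict(dyn_system.groups),
        estimator=estimator,
        n_traj=config.n_traj - n_discarded,
        n_discarded=n_discarded,
    )
    if return_stats:
        return ts, {
            "n_hops": int(stats[2]),
            "n_frustrated": int(stats[3]),
            "n_fallback_rescalings": int(stats[4]),
            "max_energy_drift_radfs": float(stats[5]),
        }
    return ts


def run_no_backaction(system: ExcitonSystem, bath: DiscretizedBath,
                      config: MASHConfig):
    """Baseline without back-action: free harmonic nuclei drive c(t).

    The force on the nuclei is independent of the excitonic state, so the
    exciton subsystem absorbs energy indefinitely and all site
    populations approach 1/N.  Populations are reported as plain |c_n|^2
    (the Phi estimator's equilibrium rationale presumes MASH dynamics).
    """
    return run_ensemble(system, bath, replace(config, backaction="none"))
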