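"""Synthetic exciton + bath model generators.

These generators produce models with the *statistical structure* of three
well-studied light-harvesting architectures — a two-ring funnel (LH2-like),
a small weakly-coupled network (FMO-like), and a two-group funnel
(LHCII-like) — without claiming to reproduce any literature Hamiltonian;
generated files are labelled synthetic in their metadata.  Their purpose
is to make every stage of the pipeline exercisable and testable offline.

Each regime pairs a topology with an identical independent per-site bath:
a smooth Debye solvent dominated by sub-thermal frequencies plus tens of
discrete intramolecular modes.  The defining dial of a regime is the
fraction of reorganization energy in the "quantum window"
[k_B T, omega_max] relative to [0, omega_max] (omega_max = maximum
excitonic gap): large for the LH2-like regime (0.54), small for the
FMO-like regime (0.11), intermediate for the LHCII-like regime (0.44).
Huang-Rhys factors of in-window modes are rescaled exactly to the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    ContinuousComponent,
    DiscreteMode,
    ExcitonSystem,
    SpectralDensity,
    max_exciton_gap,
    reorg_fraction,
)
from .units import thermal_energy_cm

__all__ = ["RegimeSpec", "REGIMES", "make_dimer", "make_bath", "make_ring_funnel",
           "make_network_funnel", "make_model"]


@dataclass(frozen=True)
class RegimeSpec:
    """Parameters of a synthetic regime (all energies in cm^-1)."""

    regime: str
    n_inner: int = 16
    n_outer: int = 8
    energy_offset: float = 400.0
    nn_coupling: float = 300.0
    outer_coupling: float = 30.0
    inter_coupling: float = 50.0
    energy_spread: float = 0.0
    solvent_lambda: float = 100.0
    solvent_omega_c: float = 50.0
    target_high_fraction: float = 0.54
    n_low_modes: int = 4
    n_high_modes: int = 16
    n_nonresonant_modes: int = 2
    low_mode_lambda: float = 30.0
    nonresonant_mode_lambda: float = 24.0
    nominal_omega_max: float = 1450.0
    temperature: float = 300.0
    seed: int = 0


#: Default parameter sets for the shipped regimes.  The ``dimer`` entry is
#: the canonical oracle fixture; the ``*_desk`` entry is a scaled-down
#: two-ring funnel with the same bath statistics, sized for trajectory
#: ensembles on a single CPU.
REGIMES = {
    "dimer": RegimeSpec(
        regime="dimer", n_inner=1, n_outer=1, nn_coupling=0.0,
        inter_coupling=100.0, energy_offset=100.0, solvent_lambda=100.0,
        solvent_omega_c=53.0, target_high_fraction=0.0, n_low_modes=1,
        n_high_modes=0, n_nonresonant_modes=0, low_mode_lambda=90.0,
        nominal_omega_max=300.0,
    ),
    "ring_funnel_LH2like": RegimeSpec(
        regime="ring_funnel_LH2like", n_inner=16, n_outer=8,
        energy_offset=1100.0, nn_coupling=300.0, outer_coupling=30.0,
        inter_coupling=60.0, solvent_lambda=100.0, solvent_omega_c=50.0,
        target_high_fraction=0.54, n_high_modes=16, nominal_omega_max=1700.0,
    ),
    "ring_funnel_LH2like_desk": RegimeSpec(
        regime="ring_funnel_LH2like_desk", n_inner=6, n_outer=3,
        energy_offset=1000.0, nn_coupling=250.0, outer_coupling=30.0,
        inter_coupling=60.0, solvent_lambda=100.0, solvent_omega_c=50.0,
        target_high_fraction=0.54, n_high_modes=16, nominal_omega_max=1500.0,
    ),
    "eightsite_FMOlike": RegimeSpec(
        regime="eightsite_FMOlike", n_inner=8, n_outer=0, energy_offset=450.0,
        nn_coupling=-80.0, inter_coupling=15.0, energy_spread=60.0,
        solvent_lambda=35.0, solvent_omega_c=50.0, target_high_fraction=0.11,
        n_low_modes=5, n_high_modes=10, low_mode_lambda=15.0,
        nonresonant_mode_lambda=40.0, nominal_omega_max=520.0,
    ),
    "funnel_LHCIIlike": RegimeSpec(
        regime="funnel_LHCIIlike", n_inner=8, n_outer=6, energy_offset=350.0,
        nn_coupling=80.0, outer_coupling=50.0, inter_coupling=40.0,
        energy_spread=50.0, solvent_lambda=100.0, solvent_omega_c=50.0,
        target_high_fraction=0.44, n_low_modes=4, n_high_modes=12,
        nonresonant_mode_lambda=30.0, nominal_omega_max=700.0,
    ),
}


def make_dimer(delta_eps: float, J: float, sd: SpectralDensity | None = None,
               labels=("donor", "acceptor")):
    """Two-site model: canonical fixture for every oracle test.

    Site 0 sits ``delta_eps`` above site 1.  The default bath is a Debye
    solvent (lambda = 100 cm^-1, omega_c = 53 cm^-1) plus one low-
    frequency mode at 180 cm^-1 with g^2 = 0.5.
    """
    system = ExcitonSystem(
        site_energies=np.array([delta_eps, 0.0], dtype=float),
        couplings=np.array([[0.0, J], [J, 0.0]], dtype=float),
        site_labels=tuple(labels),
        groups={"donor": (0,), "acceptor": (1,)},
    )
    if sd is None:
        sd = SpectralDensity(
            discrete=(DiscreteMode(180.0, 0.5),),
            continuous=(ContinuousComponent("debye", lam=100.0, omega_c=53.0),),
        )
    return system, sd


def make_bath(spec: RegimeSpec, rng, omega_max: float | None = None) -> SpectralDensity:
    """Per-site spectral density for a regime, tuned to its window fraction.

    A Debye solvent plus three bands of discrete modes: sub-thermal modes,
    in-window modes between k_B T and omega_max, and a couple of
    nonresonant modes just above omega_max.  The in-window Huang-Rhys
    factors are rescaled exactly so that the fraction of reorganization
    energy in [k_B T, omega_max] over [0, omega_max] equals the target.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    kT = thermal_energy_cm(spec.temperature)
    if omega_max is None:
        omega_max = spec.nominal_omega_max
    solvent = ContinuousComponent("debye", lam=spec.solvent_lambda,
                                  omega_c=spec.solvent_omega_c)
    modes = []
    # sub-thermal discrete modes
    if spec.n_low_modes:
        lows = np.linspace(0.35 * kT, 0.9 * kT, spec.n_low_modes)
        lows = lows * (1.0 + 0.05 * rng.standard_normal(spec.n_low_modes))
        lows = np.clip(lows, 10.0, 0.98 * kT)
        lam_each = spec.low_mode_lambda / spec.n_low_modes
        modes += [DiscreteMode(float(w), lam_each / float(w)) for w in lows]
    # in-window modes, log-spaced with jitter (chromophore-like clustering)
    lam_window = 0.0
    window_modes = []
    if spec.n_high_modes and spec.target_high_fraction > 0:
        w = np.geomspace(1.12 * kT, 0.95 * omega_max, spec.n_high_modes)
        w = w * (1.0 + 0.03 * rng.standard_normal(spec.n_high_modes))
        w = np.clip(w, 1.02 * kT, 0.98 * omega_max)
        base_g2 = 0.02 * (1.0 + 0.3 * rng.random(spec.n_high_modes))
        window_modes = [DiscreteMode(float(wi), float(g2))
                        for wi, g2 in zip(w, base_g2)]
        lam_window = sum(m.reorganization for m in window_modes)
    # nonresonant modes just above the excitonic band
    if spec.n_nonresonant_modes:
        w = omega_max * np.linspace(1.08, 1.25, spec.n_nonresonant_modes)
        lam_each = spec.nonresonant_mode_lambda / spec.n_nonresonant_modes
        modes += [DiscreteMode(float(wi), lam_each / float(wi)) for wi in w]

    if window_modes:
        F = spec.target_high_fraction
        low_below = spec.low_mode_lambda + float(solvent.cumulative_reorg(kT))
        solvent_window = float(solvent.cumulative_reorg(omega_max)
                               - solvent.cumulative_reorg(kT))
        target_window = F * low_below / (1.0 - F) - solvent_window
        if target_window <= 0:
            raise ValueError(
                f"target window fraction {F} unreachable: solvent alone "
                "carries more in-window reorganization energy"
            )
        scale = target_window / lam_window
        modes += [DiscreteMode(m.frequency, m.huang_rhys * scale)
                  for m in window_modes]
    modes.sort(key=lambda m: m.frequency)
    return SpectralDensity(discrete=tuple(modes), continuous=(solvent,))


def _ring_positions(n, radius):
    theta = 2.0 * np.pi * np.arange(n) / n
    return np.stack([radius * np.cos(theta), radius * np.sin(theta)], axis=1)


def make_ring_funnel(spec: RegimeSpec, rng=None):
    """Two concentric rings with nearest-neighbour couplings.

    The inner ring (strongly coupled, red-shifted by ``energy_offset``)
    models a B850-like acceptor band; the outer ring a B800-like donor
    band.  Each outer site couples to its two nearest inner sites with
    ``inter_coupling``.  Returns ``(ExcitonSystem, SpectralDensity)``.
    """
    if spec.n_inner % 2 or (spec.n_outer and spec.n_inner % spec.n_outer):
        raise ValueError("n_inner must be even and a multiple of n_outer")
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    n = spec.n_inner + spec.n_outer
    eps = np.zeros(n)
    eps[spec.n_inner:] = spec.energy_offset
    if spec.energy_spread:
        eps += spec.energy_spread * rng.standard_normal(n)
    J = np.zeros((n, n))
    for i in range(spec.n_inner):
        j = (i + 1) % spec.n_inner
        J[i, j] = J[j, i] = spec.nn_coupling
    for a in range(spec.n_outer):
        i = spec.n_inner + a
        j = spec.n_inner + (a + 1) % spec.n_outer
        if spec.n_outer > 1:
            J[i, j] = J[j, i] = spec.outer_coupling
        # two nearest inner-ring sites
        anchor = a * spec.n_inner // spec.n_outer
        for jj in (anchor, (anchor + 1) % spec.n_inner):
            J[i, jj] = J[jj, i] = spec.inter_coupling
    labels = tuple(f"B850like-{i + 1}" for i in range(spec.n_inner)) + tuple(
        f"B800like-{i + 1}" for i in range(spec.n_outer))
    system = ExcitonSystem(
        site_energies=eps, couplings=J, site_labels=labels,
        groups={"inner": tuple(range(spec.n_inner)),
                "outer": tuple(range(spec.n_inner, n))},
    )
    sd = make_bath(spec, rng, omega_max=max_exciton_gap(system))
    return system, sd


def make_network_funnel(spec: RegimeSpec, rng=None):
    """Small funnel network (FMO-like when n_outer = 0, LHCII-like otherwise).

    Sites form a chain with nearest-neighbour coupling ``nn_coupling``
    and weaker next-nearest coupling ``inter_coupling``; energies descend
    from donor to acceptor group with random spread, creating a funnel.
    """
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    n = spec.n_inner + spec.n_outer
    eps = np.zeros(n)
    if spec.n_outer:
        eps[spec.n_inner:] = spec.energy_offset
    else:
        eps[:] = np.linspace(spec.energy_offset, 0.0, n)
    if spec.energy_spread:
        eps += spec.energy_spread * rng.standard_normal(n)
    J = np.zeros((n, n))
    for i in range(n - 1):
        val = spec.nn_coupling * (1.0 + 0.2 * rng.standard_normal())
        J[i, i + 1] = J[i + 1, i] = val
    for i in range(n - 2):
        val = spec.inter_coupling * (1.0 + 0.2 * rng.standard_normal())
        J[i, i + 2] = J[i + 2, i] = val
    if spec.n_outer:
        groups = {"Chla": tuple(range(spec.n_inner)),
                  "Chlb": tuple(range(spec.n_inner, n))}
        labels = tuple(f"Chla-{i + 1}" for i in range(spec.n_inner)) + tuple(
            f"Chlb-{i + 1}" for i in range(spec.n_outer))
    else:
        groups = {"acceptor": (n - 1,), "donor": (0,)}
        labels = tuple(f"site-{i + 1}" for i in range(n))
    system = ExcitonSystem(site_energies=eps, couplings=J, site_labels=labels,
                           groups=groups)
    sd = make_bath(spec, rng, omega_max=max_exciton_gap(system))
    return system, sd


def make_model(regime: str, seed: int | None = None, **overrides):
    """Generate a regime's model; returns ``(system, sd, spec)``.

    Deterministic at fixed seed: the same spec always produces the same
    model (and hence byte-identical files through ``write_model``).
    """
    if regime not in REGIMES:
        raise KeyError(f"unknown regime {regime!r}; choose from {sorted(REGIMES)}")
    spec = REGIMES[regime]
    changes = dict(overrides)
    if seed is not None:
        changes["seed"] = seed
    if changes:
        from dataclasses import replace

        spec = replace(spec, **changes)
    if regime == "dimer":
        system, sd = make_dimer(spec.energy_offset, spec.inter_coupling)
    elif regime.startswith("ring_funnel"):
        system, sd = make_ring_funnel(spec)
    else:
        system, sd = make_network_funnel(spec)
    return system, sd, spec


def realized_fraction(system: ExcitonSystem, sd: SpectralDensity,
                      temperature: float) -> float:
    """Convenience: achieved quantum-window reorganization fraction."""
    return reorg_fraction(sd, temperature, max_exciton_gap(system))
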