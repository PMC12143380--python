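"""Frenkel-exciton model and harmonic-bath spectral densities.

The electronic model is the standard Frenkel-exciton Hamiltonian

    H_s = sum_n eps_n |n><n| + sum_{n != m} J_nm |n><m|

with site energies eps_n and intersite couplings J_nm in cm^-1.  Every
site is coupled to an identical, independent harmonic bath described by a
:class:`SpectralDensity`: a list of discrete intramolecular modes
(frequency omega_k, Huang-Rhys factor g_k^2, per-mode reorganization
energy lambda_k = omega_k * g_k^2 in cm^-1) plus smooth low-frequency
solvent/protein components given in parametric form.

The module also implements the bookkeeping that the dynamics and polaron
machinery rely on: the reorganization-energy density Lambda(omega), the
low/high/nonresonant partition of the bath relative to k_B*T and the
maximum excitonic gap, and the discretization of continuous components
into effective modes for trajectory propagation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .units import CM_TO_RADFS, thermal_energy_cm

__all__ = [
    "ModelValidationError",
    "ExcitonSystem",
    "DiscreteMode",
    "ContinuousComponent",
    "SpectralDensity",
    "BathPartition",
    "DiscretizedBath",
    "load_model",
    "write_model",
    "reorganization_density",
    "total_reorganization",
    "max_exciton_gap",
    "partition_bath",
    "reorg_fraction",
    "discretize_continuous",
    "build_dynamical_bath",
]


class ModelValidationError(ValueError):
    """A model file or model object violates the schema or an invariant."""


@dataclass(frozen=True)
class ExcitonSystem:
    """Excitonic system Hamiltonian in the site basis.

    Parameters
    ----------
    site_energies:
        Vector of site energies eps_n in cm^-1.
    couplings:
        Symmetric coupling matrix J_nm in cm^-1 with zero diagonal.
    site_labels:
        Optional human-readable labels, one per site.
    groups:
        Map from group name (e.g. ``"B850"``) to a tuple of site indices.
    """

    site_energies: np.ndarray
    couplings: np.ndarray
    site_labels: tuple = ()
    groups: dict = field(default_factory=dict)

    def __post_init__(self):
        eps = np.asarray(self.site_energies, dtype=float)
        J = np.asarray(self.couplings, dtype=float)
        object.__setattr__(self, "site_energies", eps)
        object.__setattr__(self, "couplings", J)
        if eps.ndim != 1:
            raise ModelValidationError("site_energies must be a 1-D vector")
        n = eps.size
        if J.shape != (n, n):
            raise ModelValidationError(
                f"couplings must be {n}x{n}, got {J.shape}"
            )
        if not np.allclose(J, J.T, atol=1e-10):
            raise ModelValidationError("couplings matrix is not symmetric")
        if np.any(np.abs(np.diag(J)) > 0.0):
            raise ModelValidationError("couplings diagonal must be exactly zero")
        if self.site_labels and len(self.site_labels) != n:
            raise ModelValidationError("site_labels length mismatch")
        for name, members in self.groups.items():
            members = tuple(int(i) for i in members)
            if any(i < 0 or i >= n for i in members):
                raise ModelValidationError(
                    f"group {name!r} refers to a site index outside 0..{n - 1}"
                )
            self.groups[name] = members

    @property
    def n_sites(self) -> int:
        return self.site_energies.size

    def hamiltonian(self) -> np.ndarray:
        """Dense H_s matrix in cm^-1."""
        return np.diag(self.site_energies) + self.couplings

    def group_indices(self, group) -> np.ndarray:
        """Resolve a group name or an explicit index collection."""
        if isinstance(group, str):
            if group not in self.groups:
                raise KeyError(f"unknown site group {group!r}")
            return np.asarray(self.groups[group], dtype=int)
        return np.asarray(list(group), dtype=int)


@dataclass(frozen=True)
class DiscreteMode:
    """A single intramolecular vibration: frequency (cm^-1) and Huang-Rhys g^2."""

    frequency: float
    huang_rhys: float

    def __post_init__(self):
        if not self.frequency > 0:
            raise ModelValidationError(
                f"mode frequency must be positive, got {self.frequency}"
            )
        if self.huang_rhys < 0:
            raise ModelValidationError("huang_rhys must be non-negative")

    @property
    def reorganization(self) -> float:
        """Per-mode reorganization energy lambda_k = omega_k * g_k^2 (cm^-1)."""
        return self.frequency * self.huang_rhys


@dataclass(frozen=True)
class ContinuousComponent:
    """A smooth (solvent/protein) part of the spectral density.

    Supported forms, parameterized by total reorganization energy
    ``lam`` (cm^-1) and characteristic frequency ``omega_c`` (cm^-1):

    ``debye`` / ``overdamped_brownian``
        reorganization density rho(omega) = (2/pi) lam omega_c / (omega^2 + omega_c^2),
        i.e. the spectral function J(omega) = 2 lam omega_c omega / (omega^2 + omega_c^2).
    ``lognormal``
        rho(omega) = lam * LogNormal(ln omega_c, width) density; requires ``width``.

    ``rho`` integrates to ``lam`` exactly, so total reorganization energies
    are available in closed form.
    """

    form: str
    lam: float
    omega_c: float
    width: float = 0.0

    def __post_init__(self):
        if self.form not in ("debye", "overdamped_brownian", "lognormal"):
            raise ModelValidationError(f"unknown continuous form {self.form!r}")
        if self.lam < 0:
            raise ModelValidationError("lambda must be non-negative")
        if not self.omega_c > 0:
            raise ModelValidationError("omega_c must be positive")
        if self.form == "lognormal" and not self.width > 0:
            raise ModelValidationError("lognormal form requires width > 0")

    def reorg_density(self, omega) -> np.ndarray:
        """Reorganization-energy density rho(omega) in cm^-1 per cm^-1."""
        omega = np.asarray(omega, dtype=float)
        if self.form in ("debye", "overdamped_brownian"):
            return (2.0 / np.pi) * self.lam * self.omega_c / (
                omega**2 + self.omega_c**2
            )
        z = np.where(omega > 0, omega, np.nan)
        out = (
            self.lam
            / (z * self.width * math.sqrt(2 * math.pi))
            * np.exp(-0.5 * (np.log(z / self.omega_c) / self.width) ** 2)
        )
        return np.where(omega > 0, out, 0.0)

    def cumulative_reorg(self, omega) -> np.ndarray:
        """Reorganization energy carried by frequencies up to ``omega`` (cm^-1)."""
        omega = np.asarray(omega, dtype=float)
        if self.form in ("debye", "overdamped_brownian"):
            return (2.0 / np.pi) * self.lam * np.arctan(omega / self.omega_c)
        z = np.where(omega > 0, omega, np.nan)
        out = self.lam * norm.cdf(np.log(z / self.omega_c) / self.width)
        return np.where(omega > 0, out, 0.0)

    def inverse_cumulative(self, fraction) -> np.ndarray:
        """Frequency below which ``fraction`` of the reorganization energy lies."""
        x = np.asarray(fraction, dtype=float)
        if np.any((x <= 0) | (x >= 1)):
            raise ValueError("fraction must be strictly inside (0, 1)")
        if self.form in ("debye", "overdamped_brownian"):
            return self.omega_c * np.tan(0.5 * np.pi * x)
        return self.omega_c * np.exp(self.width * norm.ppf(x))


@dataclass(frozen=True)
class SpectralDensity:
    """Identical independent per-site bath: discrete modes + smooth components."""

    discrete: tuple = ()
    continuous: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "discrete", tuple(self.discrete))
        object.__setattr__(self, "continuous", tuple(self.continuous))
        if not math.isfinite(self.total_reorganization):
            raise ModelValidationError("total reorganization energy is not finite")

    @property
    def total_reorganization(self) -> float:
        return sum(m.reorganization for m in self.discrete) + sum(
            c.lam for c in self.continuous
        )


@dataclass(frozen=True)
class BathPartition:
    """Routing of the bath relative to k_B*T and the maximum excitonic gap.

    Discrete modes with omega < k_B*T are "low", those with
    k_B*T <= omega <= omega_max are "high" (the quantum-relevant window),
    and those with omega > omega_max are nonresonant with the exciton
    dynamics.  All continuous components are classified low, on the
    assumption that the solvent density is dominated by sub-thermal
    frequencies.
    """

    kT: float
    omega_max: float
    low: tuple
    high: tuple
    nonresonant: tuple
    continuous: tuple

    def counts(self):
        return {
            "low": len(self.low),
            "high": len(self.high),
            "nonresonant": len(self.nonresonant),
            "continuous": len(self.continuous),
        }


@dataclass(frozen=True)
class DiscretizedBath:
    """Per-site bath as a flat list of effective modes for trajectory dynamics.

    ``frequencies`` (cm^-1) and dimensionless couplings g_k, with per-mode
    reorganization omega_k * g_k^2.  ``origin`` tags each mode as coming
    directly from the discrete list or from discretizing a continuous
    component.  ``coupling_coefficients`` returns the mass-scaled linear
    coefficient kappa_k multiplying q_nk in the site-energy fluctuation,
    in the internal rad/fs unit system (hbar = 1):

        kappa_k = sqrt(2) * g_k * Omega_k^{3/2},  Omega_k = 2 pi c omega_k
    """

    frequencies: np.ndarray
    couplings: np.ndarray
    origin: tuple = ()

    def __post_init__(self):
        w = np.atleast_1d(np.asarray(self.frequencies, dtype=float))
        g = np.atleast_1d(np.asarray(self.couplings, dtype=float))
        object.__setattr__(self, "frequencies", w)
        object.__setattr__(self, "couplings", g)
        if w.shape != g.shape:
            raise ModelValidationError("frequencies/couplings shape mismatch")
        if w.size and np.any(w <= 0):
            raise ModelValidationError("all mode frequencies must be positive")

    @property
    def n_modes(self) -> int:
        return self.frequencies.size

    @property
    def reorganizations(self) -> np.ndarray:
        return self.frequencies * self.couplings**2

    @property
    def total_reorganization(self) -> float:
        return float(np.sum(self.reorganizations))

    @property
    def coupling_coefficients(self) -> np.ndarray:
        omega = CM_TO_RADFS * self.frequencies
        return math.sqrt(2.0) * self.couplings * omega**1.5

    def to_modes(self):
        return tuple(
            DiscreteMode(float(w), float(g) ** 2)
            for w, g in zip(self.frequencies, self.couplings)
        )


# ---------------------------------------------------------------------------
# model file I/O
# ---------------------------------------------------------------------------

def _require(condition, message):
    if not condition:
        raise ModelValidationError(message)


def load_model(path):
    """Read a JSON model file and return ``(ExcitonSystem, SpectralDensity)``.

    The schema has top-level keys ``system`` (energies_cm1, couplings_cm1,
    labels, groups), ``bath`` (discrete, continuous) and optional ``meta``.
    All energies are in cm^-1.
    """
    with open(path) as fh:
        doc = json.load(fh)
    _require("system" in doc, "model file missing top-level key 'system'")
    _require("bath" in doc, "model file missing top-level key 'bath'")
    sys_doc = doc["system"]
    for key in ("energies_cm1", "couplings_cm1"):
        _require(key in sys_doc, f"system section missing field '{key}'")
    system = ExcitonSystem(
        site_energies=np.asarray(sys_doc["energies_cm1"], dtype=float),
        couplings=np.asarray(sys_doc["couplings_cm1"], dtype=float),
        site_labels=tuple(sys_doc.get("labels", ())),
        groups={k: tuple(v) for k, v in sys_doc.get("groups", {}).items()},
    )
    bath_doc = doc["bath"]
    modes = []
    for i, entry in enumerate(bath_doc.get("discrete", [])):
        _require(
            "omega_cm1" in entry and "huang_rhys" in entry,
            f"bath.discrete[{i}] must have fields 'omega_cm1' and 'huang_rhys'",
        )
        modes.append(DiscreteMode(float(entry["omega_cm1"]), float(entry["huang_rhys"])))
    comps = []
    for i, entry in enumerate(bath_doc.get("continuous", [])):
        _require("form" in entry, f"bath.continuous[{i}] missing field 'form'")
        _require(
            "lambda_cm1" in entry and "omega_c_cm1" in entry,
            f"bath.continuous[{i}] must have 'lambda_cm1' and 'omega_c_cm1'",
        )
        comps.append(
            ContinuousComponent(
                form=str(entry["form"]),
                lam=float(entry["lambda_cm1"]),
                omega_c=float(entry["omega_c_cm1"]),
                width=float(entry.get("width", 0.0)),
            )
        )
    sd = SpectralDensity(discrete=modes, continuous=comps)
    return system, sd


def write_model(path, system: ExcitonSystem, sd: SpectralDensity, meta=None):
    """Write a model to the JSON schema read by :func:`load_model`."""
    doc = {
        "system": {
            "energies_cm1": [float(e) for e in system.site_energies],
            "couplings_cm1": [[float(x) for x in row] for row in system.couplings],
            "labels": list(system.site_labels),
            "groups": {k: list(v) for k, v in system.groups.items()},
        },
        "bath": {
            "discrete": [
                {"omega_cm1": m.frequency, "huang_rhys": m.huang_rhys}
                for m in sd.discrete
            ],
            "continuous": [
                {
                    "form": c.form,
                    "lambda_cm1": c.lam,
                    "omega_c_cm1": c.omega_c,
                    **({"width": c.width} if c.form == "lognormal" else {}),
                }
                for c in sd.continuous
            ],
        },
        "meta": {"units": "cm^-1"} | dict(meta or {}),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# spectral-density observables
# ---------------------------------------------------------------------------

def reorganization_density(sd: SpectralDensity, grid, broadening: float = 10.0):
    """Dimensionless density of reorganization energies Lambda(omega).

    Each discrete mode contributes a Brownian-oscillator lineshape

        g_k^2 * (2/pi) * omega_k^2 gamma omega /
            [(omega_k^2 - omega^2)^2 + omega^2 gamma^2]

    whose integral over omega recovers the per-mode reorganization energy
    lambda_k = omega_k g_k^2 (for gamma << omega_k).  Continuous
    components contribute their analytic density.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("frequency grid must be non-empty")
    if np.any(np.diff(grid) <= 0) or np.any(grid < 0):
        raise ValueError("frequency grid must be non-negative and strictly increasing")
    if not broadening > 0:
        raise ValueError("broadening gamma must be positive")
    out = np.zeros_like(grid)
    g2 = broadening**2
    for mode in sd.discrete:
        wk2 = mode.frequency**2
        line = (
            (2.0 / np.pi)
            * wk2
            * broadening
            * grid
            / ((wk2 - grid**2) ** 2 + grid**2 * g2)
        )
        out += mode.huang_rhys * line
    for comp in sd.continuous:
        out += comp.reorg_density(grid)
    return out


def total_reorganization(sd: SpectralDensity) -> float:
    """Total bath reorganization energy Lambda in cm^-1 (exact, no quadrature)."""
    return sd.total_reorganization


def max_exciton_gap(system: ExcitonSystem) -> float:
    """Maximum gap between eigenenergies of H_s (cm^-1); sets the resonance window."""
    if system.n_sites < 2:
        raise ValueError("max_exciton_gap requires at least two sites")
    evals = np.linalg.eigvalsh(system.hamiltonian())
    return float(evals[-1] - evals[0])


def partition_bath(sd: SpectralDensity, temperature: float, omega_max: float):
    """Route bath content into low / high / nonresonant classes."""
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    if not omega_max > 0:
        raise ValueError("omega_max must be positive")
    kT = thermal_energy_cm(temperature)
    low, high, nonres = [], [], []
    for mode in sd.discrete:
        if mode.frequency < kT:
            low.append(mode)
        elif mode.frequency <= omega_max:
            high.append(mode)
        else:
            nonres.append(mode)
    return BathPartition(
        kT=kT,
        omega_max=omega_max,
        low=tuple(low),
        high=tuple(high),
        nonresonant=tuple(nonres),
        continuous=tuple(sd.continuous),
    )


def reorg_fraction(sd: SpectralDensity, temperature: float, omega_max: float) -> float:
    """Fraction of reorganization energy in [k_B*T, omega_max] relative to [0, omega_max]."""
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    if not omega_max > 0:
        raise ValueError("omega_max must be positive")
    kT = thermal_energy_cm(temperature)
    num = 0.0
    den = 0.0
    for mode in sd.discrete:
        if mode.frequency <= omega_max:
            den += mode.reorganization
            if mode.frequency >= kT:
                num += mode.reorganization
    for comp in sd.continuous:
        below_max = float(comp.cumulative_reorg(omega_max))
        below_kT = float(comp.cumulative_reorg(kT))
        den += below_max
        num += max(below_max - below_kT, 0.0)
    if den <= 0:
        raise ZeroDivisionError(
            "no reorganization energy below omega_max; fraction undefined"
        )
    return num / den


#: Fraction of a continuous component's reorganization energy captured by
#: the discretization cutoff (the Debye density has a very slow tail, so a
#: hard 100% cutoff would place modes at absurdly high frequencies).
DISCRETIZATION_CAPTURE = 0.999


def discretize_continuous(component: ContinuousComponent, n_modes: int):
    """Equal-reorganization discretization of a smooth component.

    The cumulative reorganization profile up to the frequency capturing
    99.9% of lambda is cut into ``n_modes`` slices of equal reorganization
    energy; each slice is represented by one mode at its median frequency
    with g_j^2 = (slice reorganization) / omega_j.
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    cap = DISCRETIZATION_CAPTURE
    fractions = cap * (np.arange(n_modes) + 0.5) / n_modes
    freqs = component.inverse_cumulative(fractions)
    lam_per_mode = component.lam * cap / n_modes
    return [DiscreteMode(float(w), lam_per_mode / float(w)) for w in freqs]


def build_dynamical_bath(
    sd: SpectralDensity,
    temperature: float,
    omega_max: float,
    include=("low", "high"),
    n_solvent_modes: int = 24,
) -> DiscretizedBath:
    """Assemble the per-site mode list actually propagated by the dynamics.

    ``include`` selects which partition classes of discrete modes enter;
    continuous components (always "low") are discretized with
    ``n_solvent_modes`` effective modes each.  By default nonresonant
    modes (above the maximum excitonic gap) are excluded, which leaves the
    population dynamics unchanged.
    """
    part = partition_bath(sd, temperature, omega_max)
    modes = []
    origin = []
    class_map = {"low": part.low, "high": part.high, "nonresonant": part.nonresonant}
    for name in include:
        if name not in class_map:
            raise ValueError(f"unknown partition class {name!r}")
        for m in class_map[name]:
            modes.append(m)
            origin.append("discrete")
    if "low" in include:
        for comp in part.continuous:
            for m in discretize_continuous(comp, n_solvent_modes):
                modes.append(m)
                origin.append("from-continuous")
    freqs = np.array([m.frequency for m in modes], dtype=float)
    gs = np.array([math.sqrt(m.huang_rhys) for m in modes], dtype=float)
    order = np.argsort(freqs) if freqs.size else np.array([], dtype=int)
    return DiscretizedBath(
        frequencies=freqs[order],
        couplings=gs[order],
        origin=tuple(origin[i] for i in order),
    )
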