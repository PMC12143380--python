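"""Unit system and physical constants.

All user-facing energies and frequencies are in wavenumbers (cm^-1) and
times in femtoseconds, the natural units of molecular spectroscopy.
Internally, trajectory propagation works in angular frequency units
(rad/fs) with hbar = 1, so that a wavenumber value nu corresponds to the
angular frequency 2*pi*c*nu and a quantum of energy hbar*omega is simply
omega.  Mass-scaled nuclear coordinates q then carry units of
(rad/fs)^(-1/2) and momenta (rad/fs)^(+1/2), making p^2/2 + omega^2 q^2/2
an energy in rad/fs.
"""

import math

#: Speed of light in cm/fs.
SPEED_OF_LIGHT_CM_FS = 2.99792458e-5

#: Conversion factor: angular frequency [rad/fs] per wavenumber [cm^-1].
CM_TO_RADFS = 2.0 * math.pi * SPEED_OF_LIGHT_CM_FS

#: Boltzmann constant in cm^-1 per kelvin.
KB_CM_PER_K = 0.69503476


def thermal_energy_cm(temperature_k: float) -> float:
    """k_B*T in cm^-1 (about 208.5 cm^-1 at 300 K)."""
    return KB_CM_PER_K * temperature_k


def cm_to_radfs(value_cm: float):
    """Convert an energy/frequency from cm^-1 to rad/fs."""
    return CM_TO_RADFS * value_cm


def radfs_to_cm(value_radfs: float):
    """Convert an energy/frequency from rad/fs to cm^-1."""
    return value_radfs / CM_TO_RADFS
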