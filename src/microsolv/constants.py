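"""Physical constants, unit conversions and standard masses.

All CODATA values come from :mod:`scipy.constants`.  Internal unit
conventions used throughout the package:

* time in picoseconds (fs accepted at some interfaces and converted),
* rates and angular frequencies in 1/ps and rad/ps,
* energies in eV internally, meV for reported spectra,
* dipole moments in debye, separations in pm at the interfaces.
"""

from __future__ import annotations

import math

from scipy import constants as _codata

E_CHARGE = _codata.e  # C
HBAR = _codata.hbar  # J s
EPSILON_0 = _codata.epsilon_0  # F/m
C_LIGHT = _codata.c  # m/s

#: 1 debye in C m
DEBYE = 1e-21 / _codata.c

#: speed of light in cm/ps, for rad/ps -> wavenumber conversions
C_CM_PER_PS = _codata.c * 1e2 * 1e-12

FS_PER_PS = 1e3
PM_PER_M = 1e12

#: standard atomic weights (u)
ATOMIC_WEIGHTS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}

def _formula_mass(counts: dict[str, int]) -> float:
    return sum(n * ATOMIC_WEIGHTS[el] for el, n in counts.items())

#: indole, C8H7N (u)
M_INDOLE_U = round(_formula_mass({"C": 8, "H": 7, "N": 1}), 3)
#: water (u)
M_WATER_U = round(_formula_mass({"H": 2, "O": 1}), 3)
#: indole-water cluster (u)
M_CLUSTER_U = round(M_INDOLE_U + M_WATER_U, 3)


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a Gaussian FWHM to the standard deviation, same units."""
    return fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def angular_freq_to_wavenumber(omega_rad_per_ps: float) -> float:
    """Convert an angular frequency in rad/ps to wavenumbers in 1/cm."""
    return omega_rad_per_ps / (2.0 * math.pi * C_CM_PER_PS)
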