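"""Physical constants and reference tables used across the package.

Masses are in unified atomic mass units (Da), radii in Angstrom.
"""

from __future__ import annotations

import numpy as np

#: Mass of a proton (Da); subtracted per charge when converting m/z to neutral mass.
PROTON_MASS = 1.00727646688

#: Mass added per incorporated deuterium: m(2H) - m(1H) (Da).
DEUTERIUM_MASS_SHIFT = 1.00627675

#: Nominal mass spacing between aggregated isotopologue peaks (13C-dominated, Da).
ISOTOPE_SPACING = 1.0033548

#: Fraction of D2O in the labeling reaction after the 18-fold dilution protocol.
DEFAULT_D2O_FRACTION = 17.0 / 18.0

#: Standard atomic masses (Da) for center-of-mass calculations.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
}

#: van der Waals radii (Bondi, Angstrom) used by the accessible-surface sampler.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "P": 1.80,
    "S": 1.80,
}

#: Default probe radius for solvent-accessible surface area (water, Angstrom).
DEFAULT_PROBE_RADIUS = 1.4

# --- ideal backbone geometry (bond lengths in A, angles in degrees) -------
# Fixed textbook values; only phi/psi are free in the builder.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

#: Canonical alpha-helix backbone dihedrals (degrees).
ALPHA_PHI = -57.0
ALPHA_PSI = -47.0

# --- circular dichroism reference basis ----------------------------------
# Mean-residue-ellipticity basis spectra (deg cm^2 dmol^-1) as sums of
# Gaussian bands.  These are nominal package constants: absolute helicity
# derived from them is a nominal scale and only relative comparisons between
# samples analyzed with the same basis are meaningful.
_CD_HELIX_BANDS = ((-36000.0, 222.0, 6.5), (-33000.0, 208.0, 5.5), (65000.0, 192.0, 6.0))
_CD_COIL_BANDS = ((-42000.0, 198.0, 7.0), (1500.0, 222.0, 15.0))


def _bands(wavelengths_nm: np.ndarray, bands) -> np.ndarray:
    wl = np.asarray(wavelengths_nm, dtype=float)
    out = np.zeros_like(wl)
    for amp, center, width in bands:
        out += amp * np.exp(-((wl - center) ** 2) / (2.0 * width**2))
    return out


def cd_helix_basis(wavelengths_nm) -> np.ndarray:
    """Mean residue ellipticity of the fully helical reference state."""
    return _bands(wavelengths_nm, _CD_HELIX_BANDS)


def cd_coil_basis(wavelengths_nm) -> np.ndarray:
    """Mean residue ellipticity of the fully disordered reference state."""
    return _bands(wavelengths_nm, _CD_COIL_BANDS)


#: Reference MRE values at 222 nm for the helicity estimator (deg cm^2 dmol^-1).
THETA_HELIX_222 = float(cd_helix_basis(np.array([222.0]))[0])
THETA_COIL_222 = float(cd_coil_basis(np.array([222.0]))[0])
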