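"""Synthetic absorbance kinetic traces and circular dichroism spectra.

The kinetic generator emulates a dehydrogenase assay followed by the
decay of electron-acceptor (ferrocenium) absorbance at 300 nm: a linear
initial-rate segment that flattens exponentially once substrate or
acceptor depletes.  The CD generator mixes fixed helix and coil
reference basis spectra in a chosen ratio, optionally masking the
short-wavelength region (<= 217 nm) that liposome light scattering
renders unusable in practice.
"""

from __future__ import annotations

import numpy as np

from .. import constants as C
from ..assays import CDSpectrum, KineticTrace
from ..errors import InputError

#: timescale of the post-depletion flattening (min)
DEPLETION_TAU_MIN = 1.0

# defaults mirroring the assay scale: 150 uL reaction at 0.72 uM enzyme
# (~70 kDa) -> ~0.0076 mg per reaction
DEFAULT_REACTION_VOLUME_L = 150e-6
DEFAULT_ENZYME_MASS_MG = 0.72e-6 * 150e-6 * 70_000 * 1e3


def simulate_kinetic_trace(
    slope_AU_per_min: float,
    A0: float = 1.2,
    duration_min: float = 10.0,
    depletion_t_min: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    dt_min: float = 0.05,
    epsilon_mM_cm: float = 4.3,
    path_cm: float = 1.0,
    reaction_volume_L: float = DEFAULT_REACTION_VOLUME_L,
    enzyme_mass_mg: float = DEFAULT_ENZYME_MASS_MG,
) -> KineticTrace:
    """Linear-then-depleting absorbance decay with Gaussian noise.

    Absorbance falls at ``slope_AU_per_min`` (<= 0 for decays) until
    ``depletion_t_min`` (default: the full duration, i.e. purely linear),
    then the rate decays exponentially with a 1-min timescale.
    Deterministic under ``seed``.
    """
    if A0 <= 0:
        raise InputError("A0 must be positive")
    if slope_AU_per_min > 0:
        raise InputError("decay slope must be <= 0")
    if depletion_t_min is None:
        depletion_t_min = duration_min
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_min + dt_min / 2, dt_min)
    a = np.where(
        t <= depletion_t_min,
        A0 + slope_AU_per_min * t,
        A0 + slope_AU_per_min * depletion_t_min
        + slope_AU_per_min * DEPLETION_TAU_MIN
        * (1.0 - np.exp(-(t - depletion_t_min) / DEPLETION_TAU_MIN)),
    )
    if noise_sd > 0:
        a = a + rng.normal(0.0, noise_sd, a.shape)
    return KineticTrace(t, a, epsilon_mM_cm=epsilon_mM_cm, path_cm=path_cm,
                        reaction_volume_L=reaction_volume_L,
                        enzyme_mass_mg=enzyme_mass_mg)


def simulate_cd(
    f_helix: float,
    noise_sd_mdeg: float = 0.0,
    seed: int = 0,
    wavelengths_nm: np.ndarray | None = None,
    mask_below_nm: float | None = None,
    concentration_M: float = 20e-6,
    path_cm: float = 0.1,
    n_residues: int = 34,
) -> CDSpectrum:
    """CD spectrum of an ``f_helix`` : ``1 - f_helix`` helix/coil mixture.

    The underlying mean-residue-ellipticity basis spectra are fixed
    package constants, so the absolute helicity scale is nominal; only
    relative comparisons between spectra generated (or analyzed) with the
    same basis are meaningful.  ``mask_below_nm`` (e.g. 217) marks the
    scattering-affected region as missing.
    """
    if not 0.0 <= f_helix <= 1.0:
        raise InputError("f_helix must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    wl = np.arange(190.0, 261.0) if wavelengths_nm is None else np.asarray(
        wavelengths_nm, dtype=float)
    mre = f_helix * C.cd_helix_basis(wl) + (1.0 - f_helix) * C.cd_coil_basis(wl)
    # mdeg = MRE * 10 * path * molar concentration * residue count
    mdeg = mre * 10.0 * path_cm * concentration_M * n_residues
    if noise_sd_mdeg > 0:
        mdeg = mdeg + rng.normal(0.0, noise_sd_mdeg, mdeg.shape)
    masked = wl <= mask_below_nm if mask_below_nm is not None else np.zeros(
        len(wl), dtype=bool)
    return CDSpectrum(wl, mdeg, concentration_M=concentration_M,
                      path_cm=path_cm, n_residues=n_residues, masked=masked)
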