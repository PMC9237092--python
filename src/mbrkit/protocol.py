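"""Protocol bookkeeping arithmetic for the experimental design.

Small, exact calculators for the quantities a bench protocol prints:
the usable production span of a simulation after discarding the initial
equilibration period, concentrations after mixing/dilution, and molar
excess ratios (e.g. lipid over protein in a labeling reaction).
"""

from __future__ import annotations

from .errors import InputError


def production_window_ns(total_ns: float = 185.0, discard_ns: float = 25.0) -> float:
    """Usable production span after discarding initial equilibration.

    Defaults reflect a 185 ns run whose first 25 ns are discounted as
    equilibration, leaving 160 ns of production trajectory.
    """
    if total_ns <= 0 or discard_ns < 0:
        raise InputError("total must be positive and discard non-negative")
    if discard_ns >= total_ns:
        raise InputError("discard period consumes the whole run")
    return total_ns - discard_ns


def n_frames(window_ns: float, sampling_ps: float = 5.0) -> int:
    """Number of structural samples captured at ``sampling_ps`` spacing."""
    if sampling_ps <= 0:
        raise InputError("sampling interval must be positive")
    return int(round(window_ns * 1000.0 / sampling_ps))


def mixed_concentration(conc: float, volume: float, *other_volumes: float) -> float:
    """Concentration after combining with additional volumes.

    Example: 1.44 uM enzyme in 75 uL mixed with an equal 75 uL of
    substrate solution gives a final 0.72 uM.
    """
    if conc <= 0 or volume <= 0 or any(v < 0 for v in other_volumes):
        raise InputError("concentration and volumes must be positive")
    total = volume + sum(other_volumes)
    return conc * volume / total


def molar_excess(ligand_conc: float, protein_conc: float,
                 ligand_volume: float = 1.0, protein_volume: float = 1.0) -> float:
    """Mole ratio of ligand to protein in a mixture.

    Example: 1 uL of 10 mM liposomes combined with 1 uL of 40 uM protein
    is a 250-fold molar excess of lipid.
    """
    if min(ligand_conc, protein_conc, ligand_volume, protein_volume) <= 0:
        raise InputError("concentrations and volumes must be positive")
    return (ligand_conc * ligand_volume) / (protein_conc * protein_volume)
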