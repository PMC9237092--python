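"""Ideal peptide-backbone builder for helix/coil test geometry.

Builds N/CA/C/O backbone atoms from fixed textbook bond lengths and angles;
only the phi/psi dihedrals vary.  Residue intervals listed in
``coil_ranges`` are forced to extended dihedrals (phi = psi = 180 deg),
which models proline-induced fraying of an otherwise helical segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .. import constants as C
from ..errors import InputError
from ..structure import Frame

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass
class HelixSpec:
    """Backbone geometry specification for a single peptide chain.

    Parameters
    ----------
    sequence : str
        One-letter amino-acid sequence.
    phi, psi : float
        Backbone dihedrals in degrees applied to every residue outside
        ``coil_ranges`` (defaults: canonical alpha-helix).
    coil_ranges : list of (int, int)
        Inclusive residue-id intervals forced to extended dihedrals.
    start_resid : int
        Residue id of the first residue (ids are absolute, so specs can
        mirror numbering of a larger protein).
    chain : str
        Chain identifier for the built atoms.
    """

    sequence: str
    phi: float = C.ALPHA_PHI
    psi: float = C.ALPHA_PSI
    coil_ranges: list[tuple[int, int]] = field(default_factory=list)
    start_resid: int = 1
    chain: str = "A"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError("sequence must be non-empty")
        bad = sorted({c for c in self.sequence if c not in ONE_TO_THREE})
        if bad:
            raise InputError(f"unknown residue letter(s): {', '.join(bad)}")
        if not (np.isfinite(self.phi) and np.isfinite(self.psi)):
            raise InputError("dihedrals must be finite")
        last = self.start_resid + len(self.sequence) - 1
        for lo, hi in self.coil_ranges:
            if lo > hi or lo < self.start_resid or hi > last:
                raise InputError(f"coil range ({lo}, {hi}) outside residues "
                                 f"{self.start_resid}-{last}")

    def dihedrals(self) -> np.ndarray:
        """Per-residue (phi, psi) in degrees after applying coil ranges."""
        n = len(self.sequence)
        out = np.tile([self.phi, self.psi], (n, 1))
        for lo, hi in self.coil_ranges:
            i0, i1 = lo - self.start_resid, hi - self.start_resid
            out[i0 : i1 + 1] = 180.0
        return out


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom d with bond |cd|, angle b-c-d and dihedral a-b-c-d (NeRF)."""
    theta = np.radians(angle_deg)
    tau = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(theta),
                        bond * np.sin(theta) * np.cos(tau),
                        bond * np.sin(theta) * np.sin(tau)])
    return c + np.column_stack([bc, m, n]) @ d_local


def build_ideal_helix(spec: HelixSpec) -> Frame:
    """Build backbone (N, CA, C, O) coordinates for a :class:`HelixSpec`.

    A single-residue spec yields its four atoms with no dihedral applied.
    """
    n_res = len(spec.sequence)
    dih = spec.dihedrals()

    coords: list[np.ndarray] = []
    names: list[str] = []
    res_of_atom: list[int] = []

    # first residue in a canonical local frame
    n0 = np.zeros(3)
    ca0 = np.array([C.BOND_N_CA, 0.0, 0.0])
    a = np.radians(180.0 - C.ANGLE_N_CA_C)
    c0 = ca0 + C.BOND_CA_C * np.array([np.cos(a), np.sin(a), 0.0])
    n_prev, ca_prev, c_prev = n0, ca0, c0

    per_res: list[dict[str, np.ndarray]] = [{"N": n0, "CA": ca0, "C": c0}]
    for i in range(1, n_res):
        psi_prev = dih[i - 1, 1]
        n_i = _place(n_prev, ca_prev, c_prev, C.BOND_C_N, C.ANGLE_CA_C_N, psi_prev)
        ca_i = _place(ca_prev, c_prev, n_i, C.BOND_N_CA, C.ANGLE_C_N_CA, C.OMEGA)
        c_i = _place(c_prev, n_i, ca_i, C.BOND_CA_C, C.ANGLE_N_CA_C, dih[i, 0])
        per_res.append({"N": n_i, "CA": ca_i, "C": c_i})
        n_prev, ca_prev, c_prev = n_i, ca_i, c_i

    # carbonyl oxygens: dihedral N-CA-C-O = psi + 180
    for i, atoms in enumerate(per_res):
        atoms["O"] = _place(atoms["N"], atoms["CA"], atoms["C"],
                            C.BOND_C_O, C.ANGLE_CA_C_O, dih[i, 1] + 180.0)

    for i, atoms in enumerate(per_res):
        for name in ("N", "CA", "C", "O"):
            coords.append(atoms[name])
            names.append(name)
            res_of_atom.append(spec.start_resid + i)

    elements = np.array([nm[0] for nm in names])
    res_ids = np.array(res_of_atom)
    res_names = np.array([ONE_TO_THREE[spec.sequence[r - spec.start_resid]]
                          for r in res_of_atom])
    return Frame(elements, np.array(names), res_ids, res_names,
                 np.full(len(names), spec.chain), np.vstack(coords))
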