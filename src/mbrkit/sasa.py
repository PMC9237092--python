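"""Solvent-accessible surface area by Shrake-Rupley sphere-point sampling.

Each atom is inflated by the probe radius and covered with a deterministic
golden-spiral point set; points falling inside any neighboring inflated
sphere are occluded.  The buried interface area of a protein-membrane
complex is the protein-side SASA lost on complex formation:
``SASA(protein alone) - SASA(protein | lipids present)``.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .constants import DEFAULT_PROBE_RADIUS, VDW_RADII
from .errors import InputError
from .structure import Frame, Selection


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def _radii_for(elements: np.ndarray, radii: dict[str, float] | None) -> np.ndarray:
    table = VDW_RADII if radii is None else radii
    unknown = sorted({e for e in elements if e not in table})
    if unknown:
        raise InputError(f"no van der Waals radius for element(s): {', '.join(unknown)}")
    return np.array([table[e] for e in elements])


def sasa(
    structure: Frame,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
    context: Frame | None = None,
) -> np.ndarray:
    """Per-atom solvent-accessible areas (A^2) of ``structure``.

    If ``context`` is given, its atoms occlude surface but contribute no
    area of their own (used for buried-interface calculations).
    """
    if n_points < 32:
        raise InputError("n_points must be at least 32")
    r_self = _radii_for(structure.elements, radii) + probe_radius
    coords = structure.coords
    if context is not None and context.n_atoms:
        r_ctx = _radii_for(context.elements, radii) + probe_radius
        all_coords = np.vstack([coords, context.coords])
        all_r = np.concatenate([r_self, r_ctx])
    else:
        all_coords = coords
        all_r = r_self

    unit = sphere_points(n_points)
    tree = cKDTree(all_coords)
    r_max = all_r.max()
    areas = np.empty(structure.n_atoms)
    for i in range(structure.n_atoms):
        pts = coords[i] + r_self[i] * unit
        neighbors = tree.query_ball_point(coords[i], r_self[i] + r_max)
        neighbors = [j for j in neighbors if j != i]
        if neighbors:
            diff = pts[:, None, :] - all_coords[neighbors][None, :, :]
            d2 = np.einsum("pjk,pjk->pj", diff, diff)
            occluded = (d2 < (all_r[neighbors] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - occluded.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * r_self[i] ** 2 * frac
    return areas


def buried_sasa(
    frame: Frame,
    protein_selection: Selection,
    lipid_selection: Selection,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
    symmetric: bool = False,
) -> float:
    """Protein surface area (A^2) buried at the protein-lipid interface.

    Computed protein-side: SASA of the protein atoms alone minus their
    SASA in the presence of the lipid atoms, clamped at 0.  With
    ``symmetric=True`` the lipid-side loss is added as well.
    """
    protein = frame.atoms(protein_selection)
    lipids = frame.atoms(lipid_selection)
    if protein.n_atoms == 0:
        raise InputError("protein selection matched no atoms")
    if lipids.n_atoms == 0:
        raise InputError("lipid selection matched no atoms")
    alone = sasa(protein, probe_radius, n_points, radii).sum()
    in_complex = sasa(protein, probe_radius, n_points, radii, context=lipids).sum()
    buried = max(alone - in_complex, 0.0)
    if symmetric:
        l_alone = sasa(lipids, probe_radius, n_points, radii).sum()
        l_complex = sasa(lipids, probe_radius, n_points, radii, context=protein).sum()
        buried += max(l_alone - l_complex, 0.0)
    return float(buried)
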