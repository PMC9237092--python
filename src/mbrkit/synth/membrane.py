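"""Phosphate pseudo-atom membrane model and rigid-body pose construction.

The membrane is represented by the only atoms the geometric estimators
depend on: phosphorus pseudo-atoms arranged on two jittered planar
lattices (one per leaflet).  A configurable fraction of sites is flagged
cardiolipin-like (residue name ``CDL`` vs ``POC``), mirroring an
80% phosphatidylcholine / 20% cardiolipin composition.  Optional coarse
acyl-chain carbon layers below each leaflet support buried-surface-area
tests without a full lipid model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import GeometryError, InputError
from ..structure import Frame, Selection, concat_frames

ACYL_LAYER_SPACING = 3.5  # A between coarse acyl carbon layers

#: membrane residue ids start here so they never collide with protein
#: residue numbering in combined frames
MEMBRANE_RESID_BASE = 9000


@dataclass
class MembraneModelSpec:
    """Two-leaflet phosphate-lattice membrane.

    ``leaflet_z`` gives the z offsets (A) of the two headgroup planes;
    ``cl_fraction`` of sites per leaflet are flagged cardiolipin-like;
    ``jitter_sd`` is the per-coordinate Gaussian positional noise (A);
    ``acyl_layers`` adds that many coarse carbon layers per leaflet,
    spaced toward the bilayer midplane, giving the bilayer an interior
    so that buried-surface calculations see an asymmetric environment.
    The defaults put pseudo-atoms ~5 A apart, dense enough that a
    1.4 A probe cannot slip between headgroups of a flat leaflet.
    """

    box_xy: tuple[float, float] = (60.0, 60.0)
    leaflet_z: tuple[float, float] = (20.0, -20.0)
    n_phosphates_per_leaflet: int = 144
    jitter_sd: float = 0.8
    cl_fraction: float = 0.2
    acyl_layers: int = 2

    def __post_init__(self) -> None:
        if self.n_phosphates_per_leaflet <= 0:
            raise InputError("n_phosphates_per_leaflet must be positive")
        if not 0.0 <= self.cl_fraction <= 1.0:
            raise InputError("cl_fraction must lie in [0, 1]")
        if self.leaflet_z[0] == self.leaflet_z[1]:
            raise InputError("leaflet z offsets must be distinct")


def make_membrane(spec: MembraneModelSpec, seed: int) -> Frame:
    """Build the membrane frame; identical ``seed`` gives identical coordinates."""
    rng = np.random.default_rng(seed)
    n = spec.n_phosphates_per_leaflet
    nx = int(np.ceil(np.sqrt(n)))
    xs = (np.arange(nx) + 0.5) * spec.box_xy[0] / nx - spec.box_xy[0] / 2
    ys = (np.arange(nx) + 0.5) * spec.box_xy[1] / nx - spec.box_xy[1] / 2
    gx, gy = np.meshgrid(xs, ys)
    lattice = np.column_stack([gx.ravel(), gy.ravel()])[:n]

    n_cl = int(round(spec.cl_fraction * n))
    midplane = 0.5 * (spec.leaflet_z[0] + spec.leaflet_z[1])

    parts: list[Frame] = []
    res_offset = MEMBRANE_RESID_BASE
    for z0 in spec.leaflet_z:
        coords = np.column_stack([lattice, np.full(n, float(z0))])
        coords = coords + rng.normal(0.0, spec.jitter_sd, coords.shape)
        cl_sites = rng.permutation(n)[:n_cl]
        res_names = np.full(n, "POC")
        res_names[cl_sites] = "CDL"
        parts.append(
            Frame(
                np.full(n, "P"),
                np.full(n, "P"),
                np.arange(n) + 1 + res_offset,
                res_names,
                np.full(n, "M"),
                coords,
            )
        )
        res_offset += n
        toward_mid = np.sign(midplane - z0)
        for layer in range(spec.acyl_layers):
            zc = z0 + toward_mid * ACYL_LAYER_SPACING * (layer + 1)
            ac = np.column_stack([lattice, np.full(n, zc)])
            ac = ac + rng.normal(0.0, spec.jitter_sd, ac.shape)
            parts.append(
                Frame(
                    np.full(n, "C"),
                    np.full(n, "C1"),
                    np.arange(n) + 1 + res_offset,
                    np.full(n, "ACY"),
                    np.full(n, "M"),
                    ac,
                )
            )
            res_offset += n
    return concat_frames(parts)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector ``a`` onto unit vector ``b``."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    s = np.linalg.norm(v)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180 degree turn about any axis perpendicular to a
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def principal_axis(points: np.ndarray) -> np.ndarray:
    """Dominant principal direction of a point set, oriented first-to-last."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise GeometryError("need at least 3 points for a principal axis")
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, pts[-1] - pts[0]) < 0:
        axis = -axis
    return axis


def place_on_membrane(
    structure: Frame,
    tilt_deg: float,
    depth_A: float,
    membrane: Frame,
    helix_range: tuple[int, int],
    helix_selection: Selection | None = None,
) -> Frame:
    """Pose ``structure`` on ``membrane`` at a prescribed tilt and depth.

    The structure is rigid-body transformed so that the dominant principal
    axis of the CA atoms in ``helix_range`` makes ``tilt_deg`` with the
    proximal-leaflet headgroup plane, and the mass-weighted center of mass
    of all atoms in that range sits at signed height ``depth_A`` along the
    plane normal (negative = below the headgroups, inside the bilayer).
    The proximal leaflet is the upper one (larger coordinate along the
    membrane normal); the plane normal points away from the bilayer.

    Returns the combined protein + membrane frame.
    """
    from ..geometry import _leaflet_split, _lstsq_plane

    sel = helix_selection or f"resid {helix_range[0]}-{helix_range[1]}"
    phos = membrane.atoms("element P")
    if phos.n_atoms < 6:
        raise GeometryError("membrane needs at least 3 phosphates per leaflet")
    upper, lower, axis_n = _leaflet_split(phos.coords)
    # proximal = leaflet further along the split axis (upper by convention)
    point, normal, _ = _lstsq_plane(phos.coords[upper])
    distal_centroid = phos.coords[lower].mean(axis=0)
    if np.dot(normal, point - distal_centroid) < 0:
        normal = -normal

    ca = structure.atoms(f"{sel} and name CA")
    if ca.n_atoms < 3:
        raise InputError("helix_range must contain at least 3 CA atoms")
    axis = principal_axis(ca.coords)

    # in-plane direction for the tilted axis
    ref = np.array([1.0, 0.0, 0.0])
    in_plane = ref - np.dot(ref, normal) * normal
    if np.linalg.norm(in_plane) < 1e-8:
        in_plane = np.array([0.0, 1.0, 0.0]) - normal[1] * normal
    in_plane /= np.linalg.norm(in_plane)
    t = np.radians(tilt_deg)
    target_axis = np.cos(t) * in_plane + np.sin(t) * normal

    rot = _rotation_between(axis, target_axis)
    com = structure.com(sel)
    posed = structure.rotated(rot, center=com)
    target_com = point + depth_A * normal
    posed = posed.translated(target_com - posed.com(sel))
    return concat_frames([posed, membrane], time_ps=structure.time_ps)
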