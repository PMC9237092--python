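"""Membrane-interaction geometry: plane fits, helical content, tilt, depth,
and binned trajectory statistics.

These are the per-frame quantities used to characterise how a
membrane-binding helix engages a bilayer: the helical-content order
parameter ``hlx`` of a residue window, the tilt angle ``theta`` between a
helix axis and the membrane surface, the signed insertion depth ``d`` of
the helix center of mass relative to the plane through the
proximal-leaflet phosphates (d < 0 means below the lipid headgroups), and
binned time-series summaries (0.5 ns bins by default downstream, with
mean +/- s.d. bands).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import GeometryError, InputError
from .structure import Frame, Selection, Trajectory
from .synth.membrane import principal_axis

# default parameters of the helical-content order parameter (the widely used
# collective-variable alpha measure): CA-triplet bend angle term and
# O(i)...N(i+4) H-bond term.
HLX_THETA0 = 88.0   # deg
HLX_DTHETA = 15.0   # deg
HLX_D0 = 3.3        # A


@dataclass
class MembranePlane:
    """Least-squares plane through one leaflet's phosphate atoms."""

    point: np.ndarray
    normal: np.ndarray
    leaflet: str = "proximal"
    rmsd_fit: float = 0.0

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(self.normal)
        if not np.isclose(norm, 1.0, atol=1e-8):
            self.normal = self.normal / norm

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.point) @ self.normal


def _lstsq_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Total-least-squares plane fit: (centroid, unit normal, rmsd)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise GeometryError("plane fit needs at least 3 points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise GeometryError("plane fit degenerate: points are collinear")
    normal = vt[2]
    rmsd = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return centroid, normal, rmsd


def _leaflet_split(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition phosphate coordinates into two leaflets.

    The membrane normal is taken as the principal direction along which a
    1-D two-means clustering best separates the points (largest
    between-cluster gap relative to within-cluster spread); this is robust
    both to wide membranes (normal = smallest principal direction) and to
    small test patches whose leaflet separation exceeds the lateral
    extent.  Returns (mask_upper, mask_lower, axis) where "upper" is the
    cluster further along the axis.
    """
    pts = np.asarray(coords, dtype=float)
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)

    def two_means(proj):
        c0, c1 = proj.min(), proj.max()
        assign = np.abs(proj - c0) <= np.abs(proj - c1)
        for _ in range(100):
            assign = np.abs(proj - c0) <= np.abs(proj - c1)
            if assign.all() or (~assign).all():
                break
            n0, n1 = proj[assign].mean(), proj[~assign].mean()
            if np.isclose(n0, c0) and np.isclose(n1, c1):
                break
            c0, c1 = n0, n1
        return assign, c0, c1

    best = None
    for axis in vt:
        proj = centered @ axis
        assign, c0, c1 = two_means(proj)
        if assign.all() or (~assign).all():
            score = 0.0
        else:
            within = np.sqrt(
                (np.sum((proj[assign] - c0) ** 2)
                 + np.sum((proj[~assign] - c1) ** 2)) / len(proj))
            score = abs(c1 - c0) / (within + 1e-12)
        if best is None or score > best[0]:
            best = (score, axis, assign, c0, c1)
    _, axis, assign, c0, c1 = best
    if axis[2] < 0 or (axis[2] == 0 and axis[np.argmax(np.abs(axis))] < 0):
        axis = -axis
        c0, c1 = -c0, -c1
    lower = assign if c0 <= c1 else ~assign
    return ~lower, lower, axis


def fit_membrane_plane(
    frame: Frame,
    phosphate_selection: Selection = "element P",
    protein_selection: Selection = "chain A",
) -> MembranePlane:
    """Fit the proximal-leaflet headgroup plane of a protein+membrane frame.

    Phosphates are split into two leaflets; the plane is the least-squares
    fit to the leaflet whose centroid lies nearest the protein-selection
    center of mass.  The normal points away from the bilayer interior
    (from the distal leaflet toward the proximal one), so signed distances
    are negative below the headgroups.
    """
    phos = frame.atoms(phosphate_selection)
    if phos.n_atoms < 3:
        raise GeometryError("need at least 3 phosphate atoms")
    prot = frame.atoms(protein_selection)
    if prot.n_atoms == 0:
        raise InputError("protein selection matched no atoms")
    prot_com = prot.com()

    upper, lower, _ = _leaflet_split(phos.coords)
    if upper.sum() < 3 or lower.sum() < 3:
        # effectively a single leaflet: fit everything, orient toward protein
        point, normal, rmsd = _lstsq_plane(phos.coords)
        if np.dot(normal, prot_com - point) < 0:
            normal = -normal
        return MembranePlane(point, normal, "proximal", rmsd)

    cent_u = phos.coords[upper].mean(axis=0)
    cent_l = phos.coords[lower].mean(axis=0)
    if np.linalg.norm(prot_com - cent_u) <= np.linalg.norm(prot_com - cent_l):
        prox_mask, distal_centroid = upper, cent_l
    else:
        prox_mask, distal_centroid = lower, cent_u
    point, normal, rmsd = _lstsq_plane(phos.coords[prox_mask])
    if np.dot(normal, point - distal_centroid) < 0:
        normal = -normal
    return MembranePlane(point, normal, "proximal", rmsd)


# --------------------------------------------------------------------------
# helical content


def _angle_term(theta_deg: np.ndarray, theta0: float, dtheta: float) -> np.ndarray:
    return 1.0 / (1.0 + ((theta_deg - theta0) / dtheta) ** 2)


def _hbond_term(dist: np.ndarray, d0: float) -> np.ndarray:
    x = dist / d0
    num, den = 1.0 - x**6, 1.0 - x**8
    out = np.where(np.abs(den) < 1e-12, 0.75, num / np.where(den == 0, 1.0, den))
    return out


def _backbone_coords(frame: Frame, residue_range: tuple[int, int],
                     names: Iterable[str]) -> dict[str, np.ndarray]:
    lo, hi = residue_range
    sub = frame.atoms(f"resid {lo}-{hi}")
    res_ids = np.unique(sub.res_ids)
    out: dict[str, np.ndarray] = {}
    for name in names:
        coords = []
        for rid in res_ids:
            mask = (sub.res_ids == rid) & (sub.atom_names == name)
            if not mask.any():
                raise InputError(f"residue {rid} is missing atom {name!r}")
            coords.append(sub.coords[mask][0])
        out[name] = np.asarray(coords)
    out["res_ids"] = res_ids
    return out


def helical_content(
    frame: Frame,
    residue_range: tuple[int, int],
    theta0: float = HLX_THETA0,
    dtheta: float = HLX_DTHETA,
    d0: float = HLX_D0,
) -> float:
    """Helical-content order parameter ``hlx`` of a residue window, in [0, 1].

    hlx = [1/(2(N-2))] sum_k angf(theta_k) + [1/(2(N-4))] sum_k hbf(d_k)

    where theta_k is the CA(k)-CA(k+1)-CA(k+2) bend angle scored by a
    Lorentzian centered at ``theta0`` with half-width ``dtheta``, and d_k is
    the O(k)...N(k+4) hydrogen-bond distance scored by the rational
    switching function (1-(d/d0)^6)/(1-(d/d0)^8).  An ideal alpha-helix
    scores near 1, an extended chain near 0.
    """
    bb = _backbone_coords(frame, residue_range, ("CA", "O", "N"))
    ca, o, n = bb["CA"], bb["O"], bb["N"]
    n_res = len(ca)
    if n_res < 5:
        raise InputError("helical content needs at least 5 residues "
                         "(the O(i)...N(i+4) term is undefined below that)")
    v1 = ca[:-2] - ca[1:-1]
    v2 = ca[2:] - ca[1:-1]
    cosang = np.einsum("ij,ij->i", v1, v2) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
    )
    theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ang_sum = _angle_term(theta, theta0, dtheta).sum()
    hb_dist = np.linalg.norm(o[: n_res - 4] - n[4:], axis=1)
    hb_sum = _hbond_term(hb_dist, d0).sum()
    hlx = ang_sum / (2.0 * (n_res - 2)) + hb_sum / (2.0 * (n_res - 4))
    return float(np.clip(hlx, 0.0, 1.0))


def helix_tilt(frame: Frame, residue_range: tuple[int, int],
               plane: MembranePlane) -> float:
    """Tilt angle (degrees, in [0, 90]) between a helix axis and the membrane
    surface; 0 deg means parallel to the surface.

    The axis is the dominant principal direction of the centered CA
    coordinates of ``residue_range``, oriented N-to-C; the reported angle is
    unsigned.
    """
    lo, hi = residue_range
    ca = frame.atoms(f"resid {lo}-{hi} and name CA")
    if ca.n_atoms < 3:
        raise InputError("helix tilt needs at least 3 CA atoms")
    axis = principal_axis(ca.coords)
    s = np.clip(np.abs(np.dot(axis, plane.normal)), 0.0, 1.0)
    return float(np.degrees(np.arcsin(s)))


def insertion_depth(frame: Frame, residue_range: tuple[int, int],
                    plane: MembranePlane) -> float:
    """Signed height d (A) of the residue-range center of mass above the
    proximal headgroup plane; d < 0 lies below the lipid headgroups."""
    lo, hi = residue_range
    sel = frame.atoms(f"resid {lo}-{hi}")
    if sel.n_atoms == 0:
        raise InputError("insertion depth: empty residue selection")
    com = sel.com()
    return float(np.dot(com - plane.point, plane.normal))


# --------------------------------------------------------------------------
# time series and binned statistics


@dataclass
class GeomSeries:
    """A per-frame geometric observable over a trajectory."""

    name: str
    times_ps: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_ps.shape != self.values.shape:
            raise InputError("times and values must have equal length")
        if len(self.times_ps) and np.any(np.diff(self.times_ps) <= 0):
            raise InputError("times must be strictly increasing")


@dataclass
class BinnedSeries:
    """Non-overlapping time-bin means and population s.d. bands."""

    name: str
    bin_centers_ns: np.ndarray
    bin_means: np.ndarray
    bin_sds: np.ndarray
    bin_counts: np.ndarray
    bin_width_ns: float


def bin_series(series: GeomSeries, bin_width_ns: float = 0.5) -> BinnedSeries:
    """Average a series over non-overlapping time bins.

    Bins are anchored at the first sample time; the band s.d. uses the
    population convention (divide by n).  Partial trailing bins are
    reported with their true counts.
    """
    if len(series.times_ps) == 0:
        raise InputError("cannot bin an empty series")
    if bin_width_ns <= 0:
        raise InputError("bin width must be positive")
    t_ns = series.times_ps / 1000.0
    idx = np.floor((t_ns - t_ns[0]) / bin_width_ns + 1e-9).astype(int)
    n_bins = idx.max() + 1
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=series.values, minlength=n_bins)
    sq = np.bincount(idx, weights=series.values**2, minlength=n_bins)
    centers = t_ns[0] + (np.arange(n_bins) + 0.5) * bin_width_ns
    occupied = counts > 0  # only bins that contain frames are reported
    counts = counts[occupied]
    means = sums[occupied] / counts
    var = np.maximum(sq[occupied] / counts - means**2, 0.0)
    return BinnedSeries(series.name, centers[occupied], means, np.sqrt(var),
                        counts, bin_width_ns)


def summarize_window(binned: BinnedSeries, last_ns: float) -> tuple[float, float, int]:
    """Mean, sample s.d. and count of binned values in the trailing window.

    The window covers bin centers strictly within ``last_ns`` of the final
    bin center (inclusive of the final bin).
    """
    centers = binned.bin_centers_ns
    span = centers[-1] - centers[0] + binned.bin_width_ns
    if last_ns > span + 1e-9:
        raise InputError(f"window {last_ns} ns exceeds series span {span:g} ns")
    cutoff = centers[-1] - last_ns
    mask = centers > cutoff + 1e-9
    vals = binned.bin_means[mask]
    n = int(mask.sum())
    sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
    return float(np.mean(vals)), sd, n


def measure_trajectory(
    traj: Trajectory,
    hlx_range: tuple[int, int] = (436, 488),
    helix_range: tuple[int, int] = (460, 474),
    phosphate_selection: Selection = "element P",
    protein_selection: Selection = "chain A",
    probe_radius: float = 1.4,
    n_points: int = 960,
    sasa_stride: int = 1,
) -> dict[str, GeomSeries]:
    """Compute hlx, theta, d and buried-SASA series over a trajectory.

    Buried SASA (the most expensive observable) may be evaluated on every
    ``sasa_stride``-th frame.
    """
    from .sasa import buried_sasa

    times = traj.times_ps
    hlx, theta, depth = [], [], []
    sasa_t, sasa_v = [], []
    for i, frame in enumerate(traj):
        plane = fit_membrane_plane(frame, phosphate_selection, protein_selection)
        hlx.append(helical_content(frame, hlx_range))
        theta.append(helix_tilt(frame, helix_range, plane))
        depth.append(insertion_depth(frame, helix_range, plane))
        if i % sasa_stride == 0:
            sasa_t.append(frame.time_ps)
            sasa_v.append(
                buried_sasa(frame, protein_selection, "resname POC CDL ACY",
                            probe_radius, n_points)
            )
    return {
        "hlx": GeomSeries("hlx", times, hlx),
        "theta": GeomSeries("theta", times, theta),
        "d": GeomSeries("d", times, depth),
        "sasa_buried": GeomSeries("sasa_buried", np.array(sasa_t), sasa_v),
    }
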