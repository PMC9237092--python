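"""Enzymology, circular dichroism, and translocation quantitation.

Covers: initial-rate extraction from absorbance kinetic traces and
conversion to specific activity (U/mg) via Beer-Lambert with the
ferrocenium molar absorptivity (eps = 4.3 mM^-1 cm^-1 at 300 nm by
default); mean residue ellipticity and a two-reference fractional
helicity estimate at 222 nm; and densitometry-based quantitation of the
protein fraction co-eluting with liposomes in SEC translocation assays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import f as f_dist

from .constants import THETA_COIL_222, THETA_HELIX_222
from .errors import InputError


@dataclass
class KineticTrace:
    """Absorbance (AU) vs time (min) with assay metadata."""

    times_min: np.ndarray
    absorbance_AU: np.ndarray
    epsilon_mM_cm: float = 4.3
    path_cm: float = 1.0
    reaction_volume_L: float = 150e-6
    enzyme_mass_mg: float = 1.0

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.absorbance_AU = np.asarray(self.absorbance_AU, dtype=float)
        if self.times_min.shape != self.absorbance_AU.shape:
            raise InputError("times and absorbance must have equal length")
        if len(self.times_min) and np.any(np.diff(self.times_min) <= 0):
            raise InputError("times must be strictly increasing")
        for name in ("epsilon_mM_cm", "path_cm", "reaction_volume_L",
                     "enzyme_mass_mg"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")


@dataclass
class ActivityResult:
    slope_AU_per_min: float
    window: tuple[int, int]  # inclusive sample-index window
    r_squared: float
    activity_U_per_mg: float
    fallback: bool = False


@dataclass
class CDSpectrum:
    """Observed ellipticity (mdeg) vs wavelength (nm)."""

    wavelengths_nm: np.ndarray
    ellipticity_mdeg: np.ndarray
    concentration_M: float
    path_cm: float
    n_residues: int
    masked: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.ellipticity_mdeg = np.asarray(self.ellipticity_mdeg, dtype=float)
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise InputError("wavelengths must be strictly increasing")
        if self.masked is None:
            self.masked = np.zeros(len(self.wavelengths_nm), dtype=bool)
        self.masked = np.asarray(self.masked, dtype=bool)


@dataclass
class FractionProfile:
    """Gel-densitometry band intensities across SEC fractions."""

    fractions: np.ndarray
    intensities: np.ndarray
    liposome_positive: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=int)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.liposome_positive = np.asarray(self.liposome_positive, dtype=int)
        if len(np.unique(self.fractions)) != len(self.fractions):
            raise InputError("fraction indices must be unique")
        if np.any(self.intensities < 0):
            raise InputError("band intensities must be non-negative")


# --------------------------------------------------------------------------
# enzyme kinetics


def _window_stats(t: np.ndarray, y: np.ndarray):
    """Slope and r^2 of the least-squares line through (t, y)."""
    tm, ym = t.mean(), y.mean()
    st = t - tm
    ss_t = np.dot(st, st)
    slope = np.dot(st, y - ym) / ss_t
    resid = y - ym - slope * st
    ss_res = np.dot(resid, resid)
    ss_tot = np.dot(y - ym, y - ym)
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return slope, r2


def _curvature_detected(t: np.ndarray, y: np.ndarray, alpha: float) -> bool:
    """F-test: does a quadratic term significantly improve on the line?

    The r^2 criterion alone is insensitive when noise is low (a gently
    curving window can keep r^2 above any fixed threshold while biasing
    the slope), so candidate windows with statistically detectable
    curvature are rejected as not linear.
    """
    n = len(t)
    if n < 4:
        return False
    X1 = np.column_stack([np.ones(n), t])
    X2 = np.column_stack([np.ones(n), t, t**2])
    rss1 = np.sum((y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]) ** 2)
    rss2 = np.sum((y - X2 @ np.linalg.lstsq(X2, y, rcond=None)[0]) ** 2)
    scale = float(np.abs(y).max()) + 1.0
    if rss1 <= 1e-18 * n * scale**2:  # numerically perfect line
        return False
    if rss2 <= 0:
        return True
    f_stat = (rss1 - rss2) / (rss2 / (n - 3))
    return f_stat > f_dist.ppf(1.0 - alpha, 1, n - 3)


def find_linear_region(
    trace: KineticTrace,
    min_points: int = 5,
    r2_threshold: float = 0.99,
    curvature_alpha: float = 0.05,
) -> tuple[tuple[int, int], float, float, bool]:
    """Earliest maximal-length linear window of a kinetic trace.

    A window qualifies when its least-squares fit reaches the r^2
    threshold and shows no statistically detectable curvature (quadratic
    F-test at ``curvature_alpha``); candidate windows are scanned from
    the longest down and, within a length, from the trace start.
    Returns ``(window, slope, r2, fallback)`` with an inclusive
    sample-index window.  If nothing qualifies, the best ``min_points``
    window is returned with ``fallback=True``.  A constant trace counts
    as perfectly linear.
    """
    t, y = trace.times_min, trace.absorbance_AU
    n = len(t)
    if n < min_points:
        raise InputError(f"trace has fewer than min_points={min_points} samples")
    best_fallback = None
    for length in range(n, min_points - 1, -1):
        for start in range(0, n - length + 1):
            sl = slice(start, start + length)
            slope, r2 = _window_stats(t[sl], y[sl])
            if r2 >= r2_threshold and not _curvature_detected(
                    t[sl], y[sl], curvature_alpha):
                return (start, start + length - 1), float(slope), float(r2), False
            if length == min_points and (best_fallback is None or r2 > best_fallback[2]):
                best_fallback = ((start, start + length - 1), float(slope), float(r2))
    window, slope, r2 = best_fallback
    return window, slope, r2, True


def activity_u_per_mg(
    slope_AU_per_min: float,
    epsilon_mM_cm: float = 4.3,
    path_cm: float = 1.0,
    reaction_volume_L: float = 150e-6,
    enzyme_mass_mg: float = 1.0,
    stoichiometry: float = 1.0,
) -> float:
    """Specific activity (U/mg) from an initial-rate slope.

    1 U = 1 umol acceptor reduced per minute.  Beer-Lambert converts the
    absorbance rate to a concentration rate, |slope| / (eps * path) in
    mM/min = 1000 uM/min; multiplied by the reaction volume this is
    umol/min, scaled by ``stoichiometry`` (electrons transferred per
    substrate oxidation, default 1 = per acceptor reduced) and divided by
    the enzyme mass.
    """
    if not np.isfinite(slope_AU_per_min):
        raise InputError("slope must be finite")
    for name, v in (("epsilon", epsilon_mM_cm), ("path", path_cm),
                    ("volume", reaction_volume_L), ("mass", enzyme_mass_mg)):
        if v <= 0:
            raise InputError(f"{name} must be positive")
    rate_uM_per_min = abs(slope_AU_per_min) / (epsilon_mM_cm * path_cm) * 1000.0
    umol_per_min = rate_uM_per_min * reaction_volume_L
    return umol_per_min * stoichiometry / enzyme_mass_mg


def trace_activity(trace: KineticTrace, min_points: int = 5,
                   r2_threshold: float = 0.99,
                   stoichiometry: float = 1.0) -> ActivityResult:
    """Full pipeline: linear region -> slope -> specific activity."""
    window, slope, r2, fallback = find_linear_region(trace, min_points,
                                                     r2_threshold)
    activity = activity_u_per_mg(slope, trace.epsilon_mM_cm, trace.path_cm,
                                 trace.reaction_volume_L,
                                 trace.enzyme_mass_mg, stoichiometry)
    return ActivityResult(slope, window, r2, activity, fallback)


# --------------------------------------------------------------------------
# circular dichroism


def mean_residue_ellipticity(spectrum: CDSpectrum) -> np.ndarray:
    """Mean residue ellipticity [theta] (deg cm^2 dmol^-1) per wavelength.

    [theta] = theta_mdeg / (10 * path_cm * concentration_M * n_residues);
    masked wavelengths propagate as NaN.
    """
    if spectrum.concentration_M <= 0 or spectrum.path_cm <= 0 \
            or spectrum.n_residues <= 0:
        raise InputError("concentration, path and residue count must be positive")
    mre = spectrum.ellipticity_mdeg / (
        10.0 * spectrum.path_cm * spectrum.concentration_M * spectrum.n_residues)
    return np.where(spectrum.masked, np.nan, mre)


def fractional_helicity(
    spectrum: CDSpectrum,
    theta_helix_222: float = THETA_HELIX_222,
    theta_coil_222: float = THETA_COIL_222,
) -> float:
    """Fractional helicity from [theta] at 222 nm, clamped to [0, 1].

    f = ([theta]222 - [theta]coil) / ([theta]helix - [theta]coil).  The
    helix/coil reference values are nominal package constants, so the
    absolute value is a nominal scale; ratios between samples analyzed
    with the same references are the supported comparison.
    """
    mre = mean_residue_ellipticity(spectrum)
    idx = np.flatnonzero(np.isclose(spectrum.wavelengths_nm, 222.0, atol=0.5))
    if len(idx) == 0:
        raise InputError("222 nm is absent from the spectrum")
    i = idx[np.argmin(np.abs(spectrum.wavelengths_nm[idx] - 222.0))]
    if spectrum.masked[i] or np.isnan(mre[i]):
        raise InputError("222 nm is masked in the spectrum")
    f = (mre[i] - theta_coil_222) / (theta_helix_222 - theta_coil_222)
    return float(np.clip(f, 0.0, 1.0))


def relative_helicity(values: dict[str, float]) -> dict[str, float]:
    """Helicity values normalized so the smallest equals 1, one decimal.

    E.g. ``{"WT": 0.50, "A450P": 0.34, "L462P": 0.20}`` normalizes to
    2.5 : 1.7 : 1.
    """
    if not values:
        raise InputError("no values given")
    if any(v <= 0 for v in values.values()):
        raise InputError("all helicity values must be positive")
    vmin = min(values.values())
    return {k: round(v / vmin, 1) for k, v in values.items()}


def format_helicity_ratio(values: dict[str, float]) -> str:
    """Ratio string like ``2.5:1.7:1`` (reference sample prints as 1)."""
    rel = relative_helicity(values)
    parts = []
    for v in rel.values():
        parts.append("1" if v == 1.0 else f"{v:.1f}")
    return ":".join(parts)


# --------------------------------------------------------------------------
# translocation


def translocation_fraction(profile: FractionProfile) -> tuple[float, np.ndarray]:
    """Fraction of protein signal co-eluting with liposome-positive fractions.

    Returns ``(fraction, distribution)`` where distribution is the full
    per-fraction normalized intensity profile (sums to 1).
    """
    total = profile.intensities.sum()
    if total <= 0:
        raise InputError("total band intensity must be positive")
    dist = profile.intensities / total
    mask = np.isin(profile.fractions, profile.liposome_positive)
    return float(dist[mask].sum()), dist
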