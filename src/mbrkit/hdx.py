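"""Peptide-level HDX-MS analysis.

Centroid masses of isotopic envelopes, relative deuterium uptake
(labeled minus undeuterated centroid, reported uncorrected for back
exchange), state-difference tables with a fixed-magnitude
meaningfulness threshold (default: |delta| strictly above 0.5 Da), and
EX1/EX2 kinetic classification of envelopes by competitive 1- vs
2-component Gaussian mixture fits.

No multiple-testing correction is applied: the difference analysis uses
a fixed-magnitude rule rather than a statistical test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .constants import PROTON_MASS
from .errors import InputError

DEFAULT_THRESHOLD_DA = 0.5

#: EX1 call defaults; the field offers no quantitative convention, so these
#: are package choices, exposed as parameters.
DEFAULT_MIN_SEPARATION_DA = 1.0
DEFAULT_MIN_FRACTION = 0.1
DEFAULT_SCORE_MARGIN = 10.0
DEFAULT_DIP_RATIO = 0.7


@dataclass
class PeptideEnvelope:
    """Isotopic envelope of one peptide at one labeling timepoint."""

    start: int
    end: int
    sequence: str
    charge: int
    timepoint_s: float
    state: str
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.charge < 1:
            raise InputError("charge must be a positive integer")
        if len(self.mz) < 3:
            raise InputError("envelope needs at least 3 points")
        if len(self.mz) != len(self.intensity):
            raise InputError("m/z and intensity lengths differ")
        if np.any(np.diff(self.mz) <= 0):
            raise InputError("m/z values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise InputError("intensities must be non-negative")
        if not np.any(self.intensity > 0):
            raise InputError("envelope intensities are all zero")

    @property
    def peptide_key(self) -> tuple:
        return (self.start, self.end, self.sequence, self.charge)


@dataclass
class UptakeRecord:
    """Relative deuterium uptake of one peptide at one timepoint."""

    start: int
    end: int
    sequence: str
    charge: int
    state: str
    timepoint_s: float
    uptake_Da: float


@dataclass
class DifferenceRecord:
    """Per-peptide uptake difference between two states."""

    start: int
    end: int
    sequence: str
    charge: int
    timepoint_s: float
    delta_Da: float
    meaningful: bool


@dataclass
class DifferenceResult:
    records: list[DifferenceRecord]
    unmatched_a: list[tuple]
    unmatched_b: list[tuple]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


@dataclass
class Ex1Call:
    """EX1/EX2 classification of one envelope."""

    start: int
    end: int
    sequence: str
    charge: int
    timepoint_s: float
    classification: str  # EX1 | EX2 | indeterminate
    component_means_Da: tuple[float, ...] = ()
    weights: tuple[float, ...] = ()
    separation_Da: float = 0.0
    score_1comp: float = float("nan")
    score_2comp: float = float("nan")


def centroid_mass(envelope: PeptideEnvelope) -> float:
    """Intensity-weighted centroid of an envelope as a neutral mass (Da)."""
    total = envelope.intensity.sum()
    centroid_mz = float(np.dot(envelope.mz, envelope.intensity) / total)
    return centroid_mz * envelope.charge - envelope.charge * PROTON_MASS


def relative_uptake(labeled: PeptideEnvelope,
                    undeuterated: PeptideEnvelope) -> UptakeRecord:
    """Relative deuterium uptake: labeled minus undeuterated centroid mass.

    No back-exchange correction is applied; values are relative levels.
    """
    if labeled.peptide_key != undeuterated.peptide_key:
        raise InputError("labeled and undeuterated envelopes describe "
                         "different peptides or charge states")
    uptake = centroid_mass(labeled) - centroid_mass(undeuterated)
    return UptakeRecord(labeled.start, labeled.end, labeled.sequence,
                        labeled.charge, labeled.state, labeled.timepoint_s,
                        uptake)


def uptake_table(envelopes: list[PeptideEnvelope]) -> pd.DataFrame:
    """Uptake records for every labeled envelope, referenced to the
    ``timepoint_s == 0`` envelope of the same peptide and state."""
    refs = {}
    for env in envelopes:
        if env.timepoint_s == 0:
            refs[(env.peptide_key, env.state)] = env
    rows = []
    for env in envelopes:
        if env.timepoint_s == 0:
            continue
        ref = refs.get((env.peptide_key, env.state))
        if ref is None:
            raise InputError(f"no undeuterated reference for peptide "
                             f"{env.start}-{env.end} state {env.state!r}")
        rows.append(vars(relative_uptake(env, ref)))
    return pd.DataFrame(rows)


_MATCH_KEY = ["start", "end", "sequence", "charge", "timepoint_s"]


def difference_table(
    state_a: pd.DataFrame,
    state_b: pd.DataFrame,
    threshold_Da: float = DEFAULT_THRESHOLD_DA,
) -> DifferenceResult:
    """Per-peptide uptake differences (state A minus state B).

    Peptides are matched exactly on (start, end, sequence, charge,
    timepoint); unmatched entries are reported, never silently dropped.
    A difference is flagged meaningful when |delta| is strictly greater
    than ``threshold_Da``.  With A the perturbed (e.g. liposome-bound)
    state, negative deltas indicate protection in A relative to B.
    """
    a = pd.DataFrame(state_a)
    b = pd.DataFrame(state_b)
    merged = a.merge(b, on=_MATCH_KEY, how="outer", suffixes=("_a", "_b"),
                     indicator=True)
    matched = merged[merged["_merge"] == "both"]
    if len(matched) == 0:
        raise InputError("no matched peptide/timepoint pairs between states")
    records = []
    for _, row in matched.sort_values(["start", "end", "timepoint_s"]).iterrows():
        delta = float(row["uptake_Da_a"] - row["uptake_Da_b"])
        records.append(DifferenceRecord(
            int(row["start"]), int(row["end"]), row["sequence"],
            int(row["charge"]), float(row["timepoint_s"]), delta,
            abs(delta) > threshold_Da))
    unmatched_a = [tuple(r) for r in
                   merged.loc[merged["_merge"] == "left_only", _MATCH_KEY].itertuples(index=False)]
    unmatched_b = [tuple(r) for r in
                   merged.loc[merged["_merge"] == "right_only", _MATCH_KEY].itertuples(index=False)]
    return DifferenceResult(records, unmatched_a, unmatched_b)


# --------------------------------------------------------------------------
# EX1 / EX2 classification


def _gauss(mz, amp, mu, sigma):
    return amp * np.exp(-((mz - mu) ** 2) / (2.0 * sigma**2))


def _fit_mixture(mz, inten, n_comp, seeds_rng):
    """Least-squares fit of a 1- or 2-Gaussian model with shared width.

    Multi-start: means at the 25th/75th intensity-weighted percentiles
    plus three seeded random restarts.  Returns (rss, params) or None.
    """
    w = inten / inten.sum()
    mean = float(np.dot(mz, w))
    sd = float(np.sqrt(np.dot((mz - mean) ** 2, w))) or (mz[-1] - mz[0]) / 4
    cdf = np.cumsum(w)
    q25 = float(np.interp(0.25, cdf, mz))
    q75 = float(np.interp(0.75, cdf, mz))
    amp0 = float(inten.max())
    span = mz[-1] - mz[0]

    if n_comp == 1:
        starts = [(amp0, mean, sd)]
        lo = [0.0, mz[0], 1e-3]
        hi = [np.inf, mz[-1], span]

        def resid(p):
            return _gauss(mz, *p) - inten
    else:
        starts = [(amp0, q25, amp0, q75, sd)]
        for _ in range(3):
            m1, m2 = np.sort(seeds_rng.uniform(mz[0], mz[-1], 2))
            starts.append((amp0, m1, amp0, m2, sd))
        lo = [0.0, mz[0], 0.0, mz[0], 1e-3]
        hi = [np.inf, mz[-1], np.inf, mz[-1], span]

        def resid(p):
            return _gauss(mz, p[0], p[1], p[4]) + _gauss(mz, p[2], p[3], p[4]) - inten

    best = None
    for p0 in starts:
        p0 = np.clip(p0, lo, hi)
        try:
            fit = least_squares(resid, p0, bounds=(lo, hi), max_nfev=2000)
        except Exception:
            continue
        rss = float(np.sum(fit.fun**2))
        if best is None or rss < best[0]:
            best = (rss, fit.x)
    return best


def _aic(rss: float, n: int, k: int) -> float:
    return n * np.log(max(rss, 1e-300) / n) + 2.0 * k


def _has_dip(env: PeptideEnvelope, mu1: float, mu2: float,
             dip_ratio: float) -> bool:
    """True when the envelope shows a genuine valley between two modes.

    The minimum intensity at peak positions strictly between the fitted
    component means must fall below ``dip_ratio`` times the smaller of the
    two flanking mode heights.  Distinguishes true bimodality from a
    2-component fit that is merely absorbing skew of a unimodal envelope
    (which has no interior valley).
    """
    lo, hi = sorted((mu1, mu2))
    half = 0.6 / env.charge  # mode height window, ~isotope spacing
    h1 = env.intensity[np.abs(env.mz - lo) <= half]
    h2 = env.intensity[np.abs(env.mz - hi) <= half]
    between = env.intensity[(env.mz > lo + half) & (env.mz < hi - half)]
    if len(h1) == 0 or len(h2) == 0 or len(between) == 0:
        return False
    return float(between.min()) < dip_ratio * min(float(h1.max()),
                                                  float(h2.max()))


def detect_ex1(
    envelopes: list[PeptideEnvelope],
    min_separation_Da: float = DEFAULT_MIN_SEPARATION_DA,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    score_margin: float = DEFAULT_SCORE_MARGIN,
    dip_ratio: float = DEFAULT_DIP_RATIO,
) -> list[Ex1Call]:
    """Classify envelopes as EX1 (bimodal), EX2 (unimodal) or indeterminate.

    For each envelope a 1-component and a 2-component Gaussian mixture
    (shared width) are fit by least squares; the 2-component model is
    preferred when its information-criterion score improves on the
    1-component score by more than ``score_margin``.  An EX1 call
    additionally requires component separation >= ``min_separation_Da``,
    a minor-component weight >= ``min_fraction``, and a real valley
    between the two modes (intensity dropping below ``dip_ratio`` of the
    smaller mode) so that skewed unimodal envelopes are not miscalled.
    Envelopes whose fits fail to converge are flagged indeterminate, not
    raised.
    """
    if not envelopes:
        raise InputError("at least one envelope is required")
    calls = []
    for env in envelopes:
        rng = np.random.default_rng(0)
        fit1 = _fit_mixture(env.mz, env.intensity, 1, rng)
        fit2 = _fit_mixture(env.mz, env.intensity, 2, rng)
        base = Ex1Call(env.start, env.end, env.sequence, env.charge,
                       env.timepoint_s, "indeterminate")
        if fit1 is None or fit2 is None:
            calls.append(base)
            continue
        n = len(env.mz)
        s1 = _aic(fit1[0], n, 3)
        s2 = _aic(fit2[0], n, 5)
        a1, m1, a2, m2, _ = fit2[1]
        total = a1 + a2
        if total <= 0:
            calls.append(base)
            continue
        weights = (float(a1 / total), float(a2 / total))
        separation = float(abs(m2 - m1) * env.charge)
        two_preferred = (s1 - s2) > score_margin
        is_ex1 = (two_preferred and separation >= min_separation_Da
                  and min(weights) >= min_fraction
                  and _has_dip(env, m1, m2, dip_ratio))
        means_da = (float(m1 * env.charge - env.charge * PROTON_MASS),
                    float(m2 * env.charge - env.charge * PROTON_MASS))
        calls.append(Ex1Call(env.start, env.end, env.sequence, env.charge,
                             env.timepoint_s,
                             "EX1" if is_ex1 else "EX2",
                             means_da, weights, separation,
                             float(s1), float(s2)))
    return calls


# --------------------------------------------------------------------------
# table I/O

ENVELOPE_COLUMNS = ["start", "end", "sequence", "charge", "timepoint_s",
                    "state", "mz", "intensity"]


def envelopes_to_frame(envelopes: list[PeptideEnvelope]) -> pd.DataFrame:
    """Long-format table (one row per envelope point)."""
    rows = []
    for env in envelopes:
        for m, i in zip(env.mz, env.intensity):
            rows.append((env.start, env.end, env.sequence, env.charge,
                         env.timepoint_s, env.state, m, i))
    return pd.DataFrame(rows, columns=ENVELOPE_COLUMNS)


def envelopes_from_frame(df: pd.DataFrame) -> list[PeptideEnvelope]:
    envs = []
    keys = ["start", "end", "sequence", "charge", "timepoint_s", "state"]
    for key, grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("mz")
        envs.append(PeptideEnvelope(int(key[0]), int(key[1]), key[2],
                                    int(key[3]), float(key[4]), str(key[5]),
                                    grp["mz"].to_numpy(),
                                    grp["intensity"].to_numpy()))
    return envs
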