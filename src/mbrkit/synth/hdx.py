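"""Synthetic peptide-level HDX-MS isotopic envelopes and uptake tables.

Deuterium uptake follows per-residue intrinsic exchange rates slowed by
protection factors.  In the EX2 regime every amide exchanges
independently, so the envelope shifts gradually: it is the peptide's
natural isotope distribution convolved with a Poisson-binomial
deuteration distribution.  In the EX1 regime a cooperative opening event
converts molecules from a protected (closed) to an exchange-competent
(open) population, producing a bimodal envelope whose open-state weight
grows as f(t) = open_fraction * (1 - exp(-k_open * t)).

The maximum-exchange plateau is set by the D2O fraction of the labeling
reaction (default 17/18, i.e. an 18-fold dilution into deuterated
buffer); back-exchange is not simulated, matching the convention of
reporting relative (uncorrected) deuterium levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from pyteomics import mass as pmass

from .. import constants as C
from ..errors import InputError
from ..hdx import PeptideEnvelope

RateMap = Union[float, Mapping[int, float], Sequence[float]]


@dataclass
class Ex1Kinetics:
    """Cooperative-opening kinetics for the EX1 regime."""

    k_open_per_min: float = 0.5
    open_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.k_open_per_min < 0:
            raise InputError("k_open must be non-negative")
        if not 0.0 <= self.open_fraction <= 1.0:
            raise InputError("open_fraction must lie in [0, 1]")


@dataclass
class HDXSimSpec:
    """Simulation specification for a set of peptides.

    ``k_int`` (1/min) and ``P`` (dimensionless, >= 1) may be scalars, maps
    from absolute residue id to value, or per-protein sequences indexed by
    residue id - 1.  ``timepoints_s`` default to the 10 s / 1 m / 10 m / 1 h
    labeling series.  ``noise_sd`` is Gaussian intensity noise relative to
    the base peak.
    """

    peptides: list[tuple[int, int, str]] = field(default_factory=list)
    k_int: RateMap = 10.0
    P: RateMap = 1.0
    timepoints_s: tuple[float, ...] = (10.0, 60.0, 600.0, 3600.0)
    mode: str = "EX2"
    ex1: Ex1Kinetics | None = None
    d2o_fraction: float = C.DEFAULT_D2O_FRACTION
    charge: int = 1
    noise_sd: float = 0.0
    state: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.peptides:
            raise InputError("at least one peptide is required")
        for start, end, seq in self.peptides:
            if end - start + 1 != len(seq):
                raise InputError(f"peptide {start}-{end} length mismatch with sequence")
        if any(t <= 0 for t in self.timepoints_s):
            raise InputError("timepoints must be positive")
        if self.mode not in ("EX2", "EX1"):
            raise InputError("mode must be 'EX2' or 'EX1'")
        if self.mode == "EX1" and self.ex1 is None:
            self.ex1 = Ex1Kinetics()
        if not 0.0 <= self.d2o_fraction <= 1.0:
            raise InputError("d2o_fraction must lie in [0, 1]")


def _per_residue(value: RateMap, start: int, seq: str, name: str) -> np.ndarray:
    n = len(seq)
    if np.isscalar(value):
        arr = np.full(n, float(value))
    elif isinstance(value, Mapping):
        arr = np.array([float(value.get(start + i, np.nan)) for i in range(n)])
        if np.isnan(arr).any():
            raise InputError(f"{name} missing for some residues of peptide at {start}")
    else:
        seqv = np.asarray(value, dtype=float)
        arr = seqv[start - 1 : start - 1 + n]
        if len(arr) != n:
            raise InputError(f"{name} array does not cover peptide at {start}")
    return arr


def exchangeable_mask(sequence: str) -> np.ndarray:
    """Amides that can retain label: non-proline, non-N-terminal residues."""
    mask = np.array([r != "P" for r in sequence])
    mask[0] = False
    return mask


def natural_isotope_distribution(sequence: str) -> tuple[np.ndarray, np.ndarray]:
    """Aggregated natural isotopologue masses and abundances of a peptide.

    Returns neutral monoisotopic-anchored peak masses (Da) and normalized
    abundances, aggregated on the neutron-count grid.
    """
    comp = pmass.Composition(sequence=sequence)
    dist = np.array([1.0])
    for element, count in comp.items():
        isotopes = pmass.nist_mass[element]
        keys = sorted(k for k in isotopes if k != 0 and isotopes[k][1] > 0)
        single = np.zeros(keys[-1] - keys[0] + 1)
        for k in keys:
            single[k - keys[0]] = isotopes[k][1]
        for _ in range(count):
            dist = np.convolve(dist, single)
            keep = dist > 1e-10
            last = np.nonzero(keep)[0][-1]
            dist = dist[: last + 1]
    dist = dist / dist.sum()
    mono = pmass.calculate_mass(sequence=sequence)
    masses = mono + np.arange(len(dist)) * C.ISOTOPE_SPACING
    keep = dist > 1e-7
    return masses[keep], dist[keep] / dist[keep].sum()


def poisson_binomial(ps: np.ndarray) -> np.ndarray:
    """Distribution of the number of successes of independent Bernoullis."""
    dist = np.array([1.0])
    for p in ps:
        dist = np.convolve(dist, [1.0 - p, p])
    return dist


def _mix_envelope(
    masses: np.ndarray,
    abundances: np.ndarray,
    deut_dist: np.ndarray,
    charge: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross natural peaks with the deuteration distribution -> m/z envelope.

    Isotopologue/deuteration cross terms landing closer than a typical
    instrument can resolve are merged into single centroided peaks at
    their intensity-weighted position, which leaves the envelope centroid
    exactly unchanged.
    """
    peak_m = masses[:, None] + np.arange(len(deut_dist))[None, :] * C.DEUTERIUM_MASS_SHIFT
    peak_i = abundances[:, None] * deut_dist[None, :]
    mz = (peak_m + charge * C.PROTON_MASS) / charge
    order = np.argsort(mz.ravel())
    mz, inten = mz.ravel()[order], peak_i.ravel()[order]
    tol = 0.3 / charge  # merge what a unit-resolution instrument cannot split
    out_mz: list[float] = []
    out_i: list[float] = []
    for m, ii in zip(mz, inten):
        if out_mz and m - out_mz[-1] < tol:
            w = out_i[-1] + ii
            out_mz[-1] = (out_mz[-1] * out_i[-1] + m * ii) / w
            out_i[-1] = w
        else:
            out_mz.append(float(m))
            out_i.append(float(ii))
    return np.array(out_mz), np.array(out_i)


def simulate_hdx(spec: HDXSimSpec, seed: int = 0):
    """Generate envelopes and a ground-truth uptake table.

    Returns ``(envelopes, uptake)``: a list of :class:`PeptideEnvelope`
    including an undeuterated reference (``timepoint_s = 0``) per peptide,
    and a DataFrame with the expected uptake (Da) per peptide/timepoint.
    """
    rng = np.random.default_rng(seed)
    envelopes: list[PeptideEnvelope] = []
    rows = []
    for start, end, seq in spec.peptides:
        k = _per_residue(spec.k_int, start, seq, "k_int")
        P = _per_residue(spec.P, start, seq, "P")
        if np.any(P < 1.0):
            raise InputError("protection factors must be >= 1")
        ex_mask = exchangeable_mask(seq)
        k_ex, P_ex = k[ex_mask], P[ex_mask]
        n_amides = int(ex_mask.sum())
        masses, abund = natural_isotope_distribution(seq)

        def emit(timepoint_s: float, deut_dist: np.ndarray, uptake_true: float):
            mz, inten = _mix_envelope(masses, abund, deut_dist, spec.charge)
            inten = inten / inten.max()
            # drop peaks far below detectability so intensity noise cannot
            # bias the centroid through a long tail of numerically-zero peaks
            keep = inten > 1e-6
            if keep.sum() < 3:
                keep[np.argsort(inten)[-3:]] = True
            mz, inten = mz[keep], inten[keep]
            if spec.noise_sd > 0:
                inten = np.clip(inten + rng.normal(0, spec.noise_sd, inten.shape), 0, None)
            envelopes.append(PeptideEnvelope(start, end, seq, spec.charge,
                                             timepoint_s, spec.state, mz, inten))
            rows.append({
                "start": start, "end": end, "sequence": seq,
                "charge": spec.charge, "state": spec.state,
                "timepoint_s": timepoint_s, "uptake_true_Da": uptake_true,
                "n_exchangeable": n_amides,
            })

        emit(0.0, np.array([1.0]), 0.0)
        for t_s in spec.timepoints_s:
            t_min = t_s / 60.0
            if spec.mode == "EX2":
                p = spec.d2o_fraction * (1.0 - np.exp(-k_ex * t_min / P_ex))
                deut = poisson_binomial(p)
            else:
                p_open = spec.d2o_fraction * (1.0 - np.exp(-k_ex * t_min))
                p_closed = spec.d2o_fraction * (1.0 - np.exp(-k_ex * t_min / P_ex))
                f_open = spec.ex1.open_fraction * (1.0 - np.exp(-spec.ex1.k_open_per_min * t_min))
                d_open = poisson_binomial(p_open)
                d_closed = poisson_binomial(p_closed)
                n = max(len(d_open), len(d_closed))
                deut = np.zeros(n)
                deut[: len(d_open)] += f_open * d_open
                deut[: len(d_closed)] += (1.0 - f_open) * d_closed
            mean_nd = float(np.dot(np.arange(len(deut)), deut))
            emit(t_s, deut, mean_nd * C.DEUTERIUM_MASS_SHIFT)
    uptake = pd.DataFrame(rows)
    return envelopes, uptake
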