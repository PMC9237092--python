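"""Self-validation studies: parameter recovery, classifier performance,
geometric round trips and oracle comparisons.

These routines regenerate synthetic data with known ground truth and
measure how well the analysis recovers it.  They are used by the test
suite and by the acceptance script; each takes an explicit seed and
problem size so runs are reproducible and scalable.
"""

from __future__ import annotations

import numpy as np

from . import sasa as sasa_mod
from .assays import find_linear_region, fractional_helicity
from .geometry import (fit_membrane_plane, helical_content, helix_tilt,
                       insertion_depth)
from .hdx import detect_ex1
from .synth import (Ex1Kinetics, HDXSimSpec, HelixSpec, MembraneModelSpec,
                    TwoStateModel, build_ideal_helix, make_membrane,
                    simulate_cd, simulate_hdx, simulate_kinetic_trace,
                    simulate_trajectory)


def pose_roundtrip_max_error(tilts=(0.0, 30.0, 60.0),
                             depths=(-5.0, 0.0, 5.0)) -> tuple[float, float]:
    """Max |tilt error| (deg) and |depth error| (A) over a pose grid."""
    from .synth import place_on_membrane

    helix = build_ideal_helix(HelixSpec("A" * 20, start_resid=460))
    membrane = make_membrane(MembraneModelSpec(jitter_sd=0.0), seed=1)
    tilt_err = depth_err = 0.0
    for tilt in tilts:
        for depth in depths:
            frame = place_on_membrane(helix, tilt, depth, membrane, (460, 479))
            plane = fit_membrane_plane(frame, "element P", "chain A")
            tilt_err = max(tilt_err,
                           abs(helix_tilt(frame, (460, 479), plane) - tilt))
            depth_err = max(depth_err,
                            abs(insertion_depth(frame, (460, 479), plane) - depth))
    return tilt_err, depth_err


def helical_content_extremes() -> tuple[float, float]:
    """(hlx of an ideal alpha-helix, hlx of a fully extended chain)."""
    ideal = build_ideal_helix(HelixSpec("A" * 15))
    extended = build_ideal_helix(HelixSpec("A" * 15, phi=180.0, psi=180.0))
    return helical_content(ideal, (1, 15)), helical_content(extended, (1, 15))


def sasa_single_sphere_error(n_points: int = 960) -> float:
    """Relative error vs the analytic sphere area (r_vdw 1.9, probe 1.4)."""
    from .structure import Frame

    frame = Frame(["C"], ["C"], [1], ["UNK"], ["A"], [[0.0, 0.0, 0.0]])
    total = sasa_mod.sasa(frame, 1.4, n_points, {"C": 1.9}).sum()
    exact = 4 * np.pi * 3.3**2
    return abs(total - exact) / exact


def sasa_two_sphere_error(dist: float = 3.5, n_points: int = 960) -> float:
    """Relative error vs the closed-form two-sphere spherical-cap area."""
    from .structure import Frame

    frame = Frame(["C", "C"], ["C", "C"], [1, 2], ["UNK"] * 2, ["A"] * 2,
                  [[0.0, 0.0, 0.0], [dist, 0.0, 0.0]])
    total = sasa_mod.sasa(frame, 1.4, n_points, {"C": 1.9}).sum()
    R = 1.9 + 1.4
    h = R - dist / 2.0
    exact = 2 * (4 * np.pi * R**2 - 2 * np.pi * R * h)
    return abs(total - exact) / exact


def sasa_monte_carlo_error(n_atoms: int = 8, n_samples: int = 40000,
                           seed: int = 1) -> float:
    """Relative disagreement with a Monte-Carlo rejection-sampling oracle."""
    from .structure import Frame

    rng = np.random.default_rng(seed)
    coords = rng.uniform(-3.0, 3.0, size=(n_atoms, 3))
    elements = np.array(["C", "N", "O", "P"] * ((n_atoms + 3) // 4))[:n_atoms]
    frame = Frame(elements, elements, np.arange(1, n_atoms + 1),
                  np.full(n_atoms, "UNK"), np.full(n_atoms, "A"), coords)
    mine = sasa_mod.sasa(frame, 1.4, 960).sum()
    from .constants import VDW_RADII

    inflated = np.array([VDW_RADII[e] for e in elements]) + 1.4
    total = 0.0
    for i in range(n_atoms):
        v = rng.normal(size=(n_samples, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pts = coords[i] + inflated[i] * v
        free = np.ones(n_samples, dtype=bool)
        for j in range(n_atoms):
            if j != i:
                free &= np.sum((pts - coords[j]) ** 2, axis=1) >= inflated[j] ** 2
        total += 4 * np.pi * inflated[i] ** 2 * free.mean()
    return abs(mine - total) / total


def ex1_power_study(n_reps: int = 100, seed: int = 0) -> float:
    """Detection rate on bimodal (EX1) envelopes at >= 2 Da separation.

    The EX1 scenario is a cooperative opening: a fully protected closed
    population and a fully exchanged open one, on short peptides whose
    open-closed centroid separations span ~2-5 Da.
    """
    rng = np.random.default_rng(seed)
    peptides = [(1, 3, "AGL"), (1, 4, "AGLS"), (1, 6, "AGLSFK")]
    hits = total = 0
    for rep in range(n_reps):
        start, end, seq = peptides[rep % len(peptides)]
        spec = HDXSimSpec(peptides=[(start, end, seq)], k_int=50.0, P=1e6,
                          d2o_fraction=1.0, mode="EX1",
                          ex1=Ex1Kinetics(k_open_per_min=0.07),
                          timepoints_s=(600.0,), noise_sd=0.01)
        envelopes, _ = simulate_hdx(spec, seed=int(rng.integers(2**31)))
        call = detect_ex1([e for e in envelopes if e.timepoint_s > 0])[0]
        total += 1
        hits += call.classification == "EX1"
    return hits / total


def ex1_false_positive_study(n_reps: int = 100, seed: int = 0) -> float:
    """False-EX1 rate on unimodal EX2 envelopes across protection levels."""
    rng = np.random.default_rng(seed)
    protections = (10.0, 50.0, 500.0)
    false = total = 0
    for rep in range(n_reps):
        spec = HDXSimSpec(peptides=[(10, 24, "GLSAFDKTAYDLAVK")], k_int=5.0,
                          P=protections[rep % len(protections)],
                          timepoints_s=(60.0,), noise_sd=0.01)
        envelopes, _ = simulate_hdx(spec, seed=int(rng.integers(2**31)))
        call = detect_ex1([e for e in envelopes if e.timepoint_s > 0])[0]
        total += 1
        false += call.classification == "EX1"
    return false / total


def slope_recovery_max_error(n_reps: int = 100, seed: int = 0,
                             slope: float = -0.0215) -> float:
    """Max relative slope error over linear-then-depleting noisy traces."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_reps):
        trace = simulate_kinetic_trace(slope, 1.2, 10.0, 6.0, 0.002,
                                       seed=int(rng.integers(2**31)))
        _, fitted, _, _ = find_linear_region(trace)
        worst = max(worst, abs(fitted - slope) / abs(slope))
    return worst


def cd_recovery_max_error(fractions=(0.2, 0.5, 0.8), seed: int = 0) -> float:
    """Max |f_helix error| of the 222 nm estimator on noisy spectra."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for f in fractions:
        s = simulate_cd(f, noise_sd_mdeg=0.1, seed=int(rng.integers(2**31)),
                        mask_below_nm=217.0)
        worst = max(worst, abs(fractional_helicity(s) - f))
    return worst


def occupancy_deviation(n_frames: int = 4000, k: float = 0.1,
                        seed: int = 7) -> tuple[float, float]:
    """(|occupancy - stationary|, 3 x autocorrelation-corrected s.e.)."""
    model = TwoStateModel(k_hc=k, k_ch=k, noise_sd=0.0, seed=seed)
    helix = HelixSpec("A" * 5)
    membrane = MembraneModelSpec(n_phosphates_per_leaflet=9,
                                 box_xy=(30.0, 30.0), jitter_sd=0.0)
    traj = simulate_trajectory(model, helix, membrane, n_frames)
    occ = float(np.mean(traj.labels["state"]))
    rho = 1.0 - 2 * k
    se = np.sqrt(0.25 / n_frames) * np.sqrt((1 + rho) / (1 - rho))
    return abs(occ - model.stationary_helix_occupancy()), 3 * se


def demo_summary(seed: int = 0, n_frames: int = 640):
    """End-to-end demo at production scale (160 ns of 0.25 ns frames at
    the default count, trailing half summarized); returns the pipeline
    result dict."""
    import tempfile

    from .pipeline import PipelineConfig, run_pipeline

    span_ns = n_frames * 250.0 / 1000.0
    config = PipelineConfig(seed=seed, n_frames=n_frames, dt_ps=250.0,
                            summary_window_ns=span_ns / 2.0, sasa_stride=8)
    with tempfile.TemporaryDirectory() as tmp:
        results = run_pipeline(config, tmp)
    return results
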