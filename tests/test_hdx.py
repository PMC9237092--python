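"""HDX-MS: centroiding, uptake, difference tables, EX1 classification."""

import numpy as np
import pandas as pd
import pytest

from mbrkit.constants import DEFAULT_D2O_FRACTION, DEUTERIUM_MASS_SHIFT, \
    PROTON_MASS
from mbrkit.errors import InputError
from mbrkit.hdx import (PeptideEnvelope, centroid_mass, detect_ex1,
                        difference_table, envelopes_from_frame,
                        envelopes_to_frame, relative_uptake, uptake_table)
from mbrkit.synth import Ex1Kinetics, HDXSimSpec, simulate_hdx

PEPTIDE = (10, 24, "GLSAFDKTAYDLAVK")


def make_envelope(mz, intensity, charge=1, timepoint=60.0, state="s"):
    return PeptideEnvelope(*PEPTIDE, charge, timepoint, state,
                           np.asarray(mz, dtype=float),
                           np.asarray(intensity, dtype=float))


# ------------------------------------------------------------ centroid ----


def test_centroid_of_symmetric_envelope():
    env = make_envelope([799.0, 800.0, 801.0], [0.5, 1.0, 0.5])
    assert centroid_mass(env) == pytest.approx(800.0 - PROTON_MASS, abs=1e-9)


def test_centroid_of_two_equal_peaks():
    env = make_envelope([799.0, 800.0, 801.0], [1.0, 0.0, 1.0])
    assert centroid_mass(env) + PROTON_MASS == pytest.approx(800.0)


def test_centroid_invariant_under_intensity_scaling():
    env1 = make_envelope([799.0, 800.0, 801.5], [0.2, 1.0, 0.4])
    env2 = make_envelope([799.0, 800.0, 801.5], [0.4, 2.0, 0.8])
    assert centroid_mass(env1) == pytest.approx(centroid_mass(env2), abs=1e-12)


def test_centroid_charge_conversion():
    env = make_envelope([400.0, 400.5, 401.0], [0.5, 1.0, 0.5], charge=2)
    assert centroid_mass(env) == pytest.approx(2 * 400.5 - 2 * PROTON_MASS)


def test_invalid_envelopes_rejected():
    with pytest.raises(InputError):
        make_envelope([800.0, 799.0, 801.0], [1, 1, 1])  # not increasing
    with pytest.raises(InputError):
        make_envelope([799.0, 800.0, 801.0], [0, 0, 0])  # all zero
    with pytest.raises(InputError):
        make_envelope([799.0, 800.0], [1, 1])  # too few points


# ------------------------------------------------------------ uptake ------


def test_uptake_zero_for_identical_envelopes():
    env = make_envelope([799.0, 800.0, 801.0], [0.5, 1.0, 0.2])
    ref = make_envelope([799.0, 800.0, 801.0], [0.5, 1.0, 0.2], timepoint=0.0)
    assert relative_uptake(env, ref).uptake_Da == pytest.approx(0.0)


def test_uptake_requires_matching_peptide():
    env = make_envelope([799.0, 800.0, 801.0], [1, 1, 1])
    other = PeptideEnvelope(10, 24, PEPTIDE[2], 2, 0.0, "s",
                            np.array([400.0, 400.5, 401.0]),
                            np.array([1.0, 1.0, 1.0]))
    with pytest.raises(InputError):
        relative_uptake(env, other)


def test_ex2_uptake_recovers_generator_truth():
    """Measured centroid uptake matches the expected-uptake ground truth."""
    spec = HDXSimSpec(peptides=[PEPTIDE], k_int=5.0, P=50.0, noise_sd=0.01)
    envelopes, truth = simulate_hdx(spec, seed=12)
    measured = uptake_table(envelopes)
    expected = truth[truth["timepoint_s"] > 0].reset_index(drop=True)
    assert np.allclose(measured["uptake_Da"], expected["uptake_true_Da"],
                       atol=0.1)


def test_ex2_uptake_monotone_in_time():
    spec = HDXSimSpec(peptides=[PEPTIDE], k_int=2.0, P=30.0)
    envelopes, truth = simulate_hdx(spec, seed=0)
    measured = uptake_table(envelopes).sort_values("timepoint_s")
    assert np.all(np.diff(measured["uptake_Da"]) >= -1e-9)
    t = truth.sort_values("timepoint_s")["uptake_true_Da"]
    assert np.all(np.diff(t) >= 0)


def test_full_protection_gives_zero_uptake():
    spec = HDXSimSpec(peptides=[PEPTIDE], k_int=5.0, P=1e12)
    envelopes, truth = simulate_hdx(spec, seed=0)
    assert np.allclose(truth["uptake_true_Da"], 0.0, atol=1e-6)
    assert np.allclose(uptake_table(envelopes)["uptake_Da"], 0.0, atol=1e-6)


def test_unprotected_uptake_saturates_at_d2o_fraction():
    """P = 1 and t >> 1/k gives D -> d2o_fraction x exchangeable amides."""
    spec = HDXSimSpec(peptides=[PEPTIDE], k_int=50.0, P=1.0,
                      timepoints_s=(36000.0,))
    _, truth = simulate_hdx(spec, seed=0)
    n_ex = truth["n_exchangeable"].iloc[0]
    expected = DEFAULT_D2O_FRACTION * n_ex * DEUTERIUM_MASS_SHIFT
    assert truth["uptake_true_Da"].iloc[-1] == pytest.approx(expected, rel=1e-6)


def test_protection_factor_below_one_rejected():
    with pytest.raises(InputError):
        simulate_hdx(HDXSimSpec(peptides=[PEPTIDE], k_int=5.0, P=0.5), seed=0)


def test_envelope_table_round_trip():
    spec = HDXSimSpec(peptides=[PEPTIDE], k_int=5.0, P=50.0)
    envelopes, _ = simulate_hdx(spec, seed=0)
    back = envelopes_from_frame(envelopes_to_frame(envelopes))
    assert len(back) == len(envelopes)
    key = lambda e: (e.peptide_key, e.timepoint_s)
    for a, b in zip(sorted(envelopes, key=key), sorted(back, key=key)):
        assert np.allclose(a.mz, b.mz)
        assert np.allclose(a.intensity, b.intensity)


# ------------------------------------------------------------ diff --------


def _uptake_frame(state, uptakes):
    rows = []
    for i, u in enumerate(uptakes):
        rows.append({"start": 10 + i, "end": 20 + i, "sequence": "A" * 11,
                     "charge": 1, "state": state, "timepoint_s": 60.0,
                     "uptake_Da": u})
    return pd.DataFrame(rows)


def test_difference_of_identical_states_is_zero():
    a = _uptake_frame("a", [1.0, 2.0, 3.0])
    result = difference_table(a, a.assign(state="b"))
    deltas = [r.delta_Da for r in result.records]
    assert np.allclose(deltas, 0.0)
    assert not any(r.meaningful for r in result.records)


def test_difference_antisymmetry():
    a = _uptake_frame("a", [1.0, 2.5, 0.3])
    b = _uptake_frame("b", [2.0, 1.1, 0.9])
    ab = difference_table(a, b).records
    ba = difference_table(b, a).records
    for r1, r2 in zip(ab, ba):
        assert r1.delta_Da == pytest.approx(-r2.delta_Da)
        assert r1.meaningful == r2.meaningful


@pytest.mark.parametrize("delta,meaningful", [
    (-0.6, True), (0.6, True), (-0.4, False), (0.4, False),
    (0.5, False), (-0.5, False), (0.5000001, True),
])
def test_meaningfulness_threshold_is_strictly_above_half_dalton(delta, meaningful):
    a = _uptake_frame("a", [1.0 + delta])
    b = _uptake_frame("b", [1.0])
    rec = difference_table(a, b).records[0]
    assert rec.meaningful is meaningful


def test_unmatched_pairs_reported_not_dropped():
    a = _uptake_frame("a", [1.0, 2.0])
    b = _uptake_frame("b", [1.0, 2.0, 3.0])
    result = difference_table(a, b)
    assert len(result.records) == 2
    assert len(result.unmatched_b) == 1
    assert result.unmatched_a == []


def test_no_matches_rejected():
    a = _uptake_frame("a", [1.0])
    b = _uptake_frame("b", [1.0]).assign(charge=3)
    with pytest.raises(InputError):
        difference_table(a, b)


def test_records_ordered_by_peptide_start():
    a = _uptake_frame("a", [1.0, 2.0, 3.0]).iloc[::-1]
    b = _uptake_frame("b", [0.0, 0.0, 0.0])
    starts = [r.start for r in difference_table(a, b).records]
    assert starts == sorted(starts)


# ------------------------------------------------------------ EX1 ---------


def test_clean_unimodal_envelope_is_ex2():
    spec = HDXSimSpec(peptides=[PEPTIDE], k_int=5.0, P=50.0, noise_sd=0.005)
    envelopes, _ = simulate_hdx(spec, seed=5)
    calls = detect_ex1([e for e in envelopes if e.timepoint_s > 0])
    assert all(c.classification == "EX2" for c in calls)


def test_bimodal_envelope_detected_with_weights():
    """Separation ~3 Da at open fraction 0.5 is called EX1; weights and the
    envelope's two local maxima are recovered."""
    spec = HDXSimSpec(peptides=[(1, 4, "AGLS")], k_int=50.0, P=1e6,
                      mode="EX1", ex1=Ex1Kinetics(k_open_per_min=0.07),
                      timepoints_s=(600.0,), noise_sd=0.005)
    envelopes, _ = simulate_hdx(spec, seed=8)
    env = [e for e in envelopes if e.timepoint_s > 0][0]
    # two local maxima in the raw envelope
    interior = env.intensity[1:-1]
    n_maxima = int(np.sum((interior > env.intensity[:-2])
                          & (interior > env.intensity[2:])))
    assert n_maxima >= 2
    call = detect_ex1([env])[0]
    assert call.classification == "EX1"
    assert call.separation_Da >= 2.0
    assert abs(min(call.weights) - 0.5) < 0.1


def test_ex1_weights_follow_opening_kinetics():
    k_open = 0.05
    spec = HDXSimSpec(peptides=[(1, 5, "AGLSF")], k_int=50.0, P=1e6,
                      mode="EX1", ex1=Ex1Kinetics(k_open_per_min=k_open),
                      timepoints_s=(600.0,), noise_sd=0.005)
    envelopes, _ = simulate_hdx(spec, seed=2)
    call = detect_ex1([e for e in envelopes if e.timepoint_s > 0])[0]
    f_open = 1.0 - np.exp(-k_open * 10.0)
    assert call.classification == "EX1"
    assert min(call.weights) == pytest.approx(min(f_open, 1 - f_open), abs=0.1)


def test_detect_ex1_requires_envelopes():
    with pytest.raises(InputError):
        detect_ex1([])
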