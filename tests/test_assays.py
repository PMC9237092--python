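"""Enzyme kinetics, CD helicity, translocation quantitation, protocol math."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbrkit import protocol
from mbrkit.assays import (CDSpectrum, FractionProfile, KineticTrace,
                           activity_u_per_mg, find_linear_region,
                           format_helicity_ratio, fractional_helicity,
                           mean_residue_ellipticity, relative_helicity,
                           trace_activity, translocation_fraction)
from mbrkit.constants import THETA_COIL_222, THETA_HELIX_222, cd_coil_basis, \
    cd_helix_basis
from mbrkit.errors import InputError
from mbrkit.synth import simulate_cd, simulate_kinetic_trace


# ------------------------------------------------------------ kinetics ----


def test_perfectly_linear_trace_selected_in_full():
    trace = simulate_kinetic_trace(-0.02, 1.0, 5.0, None, 0.0, 0)
    window, slope, r2, fallback = find_linear_region(trace)
    assert window == (0, len(trace.times_min) - 1)
    assert slope == pytest.approx(-0.02, rel=1e-9)
    assert not fallback


def test_constant_trace_has_zero_slope():
    trace = simulate_kinetic_trace(0.0, 1.0, 5.0, None, 0.0, 0)
    _, slope, _, _ = find_linear_region(trace)
    assert slope == pytest.approx(0.0, abs=1e-12)


def test_depleting_trace_slope_recovered_within_two_percent():
    """Linear 0-6 min then flattening: window stays in the linear part."""
    for seed in range(10):
        trace = simulate_kinetic_trace(-0.0215, 1.2, 10.0, 6.0, 0.002, seed)
        window, slope, _, fallback = find_linear_region(trace)
        assert not fallback
        assert trace.times_min[window[1]] <= 7.1
        assert abs(slope + 0.0215) / 0.0215 < 0.02


def test_activity_arithmetic_with_ferrocenium_absorptivity():
    """slope -4.3e-3 AU/min at eps 4.3 mM^-1 cm^-1 is exactly 1 uM/min."""
    act = activity_u_per_mg(-4.3e-3, epsilon_mM_cm=4.3, path_cm=1.0,
                            reaction_volume_L=1.0, enzyme_mass_mg=1.0)
    assert act == pytest.approx(1.0)  # 1 uM/min x 1 L = 1 umol/min per mg


def test_zero_slope_gives_zero_activity():
    assert activity_u_per_mg(0.0) == 0.0


@settings(max_examples=30, deadline=None)
@given(st.floats(1e-4, 1.0), st.floats(0.1, 10.0))
def test_activity_scaling_laws(slope, mass):
    """Linear in |slope|, inversely linear in enzyme mass."""
    base = activity_u_per_mg(-slope, enzyme_mass_mg=mass)
    assert activity_u_per_mg(-2 * slope, enzyme_mass_mg=mass) == \
        pytest.approx(2 * base, rel=1e-9)
    assert activity_u_per_mg(-slope, enzyme_mass_mg=2 * mass) == \
        pytest.approx(base / 2, rel=1e-9)


def test_trace_activity_round_trip():
    """End-to-end: generated trace with known activity recovered within 2%."""
    slope = -0.0215
    trace = simulate_kinetic_trace(slope, 1.2, 10.0, 6.0, 0.002, seed=5)
    truth = activity_u_per_mg(slope, trace.epsilon_mM_cm, trace.path_cm,
                              trace.reaction_volume_L, trace.enzyme_mass_mg)
    res = trace_activity(trace)
    assert res.activity_U_per_mg == pytest.approx(truth, rel=0.02)


def test_invalid_metadata_rejected():
    with pytest.raises(InputError):
        activity_u_per_mg(-0.01, epsilon_mM_cm=0.0)
    with pytest.raises(InputError):
        KineticTrace([0.0, 1.0], [1.0, 0.9], enzyme_mass_mg=-1.0)


# ------------------------------------------------------------ CD ----------


def test_pure_helix_spectrum_equals_basis():
    s = simulate_cd(1.0, 0.0, 0)
    mre = mean_residue_ellipticity(s)
    assert np.allclose(mre, cd_helix_basis(s.wavelengths_nm), rtol=1e-9)


def test_pure_coil_spectrum_equals_basis():
    s = simulate_cd(0.0, 0.0, 0)
    mre = mean_residue_ellipticity(s)
    assert np.allclose(mre, cd_coil_basis(s.wavelengths_nm), rtol=1e-9)


def test_mre_zero_for_zero_signal():
    s = CDSpectrum(np.arange(200.0, 250.0), np.zeros(50), 1e-5, 0.1, 30)
    assert np.allclose(mean_residue_ellipticity(s), 0.0)


def test_mre_inverse_in_concentration():
    wl = np.arange(200.0, 250.0)
    y = np.linspace(-5, 5, 50)
    s1 = CDSpectrum(wl, y, 1e-5, 0.1, 30)
    s2 = CDSpectrum(wl, y, 2e-5, 0.1, 30)
    assert np.allclose(mean_residue_ellipticity(s2),
                       mean_residue_ellipticity(s1) / 2)


def test_fractional_helicity_reference_points():
    wl = np.array([220.0, 222.0, 224.0])
    def spec_at(theta222):
        mdeg = theta222 * 10 * 0.1 * 2e-5 * 34
        return CDSpectrum(wl, np.full(3, mdeg), 2e-5, 0.1, 34)
    assert fractional_helicity(spec_at(THETA_HELIX_222)) == pytest.approx(1.0)
    assert fractional_helicity(spec_at(THETA_COIL_222)) == pytest.approx(0.0)
    mid = 0.5 * (THETA_HELIX_222 + THETA_COIL_222)
    assert fractional_helicity(spec_at(mid)) == pytest.approx(0.5)


@pytest.mark.parametrize("f", [0.2, 0.5, 0.8])
def test_helicity_recovered_from_noisy_spectrum(f):
    """Estimator recovers the generating helix fraction within 0.05."""
    s = simulate_cd(f, noise_sd_mdeg=0.1, seed=17, mask_below_nm=217.0)
    assert fractional_helicity(s) == pytest.approx(f, abs=0.05)


def test_masked_222_rejected():
    s = simulate_cd(0.5, 0.0, 0, mask_below_nm=222.0)
    with pytest.raises(InputError, match="masked"):
        fractional_helicity(s)


def test_222_absent_rejected():
    s = CDSpectrum(np.arange(240.0, 260.0), np.zeros(20), 1e-5, 0.1, 30)
    with pytest.raises(InputError):
        fractional_helicity(s)


def test_relative_helicity_matches_membrane_bound_ratio():
    rel = relative_helicity({"WT": 0.50, "A450P": 0.34, "L462P": 0.20})
    assert rel == {"WT": 2.5, "A450P": 1.7, "L462P": 1.0}
    assert format_helicity_ratio(
        {"WT": 0.50, "A450P": 0.34, "L462P": 0.20}) == "2.5:1.7:1"


def test_relative_helicity_equal_and_single_values():
    assert relative_helicity({"a": 0.3, "b": 0.3}) == {"a": 1.0, "b": 1.0}
    assert relative_helicity({"only": 0.42}) == {"only": 1.0}


def test_relative_helicity_rejects_nonpositive():
    with pytest.raises(InputError):
        relative_helicity({"a": 0.5, "b": 0.0})


# ------------------------------------------------------------ transloc ----


def test_translocation_all_signal_in_liposome_fractions():
    p = FractionProfile(np.arange(1, 15),
                        np.array([0.0] * 4 + [1.0, 2.0] + [0.0] * 8),
                        np.array([5, 6]))
    frac, dist = translocation_fraction(p)
    assert frac == pytest.approx(1.0)
    assert dist.sum() == pytest.approx(1.0)


def test_translocation_none_in_liposome_fractions():
    p = FractionProfile(np.arange(1, 15),
                        np.array([1.0] * 4 + [0.0, 0.0] + [1.0] * 8),
                        np.array([5, 6]))
    frac, _ = translocation_fraction(p)
    assert frac == 0.0


def test_translocation_uniform_signal():
    p = FractionProfile(np.arange(1, 15), np.ones(14), np.array([2, 3, 4, 5]))
    frac, dist = translocation_fraction(p)
    assert frac == pytest.approx(4 / 14)
    assert np.allclose(dist, 1 / 14)


def test_translocation_zero_total_rejected():
    p = FractionProfile(np.arange(1, 15), np.zeros(14), np.array([2]))
    with pytest.raises(InputError):
        translocation_fraction(p)


# ------------------------------------------------------------ protocol ----


def test_production_window_after_equilibration_discard():
    assert protocol.production_window_ns(185.0, 25.0) == pytest.approx(160.0)
    assert protocol.n_frames(160.0, 5.0) == 32000


def test_equal_volume_mixing_halves_concentration():
    assert protocol.mixed_concentration(1.44, 75.0, 75.0) == pytest.approx(0.72)


def test_liposome_molar_excess():
    assert protocol.molar_excess(10e-3, 40e-6) == pytest.approx(250.0)


def test_protocol_validation():
    with pytest.raises(InputError):
        protocol.production_window_ns(100.0, 100.0)
    with pytest.raises(InputError):
        protocol.molar_excess(0.0, 1.0)
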