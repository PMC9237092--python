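"""Plane fits, helical content, tilt, depth, binning and window summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_point_frame
from mbrkit.errors import GeometryError, InputError
from mbrkit.geometry import (BinnedSeries, GeomSeries, MembranePlane,
                             bin_series, fit_membrane_plane, helical_content,
                             helix_tilt, insertion_depth, summarize_window)
from mbrkit.structure import concat_frames
from mbrkit.synth import HelixSpec, MembraneModelSpec, build_ideal_helix, \
    make_membrane, place_on_membrane


def _two_leaflet_frame(upper_pts, protein_xyz=(0.0, 0.0, 30.0)):
    """Frame with given upper-leaflet phosphates, a flat lower leaflet and
    one protein atom above the membrane."""
    upper = np.asarray(upper_pts, dtype=float)
    xs = upper[:, 0]
    lower = np.column_stack([upper[:, 0], upper[:, 1],
                             np.full(len(upper), -20.0)])
    phos = np.vstack([upper, lower])
    mem = make_point_frame(phos, elements=np.full(len(phos), "P"), chain="M")
    prot = make_point_frame([protein_xyz], elements=["C"], chain="A")
    return concat_frames([mem, prot])


def test_flat_leaflet_fit_is_exact():
    gx, gy = np.meshgrid(np.arange(5.0), np.arange(5.0))
    upper = np.column_stack([gx.ravel(), gy.ravel(), np.full(25, 20.0)])
    plane = fit_membrane_plane(_two_leaflet_frame(upper))
    assert plane.rmsd_fit == pytest.approx(0.0, abs=1e-10)
    assert abs(plane.normal[2]) == pytest.approx(1.0, abs=1e-12)
    assert plane.point[2] == pytest.approx(20.0)


def test_sloped_plane_normal_recovered():
    """Points on z = 0.1 x + 15 give normal parallel to (-0.1, 0, 1)."""
    gx, gy = np.meshgrid(np.linspace(-10, 10, 7), np.linspace(-10, 10, 7))
    z = 0.1 * gx + 15.0
    upper = np.column_stack([gx.ravel(), gy.ravel(), z.ravel()])
    plane = fit_membrane_plane(_two_leaflet_frame(upper))
    expected = np.array([-0.1, 0.0, 1.0])
    expected /= np.linalg.norm(expected)
    assert np.allclose(np.abs(plane.normal @ expected), 1.0, atol=1e-8)


def test_jittered_flat_leaflet_offset_is_mean_z():
    rng = np.random.default_rng(5)
    gx, gy = np.meshgrid(np.linspace(-20, 20, 10), np.linspace(-20, 20, 10))
    z = 20.0 + rng.normal(0, 1.0, gx.size)
    upper = np.column_stack([gx.ravel(), gy.ravel(), z])
    plane = fit_membrane_plane(_two_leaflet_frame(upper))
    assert plane.point[2] == pytest.approx(z.mean(), abs=1e-8)


def test_collinear_phosphates_rejected():
    upper = np.column_stack([np.arange(5.0), np.zeros(5), np.full(5, 20.0)])
    with pytest.raises(GeometryError, match="collinear"):
        fit_membrane_plane(_two_leaflet_frame(upper))


def test_no_protein_atoms_rejected(flat_membrane):
    with pytest.raises(InputError):
        fit_membrane_plane(flat_membrane, "element P", "chain A")


def test_normal_points_away_from_bilayer(flat_membrane):
    helix = build_ideal_helix(HelixSpec("A" * 10, start_resid=1))
    frame = place_on_membrane(helix, 0.0, -8.0, flat_membrane, (1, 10))
    plane = fit_membrane_plane(frame)
    # proximal leaflet is the upper one; normal must point up (to solvent)
    assert plane.normal[2] > 0.99


# ----------------------------------------------------------- hlx ----------


def test_helical_content_of_ideal_helix(ideal_helix):
    assert helical_content(ideal_helix, (1, 15)) >= 0.85


def test_helical_content_of_extended_chain(extended_chain):
    assert helical_content(extended_chain, (1, 15)) <= 0.10


def test_helical_content_needs_five_residues(ideal_helix):
    with pytest.raises(InputError):
        helical_content(ideal_helix, (1, 4))


def test_helical_content_names_missing_atom(ideal_helix):
    no_oxygens = ideal_helix.atoms("not name O")
    with pytest.raises(InputError, match="missing atom 'O'"):
        helical_content(no_oxygens, (1, 15))


def test_helical_content_bounded():
    for phi, psi in [(-57.0, -47.0), (180.0, 180.0), (-120.0, 120.0),
                     (-75.0, -35.0)]:
        frame = build_ideal_helix(HelixSpec("A" * 12, phi=phi, psi=psi))
        assert 0.0 <= helical_content(frame, (1, 12)) <= 1.0


# ----------------------------------------------------------- tilt ---------


def _line_frame(direction, n=8):
    direction = np.asarray(direction, dtype=float)
    pts = np.outer(np.arange(n, dtype=float), direction)
    f = make_point_frame(pts, elements=np.full(n, "C"))
    f.atom_names[:] = "CA"
    return f


def test_tilt_zero_for_in_plane_axis():
    plane = MembranePlane(np.zeros(3), np.array([0.0, 0.0, 1.0]))
    assert helix_tilt(_line_frame([1, 0, 0]), (1, 8), plane) == pytest.approx(0.0)


def test_tilt_ninety_along_normal():
    plane = MembranePlane(np.zeros(3), np.array([0.0, 0.0, 1.0]))
    assert helix_tilt(_line_frame([0, 0, 1]), (1, 8), plane) == pytest.approx(90.0)


def test_tilt_range_needs_three_cas(ideal_helix):
    plane = MembranePlane(np.zeros(3), np.array([0.0, 0.0, 1.0]))
    with pytest.raises(InputError):
        helix_tilt(ideal_helix, (1, 2), plane)


# ----------------------------------------------------------- depth --------


def test_depth_zero_on_plane():
    plane = MembranePlane(np.array([0, 0, 20.0]), np.array([0, 0, 1.0]))
    frame = make_point_frame([[0, 0, 20.0]])
    assert insertion_depth(frame, (1, 1), plane) == pytest.approx(0.0)


def test_depth_sign_convention():
    """5 A on the membrane-interior side of the headgroup plane is -5."""
    plane = MembranePlane(np.array([0, 0, 20.0]), np.array([0, 0, 1.0]))
    below = make_point_frame([[0, 0, 15.0]])
    assert insertion_depth(below, (1, 1), plane) == pytest.approx(-5.0)


def test_depth_invariant_under_rigid_translation(flat_membrane):
    helix = build_ideal_helix(HelixSpec("A" * 10, start_resid=1))
    frame = place_on_membrane(helix, 20.0, -3.0, flat_membrane, (1, 10))
    moved = frame.translated([13.0, -7.0, 4.0])
    d0 = insertion_depth(frame, (1, 10), fit_membrane_plane(frame))
    d1 = insertion_depth(moved, (1, 10), fit_membrane_plane(moved))
    assert d1 == pytest.approx(d0, abs=1e-9)


@settings(max_examples=20, deadline=None)
@given(st.floats(-179.0, 179.0), st.floats(-89.0, 89.0), st.floats(-179.0, 179.0))
def test_observables_invariant_under_rigid_rotation(alpha, beta, gamma):
    """hlx, tilt and depth are unchanged by a joint rigid rotation."""
    from scipy.spatial.transform import Rotation

    helix = build_ideal_helix(HelixSpec("A" * 12, start_resid=1))
    mem = make_membrane(MembraneModelSpec(n_phosphates_per_leaflet=25,
                                          jitter_sd=0.0), seed=0)
    frame = place_on_membrane(helix, 25.0, -2.0, mem, (1, 12))
    rot = Rotation.from_euler("zyx", [alpha, beta, gamma], degrees=True).as_matrix()
    moved = frame.rotated(rot)
    for fr in (frame, moved):
        plane = fit_membrane_plane(fr)
        assert helical_content(fr, (1, 12)) == pytest.approx(
            helical_content(frame, (1, 12)), abs=1e-8)
        assert helix_tilt(fr, (1, 12), plane) == pytest.approx(25.0, abs=1e-6)
        assert insertion_depth(fr, (1, 12), plane) == pytest.approx(-2.0, abs=1e-6)


# ----------------------------------------------------------- binning ------


def test_bin_means_example():
    series = GeomSeries("x", np.array([0.0, 250.0, 500.0, 750.0]),
                        np.array([1.0, 1.0, 2.0, 2.0]))
    binned = bin_series(series, 0.5)
    assert np.allclose(binned.bin_means, [1.0, 2.0])
    assert np.array_equal(binned.bin_counts, [2, 2])


def test_constant_series_has_zero_sd():
    series = GeomSeries("x", np.arange(10) * 100.0, np.full(10, 3.0))
    binned = bin_series(series, 0.5)
    assert np.allclose(binned.bin_sds, 0.0)


def test_full_production_run_gives_320_bins():
    """160 ns sampled at 0.25 ns with 0.5 ns bins yields 320 bins."""
    times_ps = np.arange(640) * 250.0
    series = GeomSeries("x", times_ps, np.zeros(640))
    binned = bin_series(series, 0.5)
    assert len(binned.bin_means) == 320


def test_empty_series_rejected():
    with pytest.raises(InputError):
        bin_series(GeomSeries("x", np.array([]), np.array([])), 0.5)


def test_window_uses_trailing_bins():
    binned = BinnedSeries("x", np.array([0.25, 0.75, 1.25, 1.75]),
                          np.array([1.0, 2.0, 3.0, 4.0]),
                          np.zeros(4), np.ones(4, dtype=int), 0.5)
    mean, sd, n = summarize_window(binned, 1.0)
    assert mean == pytest.approx(3.5)
    assert n == 2


def test_window_covering_everything_uses_all_bins():
    binned = BinnedSeries("x", np.array([0.25, 0.75, 1.25, 1.75]),
                          np.array([1.0, 2.0, 3.0, 4.0]),
                          np.zeros(4), np.ones(4, dtype=int), 0.5)
    mean, sd, n = summarize_window(binned, 2.0)
    assert n == 4
    assert mean == pytest.approx(2.5)


def test_oversized_window_rejected():
    binned = BinnedSeries("x", np.array([0.25, 0.75]), np.array([1.0, 2.0]),
                          np.zeros(2), np.ones(2, dtype=int), 0.5)
    with pytest.raises(InputError):
        summarize_window(binned, 5.0)


def test_windowed_mean_tracks_stationary_series():
    """Windowed mean of a stationary noisy series stays within 3 s.e."""
    rng = np.random.default_rng(11)
    values = rng.normal(0.7, 0.05, 640)
    series = GeomSeries("x", np.arange(640) * 250.0, values)
    mean, sd, n = summarize_window(bin_series(series, 0.5), 80.0)
    assert n == 160
    assert abs(mean - 0.7) < 3 * 0.05 / np.sqrt(320)
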