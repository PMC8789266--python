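"""Curvature field, region growing, jawline fit and blob merging."""

import numpy as np
import pytest

from dentmark.errors import DegenerateGeometryError
from dentmark.mesh_core import build_adjacency
from dentmark.orientation import ArchFrame, disambiguate_signs, pca_axes
from dentmark.peak_detection import PeakPoint, find_peaks
from dentmark.tooth_partition import (
    Blob,
    Jawline,
    edge_curvature,
    fit_jawline,
    grow_tooth_region,
    merge_blobs,
)

from .conftest import make_cube, make_grid_surface, make_vgroove


def z_up_frame():
    return ArchFrame(
        np.zeros(3), np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0])
    )


# -- curvature ---------------------------------------------------------------


def test_cube_fold_edges_positive():
    cube = make_cube()
    adj = build_adjacency(cube)
    curv = edge_curvature(cube, adj)
    # every cube edge that is a fold (non-diagonal) is a convex 90-degree corner
    folds = [v for v in curv.values if abs(v) > 1e-6]
    assert len(folds) > 0
    assert all(v > 0 for v in folds)
    assert max(folds) == pytest.approx(np.pi / 2, abs=1e-6)


def test_flat_plane_zero_curvature():
    mesh = make_grid_surface(np.zeros((8, 8)))
    adj = build_adjacency(mesh)
    curv = edge_curvature(mesh, adj)
    np.testing.assert_allclose(curv.values, 0.0, atol=1e-9)


def test_vgroove_concave_crease_magnitude():
    mesh = make_vgroove(angle_deg=90.0)
    adj = build_adjacency(mesh)
    curv = edge_curvature(mesh, adj)
    crease = curv.values[curv.values < -0.1]
    assert len(crease) > 0
    assert np.min(crease) == pytest.approx(-np.pi / 2, abs=1e-6)


# -- region growing ----------------------------------------------------------


def tooth_on_base():
    """A synthetic single tooth: use the full generator with one tooth present."""
    from dentmark.synthetic_arch import ArchSpec, generate_arch

    present = {f"LR{i}": False for i in range(1, 9)}
    present.update({f"LL{i}": False for i in range(1, 9)})
    present["LR4"] = True
    spec = ArchSpec(jaw="L", seed=5, present=present)
    return generate_arch(spec)


def test_single_tooth_blob_matches_truth_mask():
    mesh, truth = tooth_on_base()
    frame = disambiguate_signs(mesh, pca_axes(mesh))
    adj = build_adjacency(mesh)
    peaks = find_peaks(mesh, adj, frame)
    curv = edge_curvature(mesh, adj)
    blob = grow_tooth_region(mesh, adj, curv, peaks[0], frame)
    assert not blob.spilled
    tt = next(iter(truth.teeth.values()))
    mask = set(int(f) for f in tt.face_mask)
    jac = len(mask & blob.faces) / len(mask | blob.faces)
    assert jac >= 0.9


def test_peak_on_smooth_slab_spills():
    z = np.zeros((40, 40))
    z[20, 20] = 0.6  # a tiny pimple on an otherwise flat slab
    mesh = make_grid_surface(z, spacing=1.0)
    adj = build_adjacency(mesh)
    frame = z_up_frame()
    curv = edge_curvature(mesh, adj)
    peak = PeakPoint(vertex_index=20 * 40 + 20, position=mesh.vertices[20 * 40 + 20],
                     height=0.6)
    blob = grow_tooth_region(mesh, adj, curv, peak, frame, max_travel=10.0)
    assert blob.spilled


def test_two_teeth_give_disjoint_blobs(arch1, arch1_adjacency):
    mesh, truth = arch1
    frame = disambiguate_signs(mesh, pca_axes(mesh))
    peaks = find_peaks(mesh, arch1_adjacency, frame)
    curv = edge_curvature(mesh, arch1_adjacency)
    # pick one peak on LR4 and one on LR5
    blobs = []
    for code in ("LR4", "LR5"):
        apex = truth.tooth(code).top_apex.position
        peak = min(peaks, key=lambda p: np.linalg.norm(p.position - apex))
        blobs.append(grow_tooth_region(mesh, arch1_adjacency, curv, peak, frame))
    assert not (blobs[0].faces & blobs[1].faces)


def test_growth_deterministic(arch1, arch1_adjacency):
    mesh, _ = arch1
    frame = disambiguate_signs(mesh, pca_axes(mesh))
    peaks = find_peaks(mesh, arch1_adjacency, frame)
    curv = edge_curvature(mesh, arch1_adjacency)
    b1 = grow_tooth_region(mesh, arch1_adjacency, curv, peaks[0], frame)
    b2 = grow_tooth_region(mesh, arch1_adjacency, curv, peaks[0], frame)
    assert b1.faces == b2.faces


# -- jawline -----------------------------------------------------------------


def _peaks_at(xy):
    return [
        PeakPoint(vertex_index=i, position=np.array([x, y, 0.0]), height=0.0)
        for i, (x, y) in enumerate(xy)
    ]


def test_jawline_exact_quadratic_recovered():
    ts = np.linspace(-20, 20, 9)
    pts = _peaks_at([(t, 0.05 * t * t + 2.0) for t in ts])
    jaw = fit_jawline(pts, z_up_frame())
    assert jaw.a == pytest.approx(0.05, abs=1e-6)
    assert jaw.b == pytest.approx(0.0, abs=1e-6)
    assert jaw.c == pytest.approx(2.0, abs=1e-6)


def test_jawline_noisy_residual_in_expected_range():
    rng = np.random.default_rng(3)
    ts = np.linspace(-25, 25, 20)
    pts = _peaks_at([(t, 0.05 * t * t + 2.0 + rng.normal(0, 0.3)) for t in ts])
    jaw = fit_jawline(pts, z_up_frame())
    assert 0.15 <= jaw.rms_residual <= 0.6


def test_jawline_too_few_peaks_raises():
    with pytest.raises(DegenerateGeometryError):
        fit_jawline(_peaks_at([(0, 0), (1, 1)]), z_up_frame())


def test_jawline_ignores_spilled_peaks():
    pts = _peaks_at([(t, 0.1 * t * t) for t in (-10, -5, 0, 5, 10)])
    outlier = PeakPoint(vertex_index=99, position=np.array([0.0, 50.0, 0.0]),
                        height=0.0, spilled=True)
    jaw = fit_jawline(pts + [outlier], z_up_frame())
    assert jaw.a == pytest.approx(0.1, abs=1e-9)


def test_arc_length_monotone_and_metric():
    jaw = Jawline(a=-0.05, b=0.0, c=0.0)
    ts = np.linspace(-30, 30, 121)
    s = np.array([jaw.arc_length(t) for t in ts])
    assert np.all(np.diff(s) > 0)
    # arc length between close points approximates chord length
    chord = np.hypot(np.diff(ts), np.diff(jaw.ap(ts)))
    np.testing.assert_allclose(np.diff(s), chord, rtol=1e-3)


# -- merging -----------------------------------------------------------------


def _blob(faces, x, height=1.0, idx=0, spilled=False):
    peak = PeakPoint(vertex_index=idx, position=np.array([x, 0.0, height]),
                     height=height)
    return Blob(faces=frozenset(faces), peaks=[peak], spilled=spilled)


def test_overlapping_blobs_merge():
    flat = Jawline(a=0.0, b=0.0, c=0.0)
    blobs = [_blob({1, 2, 3}, 0.0, idx=0), _blob({3, 4, 5}, 1.0, idx=1)]
    merged = merge_blobs(blobs, flat, z_up_frame(), merge_distance=0.5)
    assert len(merged) == 1
    assert merged[0].faces == frozenset({1, 2, 3, 4, 5})
    assert len(merged[0].peaks) == 2


def test_same_jaw_position_disjoint_blobs_merge():
    """Buccal/lingual halves at one arch position unite without sharing faces."""
    flat = Jawline(a=0.0, b=0.0, c=0.0)
    blobs = [_blob({1, 2}, 0.0, idx=0), _blob({10, 11}, 1.0, idx=1)]
    merged = merge_blobs(blobs, flat, z_up_frame(), merge_distance=3.0)
    assert len(merged) == 1


def test_distant_blobs_stay_separate_and_sorted():
    flat = Jawline(a=0.0, b=0.0, c=0.0)
    blobs = [_blob({10, 11}, 9.0, idx=1), _blob({1, 2}, 0.0, idx=0)]
    merged = merge_blobs(blobs, flat, z_up_frame(), merge_distance=3.0)
    assert len(merged) == 2
    assert merged[0].jaw_parameter < merged[1].jaw_parameter


def test_spilled_blobs_discarded():
    flat = Jawline(a=0.0, b=0.0, c=0.0)
    blobs = [_blob({1}, 0.0, idx=0, spilled=True), _blob({5}, 9.0, idx=1)]
    merged = merge_blobs(blobs, flat, z_up_frame(), merge_distance=3.0)
    assert len(merged) == 1
    assert merged[0].faces == frozenset({5})


def test_merged_blobs_pairwise_disjoint_on_arch(rec1):
    blobs = rec1.blobs
    for i in range(len(blobs)):
        for j in range(i + 1, len(blobs)):
            assert not (blobs[i].faces & blobs[j].faces)
    assert all(len(b.peaks) >= 1 for b in blobs)


def test_clean_arch_yields_one_blob_per_tooth(rec1, arch1):
    _, truth = arch1
    assert rec1.blob_count == len(truth.teeth)
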