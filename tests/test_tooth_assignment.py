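"""Palmer notation, features, mismatch cost and the assignment DP."""

import numpy as np
import pytest

from dentmark.tooth_assignment import (
    ToothFeatures,
    ToothType,
    TrainingSet,
    assign_teeth,
    build_template,
    compute_features,
    mismatch_cost,
    parse_tooth_type,
)

# -- notation ----------------------------------------------------------------


def test_palmer_parse_and_format_roundtrip():
    for code in ("UR6", "LL1", "URa", "LLe", "UR6.0", "LR7.1"):
        assert str(parse_tooth_type(code)) == code


def test_half_suffix_only_on_molars():
    with pytest.raises(ValueError):
        ToothType("UR", 2, False, 0)
    assert ToothType("UR", 6, False, 1).is_molar


def test_tooth_classes():
    assert parse_tooth_type("UR1").tooth_class == "I"
    assert parse_tooth_type("LL3").tooth_class == "C"
    assert parse_tooth_type("UR4").tooth_class == "P"
    assert parse_tooth_type("LL8").tooth_class == "M"
    assert parse_tooth_type("URd").tooth_class == "M"  # deciduous first molar
    assert parse_tooth_type("LLb").tooth_class == "I"


def test_training_key_collapses_sides():
    assert parse_tooth_type("UR6").training_key == parse_tooth_type("UL6").training_key
    assert parse_tooth_type("UR6").training_key != parse_tooth_type("LR6").training_key


def test_templates():
    perm = build_template("U", "permanent")
    assert len(perm.slots) == 16
    assert perm.pattern() == "MMMPPCIIIICPPMMM"
    decid = build_template("L", "deciduous")
    assert len(decid.slots) == 10
    assert decid.pattern() == "mmciiiicmm"
    # symmetric about the midline
    assert [t.position for t in perm.slots] == [t.position for t in perm.slots][::-1]


# -- features ----------------------------------------------------------------


def test_features_match_generator_dimensions(rec1, arch1, training):
    """Measured widths/heights agree with the design parameters within 10%."""
    from dentmark.synthetic_arch import PERMANENT_DIMS

    mesh, truth = arch1
    labels = rec1.assignment.label_map()
    checked = 0
    for i, blob in enumerate(rec1.blobs):
        t = labels.get(i)
        if t is None or t.half is not None or t.position not in (3, 6):
            continue
        md, bl, h, _ = PERMANENT_DIMS[t.position]
        feats = rec1_features(rec1, i, mesh)
        assert feats.mesiodistal_width == pytest.approx(md, rel=0.15)
        assert feats.buccolingual_width == pytest.approx(bl, rel=0.15)
        checked += 1
    assert checked >= 2


def rec1_features(rec1, i, mesh):
    from dentmark.tooth_partition import fit_jawline

    frame = rec1.frame
    all_peaks = [p for b in rec1.blobs for p in b.peaks]
    jawline = fit_jawline(all_peaks, frame)
    return compute_features(mesh, rec1.blobs[i], frame, jawline)


def test_features_rigid_invariance(rec1, arch1):
    from scipy.spatial.transform import Rotation

    from dentmark.orientation import ArchFrame
    from dentmark.tooth_partition import fit_jawline

    mesh, _ = arch1
    frame = rec1.frame
    jaw = fit_jawline([p for b in rec1.blobs for p in b.peaks], frame)
    blob = rec1.blobs[3]
    f0 = compute_features(mesh, blob, frame, jaw)

    rot = Rotation.from_euler("xyz", [15, 25, -40], degrees=True).as_matrix()
    shift = np.array([4.0, -7.0, 2.0])
    moved = mesh.transformed(rot, shift)
    moved_frame = ArchFrame(
        rot @ frame.origin + shift,
        rot @ frame.transverse_axis,
        rot @ frame.anteroposterior_axis,
        rot @ frame.occlusal_axis,
    )
    moved_blob = type(blob)(
        faces=blob.faces,
        peaks=[
            type(p)(p.vertex_index, rot @ p.position + shift, p.height)
            for p in blob.peaks
        ],
    )
    f1 = compute_features(moved, moved_blob, moved_frame, jaw)
    np.testing.assert_allclose(f0.vector(), f1.vector(), atol=1e-6)


def test_peak_count_single_peak(rec1, arch1):
    mesh, _ = arch1
    one_peak = [b for b in rec1.blobs if len(b.peaks) == 1]
    if one_peak:
        feats = rec1_features(rec1, rec1.blobs.index(one_peak[0]), mesh)
        assert feats.peak_count == 1


# -- training set and mismatch ----------------------------------------------


def toy_training():
    rng = np.random.default_rng(0)
    samples = {}
    base = {
        "U1": [200, 8.5, 7, 9, 1],
        "U2": [160, 6.5, 6.5, 8.5, 1],
        "U3": [220, 7.5, 8, 10, 1],
        "U4": [230, 7, 9, 8, 2],
        "U5": [231, 7, 9, 8, 2],
        "U6": [330, 10.5, 11, 7.5, 4],
        "U7": [320, 10.5, 11, 7, 4],
        "U8": [300, 10.5, 10.5, 6.5, 4],
        "U6.0": [165, 5.2, 11, 7.5, 2],
        "U6.1": [165, 5.2, 11, 7.5, 2],
        "U7.0": [160, 5.2, 11, 7, 2],
        "U7.1": [160, 5.2, 11, 7, 2],
        "U8.0": [150, 5.2, 10.5, 6.5, 2],
        "U8.1": [150, 5.2, 10.5, 6.5, 2],
    }
    for key, mean in base.items():
        mean = np.array(mean, dtype=float)
        samples[key] = [mean + rng.normal(0, 0.02, 5) for _ in range(4)]
    return TrainingSet(samples), base


def feats(vec):
    return ToothFeatures(*[float(x) for x in vec[:4]], int(round(vec[4])))


def test_mismatch_zero_at_training_mean():
    training, base = toy_training()
    t = parse_tooth_type("UR6")
    mean, _ = training.lookup(t)
    assert mismatch_cost(feats_raw(mean), t, training) == pytest.approx(0.0, abs=1e-6)


def test_mismatch_one_sigma_is_one():
    training, _ = toy_training()
    t = parse_tooth_type("UR6")
    mean, std = training.lookup(t)
    v = mean.copy()
    v[0] += std[0]
    assert mismatch_cost(feats_raw(v), t, training) == pytest.approx(1.0, abs=1e-9)


def feats_raw(vec):
    f = ToothFeatures(0, 0, 0, 0, 0)
    f.surface_area, f.mesiodistal_width, f.buccolingual_width, f.crown_height = (
        float(vec[0]), float(vec[1]), float(vec[2]), float(vec[3])
    )
    f.peak_count = vec[4]
    return f


def test_mismatch_monotone_in_feature_deviation():
    training, _ = toy_training()
    t = parse_tooth_type("UR6")
    mean, std = training.lookup(t)
    prev = -1.0
    for k in (0.0, 0.5, 1.0, 2.0, 4.0):
        v = mean.copy()
        v[1] += k * std[1]
        c = mismatch_cost(feats_raw(v), t, training)
        assert c > prev
        prev = c


def test_training_csv_roundtrip(tmp_path):
    training, _ = toy_training()
    training.to_csv(tmp_path / "t.csv")
    loaded = TrainingSet.from_csv(tmp_path / "t.csv")
    for key in training.stats:
        np.testing.assert_allclose(
            training.stats[key][0], loaded.stats[key][0], rtol=1e-6
        )


# -- assignment DP -----------------------------------------------------------


def perfect_blob_features(template, training):
    return [feats_raw(training.lookup(t)[0]) for t in template.slots]


def test_perfect_sixteen_blobs_label_exactly():
    training, _ = toy_training()
    template = build_template("U", "permanent")
    f = perfect_blob_features(template, training)
    a = assign_teeth(list(range(16)), f, template, training)
    assert [str(t) for t in a.labels] == [str(t) for t in template.slots]
    assert a.total_cost == pytest.approx(0.0, abs=1e-3)


def test_missing_premolar_skips_slot_only():
    training, _ = toy_training()
    template = build_template("U", "permanent")
    f = perfect_blob_features(template, training)
    del f[3]  # drop UR5 (slot index 3 in R8..R1 ordering)
    a = assign_teeth(list(range(15)), f, template, training)
    labels = [str(t) for t in a.labels]
    expected = [str(t) for i, t in enumerate(template.slots) if i != 3]
    assert labels == expected
    assert [str(t) for t in a.skipped_slots] == ["UR5"]


def test_half_molar_pair_consumes_one_slot():
    training, _ = toy_training()
    template = build_template("U", "permanent")
    f = perfect_blob_features(template, training)
    # split the UR6 blob (slot index 2) into its mesial and distal halves
    half = feats_raw(training.lookup(parse_tooth_type("UR6.0"))[0])
    f = f[:2] + [half, half] + f[3:]
    a = assign_teeth(list(range(17)), f, template, training)
    labels = [str(t) for t in a.labels]
    assert labels[2] == "UR6.0"
    assert labels[3] == "UR6.1"
    assert labels[4] == "UR5"


def brute_force_assign(features, template, training, gap, discard):
    """Exhaustive enumeration over monotone alignments (oracle)."""
    n = len(features)
    m = len(template.slots)
    best = [np.inf]

    def rec(i, j, cost):
        if cost >= best[0]:
            return
        if i == n and j == m:
            best[0] = min(best[0], cost)
            return
        if j < m:
            rec(i, j + 1, cost + gap)  # skip slot
            slot = template.slots[j]
            if i < n and slot in training:
                rec(i + 1, j + 1, cost + mismatch_cost(features[i], slot, training))
            if (
                i + 1 < n
                and slot.is_molar
                and slot.with_half(0) in training
                and slot.with_half(1) in training
            ):
                c = mismatch_cost(features[i], slot.with_half(0), training) + \
                    mismatch_cost(features[i + 1], slot.with_half(1), training)
                rec(i + 2, j + 1, cost + c)
        if i < n:
            rec(i + 1, j, cost + discard)  # discard blob
    rec(0, 0, 0.0)
    return best[0]


@pytest.mark.parametrize("seed", range(200))
def test_dp_equals_bruteforce_small_instances(seed):
    """DP optimum equals exhaustive enumeration for <= 6 blobs."""
    training, base = toy_training()
    rng = np.random.default_rng(seed)
    template = build_template("U", "permanent")
    # random features: perturbations of random type means, some junk blobs
    n = int(rng.integers(1, 7))
    keys = list(base)
    fs = []
    for _ in range(n):
        mean = np.array(base[keys[rng.integers(len(keys))]], dtype=float)
        vec = mean * rng.uniform(0.7, 1.3, 5)
        fs.append(feats_raw(vec))
    a = assign_teeth(list(range(n)), fs, template, training, 6.0, 9.0)
    want = brute_force_assign(fs, template, training, 6.0, 9.0)
    assert a.total_cost == pytest.approx(want, rel=1e-9)


def test_left_right_symmetry():
    """Mirrored blobs against the template give the mirrored labels, equal cost."""
    training, base = toy_training()
    template = build_template("U", "permanent")
    rng = np.random.default_rng(11)
    fs = [
        feats_raw(np.array(base[t.training_key]) * rng.uniform(0.9, 1.1, 5))
        for t in template.slots
    ]
    a = assign_teeth(list(range(16)), fs, template, training)
    b = assign_teeth(list(range(16)), fs[::-1], template, training)
    assert a.total_cost == pytest.approx(b.total_cost, rel=1e-9)
    mirrored = [t.mirrored() if t else None for t in b.labels][::-1]
    assert [str(t) for t in a.labels if t] == [str(t) for t in mirrored if t]


def test_empty_blob_list():
    training, _ = toy_training()
    template = build_template("U", "permanent")
    a = assign_teeth([], [], template, training)
    assert a.labels == []
    assert len(a.skipped_slots) == 16


def test_ground_truth_labels_on_synthetic_arch(rec1, arch1):
    mesh, truth = arch1
    from dentmark.validation_metrics import match_predictions

    matches = match_predictions(truth, rec1.blobs, rec1.assignment, mesh)
    ok = sum(1 for t, p in matches.items() if p == t.with_half(None))
    assert ok >= 15  # at least 15 of 16 teeth correctly labelled
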