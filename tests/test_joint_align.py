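"""Joint detection/alignment: features, clustering, cascade, refinement."""

import numpy as np
import pytest

from pulsepatch.joint_align import (
    CascadeConfig,
    ScanConfig,
    Shape,
    ShapeIndexedFeatureSpec,
    cascade_scores,
    cluster_representative_shapes,
    detect,
    extract_features,
    mean_shape,
    normalized_error,
    refine_shape,
    train_cascade,
    train_refiner,
)
from pulsepatch.synthetic_scene import (
    TOY_EYE_INDICES,
    plant_face_frame,
    pose_shape,
)


class TestShapeIndexedFeatures:
    def test_constant_image_gives_zero_features(self, rng):
        spec = ShapeIndexedFeatureSpec(
            rng.integers(0, 3, (16, 2)), rng.uniform(-0.2, 0.2, (16, 2, 2)), 0.2
        )
        img = np.full((32, 32), 77, dtype=np.uint8)
        shape = Shape(rng.uniform(0.2, 0.8, (3, 2)))
        assert np.array_equal(extract_features(img, shape, spec), np.zeros(16))

    def test_hand_built_spec_on_ramp_image(self):
        img = np.arange(9).reshape(3, 3).astype(np.uint8)
        shape = Shape(np.array([[1 / 3, 1 / 3]]))  # lands on pixel (1, 1) = 4
        spec = ShapeIndexedFeatureSpec(
            anchors=np.array([[0, 0], [0, 0]]),
            offsets=np.array(
                [[[0.0, 0.0], [1 / 3, 0.0]], [[0.0, 0.0], [0.0, 1 / 3]]]
            ),
            radius=0.34,
        )
        feats = extract_features(img, shape, spec)
        assert feats.tolist() == [4 - 5, 4 - 7]

    def test_out_of_window_references_clamp_to_border(self):
        img = np.arange(9).reshape(3, 3).astype(np.uint8)
        shape = Shape(np.array([[0.95, 0.95]]))
        spec = ShapeIndexedFeatureSpec(
            np.array([[0, 0]]), np.array([[[0.3, 0.3], [0.0, 0.0]]]), 0.3
        )
        feats = extract_features(img, shape, spec)  # both clamp to (2, 2) = 8
        assert feats.tolist() == [0]

    def test_translation_with_window_leaves_features_unchanged(self, rng):
        frame = rng.integers(0, 255, (64, 64)).astype(np.uint8)
        shape = Shape(rng.uniform(0.2, 0.8, (5, 2)))
        spec = ShapeIndexedFeatureSpec(
            rng.integers(0, 5, (32, 2)), rng.uniform(-0.15, 0.15, (32, 2, 2)), 0.15
        )
        a = extract_features(frame[0:32, 0:32], shape, spec)
        b = extract_features(frame[20:52, 10:42], shape, spec)
        c = extract_features(frame[20:52, 10:42], shape, spec)
        assert np.array_equal(b, c)
        assert a.shape == b.shape  # same spec, shape-relative indexing

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError):
            ShapeIndexedFeatureSpec(np.empty((0, 2)), np.empty((0, 2, 2)), 0.2)


class TestRepresentativeShapes:
    def test_single_cluster_is_coordinate_mean(self):
        shapes = [np.full((4, 2), v, dtype=float) for v in (0.2, 0.4, 0.6)]
        # identical geometry up to translation: aligned mean = anchor shape
        rep = cluster_representative_shapes(shapes, n_clusters=1)[0]
        assert rep.points.shape == (4, 2)
        base = np.full((4, 2), 0.2)
        assert np.allclose(rep.points, base, atol=1e-9)

    def test_two_separated_families_recovered(self, rng):
        fam_a = pose_shape("left")
        fam_b = pose_shape("right")
        shapes = [fam_a + rng.normal(0, 0.005, (10, 2)) for _ in range(5)]
        shapes += [fam_b + rng.normal(0, 0.005, (10, 2)) for _ in range(5)]
        reps = cluster_representative_shapes(shapes, n_clusters=2)
        means = sorted(r.points[:, 0].mean() for r in reps)
        assert means[0] == pytest.approx(fam_a[:, 0].mean(), abs=0.02)
        assert means[1] == pytest.approx(fam_b[:, 0].mean(), abs=0.02)

    def test_three_pose_families_get_pose_labels(self, detection_task):
        reps = cluster_representative_shapes(
            [s for s, _ in detection_task.training_shapes], n_clusters=3
        )
        assert sorted(r.pose_label for r in reps) == ["frontal", "left", "right"]

    def test_more_clusters_than_shapes_raises(self):
        with pytest.raises(ValueError):
            cluster_representative_shapes([np.zeros((4, 2))], n_clusters=2)


def _separable_toy(n=40, size=16, seed=0):
    """Bright windows are faces, dark windows are not; one feature separates."""
    rng = np.random.default_rng(seed)
    shape = np.full((3, 2), 0.5)
    pos = [
        (np.clip(rng.normal(220, 5, (size, size)), 0, 255).astype(np.uint8), shape)
        for _ in range(n)
    ]
    neg = [
        (np.clip(rng.normal(40, 5, (size, size)), 0, 255).astype(np.uint8), shape)
        for _ in range(n)
    ]
    return pos, neg


class TestCascade:
    def test_separable_toy_classified_on_train_set(self):
        pos, neg = _separable_toy()
        model = train_cascade(
            pos, neg, CascadeConfig(n_stages=4, pass_rate=1.0, seed=0,
                                    n_representative=1)
        )
        pos_pass = sum(cascade_scores(model, w)[0][0] for w, _ in pos)
        neg_pass = sum(cascade_scores(model, w)[0][0] for w, _ in neg)
        assert pos_pass == len(pos)
        assert neg_pass <= 0.1 * len(neg)

    def test_single_depth_one_tree_is_a_feature_threshold(self):
        pos, neg = _separable_toy()
        model = train_cascade(
            pos, neg,
            CascadeConfig(n_stages=1, tree_depth=1, pass_rate=1.0,
                          max_features=None, seed=0, n_representative=1),
        )
        assert model.n_stages == 1
        tree = model.trees[0]
        assert (tree.children_left != -1).sum() == 1  # a single split node
        feat, thr = tree.feature[0], tree.threshold[0]
        shape = model.representative_shapes[0]
        for w, _ in pos[:10] + neg[:10]:
            f = extract_features(w, shape, model.spec)
            side = tree.value[1] if f[feat] <= thr else tree.value[2]
            survived, score, _ = cascade_scores(model, w)[0]
            assert score == pytest.approx(side)

    def test_rejection_happens_at_first_failing_stage(self, detector, detection_task):
        # recompute partial sums by hand and check the rejection index
        win, shape = detection_task.negatives[0]
        for rep in detector.representative_shapes:
            feats = extract_features(win, rep, detector.spec)
            f = 0.0
            expect = detector.n_stages
            for i, (tree, theta) in enumerate(
                zip(detector.trees, detector.thresholds)
            ):
                f += tree.predict(feats[None])[0]
                if f < theta:
                    expect = i
                    break
        survived, _, passed = cascade_scores(detector, win)[-1]
        assert passed == expect or survived

    def test_tree_scores_bounded_for_sound_early_rejection(self, detector):
        for tree in detector.trees:
            assert tree.value.min() >= 0.0 and tree.value.max() <= 1.0

    def test_candidates_per_window_equal_representative_shapes(self, detector, rng):
        win = rng.integers(0, 255, (32, 32)).astype(np.uint8)
        assert len(cascade_scores(detector, win)) == 3
        assert len(detector.representative_shapes) == 3

    def test_missing_samples_raise(self):
        pos, _ = _separable_toy(n=5)
        with pytest.raises(ValueError):
            train_cascade(pos, [], CascadeConfig())
        with pytest.raises(ValueError):
            train_cascade([], pos, CascadeConfig())

    def test_detect_matches_brute_force_argmax(self, detector, rng):
        # <= 20 windows x 3 shapes: exhaustive full-sum argmax over survivors
        windows = []
        for seed in range(10):
            frame, _, _, _ = plant_face_frame(500 + seed, frame_size=32, face_size=32)
            windows.append(frame)
        for seed in range(10):
            windows.append(rng.integers(0, 255, (32, 32)).astype(np.uint8))
        best_bf, best_key = None, None
        for wi, win in enumerate(windows):
            for si, shape in enumerate(detector.representative_shapes):
                feats = extract_features(win, shape, detector.spec)
                f, alive = 0.0, True
                for tree, theta in zip(detector.trees, detector.thresholds):
                    f += tree.predict(feats[None])[0]
                    if f < theta:
                        alive = False
                        break
                if alive and (best_key is None or f > best_key):
                    best_key, best_bf = f, (wi, si)
        got_key, got = None, None
        for wi, win in enumerate(windows):
            for si, (survived, score, _) in enumerate(cascade_scores(detector, win)):
                if survived and (got_key is None or score > got_key):
                    got_key, got = score, (wi, si)
        assert got == best_bf

    def test_detect_rejects_empty_frame(self, detector):
        frame = np.zeros((64, 64), dtype=np.uint8)
        assert detect(frame, detector, ScanConfig(min_window=26, max_window=44)) is None

    def test_detect_finds_planted_face_with_good_overlap(self, detector):
        frame, box, _, _ = plant_face_frame(1234)
        det = detect(
            frame, detector,
            ScanConfig(min_window=26, max_window=44, stride_fraction=0.09),
        )
        assert det is not None
        x, y, w, h = det.box
        X, Y, W, H = box
        ix = max(0, min(x + w, X + W) - max(x, X))
        iy = max(0, min(y + h, Y + H) - max(y, Y))
        iou = ix * iy / (w * h + W * H - ix * iy)
        assert iou >= 0.5

    def test_frame_smaller_than_window_raises(self, detector):
        with pytest.raises(ValueError):
            detect(np.zeros((10, 10), dtype=np.uint8), detector)

    def test_model_json_roundtrip(self, detector, rng):
        from pulsepatch.joint_align import CascadeModel

        clone = CascadeModel.from_json(detector.to_json())
        win = rng.integers(0, 255, (32, 32)).astype(np.uint8)
        assert cascade_scores(clone, win) == cascade_scores(detector, win)


class TestRefinement:
    def test_no_refiner_is_identity(self):
        init = Shape(np.array([[5.0, 5.0], [10.0, 10.0]]))
        out = refine_shape(np.zeros((32, 32), np.uint8), (0, 0, 32, 32), init, None)
        assert out is init

    def test_wrong_landmark_count_raises(self, detection_task):
        refiner = train_refiner(detection_task.positives[:20])
        init = Shape(np.zeros((5, 2)))
        with pytest.raises(ValueError):
            refine_shape(np.zeros((32, 32), np.uint8), (0, 0, 32, 32), init, refiner)

    def test_refiner_reduces_error_on_held_out_perturbations(self, detection_task, rng):
        train = detection_task.positives[:80]
        held = detection_task.positives[80:100]
        refiner = train_refiner(train)
        err0, err1 = [], []
        for win, s in held:
            start = np.clip(s + rng.normal(0, 0.05, s.shape), 0.02, 0.98)
            init = Shape(start * 32)
            out = refine_shape(win, (0, 0, 32, 32), init, refiner)
            err0.append(normalized_error(init.points, s * 32, TOY_EYE_INDICES))
            err1.append(normalized_error(out.points, s * 32, TOY_EYE_INDICES))
        assert np.mean(err1) < np.mean(err0)

    def test_normalized_error_uses_interocular_distance(self):
        truth = np.array([[0.0, 0.0], [0.0, 4.0], [3.0, 0.0]])
        pred = truth + np.array([1.0, 0.0])
        # inter-ocular = distance between points 0 and 2 = 3
        assert normalized_error(pred, truth, (0, 2)) == pytest.approx(1.0 / 3.0)


def test_mean_shape_is_average_of_aligned_shapes(detection_task):
    shapes = [s for s, _ in detection_task.training_shapes]
    ms = mean_shape(shapes)
    assert ms.points.shape == shapes[0].shape
    assert 0.0 < ms.points.min() and ms.points.max() < 1.0
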