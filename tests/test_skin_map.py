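"""Bayesian skin model: color conversion, training, posterior, filtering."""

import warnings

import numpy as np
import pytest

from pulsepatch.patch_mesh import track_patches
from pulsepatch.skin_map import (
    SkinHistogramModel,
    filter_skin_patches,
    rgb_to_cbcr,
    skin_posterior,
    skin_probability_map,
    train_skin_model,
    ycbcr_to_rgb,
)
from pulsepatch.synthetic_scene import (
    SkinTrainingConfig,
    generate_skin_training_set,
)


class TestColorConversion:
    def test_gray_is_chroma_neutral(self):
        assert np.allclose(rgb_to_cbcr(np.array([128, 128, 128])), (128.0, 128.0))

    def test_pure_red_matches_bt601_values(self):
        cb, cr = rgb_to_cbcr(np.array([255, 0, 0]))
        assert cb == pytest.approx(84.972, abs=1e-3)
        assert cr == pytest.approx(255.0)  # clipped at the Cr ceiling

    def test_roundtrip_through_ycbcr(self, rng):
        rgb = rng.integers(30, 220, (50, 3)).astype(float)
        y = 0.299 * rgb[:, 0] + 0.587 * rgb[:, 1] + 0.114 * rgb[:, 2]
        cbcr = rgb_to_cbcr(rgb)
        back = ycbcr_to_rgb(y, cbcr[:, 0], cbcr[:, 1])
        assert np.allclose(back, rgb, atol=1e-6)

    def test_conversion_is_deterministic(self):
        px = np.array([13, 200, 77])
        assert np.array_equal(rgb_to_cbcr(px), rgb_to_cbcr(px))


class TestTraining:
    def test_all_true_mask_makes_posterior_one_everywhere_observed(self, rng):
        img = rng.integers(0, 256, (8, 8, 3)).astype(np.uint8)
        model = train_skin_model([img], [np.ones((8, 8), bool)])
        assert np.array_equal(model.h_skin, model.h_total)
        post = skin_probability_map(model, img)
        assert np.allclose(post, 1.0)

    def test_tiny_image_counts_match_manual_tally(self):
        img = np.array(
            [[[255, 0, 0], [0, 255, 0]], [[255, 0, 0], [128, 128, 128]]],
            dtype=np.uint8,
        )
        mask = np.array([[True, False], [True, False]])
        model = train_skin_model([img], [mask], bin_count=64)
        red_bin = model.bin_index(rgb_to_cbcr(np.array([255, 0, 0])))
        assert model.h_skin[red_bin] == 2
        assert model.h_total[red_bin] == 2
        assert model.n_skin == 2 and model.n_total == 4

    def test_no_skin_pixels_raises(self, rng):
        img = rng.integers(0, 256, (4, 4, 3)).astype(np.uint8)
        with pytest.raises(ValueError):
            train_skin_model([img], [np.zeros((4, 4), bool)])

    def test_synthetic_78_image_set_separates_skin(self, skin_model):
        from sklearn.metrics import roc_auc_score

        images, masks = generate_skin_training_set(SkinTrainingConfig(seed=101))
        post = np.concatenate(
            [skin_probability_map(skin_model, img).ravel() for img in images]
        )
        labels = np.concatenate([m.ravel() for m in masks])
        assert roc_auc_score(labels, post) > 0.95


class TestPosterior:
    def test_worked_bayes_example(self):
        h_skin = np.zeros((64, 64))
        h_total = np.zeros((64, 64))
        h_skin[10, 20] = 30
        h_total[10, 20] = 60
        h_skin[0, 0] = 270  # fill totals: N_skin=300, N_total=600
        h_total[0, 0] = 540
        model = SkinHistogramModel(h_skin, h_total)
        cbcr = np.array([10 * 4 + 1.0, 20 * 4 + 1.0])  # lands in bin (10, 20)
        assert skin_posterior(model, cbcr) == pytest.approx(0.5, abs=1e-12)

    def test_unseen_bin_is_zero(self):
        h = np.zeros((64, 64))
        h[0, 0] = 5
        model = SkinHistogramModel(h.copy(), h.copy())
        assert skin_posterior(model, np.array([255.0, 255.0])) == 0.0

    def test_pure_skin_bin_is_one(self):
        h = np.zeros((64, 64))
        h[3, 3] = 7
        model = SkinHistogramModel(h.copy(), h.copy())
        assert skin_posterior(model, np.array([13.0, 13.0])) == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_full_formula_reduces_to_count_ratio(self, seed):
        rng = np.random.default_rng(seed)
        h_total = rng.integers(0, 50, (64, 64)).astype(float)
        h_skin = np.floor(h_total * rng.uniform(0, 1, (64, 64)))
        model = SkinHistogramModel(h_skin, h_total)
        cbcr = rng.uniform(0, 255, (200, 2))
        post = skin_posterior(model, cbcr)
        i, j = model.bin_index(cbcr)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(h_total[i, j] > 0, h_skin[i, j] / h_total[i, j], 0.0)
        assert np.allclose(post, ratio, atol=1e-12)

    def test_posterior_converges_to_generating_truth(self):
        # two-component generator with known P(skin | bin)
        rng = np.random.default_rng(42)
        n = 10**5
        is_skin = rng.uniform(size=n) < 0.4
        cbcr = np.where(
            is_skin[:, None],
            rng.normal((110, 150), 6, (n, 2)),
            rng.uniform(0, 255, (n, 2)),
        ).clip(0, 255)
        y = np.full(n, 150.0)
        rgb = ycbcr_to_rgb(y, cbcr[:, 0], cbcr[:, 1])
        img = np.clip(np.rint(rgb), 0, 255).astype(np.uint8).reshape(-1, 1, 3)
        model = train_skin_model([img], [is_skin.reshape(-1, 1)])
        # empirical truth per bin from the same sample is the MLE the
        # posterior should match as n grows
        i, j = model.bin_index(rgb_to_cbcr(img.reshape(-1, 3)))
        flat = i * 64 + j
        tot = np.bincount(flat, minlength=64 * 64).astype(float)
        sk = np.bincount(flat[is_skin], minlength=64 * 64).astype(float)
        heavy = tot >= 500  # bins with enough mass for a stable estimate
        post = (model.h_skin.ravel() / np.maximum(model.h_total.ravel(), 1))[heavy]
        truth = (sk / np.maximum(tot, 1))[heavy]
        assert np.abs(post - truth).max() <= 0.02


class TestPatchFiltering:
    def test_default_threshold_is_point_seven(self):
        import inspect

        sig = inspect.signature(filter_skin_patches)
        assert sig.parameters["threshold"].default == 0.7

    def test_occluder_patches_filtered_out(
        self, default_scene, default_track_set, skin_model
    ):
        stack, truth = default_scene
        ts = default_track_set
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kept, scores = filter_skin_patches(
                ts.label_maps, stack.frames, skin_model,
                ts.mesh.n_triangles, return_scores=True,
            )
        # patches made of glasses/beard pixels must be gone
        skin_frac = []
        for tid in range(ts.mesh.n_triangles):
            member = ts.label_maps[0] == tid
            if member.sum() == 0:
                continue
            frac = truth.skin_mask_per_frame[0][member].mean()
            skin_frac.append((tid, frac))
        occluded = [tid for tid, f in skin_frac if f < 0.2]
        assert occluded, "scene should contain occluder-dominated patches"
        assert not set(occluded) & set(kept.tolist())
        clean = [tid for tid, f in skin_frac if f > 0.95]
        assert set(clean) <= set(kept.tolist())

    def test_zero_threshold_keeps_every_nonempty_patch(
        self, default_scene, default_track_set, skin_model
    ):
        stack, _ = default_scene
        ts = default_track_set
        nonempty = [t.triangle_id for t in ts.tracks if t.counts.sum() > 0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kept = filter_skin_patches(
                ts.label_maps, stack.frames, skin_model,
                ts.mesh.n_triangles, threshold=0.0,
            )
        assert set(kept.tolist()) == set(nonempty)
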