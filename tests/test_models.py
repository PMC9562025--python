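"""Classifier, segmenter, composite loss and heatmap prediction."""

import numpy as np
import pytest

import tntdetect as td
from tntdetect import models, nn, patching
from tntdetect.config import ClassifierConfig, SegmenterConfig
from tntdetect.types import BinaryMask, ValidationError


def _labelled_patches(n_pos=10, n_neg=10, size=128):
    """Phantom patches with/without TNTs for classifier training."""
    spec = td.PhantomSpec(image_height_px=512, image_width_px=512, n_cells=12,
                          tnt_probability_per_cell_pair=0.5, noise_sd=0.02,
                          seed=11)
    image, truth = td.generate_phantom(spec)
    rule = td.PatchLabelRule(min_tnt_pixels=20, center_fraction=0.8)
    pos, neg = [], []
    for origin in patching.slide_windows(image.shape, size, 32):
        rec = patching.PatchRecord(origin=origin, size=size, level="fine")
        rs, cs = rec.slices()
        label = patching.label_patch(
            BinaryMask(truth.tnt_mask.pixels[rs, cs]), rule)
        (pos if label else neg).append(rec)
    pos, neg = pos[:n_pos], neg[:n_neg]
    x = np.stack([patching.patch_pixels(image, r) for r in pos + neg])
    y = np.array([1] * len(pos) + [0] * len(neg))
    return x, y, image, truth


@pytest.fixture(scope="module")
def classifier_patches():
    return _labelled_patches()


class TestClassifier:
    def test_forward_on_zeros_gives_probability(self):
        cfg = ClassifierConfig(input_size=64, pool_to=32, seed=0)
        h = td.build_classifier(cfg)
        p = h.predict_proba(np.zeros((2, 64, 64)))
        assert p.shape == (2,)
        assert np.all((p >= 0) & (p <= 1))
        assert np.all(np.isfinite(p))

    def test_both_published_sizes_constructible(self):
        # two instances, one per window scale
        for size in (512, 256):
            h = td.build_classifier(ClassifierConfig(input_size=size, seed=0))
            assert h.config.input_size == size

    def test_pretrained_backbone_unavailable_error(self):
        with pytest.raises(models.PretrainedUnavailableError,
                           match="small_cnn"):
            td.build_classifier(ClassifierConfig(backbone="vgg16_pretrained"))

    def test_overfits_twenty_phantom_patches(self, classifier_patches):
        x, y, _, _ = classifier_patches
        cfg = ClassifierConfig(input_size=128, pool_to=64, epochs=50,
                               batch_size=8, learning_rate=3e-3, seed=0)
        h = td.build_classifier(cfg)
        h, history = td.train_classifier(h, x, y, cfg)
        assert max(history["accuracy"]) == 1.0
        eval_acc = ((h.predict_proba(x) >= 0.5) == (y > 0.5)).mean()
        assert eval_acc == 1.0

    def test_loss_decreases_on_separable_data(self, rng):
        # two separable intensity blobs
        x = np.concatenate([rng.normal(0.2, 0.02, (8, 32, 32)),
                            rng.normal(0.8, 0.02, (8, 32, 32))])
        y = np.array([0] * 8 + [1] * 8)
        cfg = ClassifierConfig(input_size=32, pool_to=16, epochs=5,
                               dropout_rate=0.0, seed=0)
        h = td.build_classifier(cfg)
        _, history = td.train_classifier(h, x, y, cfg)
        assert history["loss"][-1] <= history["loss"][0] + 1e-9

    def test_label_permutation_gives_chance_validation(self, rng):
        x_train = np.concatenate([rng.normal(0.2, 0.02, (16, 32, 32)),
                                  rng.normal(0.8, 0.02, (16, 32, 32))])
        y_perm = rng.permutation(np.array([0] * 16 + [1] * 16))
        x_val = np.concatenate([rng.normal(0.2, 0.02, (50, 32, 32)),
                                rng.normal(0.8, 0.02, (50, 32, 32))])
        y_val = np.array([0] * 50 + [1] * 50)
        cfg = ClassifierConfig(input_size=32, pool_to=16, epochs=10,
                               dropout_rate=0.0, seed=1)
        h = td.build_classifier(cfg)
        h, _ = td.train_classifier(h, x_train, y_perm, cfg)
        acc = ((h.predict_proba(x_val) >= 0.5) == (y_val > 0.5)).mean()
        assert abs(acc - 0.5) <= 0.15

    def test_empty_and_single_class_rejected(self):
        cfg = ClassifierConfig(input_size=32, pool_to=16, seed=0)
        h = td.build_classifier(cfg)
        with pytest.raises(ValidationError):
            td.train_classifier(h, np.zeros((0, 32, 32)), np.zeros(0), cfg)
        with pytest.raises(ValidationError):
            td.train_classifier(h, np.zeros((4, 32, 32)), np.ones(4), cfg)

    def test_inference_deterministic(self, rng):
        cfg = ClassifierConfig(input_size=32, pool_to=16, seed=0)
        h = td.build_classifier(cfg)
        x = rng.uniform(0, 1, (3, 32, 32))
        assert np.array_equal(h.predict_proba(x), h.predict_proba(x))


class TestCompositeLoss:
    def test_perfect_binary_prediction_zeroes_bce_and_dice(self, rng):
        t = (rng.uniform(0, 1, (16, 16)) > 0.5).astype(float)
        loss = td.composite_loss(t, t, weights=(1.0, 1.0, 0.0))
        assert loss == pytest.approx(0.0, abs=1e-5)

    def test_uniform_half_probability_gives_log2_bce(self):
        t = np.zeros((10, 10))
        t[:5] = 1.0
        p = np.full((10, 10), 0.5)
        loss = td.composite_loss(p, t, weights=(1.0, 0.0, 0.0))
        assert loss == pytest.approx(np.log(2.0), rel=1e-6)

    def test_ac_length_term_approximates_circle_perimeter(self):
        from skimage.draw import disk
        u = np.zeros((64, 64))
        rr, cc = disk((32, 32), 20)
        u[rr, cc] = 1.0
        length = nn.ac_length_term(u)
        assert length == pytest.approx(2 * np.pi * 20, rel=0.15)

    def test_non_negative_and_zero_only_at_match(self, rng):
        t = (rng.uniform(0, 1, (8, 8)) > 0.5).astype(float)
        p = np.clip(t + rng.uniform(-0.2, 0.2, t.shape), 0, 1)
        assert td.composite_loss(p, t, weights=(1, 1, 0)) > 0

    def test_dice_invariant_under_spatial_permutation(self, rng):
        t = (rng.uniform(0, 1, (12, 12)) > 0.5).astype(float)
        p = rng.uniform(0, 1, (12, 12))
        perm = rng.permutation(144)
        d1 = td.composite_loss(p, t, weights=(0, 1, 0))
        d2 = td.composite_loss(p.ravel()[perm].reshape(12, 12),
                               t.ravel()[perm].reshape(12, 12),
                               weights=(0, 1, 0))
        assert d1 == pytest.approx(d2, rel=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            td.composite_loss(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_gradient_matches_numeric(self, rng):
        p = rng.uniform(0.1, 0.9, (6, 6))
        t = (rng.uniform(0, 1, (6, 6)) > 0.5).astype(float)
        loss, grad = models.composite_loss(p, t, (1.0, 1.0, 1.0),
                                           return_grad=True)
        eps = 1e-6
        for idx in [(0, 0), (3, 4), (5, 5)]:
            pp = p.copy()
            pp[idx] += eps
            pm = p.copy()
            pm[idx] -= eps
            num = (models.composite_loss(pp, t, (1, 1, 1))
                   - models.composite_loss(pm, t, (1, 1, 1))) / (2 * eps)
            assert num == pytest.approx(grad[idx], rel=1e-4, abs=1e-8)


class TestSegmenter:
    def test_untrained_forward_shape_and_range(self, rng):
        cfg = SegmenterConfig(seed=0)
        h = td.build_segmenter(cfg)
        x = rng.uniform(0, 1, (2, 32, 32))
        p = h.predict_proba(x)
        assert p.shape == (2, 32, 32)
        assert np.all((p >= 0) & (p <= 1))

    def test_pretrained_encoder_unavailable_error(self):
        with pytest.raises(models.PretrainedUnavailableError,
                           match="small_encoder"):
            td.build_segmenter(SegmenterConfig(encoder="resnet_pretrained"))

    def test_indivisible_crop_size_names_padding(self):
        h = td.build_segmenter(SegmenterConfig(depth=2, seed=0))
        with pytest.raises(ValidationError, match="pad"):
            h.predict_proba(np.zeros((1, 30, 30)))

    def test_attention_toggle_changes_output_not_shape(self, rng):
        x = rng.uniform(0, 1, (1, 16, 16))
        with_att = td.build_segmenter(SegmenterConfig(use_attention=True, seed=0))
        without = td.build_segmenter(SegmenterConfig(use_attention=False, seed=0))
        pa, pb = with_att.predict_proba(x), without.predict_proba(x)
        assert pa.shape == pb.shape
        assert not np.allclose(pa, pb)

    def test_overfits_ten_phantom_crops(self, classifier_patches):
        _, _, image, truth = classifier_patches
        rng = np.random.default_rng(0)
        rr, cc = np.nonzero(truth.tnt_mask.pixels)
        crops, targets = [], []
        for _ in range(10):
            k = rng.integers(len(rr))
            r = int(np.clip(rr[k] - 32, 0, image.shape[0] - 64))
            c = int(np.clip(cc[k] - 32, 0, image.shape[1] - 64))
            crops.append(image.as_float()[r:r + 64, c:c + 64])
            targets.append(truth.tnt_mask.pixels[r:r + 64, c:c + 64])
        crops = np.stack(crops)
        targets = np.stack(targets).astype(np.float32)
        cfg = SegmenterConfig(epochs=200, batch_size=10, seed=0)
        h = td.build_segmenter(cfg)
        h, history = td.train_segmenter(h, crops, targets, cfg)
        pred = h.predict_proba(crops)
        assert models.dice_coefficient(pred >= 0.5, targets) >= 0.9

    def test_inference_deterministic(self, rng):
        h = td.build_segmenter(SegmenterConfig(seed=0))
        x = rng.uniform(0, 1, (1, 16, 16))
        assert np.array_equal(h.predict_proba(x), h.predict_proba(x))


class TestPredictHeatmap:
    class _Stub:
        def __init__(self, value):
            self.value = value

        def predict_proba(self, crops):
            return np.full(crops.shape, self.value)[..., :, :]

    def test_unit_probability_gives_255(self):
        hm = td.predict_heatmap(self._Stub(1.0), np.zeros((32, 32)))
        assert np.all(hm.pixels == 255)

    def test_counting_threshold_boundary(self):
        # p = 0.9216 maps exactly onto the counting threshold 235
        hm = td.predict_heatmap(self._Stub(0.9216), np.zeros((8, 8)))
        assert np.all(hm.pixels == 235)
        hm_low = td.predict_heatmap(self._Stub(0.9195), np.zeros((8, 8)))
        assert np.all(hm_low.pixels == 234)

    def test_trained_model_highlights_tnt_pixels(self, classifier_patches):
        _, _, image, truth = classifier_patches
        rng = np.random.default_rng(1)
        rr, cc = np.nonzero(truth.tnt_mask.pixels)
        crops, targets = [], []
        for _ in range(16):
            k = rng.integers(len(rr))
            r = int(np.clip(rr[k] - 32, 0, image.shape[0] - 64))
            c = int(np.clip(cc[k] - 32, 0, image.shape[1] - 64))
            crops.append(image.as_float()[r:r + 64, c:c + 64])
            targets.append(truth.tnt_mask.pixels[r:r + 64, c:c + 64])
        cfg = SegmenterConfig(epochs=60, batch_size=8, seed=0)
        h = td.build_segmenter(cfg)
        h, _ = td.train_segmenter(h, np.stack(crops),
                                  np.stack(targets).astype(np.float32), cfg)
        hm = td.predict_heatmap(h, crops[0])
        t0 = targets[0]
        assert hm.pixels[t0 == 1].mean() > hm.pixels[t0 == 0].mean()

    def test_wrong_patch_shape_rejected(self):
        with pytest.raises(ValidationError):
            td.predict_heatmap(self._Stub(1.0), np.zeros((2, 32, 32)))


def test_checkpoint_round_trip(tmp_path, rng):
    ccfg = ClassifierConfig(input_size=32, pool_to=16, seed=0)
    cls = td.build_classifier(ccfg)
    x = rng.uniform(0, 1, (3, 32, 32))
    models.save_classifier(str(tmp_path / "cls"), cls)
    cls2 = models.load_classifier(str(tmp_path / "cls"))
    assert np.allclose(cls.predict_proba(x), cls2.predict_proba(x))

    scfg = SegmenterConfig(seed=0)
    seg = td.build_segmenter(scfg)
    xs = rng.uniform(0, 1, (1, 16, 16))
    models.save_segmenter(str(tmp_path / "seg"), seg)
    seg2 = models.load_segmenter(str(tmp_path / "seg"))
    assert np.allclose(seg.predict_proba(xs), seg2.predict_proba(xs))
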