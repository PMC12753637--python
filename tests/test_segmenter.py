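"""Segmenter: loss, augmentation, prediction rule, training loop."""

import math
from dataclasses import dataclass

import numpy as np
import pytest

from pdl1tps.segmenter import (TrainingConfig, augment, build_model,
                               load_model, predict_mask, train, wce_loss)
from pdl1tps.validation import make_training_patches


@dataclass
class _StubModel:
    """Fixed probability map standing in for a trained network."""
    probs: np.ndarray
    config: TrainingConfig = None

    def __post_init__(self):
        if self.config is None:
            self.config = TrainingConfig(architecture="reduced", epochs=0)

    def predict_proba(self, image):
        return self.probs


class TestWCELoss:
    def test_perfect_prediction_is_zero(self):
        target = np.array([[0, 1], [2, 0]])
        probs = np.eye(3)[target]
        assert wce_loss(probs, target) == pytest.approx(0.0, abs=1e-9)

    def test_single_pixel_closed_form(self):
        # target class 1, p=0.5, weight 0.9 -> 0.9 * (-ln 0.5)
        probs = np.array([[[0.25, 0.5, 0.25]]])
        target = np.array([[1]])
        want = 0.9 * -math.log(0.5)
        assert wce_loss(probs, target, (0.4, 0.9, 0.9)) == pytest.approx(
            want, abs=1e-9)

    def test_uniform_weights_equal_plain_cross_entropy(self, rng):
        probs = rng.dirichlet((1.0, 1.0, 1.0), size=(16, 16))
        target = rng.integers(0, 3, (16, 16))
        got = wce_loss(probs, target, (1.0, 1.0, 1.0))
        # independent oracle: direct negative log-likelihood mean
        want = float(np.mean([-math.log(probs[i, j, target[i, j]])
                              for i in range(16) for j in range(16)]))
        assert got == pytest.approx(want, abs=1e-9)

    def test_zero_probability_clamped_finite(self):
        probs = np.zeros((1, 1, 3))
        probs[0, 0, 0] = 1.0
        target = np.array([[2]])
        loss = wce_loss(probs, target)
        assert np.isfinite(loss) and loss > 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            wce_loss(np.zeros((2, 2, 3)), np.zeros((3, 3), dtype=int))


class TestAugment:
    def _pair(self, rng):
        img = rng.integers(0, 255, (32, 32, 3)).astype(np.uint8)
        msk = rng.integers(0, 3, (32, 32)).astype(np.uint8)
        return img, msk

    def test_identity_when_disabled(self, rng):
        img, msk = self._pair(rng)
        cfg = TrainingConfig(flip_probability=0.0, rotation_max_deg=0.0,
                             epochs=0)
        out_img, out_msk = augment(img, msk, cfg, 0)
        np.testing.assert_array_equal(out_img, img)
        np.testing.assert_array_equal(out_msk, msk)

    def test_certain_flip_is_an_involution(self, rng):
        img, msk = self._pair(rng)
        cfg = TrainingConfig(flip_probability=1.0, rotation_max_deg=0.0,
                             epochs=0)
        once = augment(img, msk, cfg, 1)
        twice = augment(once[0], once[1], cfg, 2)
        np.testing.assert_array_equal(twice[0], img)
        np.testing.assert_array_equal(twice[1], msk)

    def test_mask_labels_preserved_under_rotation(self, rng):
        img, msk = self._pair(rng)
        cfg = TrainingConfig(flip_probability=0.5, rotation_max_deg=30.0,
                             epochs=0)
        for seed in range(5):
            _, out = augment(img, msk, cfg, seed)
            assert set(np.unique(out)) <= {0, 1, 2}

    def test_same_seed_same_transform(self, rng):
        img, msk = self._pair(rng)
        cfg = TrainingConfig(epochs=0)
        a = augment(img, msk, cfg, 3)
        b = augment(img, msk, cfg, 3)
        np.testing.assert_array_equal(a[0], b[0])


class TestPredictMask:
    def _image(self):
        return np.zeros((1, 1, 3), dtype=np.uint8)

    @pytest.mark.parametrize("probs,expected", [
        ((0.1, 0.7, 0.2), 1),   # confident positive
        ((0.1, 0.2, 0.7), 2),   # confident negative
        ((0.34, 0.33, 0.33), 0),  # no foreground reaches 0.5
        ((0.0, 0.5, 0.5), 1),   # tie breaks toward the positive class
        ((0.5, 0.5, 0.0), 1),   # foreground at exactly the threshold counts
    ])
    def test_threshold_rule(self, probs, expected):
        model = _StubModel(np.array([[list(probs)]]))
        mask = predict_mask(model, self._image(), 0.5)
        assert mask[0, 0] == expected

    def test_emits_only_valid_labels(self, rng):
        probs = rng.dirichlet((1, 1, 1), size=(8, 8))
        model = _StubModel(probs)
        mask = predict_mask(model, np.zeros((8, 8, 3), dtype=np.uint8), 0.5)
        assert set(np.unique(mask)) <= {0, 1, 2}
        assert mask.shape == (8, 8)


class TestConfigValidation:
    def test_rejects_bad_values(self):
        with pytest.raises(ValueError):
            TrainingConfig(class_weights=(0.4, -0.9, 0.9))
        with pytest.raises(ValueError):
            TrainingConfig(flip_probability=1.5)
        with pytest.raises(ValueError):
            TrainingConfig(mask_threshold=0.0)

    def test_paper_scale_defaults(self):
        cfg = TrainingConfig()
        assert cfg.learning_rate == pytest.approx(1e-4)
        assert cfg.epochs == 100
        assert cfg.batch_size == 8
        assert cfg.class_weights == (0.4, 0.9, 0.9)
        assert cfg.mask_threshold == 0.5

    def test_pretrained_hook_not_bundled(self):
        with pytest.raises(NotImplementedError):
            TrainingConfig(pretrained_encoder=True)


@pytest.fixture(scope="module")
def tiny_dataset():
    return make_training_patches(16, seed=11)


class TestTrain:
    def test_zero_epochs_is_identity(self, tiny_dataset):
        cfg = TrainingConfig(architecture="reduced", epochs=0, seed=1)
        model = build_model(cfg)
        before = [p.value.copy() for p in model.net.params()]
        model, history = train(model, tiny_dataset, cfg)
        assert len(history) == 0
        for b, p in zip(before, model.net.params()):
            np.testing.assert_array_equal(b, p.value)

    def test_loss_decreases_on_easy_data(self, tiny_dataset):
        cfg = TrainingConfig(architecture="reduced", epochs=3, seed=7,
                             learning_rate=1e-3, rotation_max_deg=0.0)
        model = build_model(cfg)
        _, history = train(model, tiny_dataset, cfg)
        assert len(history.train_loss) == 3
        assert history.train_loss[-1] < history.train_loss[0]

    def test_training_is_deterministic(self, tiny_dataset):
        traces = []
        for _ in range(2):
            cfg = TrainingConfig(architecture="reduced", epochs=2, seed=3,
                                 learning_rate=1e-3)
            model = build_model(cfg)
            _, history = train(model, tiny_dataset, cfg)
            traces.append(history.train_loss)
        assert traces[0] == traces[1]

    def test_empty_dataset_rejected(self):
        cfg = TrainingConfig(architecture="reduced", epochs=1)
        with pytest.raises(ValueError):
            train(build_model(cfg), [], cfg)

    def test_checkpoint_round_trip(self, tiny_dataset, tmp_path):
        cfg = TrainingConfig(architecture="reduced", epochs=1, seed=5,
                             learning_rate=1e-3)
        model = build_model(cfg)
        model, _ = train(model, tiny_dataset, cfg)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = load_model(path)
        img = tiny_dataset[0][0]
        np.testing.assert_array_equal(predict_mask(model, img),
                                      predict_mask(loaded, img))
        assert loaded.config.architecture == "reduced"
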