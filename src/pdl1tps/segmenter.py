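"""Trainable tumour-cell segmentation.

The model is a U-Net-style encoder-decoder that maps an RGB IHC patch to a
per-pixel probability triple over (background, PD-L1-positive tumour cell,
PD-L1-negative tumour cell). Training minimises a weighted cross-entropy
(WCE) loss — default class weights (0.4, 0.9, 0.9) for (background,
positive, negative) — with the Adam optimizer, flip/rotation augmentation,
and input intensities rescaled from [0, 255] to [0, 1].

Prediction converts probabilities to a :term:`label mask` in {0,1,2}: a
pixel takes the foreground class of highest probability when that
probability reaches ``mask_threshold`` (default 0.5), otherwise background.
Ties between the two foreground classes break toward the positive class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .nn import Adam, ShapeError, UNet

__all__ = [
    "TrainingConfig",
    "TrainingHistory",
    "SegmentationModel",
    "build_model",
    "wce_loss",
    "augment",
    "train",
    "predict_mask",
    "load_model",
]

_EPS = 1e-12


@dataclass
class TrainingConfig:
    """Hyperparameters for segmentation training.

    Defaults follow the full-scale training recipe (lr 1e-4, 100 epochs,
    batch 8, WCE weights 0.4/0.9/0.9, rotations up to 30 degrees, flips with
    probability 0.5, 0.5 mask threshold); ``epochs`` is typically overridden
    to a handful for CPU-scale runs on synthetic data.
    """

    learning_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 8
    class_weights: tuple[float, float, float] = (0.4, 0.9, 0.9)
    rotation_max_deg: float = 30.0
    flip_probability: float = 0.5
    mask_threshold: float = 0.5
    pretrained_encoder: bool = False
    architecture: str = "full"
    seed: int = 0

    def __post_init__(self):
        self.class_weights = tuple(float(w) for w in self.class_weights)
        if len(self.class_weights) != 3 or any(w <= 0 for w in self.class_weights):
            raise ValueError("class_weights must be three positive reals")
        if not 0.0 <= self.flip_probability <= 1.0:
            raise ValueError("flip_probability must lie in [0, 1]")
        if not 0.0 < self.mask_threshold < 1.0:
            raise ValueError("mask_threshold must lie in (0, 1)")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("invalid optimisation parameters")
        if self.pretrained_encoder:
            raise NotImplementedError(
                "pretrained encoder weights are an optional hook; no weight "
                "file is bundled — train from random initialisation instead")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    def __len__(self):
        return len(self.train_loss)

    def to_rows(self):
        rows = []
        for i, tl in enumerate(self.train_loss):
            vl = self.val_loss[i] if i < len(self.val_loss) else None
            rows.append({"epoch": i + 1, "train_loss": tl, "val_loss": vl})
        return rows


def _normalize(image: np.ndarray) -> np.ndarray:
    """Affine map of 8-bit intensities [0,255] -> [0,1], channel-first."""
    img = np.asarray(image, dtype=np.float32)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB image")
    return np.ascontiguousarray(img.transpose(2, 0, 1)) / 255.0


class SegmentationModel:
    """Wrapper pairing a network with the config it was built from."""

    def __init__(self, config: TrainingConfig):
        self.config = config
        self.net = UNet(variant=config.architecture, seed=config.seed)

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """Class probability map (H, W, 3); rows sum to one per pixel."""
        x = _normalize(image)[None]
        logits = self.net.forward(x)[0]
        logits -= logits.max(axis=0, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=0, keepdims=True)
        return probs.transpose(1, 2, 0)

    def save(self, path) -> None:
        """Self-describing checkpoint: config echo plus parameter blobs."""
        arrays = {f"param_{i:04d}": a for i, a in
                  enumerate(self.net.state_arrays())}
        np.savez_compressed(path, config=json.dumps(asdict(self.config)),
                            **arrays)


def load_model(path) -> SegmentationModel:
    with np.load(path, allow_pickle=False) as ckpt:
        cfg = TrainingConfig(**json.loads(str(ckpt["config"])))
        model = SegmentationModel(cfg)
        keys = sorted(k for k in ckpt.files if k.startswith("param_"))
        model.net.load_state_arrays([ckpt[k] for k in keys])
    return model


def build_model(config: TrainingConfig) -> SegmentationModel:
    """Construct an (untrained) segmentation model from a config."""
    return SegmentationModel(config)


def wce_loss(probabilities: np.ndarray, target: np.ndarray,
             class_weights=(0.4, 0.9, 0.9)) -> float:
    """Weighted cross-entropy: mean over pixels of w[t] * (-log p[t]).

    ``probabilities`` is an (H, W, 3) class probability map; ``target`` an
    (H, W) label mask in {0,1,2}. Probabilities are clamped at 1e-12 so the
    loss is always finite. With unit weights this is the ordinary pixelwise
    cross-entropy.
    """
    probs = np.asarray(probabilities, dtype=np.float64)
    target = np.asarray(target)
    if probs.shape[:2] != target.shape or probs.shape[-1] != 3:
        raise ValueError("probability map and target mask shapes differ")
    w = np.asarray(class_weights, dtype=np.float64)
    p_t = np.take_along_axis(probs, target[..., None].astype(np.int64),
                             axis=-1)[..., 0]
    return float(np.mean(w[target] * -np.log(np.maximum(p_t, _EPS))))


def augment(image: np.ndarray, mask: np.ndarray, config: TrainingConfig,
            seed_or_rng) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random flip/flip/rotation jointly to an image-mask pair.

    Horizontal and vertical flips each occur with ``flip_probability``; the
    rotation angle is uniform on [-rotation_max_deg, +rotation_max_deg].
    The mask is resampled with nearest-neighbour interpolation so labels
    stay in {0,1,2}; the image bilinearly, with edge replication.
    """
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    if image.shape[:2] != mask.shape:
        raise ValueError("image and mask spatial shapes differ")
    img, msk = image, mask
    if rng.random() < config.flip_probability:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if rng.random() < config.flip_probability:
        img, msk = img[::-1, :], msk[::-1, :]
    if config.rotation_max_deg > 0:
        angle = rng.uniform(-config.rotation_max_deg, config.rotation_max_deg)
        img = ndimage.rotate(img, angle, axes=(1, 0), reshape=False,
                             order=1, mode="nearest")
        msk = ndimage.rotate(msk, angle, axes=(1, 0), reshape=False,
                             order=0, mode="nearest")
    return np.ascontiguousarray(img), np.ascontiguousarray(msk)


def _wce_logits_grad(logits: np.ndarray, targets: np.ndarray,
                     weights: np.ndarray) -> tuple[float, np.ndarray]:
    """Loss and d(loss)/d(logits) for a (N,3,H,W) logit batch."""
    m = logits.max(axis=1, keepdims=True)
    e = np.exp(logits - m)
    probs = e / e.sum(axis=1, keepdims=True)
    n, _, h, w = logits.shape
    t = targets.astype(np.int64)
    p_t = np.take_along_axis(probs, t[:, None], axis=1)[:, 0]
    w_t = weights[t]
    loss = float(np.mean(w_t * -np.log(np.maximum(p_t, _EPS))))
    onehot = np.zeros_like(probs)
    np.put_along_axis(onehot, t[:, None], 1.0, axis=1)
    grad = (probs - onehot) * w_t[:, None] / (n * h * w)
    return loss, grad.astype(np.float32)


def _validate_dataset(dataset):
    if not dataset:
        raise ValueError("training dataset is empty")
    for img, msk in dataset:
        if img.shape[:2] != msk.shape:
            raise ValueError("image and mask spatial shapes differ")
        if not np.isin(msk, (0, 1, 2)).all():
            raise ValueError("mask contains labels outside {0,1,2}")


def train(model: SegmentationModel, dataset, config: TrainingConfig,
          val_dataset=None) -> tuple[SegmentationModel, TrainingHistory]:
    """Mini-batch Adam training of the segmentation network.

    ``dataset`` is a sequence of (HxWx3 uint8 image, HxW label mask) pairs.
    The run is fully seeded (shuffling, augmentation) from ``config.seed``;
    identical inputs give identical loss traces. With ``epochs == 0`` the
    parameters are untouched and the history is empty.
    """
    _validate_dataset(dataset)
    history = TrainingHistory()
    if config.epochs == 0:
        return model, history
    weights = np.asarray(config.class_weights, dtype=np.float64)
    opt = Adam(model.net.params(), lr=config.learning_rate)
    ss = np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 0x7121])
    shuffle_rng, aug_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    n = len(dataset)
    for _ in range(config.epochs):
        order = shuffle_rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            imgs, msks = [], []
            for i in idx:
                img, msk = augment(dataset[i][0], dataset[i][1], config, aug_rng)
                imgs.append(_normalize(img))
                msks.append(msk)
            x = np.stack(imgs)
            t = np.stack(msks)
            logits = model.net.forward(x)
            loss, dlogits = _wce_logits_grad(logits, t, weights)
            opt.zero_grad()
            model.net.backward(dlogits)
            opt.step()
            losses.append(loss)
        history.train_loss.append(float(np.mean(losses)))
        if val_dataset:
            vlosses = [wce_loss(model.predict_proba(img), msk, weights)
                       for img, msk in val_dataset]
            history.val_loss.append(float(np.mean(vlosses)))
    return model, history


def predict_mask(model: SegmentationModel, image: np.ndarray,
                 mask_threshold: float | None = None) -> np.ndarray:
    """Threshold the probability map into a {0,1,2} label mask.

    A pixel is assigned the foreground class (1 positive, 2 negative) with
    the larger probability provided that probability is at least the
    threshold; otherwise background. An exact tie prefers class 1.
    """
    thr = model.config.mask_threshold if mask_threshold is None else mask_threshold
    probs = model.predict_proba(image)
    fg = probs[..., 1:3]
    best = fg.argmax(axis=-1)          # argmax takes the first maximum on ties
    best_p = np.take_along_axis(fg, best[..., None], axis=-1)[..., 0]
    return np.where(best_p >= thr, best + 1, 0).astype(np.uint8)
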