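"""Dataset splitting, augmentation, and the training loops.

Splitting is 80:20 train/test after a seeded shuffle, then 80:20
train/validation of the remainder.  Image-mode training data are tripled by
horizontal + vertical mirroring (masks transformed identically) and further
perturbed per epoch by mild random brightness (uniform in [0.8, 1.2],
images only, clipped to the valid range) and zoom (uniform in [0.9, 1.1],
bilinear for images, nearest for masks, recropped to the original size).
All randomness flows from a single seeded generator per run, so a fixed
seed reproduces training bit-for-bit.

Default hyperparameters per task (the fixed training recipes):

==================  ======  =====  =========  ======  ========
task                epochs  batch  optimizer  lr      loss
==================  ======  =====  =========  ======  ========
detect_image            50     16  RMSprop    1e-4    BCE
detect_features        100     16  Adam       1e-3    BCE
seg2d_unet(+pp)         60      8  Adam       1e-3    hybrid
seg3d_unet(+pp)         50      8  Adam       1e-4    Dice
==================  ======  =====  =========  ======  ========
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import DegenerateDataError, ShapeError, SizeError
from . import models
from .nn import LOSSES, Network, make_optimizer

__all__ = [
    "DatasetSplit",
    "TrainConfig",
    "TrainResult",
    "split_dataset",
    "augment_flips",
    "random_augment",
    "train_detection",
    "train_segmentation",
]

_TASKS = {
    #                epochs batch  optimizer     lr    loss
    "detect_image":    (50,   16,  "rmsprop",  1e-4,  "bce"),
    "detect_features": (100,  16,  "adam",     1e-3,  "bce"),
    "seg2d_unet":      (60,    8,  "adam",     1e-3,  "hybrid"),
    "seg2d_unetpp":    (60,    8,  "adam",     1e-3,  "hybrid"),
    "seg3d_unet":      (50,    8,  "adam",     1e-4,  "dice"),
    "seg3d_unetpp":    (50,    8,  "adam",     1e-4,  "dice"),
}

_BUILDERS = {
    "seg2d_unet": models.build_unet2d,
    "seg2d_unetpp": models.build_unetpp2d,
    "seg3d_unet": models.build_unet_multimodal,
    "seg3d_unetpp": models.build_unetpp_multimodal,
}


@dataclass(frozen=True)
class DatasetSplit:
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int


@dataclass(frozen=True)
class TrainConfig:
    task: str
    epochs: int
    batch_size: int
    optimizer: str
    learning_rate: float
    loss: str
    seed: int = 0
    width_multiplier: float = 1.0

    @classmethod
    def default(cls, task: str, **overrides) -> "TrainConfig":
        if task not in _TASKS:
            raise ValueError(f"unknown task {task!r}; one of {sorted(_TASKS)}")
        epochs, batch, opt, lr, loss = _TASKS[task]
        cfg = cls(task=task, epochs=epochs, batch_size=batch, optimizer=opt,
                  learning_rate=lr, loss=loss)
        return replace(cfg, **overrides) if overrides else cfg


@dataclass
class TrainResult:
    network: Network
    history: list
    split: DatasetSplit
    test_metric: float | None = None
    per_sample: list = field(default_factory=list)


def split_dataset(n_items: int, seed: int) -> DatasetSplit:
    """Seeded shuffle, 80:20 test split, then 80:20 validation split of the
    remainder; deterministic and exhaustive."""
    if n_items < 5:
        raise SizeError(f"need at least 5 items to split, got {n_items}")
    perm = np.random.default_rng(seed).permutation(n_items)
    n_test = int(round(0.2 * n_items))
    rest = perm[n_test:]
    n_val = int(round(0.2 * len(rest)))
    return DatasetSplit(train=rest[n_val:], validation=rest[:n_val],
                        test=perm[:n_test], seed=seed)


def _pair_arrays(pairs):
    out = []
    for img, mask in pairs:
        img = np.asarray(getattr(img, "pixels", img))
        mask = None if mask is None else np.asarray(getattr(mask, "pixels", mask))
        if mask is not None and mask.shape[:2] != img.shape[:2]:
            raise ShapeError(f"mask {mask.shape} vs image {img.shape}")
        out.append((img, mask))
    return out


def augment_flips(pairs) -> list:
    """Originals + horizontally mirrored + vertically mirrored copies (3n),
    masks transformed identically; originals first."""
    pairs = _pair_arrays(pairs)
    flipped = []
    for axis in (1, 0):
        for img, mask in pairs:
            flipped.append((np.flip(img, axis=axis).copy(),
                            None if mask is None else np.flip(mask, axis=axis).copy()))
    return pairs + flipped


def _perturb(img, mask, rng):
    """One random brightness + zoom draw applied to an image/mask pair."""
    factor = rng.uniform(0.8, 1.2)
    zoomf = rng.uniform(0.9, 1.1)
    if img.min() < 0.0:          # zero-centered unit scale
        lo, hi = -0.5, 0.5
    elif img.max() > 1.5:        # byte scale
        lo, hi = 0.0, 255.0
    else:                        # unit scale
        lo, hi = 0.0, 1.0
    out = np.clip(img * factor, lo, hi)
    out = _zoom_to_same(out, zoomf, order=1)
    out = np.clip(out, lo, hi)
    if mask is not None:
        mask = (_zoom_to_same(mask.astype(np.float32), zoomf, order=0) > 0.5).astype(mask.dtype)
    return out, mask


def _zoom_to_same(arr, factor, order):
    """Spatially zoom by ``factor`` and center-crop/pad back to the input size."""
    spatial = arr.shape[:2]
    zoom = [factor, factor] + [1.0] * (arr.ndim - 2)
    z = ndimage.zoom(arr, zoom, order=order, mode="nearest", grid_mode=False)
    out = np.zeros_like(arr)
    for _ in range(1):
        sh, sw = z.shape[:2]
        th, tw = spatial
        src_h = slice(max(0, (sh - th) // 2), max(0, (sh - th) // 2) + min(sh, th))
        src_w = slice(max(0, (sw - tw) // 2), max(0, (sw - tw) // 2) + min(sw, tw))
        dst_h = slice(max(0, (th - sh) // 2), max(0, (th - sh) // 2) + min(sh, th))
        dst_w = slice(max(0, (tw - sw) // 2), max(0, (tw - sw) // 2) + min(sw, tw))
        out[dst_h, dst_w] = z[src_h, src_w]
    return out


def random_augment(pairs, seed: int):
    """Infinite generator of randomly perturbed (image, mask) pairs, cycling
    through the inputs; reproducible for a fixed seed and mask-binary safe."""
    pairs = _pair_arrays(pairs)
    rng = np.random.default_rng(seed)
    while True:
        for img, mask in pairs:
            yield _perturb(img, mask, rng)


def _fit(net, Xtr, Ytr, Xval, Yval, config, metric_fn, augment=False):
    loss_fn = LOSSES[config.loss]
    opt = make_optimizer(config.optimizer, config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(Xtr))
        batch_losses = []
        for start in range(0, len(order), config.batch_size):
            bi = order[start:start + config.batch_size]
            xb = Xtr[bi]
            yb = Ytr[bi]
            if augment:
                spatial_targets = yb.ndim > 2  # masks, not scalar labels
                pairs = [_perturb(x, y if spatial_targets else None, rng)
                         for x, y in zip(xb, yb)]
                xb = np.stack([p[0] for p in pairs])
                if spatial_targets:
                    yb = np.stack([p[1] for p in pairs])
            pred = net.forward(xb, training=True)
            loss, grad = loss_fn(pred, yb.reshape(pred.shape))
            net.backward(grad)
            opt.step(net)
            batch_losses.append(loss)
        pval = net.predict(Xval, config.batch_size)
        val_loss, _ = loss_fn(pval, Yval.reshape(pval.shape))
        history.append({
            "epoch": epoch + 1,
            "train_loss": float(np.mean(batch_losses)),
            "val_loss": float(val_loss),
            "val_metric": float(metric_fn(pval, Yval.reshape(pval.shape))),
        })
    return history


def _accuracy_metric(pred, truth):
    return float(np.mean((pred > 0.5).astype(int) == (truth > 0.5).astype(int)))


def _dice_metric(pred, truth):
    from .inference import dice_score

    scores = [dice_score((p > 0.5).astype(np.uint8), (q > 0.5).astype(np.uint8))
              for p, q in zip(pred, truth)]
    return float(np.mean(scores))


def train_detection(records, config: TrainConfig, input_mode: str = "image") -> TrainResult:
    """Train the matching detection CNN on labelled records.

    ``image`` mode consumes :class:`~tumorkit.image_io.LabeledRecord` objects
    (preprocessed to 256x256x3, byte range) with flip + random augmentation;
    ``features`` mode consumes :class:`~tumorkit.features.FeatureVector`
    objects as-is.
    """
    from .preprocess import prep_detection

    if input_mode not in ("image", "features"):
        raise ValueError(f"input_mode must be image|features, got {input_mode!r}")
    if input_mode == "image":
        # the data generator feeds the network zero-centered unit-scale
        # images (x/255 - 0.5); see the methods note on input conditioning
        X = np.stack([prep_detection(r.image).pixels for r in records]) / 255.0 - 0.5
        y = np.array([r.label for r in records], dtype=np.float32)
        graph = models.build_detection_cnn(config.width_multiplier)
    else:
        X = np.stack([np.asarray(v.values, dtype=np.float32)[:, None] for v in records])
        y = np.array([v.label for v in records], dtype=np.float32)
        graph = models.build_feature_cnn(X.shape[1], config.width_multiplier)

    split = split_dataset(len(records), config.seed)
    ytr = y[split.train]
    if len(np.unique(ytr)) < 2:
        raise DegenerateDataError("training split contains a single class")

    Xtr, Ytr = X[split.train], ytr[:, None]
    if input_mode == "image":
        tripled = augment_flips([(x, None) for x in Xtr])
        Xtr = np.stack([img for img, _ in tripled])
        Ytr = np.concatenate([Ytr, Ytr, Ytr], axis=0)

    net = Network(graph, seed=config.seed)
    history = _fit(net, Xtr, Ytr, X[split.validation], y[split.validation][:, None],
                   config, _accuracy_metric, augment=(input_mode == "image"))

    ptest = net.predict(X[split.test], config.batch_size)
    test_acc = _accuracy_metric(ptest, y[split.test][:, None])
    per_sample = [{"index": int(i), "truth": int(y[i]), "probability": float(p)}
                  for i, p in zip(split.test, ptest.ravel())]
    return TrainResult(network=net, history=history, split=split,
                       test_metric=test_acc, per_sample=per_sample)


def train_segmentation(samples, config: TrainConfig) -> TrainResult:
    """Train a U-Net / U-Net++ on (input, mask) sample pairs.

    2D tasks use the hybrid (0.5 Dice + 0.5 BCE) loss with flip + random
    augmentation; multimodal tasks use the Dice loss without augmentation.
    Held-out evaluation reports mean Dice over thresholded predictions.
    """
    if config.task not in _BUILDERS:
        raise ValueError(f"task {config.task!r} is not a segmentation task")
    pairs = _pair_arrays(samples)
    X = np.stack([img for img, _ in pairs]).astype(np.float32)
    Y = np.stack([mask for _, mask in pairs]).astype(np.float32)
    if Y.sum() == 0:
        raise DegenerateDataError("every sample mask is empty")

    split = split_dataset(len(pairs), config.seed)
    Xtr, Ytr = X[split.train], Y[split.train]
    is_2d = config.task.startswith("seg2d")
    if is_2d:
        tripled = augment_flips(list(zip(Xtr, Ytr)))
        Xtr = np.stack([img for img, _ in tripled])
        Ytr = np.stack([mask for _, mask in tripled])

    graph = _BUILDERS[config.task](config.width_multiplier)
    net = Network(graph, seed=config.seed)
    history = _fit(net, Xtr, Ytr, X[split.validation], Y[split.validation],
                   config, _dice_metric, augment=is_2d)

    ptest = net.predict(X[split.test], config.batch_size)
    test_dice = _dice_metric(ptest, Y[split.test])
    per_sample = [{"index": int(i), "dice": float(_dice_metric(p[None], q[None]))}
                  for i, p, q in zip(split.test, ptest, Y[split.test])]
    return TrainResult(network=net, history=history, split=split,
                       test_metric=test_dice, per_sample=per_sample)
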