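"""Dataset handling and the segmentation training loop.

Covers the 75/15/10 train/validation/test split (realized as a 90/10
train/test split followed by carving 15/90 of the training pool into
validation — the two descriptions give identical sizes), resizing to
the model's input grid with spacing bookkeeping, mask-aligned
augmentation (horizontal flip plus one random rotation+scale copy per
source image), and mini-batch Adam on the combined BCE + log-Dice
loss with early stopping on the monitored loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import AffineTransform, resize as sk_resize, warp

from .images import CanalMask, UltrasoundImage
from .nn import Adam
from .objectives import LossConfig, combined_loss_node
from .resunet import SegmentationModel


@dataclass
class SplitConfig:
    fractions: tuple[float, float, float] = (0.75, 0.15, 0.10)
    seed: int = 0

    def __post_init__(self):
        if any(f <= 0 for f in self.fractions):
            raise ValueError("split fractions must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class AugmentConfig:
    do_hflip: bool = True
    do_affine: bool = True
    rotation_range_deg: tuple[float, float] = (-15.0, 15.0)
    scale_range: tuple[float, float] = (0.9, 1.1)
    border_crop_px: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.rotation_range_deg[0] > self.rotation_range_deg[1]:
            raise ValueError("rotation range is not well ordered")
        if not (0 < self.scale_range[0] <= self.scale_range[1]):
            raise ValueError("scale range is not well ordered/positive")
        if self.border_crop_px < 0:
            raise ValueError("border crop must be nonnegative")


@dataclass
class TrainConfig:
    batch_size: int = 32
    max_epochs: int = 5000
    learning_rate: float = 1e-3
    early_stopping_patience: int = 50
    early_stopping_min_delta: float = 0.0
    monitor: str = "train_loss"  # or "val_loss"
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.early_stopping_patience < 1:
            raise ValueError("patience must be >= 1")
        if self.monitor not in ("train_loss", "val_loss"):
            raise ValueError("monitor must be 'train_loss' or 'val_loss'")


def split_dataset(items: list, config: SplitConfig | None = None):
    """Shuffle and partition into (train, val, test) by the configured
    fractions: floor(n*val), floor(n*test), remainder to train."""
    config = config or SplitConfig()
    items = list(items)
    n = len(items)
    if n < 3:
        raise ValueError("need at least 3 items to split")
    n_val = math.floor(n * config.fractions[1])
    n_test = math.floor(n * config.fractions[2])
    if n - n_val - n_test < 1:
        raise ValueError("split leaves no training items")
    order = np.random.default_rng(config.seed).permutation(n)
    shuffled = [items[i] for i in order]
    train = shuffled[: n - n_val - n_test]
    val = shuffled[n - n_val - n_test : n - n_test]
    test = shuffled[n - n_test :]
    assert len(train) + len(val) + len(test) == n
    return train, val, test


def resize_to_model(image: UltrasoundImage, mask: CanalMask | None,
                    target_shape: tuple[int, int]):
    """Resample to the model grid: bilinear image, nearest-neighbour
    mask; per-axis spacing rescaled so physical lengths are preserved."""
    tr, tc = target_shape
    if tr < 1 or tc < 1:
        raise ValueError("target shape must be positive")
    r, c = image.shape
    sp = image.pixel_spacing_mm
    new_sp = (sp[0] * r / tr, sp[1] * c / tc)
    img = sk_resize(image.pixels.astype(np.float64), target_shape, order=1,
                    anti_aliasing=False, preserve_range=True)
    new_image = UltrasoundImage(img.astype(np.float32), new_sp, image.image_id)
    if mask is None:
        return new_image, None
    mk = sk_resize(mask.pixels, target_shape, order=0, anti_aliasing=False,
                   preserve_range=True)
    return new_image, CanalMask(mk.astype(np.uint8), new_sp, mask.image_id)


def _crop(arr, k):
    return arr[k:arr.shape[0] - k, k:arr.shape[1] - k] if k else arr


def augment(pairs, config: AugmentConfig | None = None):
    """Expand each (image, mask) pair into up to three: the
    (border-cropped) original, its horizontal mirror, and one random
    rotation+scaling copy.  Masks receive the identical transform
    (nearest-neighbour).  With both flags on, output = 3x input."""
    config = config or AugmentConfig()
    rng = np.random.default_rng(config.seed)
    out = []
    for image, mask in pairs:
        k = config.border_crop_px
        if k and min(image.shape) <= 2 * k:
            raise ValueError("border crop exceeds half the image size")
        img = _crop(image.pixels, k)
        mk = _crop(mask.pixels, k)
        sp = image.pixel_spacing_mm
        out.append((UltrasoundImage(img, sp, image.image_id),
                    CanalMask(mk, sp, mask.image_id)))
        if config.do_hflip:
            out.append((
                UltrasoundImage(img[:, ::-1].copy(), sp, image.image_id + "/hflip"),
                CanalMask(mk[:, ::-1].copy(), sp, mask.image_id + "/hflip"),
            ))
        if config.do_affine:
            angle = math.radians(rng.uniform(*config.rotation_range_deg))
            scale = rng.uniform(*config.scale_range)
            center = np.array([img.shape[1], img.shape[0]]) / 2.0
            tform = (AffineTransform(translation=-center)
                     + AffineTransform(rotation=angle, scale=scale)
                     + AffineTransform(translation=center))
            wimg = warp(img.astype(np.float64), tform.inverse, order=1,
                        preserve_range=True)
            wmk = warp(mk, tform.inverse, order=0, preserve_range=True)
            out.append((
                UltrasoundImage(wimg.astype(np.float32), sp, image.image_id + "/affine"),
                CanalMask(wmk.astype(np.uint8), sp, mask.image_id + "/affine"),
            ))
    return out


@dataclass
class TrainHistory:
    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0


def _stack(pairs):
    x = np.stack([np.asarray(im.pixels, dtype=np.float32) for im, _ in pairs])[:, None]
    y = np.stack([m.pixels.astype(np.float32) for _, m in pairs])[:, None]
    return x, y


def _eval_loss_acc(model, x, y, loss_config, batch_size):
    model.net.eval()
    losses, accs, weights = [], [], []
    for i in range(0, len(x), batch_size):
        xb, yb = x[i : i + batch_size], y[i : i + batch_size]
        out = model.net(xb)
        losses.append(float(combined_loss_node(out, yb, loss_config).data))
        accs.append(float(np.mean((out.data >= 0.5) == (yb >= 0.5))))
        weights.append(len(xb))
    w = np.asarray(weights, float)
    return float(np.average(losses, weights=w)), float(np.average(accs, weights=w))


def train(
    model: SegmentationModel,
    train_pairs,
    val_pairs=(),
    loss_config: LossConfig | None = None,
    train_config: TrainConfig | None = None,
) -> tuple[SegmentationModel, TrainHistory]:
    """Mini-batch Adam on the combined loss with early stopping.

    Per-epoch training/validation loss and pixel accuracy are
    recorded; training stops at ``max_epochs`` or once the monitored
    loss has not improved by ``min_delta`` for ``patience`` epochs.
    The best-loss parameters are restored before returning.  Fully
    seeded: identical data and configs give identical histories.
    """
    if not train_pairs:
        raise ValueError("training set is empty")
    loss_config = loss_config or LossConfig()
    cfg = train_config or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    xtr, ytr = _stack(train_pairs)
    xval, yval = _stack(val_pairs) if len(val_pairs) else (None, None)

    opt = Adam(model.net.parameters(), lr=cfg.learning_rate)
    history = TrainHistory()
    best = np.inf
    best_state = None
    since_best = 0

    for epoch in range(1, cfg.max_epochs + 1):
        model.net.train()
        order = rng.permutation(len(xtr))
        batch_losses, batch_accs, batch_sizes = [], [], []
        for i in range(0, len(order), cfg.batch_size):
            sel = order[i : i + cfg.batch_size]
            xb, yb = xtr[sel], ytr[sel]
            out = model.net(xb)
            loss = combined_loss_node(out, yb, loss_config)
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, "
                    f"batch {i // cfg.batch_size}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            batch_losses.append(lval)
            batch_accs.append(float(np.mean((out.data >= 0.5) == (yb >= 0.5))))
            batch_sizes.append(len(sel))
        w = np.asarray(batch_sizes, float)
        tr_loss = float(np.average(batch_losses, weights=w))
        tr_acc = float(np.average(batch_accs, weights=w))
        if xval is not None:
            va_loss, va_acc = _eval_loss_acc(model, xval, yval, loss_config,
                                             cfg.batch_size)
        else:
            va_loss, va_acc = np.nan, np.nan
        history.epochs.append(epoch)
        history.train_loss.append(tr_loss)
        history.val_loss.append(va_loss)
        history.train_acc.append(tr_acc)
        history.val_acc.append(va_acc)

        monitored = tr_loss if cfg.monitor == "train_loss" else va_loss
        if monitored < best - cfg.early_stopping_min_delta:
            best = monitored
            best_state = [a.copy() for a in model.net.state_arrays()]
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.early_stopping_patience:
                history.stopped_epoch = epoch
                break
    else:
        history.stopped_epoch = cfg.max_epochs

    if best_state is not None:
        for tgt, src in zip(model.net.state_arrays(), best_state):
            tgt[...] = src
    model.metadata.update({
        "epochs_run": history.stopped_epoch,
        "best_epoch": history.best_epoch,
        "final_train_loss": history.train_loss[-1],
        "final_val_loss": history.val_loss[-1],
        "best_loss": float(best),
    })
    return model, history
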