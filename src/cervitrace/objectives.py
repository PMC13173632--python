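"""Loss functions and evaluation metrics for canal segmentation.

Training minimises a weighted sum of binary cross-entropy and log-Dice
loss; evaluation uses the Dice overlap coefficient and a single-window
structural similarity index (SSIM) computed from whole-image statistics.

The public functions take plain arrays (or the raster containers'
``pixels``); :func:`combined_loss_node` is the differentiable variant
used inside the training loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.autodiff import Tensor


@dataclass
class LossConfig:
    """Configuration of the combined segmentation loss.

    smooth
        Additive constant in the log-Dice ratio keeping it finite when
        both masks are empty (default 1.0).
    bce_weight, logdice_weight
        Nonnegative mixing weights of the two terms (default 1.0 each).
    probability_clip
        Predictions are clipped to [clip, 1-clip] before logarithms.
    """

    smooth: float = 1.0
    bce_weight: float = 1.0
    logdice_weight: float = 1.0
    probability_clip: float = 1e-7

    def __post_init__(self):
        if self.smooth <= 0:
            raise ValueError("smooth must be positive")
        if self.bce_weight < 0 or self.logdice_weight < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.bce_weight == 0 and self.logdice_weight == 0:
            raise ValueError("at least one loss weight must be positive")


@dataclass
class SSIMConfig:
    """SSIM stabilising constants: c1 = (k1*L)^2, c2 = (k2*L)^2 for
    dynamic range L; the conventional k1=0.01, k2=0.03 are the default."""

    dynamic_range: float = 1.0
    k1: float = 0.01
    k2: float = 0.03

    def __post_init__(self):
        if self.dynamic_range <= 0:
            raise ValueError("dynamic_range must be positive")

    @property
    def c1(self) -> float:
        return (self.k1 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.dynamic_range) ** 2


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _pixels(x) -> np.ndarray:
    return np.asarray(getattr(x, "pixels", x), dtype=np.float64)


def _check_same_shape(a: np.ndarray, b: np.ndarray):
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def _check_binary(a: np.ndarray, name: str):
    if not np.all(np.isin(np.unique(a), (0, 1))):
        raise ValueError(f"{name} must be binary 0/1")


def bce_loss(truth, pred, config: LossConfig | None = None) -> float:
    """Mean binary cross-entropy -(1/N) sum[x log p + (1-x) log(1-p)]."""
    config = config or LossConfig()
    x, p = _pixels(truth), _pixels(pred)
    _check_same_shape(x, p)
    c = config.probability_clip
    p = np.clip(p, c, 1.0 - c)
    return float(-np.mean(x * np.log(p) + (1.0 - x) * np.log(1.0 - p)))


def log_dice_loss(truth, pred, config: LossConfig | None = None) -> float:
    """-log[(2 sum(x*p) + smooth) / (sum x + sum p + smooth)]."""
    config = config or LossConfig()
    x, p = _pixels(truth), _pixels(pred)
    _check_same_shape(x, p)
    s = config.smooth
    num = 2.0 * np.sum(x * p) + s
    den = np.sum(x) + np.sum(p) + s
    return float(-np.log(num / den))


def combined_loss(truth, pred, config: LossConfig | None = None) -> float:
    config = config or LossConfig()
    return (
        config.bce_weight * bce_loss(truth, pred, config)
        + config.logdice_weight * log_dice_loss(truth, pred, config)
    )


def combined_loss_node(pred: Tensor, truth: np.ndarray, config: LossConfig | None = None) -> Tensor:
    """Differentiable combined loss: one fused autodiff node with a
    closed-form gradient w.r.t. the prediction.

    ``truth`` is a constant array of the same shape as ``pred.data``.
    Value agrees with bce/log_dice on the same inputs.
    """
    config = config or LossConfig()
    x = np.asarray(truth, dtype=pred.data.dtype)
    p_raw = pred.data
    if x.shape != p_raw.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {p_raw.shape}")
    c = config.probability_clip
    n = x.size
    p = np.clip(p_raw, c, 1.0 - c)
    inside = (p_raw > c) & (p_raw < 1.0 - c)

    bce = -np.mean(x * np.log(p) + (1.0 - x) * np.log(1.0 - p))
    s = config.smooth
    num = 2.0 * float(np.sum(x * p)) + s
    den = float(np.sum(x) + np.sum(p)) + s
    ld = -np.log(num / den)
    wb, wd = config.bce_weight, config.logdice_weight
    out = Tensor(np.array(wb * bce + wd * ld, dtype=np.float64), (pred,))

    def bwd(g):
        g = float(g)
        dbce = (p - x) / (p * (1.0 - p)) / n
        dld = -(2.0 * x / num - 1.0 / den)
        grad = g * (wb * dbce + wd * dld) * inside
        pred._accumulate(grad.astype(p_raw.dtype, copy=False))

    out._backward = bwd
    return out


def confusion(truth, pred_mask) -> ConfusionCounts:
    """Pixelwise TP/FP/FN/TN between two binary masks."""
    x = np.asarray(getattr(truth, "pixels", truth))
    y = np.asarray(getattr(pred_mask, "pixels", pred_mask))
    _check_same_shape(x, y)
    _check_binary(x, "truth")
    _check_binary(y, "prediction")
    xb, yb = x.astype(bool), y.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(xb & yb)),
        fp=int(np.sum(~xb & yb)),
        fn=int(np.sum(xb & ~yb)),
        tn=int(np.sum(~xb & ~yb)),
    )


def dice_coefficient(truth, pred_mask) -> float:
    """Overlap 2*TP / (2*TP + FP + FN); 1.0 when both masks are empty."""
    c = confusion(truth, pred_mask)
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return 2.0 * c.tp / denom


def ssim(x, y, config: SSIMConfig | None = None) -> float:
    """Single-window SSIM from whole-image means, SDs and covariance.

    ((2 mu_x mu_y + c1)(2 sigma_xy + c2)) /
    ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2))

    The raw value is returned; anti-correlated images can yield a
    negative result even though the index is usually quoted in [0, 1].
    """
    config = config or SSIMConfig()
    xa, ya = _pixels(x), _pixels(y)
    _check_same_shape(xa, ya)
    mx, my = xa.mean(), ya.mean()
    vx, vy = xa.var(), ya.var()
    cov = np.mean((xa - mx) * (ya - my))
    c1, c2 = config.c1, config.c2
    return float(
        ((2 * mx * my + c1) * (2 * cov + c2))
        / ((mx * mx + my * my + c1) * (vx + vy + c2))
    )


def ssim_windowed(x, y, config: SSIMConfig | None = None, window: int = 7) -> float:
    """Mean of SSIM evaluated on non-overlapping square windows.

    Provided as an alternative to the single-window default.
    """
    config = config or SSIMConfig()
    xa, ya = _pixels(x), _pixels(y)
    _check_same_shape(xa, ya)
    h, w = xa.shape
    vals = []
    for i in range(0, h - window + 1, window):
        for j in range(0, w - window + 1, window):
            vals.append(ssim(xa[i : i + window, j : j + window],
                             ya[i : i + window, j : j + window], config))
    if not vals:
        return ssim(xa, ya, config)
    return float(np.mean(vals))


def metric_report(truths, preds, prob_maps=None, config: SSIMConfig | None = None):
    """Per-image dice/ssim (and losses when probability maps given) as a
    list of dicts, ready for CSV/JSON export."""
    rows = []
    for i, (t, m) in enumerate(zip(truths, preds)):
        row = {
            "index": i,
            "dice": dice_coefficient(t, m),
            "ssim": ssim(_pixels(t), _pixels(m).astype(float), config),
        }
        if prob_maps is not None:
            row["bce"] = bce_loss(t, prob_maps[i])
            row["log_dice"] = log_dice_loss(t, prob_maps[i])
        rows.append(row)
    return rows
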