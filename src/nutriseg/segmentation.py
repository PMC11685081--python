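"""UNet food segmentation: model builder, training loop, inference, and the
four overlap metrics (Dice, Jaccard, precision, recall).

The segmenter is a symmetric encoder-decoder.  Each encoder stage applies two
3x3 convolutions (ReLU) and halves the resolution by 2x2 max pooling; the
bottleneck doubles channels once more; each decoder stage upsamples by a
kernel-2 stride-2 transposed convolution, concatenates the matching encoder
feature map through a skip connection, and applies two 3x3 convolutions.  A
final 1x1 convolution maps to the output channels (one food-vs-background
logit by default).  Training minimizes pixelwise binary cross-entropy under
Adam with per-epoch exponential learning-rate decay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .dataset_io import DishRecord

__all__ = [
    "SegNetConfig", "SegTrainConfig", "ConfusionCounts", "UNet",
    "build_unet", "train_segmenter", "predict_mask",
    "confusion", "dice", "jaccard", "precision", "recall",
    "evaluate_segmentation",
]


@dataclass(frozen=True)
class SegNetConfig:
    in_channels: int = 3
    n_stages: int = 4
    base_channels: int = 64
    out_channels: int = 1

    def __post_init__(self):
        if self.n_stages < 1 or self.base_channels < 1:
            raise ValueError("n_stages and base_channels must be >= 1")


@dataclass(frozen=True)
class SegTrainConfig:
    epochs: int = 50
    lr0: float = 1e-3
    lr_decay: float = 0.99
    batch_size: int = 8
    seed: int = 42


class _ConvBlock(nn.Module):
    """Two 3x3 same-padding convolutions with ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(c_in, c_out, 3, rng, padding=1)
        self.conv2 = nn.Conv2d(c_out, c_out, 3, rng, padding=1)

    def forward(self, x):
        return self.conv2(self.conv1(x).relu()).relu()


class UNet(nn.Module):
    """Encoder-decoder with skip connections; outputs per-pixel logits."""

    def __init__(self, config: SegNetConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        ch = [config.base_channels * 2 ** s for s in range(config.n_stages + 1)]
        self.encoders = [_ConvBlock(config.in_channels if s == 0 else ch[s - 1], ch[s], rng)
                         for s in range(config.n_stages)]
        self.bottleneck = _ConvBlock(ch[-2], ch[-1], rng)
        self.upsamplers = [nn.ConvTranspose2x2(ch[s + 1], ch[s], rng)
                           for s in reversed(range(config.n_stages))]
        self.decoders = [_ConvBlock(ch[s] * 2, ch[s], rng)
                         for s in reversed(range(config.n_stages))]
        self.head = nn.Conv2d(config.base_channels, config.out_channels, 1, rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        H, W = x.shape[2], x.shape[3]
        div = 2 ** self.config.n_stages
        if H % div or W % div:
            raise ValueError(
                f"input {H}x{W} not divisible by 2^{self.config.n_stages}={div}; "
                f"pad or resize so the {self.config.n_stages}-stage encoder can pool evenly"
            )
        skips = []
        for enc in self.encoders:
            x = enc(x)
            skips.append(x)
            x = x.maxpool2x2()
        x = self.bottleneck(x)
        for up, dec, skip in zip(self.upsamplers, self.decoders, reversed(skips)):
            x = dec(up(x).concat_channels(skip))
        return self.head(x)


def build_unet(config: SegNetConfig = SegNetConfig(), seed: int = 42) -> UNet:
    """Construct a UNet with reproducible He initialization."""
    return UNet(config, np.random.default_rng(seed))


# ------------------------------------------------------------------- training

def _to_batch(records: list[DishRecord], idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    imgs = np.stack([records[i].image for i in idx]).astype(np.float32) / 255.0
    masks = np.stack([records[i].mask for i in idx]).astype(np.float32)
    return imgs.transpose(0, 3, 1, 2), masks[:, None]


def train_segmenter(model: UNet, train_set: list[DishRecord],
                    config: SegTrainConfig = SegTrainConfig()) -> list[float]:
    """Train in place; returns the per-epoch mean BCE loss trace."""
    if not train_set:
        raise ValueError("empty training set")
    for rec in train_set:
        if rec.mask is None:
            raise ValueError(f"dish {rec.dish_id!r} has no mask; segmentation training needs masks")
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.lr0)
    sched = nn.ExponentialDecay(opt, rate=config.lr_decay)
    n = len(train_set)
    trace: list[float] = []
    model.train()
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            x, t = _to_batch(train_set, idx)
            opt.zero_grad()
            loss = model(nn.Tensor(x)).bce_with_logits(t)
            loss.backward()
            opt.step()
            losses.append(loss.item())
        trace.append(float(np.mean(losses)))
        sched.step()
    return trace


def predict_mask(model: UNet, image: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Segment one image: sigmoid of logits thresholded to a {0,1} raster."""
    model.eval()
    x = (np.asarray(image).astype(np.float32) / 255.0).transpose(2, 0, 1)[None]
    logits = model(nn.Tensor(x)).numpy()[0, 0]
    prob = 1.0 / (1.0 + np.exp(-logits))
    return (prob > threshold).astype(np.uint8)


# -------------------------------------------------------------------- metrics

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts with food (1) as the positive class."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    return ConfusionCounts(
        tp=int((pred & truth).sum()),
        fp=int((pred & ~truth).sum()),
        fn=int((~pred & truth).sum()),
        tn=int((~pred & ~truth).sum()),
    )


def _ratio(num: float, den: float, both_empty: bool) -> float:
    if den > 0:
        return num / den
    if both_empty:
        return 1.0
    warnings.warn("metric denominator is zero with non-matching masks; returning 0.0", stacklevel=3)
    return 0.0


def dice(c: ConfusionCounts) -> float:
    """2*TP / (2*TP + FP + FN); 1.0 when both masks are empty."""
    return _ratio(2.0 * c.tp, 2.0 * c.tp + c.fp + c.fn, c.fp == c.fn == c.tp == 0)


def jaccard(c: ConfusionCounts) -> float:
    """TP / (TP + FP + FN); 1.0 when both masks are empty."""
    return _ratio(float(c.tp), float(c.tp + c.fp + c.fn), c.fp == c.fn == c.tp == 0)


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); 1.0 when both prediction and truth are empty."""
    return _ratio(float(c.tp), float(c.tp + c.fp), c.tp + c.fp + c.fn == 0)


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN); 1.0 when both prediction and truth are empty."""
    return _ratio(float(c.tp), float(c.tp + c.fn), c.tp + c.fp + c.fn == 0)


def evaluate_segmentation(model: UNet, test_set: list[DishRecord],
                          threshold: float = 0.5) -> dict[str, float]:
    """Mean Dice/Jaccard/precision/recall of predicted vs ground-truth masks."""
    scores = {"dice": [], "jaccard": [], "precision": [], "recall": []}
    for rec in test_set:
        c = confusion(predict_mask(model, rec.image, threshold), rec.mask)
        scores["dice"].append(dice(c))
        scores["jaccard"].append(jaccard(c))
        scores["precision"].append(precision(c))
        scores["recall"].append(recall(c))
    return {k: float(np.mean(v)) for k, v in scores.items()}
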