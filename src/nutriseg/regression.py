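"""Nutrient regression from (masked) food images.

A convolutional backbone extracts a C-channel feature map; a
Squeeze-and-Excitation (SE) block recalibrates the channels; global average
pooling and three fully connected layers emit the five nutrient predictions
(mass, calories, fat, carb, protein).

The SE block follows the standard three steps:
  squeeze      z_c = mean over space of channel c,
  excitation   s   = sigmoid(W2 @ relu(W1 @ z)) with a C/r bottleneck,
  recalibrate  X~_c = s_c * X_c.
Plain-NumPy functional forms of the three steps are exported alongside the
trainable module so they can be checked against explicit loop oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
from PIL import Image

from . import nn
from .metrics import multitask_loss_tensor

__all__ = [
    "SEConfig", "RegNetConfig", "RegTrainConfig", "SEModule", "NutrientRegressor",
    "squeeze", "excite", "recalibrate", "build_regressor",
    "augment", "resize_short_side", "center_crop",
    "train_regressor", "predict_nutrients", "color_area_features",
]


# ------------------------------------------------------- functional SE (NumPy)

def squeeze(x: np.ndarray) -> np.ndarray:
    """Global average pooling of a C x H x W feature map to a C-vector."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3 or x.shape[1] * x.shape[2] == 0:
        raise ValueError(f"expected a non-empty C x H x W map, got shape {x.shape}")
    return x.mean(axis=(1, 2))


def excite(z: np.ndarray, w1: np.ndarray, w2: np.ndarray) -> np.ndarray:
    """Channel weights s = sigmoid(W2 @ relu(W1 @ z)); every s_c in (0, 1)."""
    z = np.asarray(z, dtype=np.float64)
    w1 = np.asarray(w1, dtype=np.float64)
    w2 = np.asarray(w2, dtype=np.float64)
    if w1.shape[1] != z.shape[0] or w2.shape[1] != w1.shape[0] or w2.shape[0] != z.shape[0]:
        raise ValueError(
            f"shape mismatch: z {z.shape}, W1 {w1.shape} (want C/r x C), W2 {w2.shape} (want C x C/r)"
        )
    hidden = np.maximum(w1 @ z, 0.0)
    return 1.0 / (1.0 + np.exp(-(w2 @ hidden)))


def recalibrate(x: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Scale channel c of a C x H x W map by s_c."""
    x = np.asarray(x, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    if s.shape != (x.shape[0],):
        raise ValueError(f"need one weight per channel: map has {x.shape[0]}, got {s.shape}")
    return x * s[:, None, None]


# ------------------------------------------------------------------- configs

@dataclass(frozen=True)
class SEConfig:
    channels: int
    reduction: int = 16

    @property
    def bottleneck(self) -> int:
        # round C/r up when it does not divide evenly
        return max(1, ceil(self.channels / self.reduction))


@dataclass(frozen=True)
class RegNetConfig:
    backbone: str = "small"
    se: SEConfig | None = None  # filled from the backbone's channel count
    se_enabled: bool = True
    head_dims: tuple[int, ...] = (512, 128)
    n_outputs: int = 5


@dataclass(frozen=True)
class RegTrainConfig:
    epochs: int = 300
    lr0: float = 1e-4
    lr_decay: float = 0.99
    batch_size: int = 8
    seed: int = 42
    augment: bool = True
    crop_size: int | None = None  # None: train at native size


# ------------------------------------------------------------------- modules

class SEModule(nn.Module):
    """Trainable squeeze-excitation-recalibration block."""

    def __init__(self, config: SEConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.fc1 = nn.Linear(config.channels, config.bottleneck, rng, bias=False)
        self.fc2 = nn.Linear(config.bottleneck, config.channels, rng, bias=False)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        z = x.global_avg_pool()                       # (B, C)
        s = self.fc2(self.fc1(z).relu()).sigmoid()    # (B, C)
        B, C = s.shape
        return x * s.reshape(B, C, 1, 1)


def _backbone_small(rng: np.random.Generator) -> tuple[nn.Module, int]:
    """Three conv stages, 3->16->32->32 channels, /8 spatial via max pooling."""
    net = nn.Sequential(
        nn.Conv2d(3, 16, 3, rng, padding=1), nn.ReLU(), nn.MaxPool2x2(),
        nn.Conv2d(16, 32, 3, rng, padding=1), nn.ReLU(), nn.MaxPool2x2(),
        nn.Conv2d(32, 32, 3, rng, padding=1), nn.ReLU(), nn.MaxPool2x2(),
    )
    return net, 32


def _backbone_tiny(rng: np.random.Generator) -> tuple[nn.Module, int]:
    """Two conv stages, 3->12->24 channels, /4 spatial."""
    net = nn.Sequential(
        nn.Conv2d(3, 12, 3, rng, padding=1), nn.ReLU(), nn.MaxPool2x2(),
        nn.Conv2d(12, 24, 3, rng, padding=1), nn.ReLU(), nn.MaxPool2x2(),
    )
    return net, 24


_BACKBONES = {"small": _backbone_small, "tiny": _backbone_tiny}


class NutrientRegressor(nn.Module):
    """backbone -> SE (optional) -> global pooling -> FC1 -> FC2 -> FC3 -> 5."""

    def __init__(self, config: RegNetConfig, rng: np.random.Generator):
        super().__init__()
        if config.backbone not in _BACKBONES:
            raise ValueError(
                f"unknown backbone {config.backbone!r}; options: {sorted(_BACKBONES)}"
            )
        self.config = config
        self.backbone, c = _BACKBONES[config.backbone](rng)
        se_cfg = config.se or SEConfig(channels=c, reduction=4)
        if se_cfg.channels != c:
            raise ValueError(f"SE channels {se_cfg.channels} != backbone channels {c}")
        self.se = SEModule(se_cfg, rng)
        dims = (c,) + tuple(config.head_dims) + (config.n_outputs,)
        self.heads = [nn.Linear(dims[i], dims[i + 1], rng) for i in range(len(dims) - 1)]

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        x = self.backbone(x)
        if self.config.se_enabled:
            x = self.se(x)
        x = x.global_avg_pool()
        for i, head in enumerate(self.heads):
            x = head(x)
            if i < len(self.heads) - 1:
                x = x.relu()
        return x


def build_regressor(config: RegNetConfig = RegNetConfig(), seed: int = 42) -> NutrientRegressor:
    """Construct a nutrient regressor with reproducible initialization."""
    return NutrientRegressor(config, np.random.default_rng(seed))


# --------------------------------------------------------------- augmentation

def resize_short_side(image: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize so the shorter image side equals `size`."""
    h, w = image.shape[:2]
    scale = size / min(h, w)
    nh, nw = round(h * scale), round(w * scale)
    return np.asarray(Image.fromarray(image).resize((nw, nh), Image.BILINEAR))

def center_crop(image: np.ndarray, size: int) -> np.ndarray:
    h, w = image.shape[:2]
    if size > h or size > w:
        raise ValueError(f"crop {size} larger than image {h}x{w}")
    top, left = (h - size) // 2, (w - size) // 2
    return image[top:top + size, left:left + size]


def augment(image: np.ndarray, rng: np.random.Generator,
            crop_size: int | None = None, flip_prob: float = 0.5,
            force_flip: bool | None = None) -> np.ndarray:
    """Training-time augmentation: random horizontal flip and random crop.

    With crop_size None the crop step is skipped (native-size training).
    force_flip overrides the coin toss for testing determinism.
    """
    out = np.asarray(image)
    flip = force_flip if force_flip is not None else (rng.random() < flip_prob)
    if flip:
        out = out[:, ::-1]
    if crop_size is not None:
        h, w = out.shape[:2]
        if crop_size > h or crop_size > w:
            raise ValueError(f"crop {crop_size} larger than image {h}x{w}")
        top = int(rng.integers(0, h - crop_size + 1))
        left = int(rng.integers(0, w - crop_size + 1))
        out = out[top:top + crop_size, left:left + crop_size]
    return np.ascontiguousarray(out)


# ------------------------------------------------------------------ training

def _prep(images: list[np.ndarray]) -> np.ndarray:
    return (np.stack(images).astype(np.float32) / 255.0).transpose(0, 3, 1, 2)


def train_regressor(model: NutrientRegressor, images: list[np.ndarray], labels: np.ndarray,
                    config: RegTrainConfig = RegTrainConfig(),
                    eval_fn=None) -> list[dict[str, float]]:
    """Train in place with the sum-normalized multi-task loss.

    Returns the per-epoch log; when eval_fn is given it is called after each
    epoch (the hook the per-epoch test evaluation and top-1 tracking use) and
    its result stored under "eval".
    """
    labels = np.asarray(labels, dtype=np.float32)
    if len(images) != len(labels):
        raise ValueError("images and labels disagree in length")
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.lr0)
    sched = nn.ExponentialDecay(opt, rate=config.lr_decay)
    n = len(images)
    log: list[dict[str, float]] = []
    model.train()
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch_imgs = [images[i] for i in idx]
            if config.augment:
                batch_imgs = [augment(im, rng, crop_size=config.crop_size) for im in batch_imgs]
            x = _prep(batch_imgs)
            opt.zero_grad()
            loss = multitask_loss_tensor(model(nn.Tensor(x)), labels[idx])
            loss.backward()
            opt.step()
            losses.append(loss.item())
        entry: dict[str, float] = {"epoch": epoch, "loss": float(np.mean(losses)),
                                   "lr": sched.lr_at(epoch)}
        sched.step()
        if eval_fn is not None:
            entry["eval"] = eval_fn(model)
        log.append(entry)
    return log


def predict_nutrients(model: NutrientRegressor, images: list[np.ndarray],
                      batch_size: int = 32) -> np.ndarray:
    """Predict N x 5 nutrient values; clamped at 0 for reporting."""
    model.eval()
    outs = []
    for start in range(0, len(images), batch_size):
        x = _prep(images[start:start + batch_size])
        outs.append(model(nn.Tensor(x)).numpy())
    return np.maximum(np.concatenate(outs, axis=0), 0.0)


# ------------------------------------------------------------ linear readout

def color_area_features(image: np.ndarray, palette) -> np.ndarray:
    """Per-ingredient pixel areas by nearest-palette-color assignment.

    Black (masked-out) pixels are ignored; every other pixel is counted for
    the palette entry its color is closest to.  On noiseless synthetic
    scenes the nutrient label is linear in these areas, so a least-squares
    readout on them bounds the error any learned regressor could reach.
    """
    img = np.asarray(image, dtype=np.float64).reshape(-1, 3)
    img = img[img.any(axis=1)]
    colors = np.array([spec.color for spec in palette], dtype=np.float64)
    if len(img) == 0:
        return np.zeros(len(colors))
    nearest = np.linalg.norm(img[:, None, :] - colors[None], axis=-1).argmin(axis=1)
    return np.bincount(nearest, minlength=len(colors)).astype(np.float64)
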