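"""Normalized multi-task loss and evaluation metrics.

The training loss treats the five nutrients as subtasks.  Each subtask loss
is the sum of absolute errors normalized by the sum of the true values,

    l_m = sum_i |yhat_i^m - y_i^m| / sum_i y_i^m,

and the total loss is the plain sum over the five subtasks.  Because each
l_m is scale-free, mass and calories (an order of magnitude larger than the
macros in grams) cannot dominate the gradient.  Algebraically l_m equals
PMAE/100 on the same data: PMAE = 100 * MAE / mean(y) and the two 1/N
factors cancel.

Evaluation reports per-nutrient PMAE, MAE, MSE, RMSE and R², plus the
unweighted mean PMAE over the five nutrients.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataset_io import NUTRIENTS
from .nn import Tensor

__all__ = [
    "subtask_loss", "total_loss", "multitask_loss_tensor",
    "mae", "mse", "rmse", "r2", "pmae", "evaluate", "EvalReport",
]


# ----------------------------------------------------------------- training loss

def subtask_loss(y_hat, y) -> float:
    """Sum-normalized absolute error for one nutrient subtask."""
    y_hat = np.asarray(y_hat, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    denom = y.sum()
    num = np.abs(y_hat - y).sum()
    if denom > 0:
        return float(num / denom)
    if num > 0:
        warnings.warn("all true values are zero; returning sum of |predictions|", stacklevel=2)
        return float(np.abs(y_hat).sum())
    return 0.0


def total_loss(y_hat: np.ndarray, y: np.ndarray) -> float:
    """Sum of the five per-nutrient subtask losses over an N x 5 batch."""
    y_hat = np.asarray(y_hat, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if y_hat.shape != y.shape or y.ndim != 2 or y.shape[1] != len(NUTRIENTS):
        raise ValueError(f"expected matching N x {len(NUTRIENTS)} arrays, got {y_hat.shape} and {y.shape}")
    if (y < 0).any():
        raise ValueError("true nutrient values must be non-negative")
    return float(sum(subtask_loss(y_hat[:, m], y[:, m]) for m in range(len(NUTRIENTS))))


def multitask_loss_tensor(pred: Tensor, target: np.ndarray, eps: float = 1e-8) -> Tensor:
    """Differentiable total loss for training: pred is an N x 5 Tensor.

    eps guards the (never-expected) all-zero-target batch so training stays
    finite; with any positive target it is negligible.
    """
    target = np.asarray(target, dtype=np.float32)
    denom = target.sum(axis=0) + eps  # per-subtask normalizers, shape (5,)
    return ((pred - target).abs().sum(axis=0) / denom).sum()


# -------------------------------------------------------------- scalar metrics

def mae(y_hat, y) -> float:
    y_hat, y = np.asarray(y_hat, np.float64), np.asarray(y, np.float64)
    return float(np.abs(y_hat - y).mean())


def mse(y_hat, y) -> float:
    y_hat, y = np.asarray(y_hat, np.float64), np.asarray(y, np.float64)
    return float(((y_hat - y) ** 2).mean())


def rmse(y_hat, y) -> float:
    return math.sqrt(mse(y_hat, y))


def r2(y_hat, y) -> float:
    """1 - SS_res/SS_tot; NaN with a warning when y has zero variance."""
    y_hat, y = np.asarray(y_hat, np.float64), np.asarray(y, np.float64)
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        warnings.warn("R² undefined: true values have zero variance", stacklevel=2)
        return float("nan")
    return float(1.0 - ((y_hat - y) ** 2).sum() / ss_tot)


def pmae(y_hat, y) -> float:
    """Percentage mean absolute error: 100 * MAE / mean(y)."""
    y = np.asarray(y, np.float64)
    m = y.mean()
    if m <= 0:
        raise ValueError("PMAE requires a positive mean of the true values")
    return 100.0 * mae(y_hat, y) / m


# -------------------------------------------------------------------- reports

@dataclass(frozen=True)
class EvalReport:
    """Per-nutrient metrics plus the unweighted mean PMAE over the five."""

    per_nutrient: dict[str, dict[str, float]]  # nutrient -> metric -> value
    mean_pmae: float
    scatter: dict[str, np.ndarray]  # nutrient -> (N, 2) array of (truth, prediction)
    segmentation: dict[str, float] | None = None

    def to_text(self) -> str:
        cols = ["PMAE (%)", "MAE", "MSE", "RMSE", "R2"]
        keys = ["pmae", "mae", "mse", "rmse", "r2"]
        lines = ["Nutrient   " + "".join(f"{c:>12}" for c in cols)]
        for n in NUTRIENTS:
            row = self.per_nutrient[n]
            lines.append(f"{n:<11}" + "".join(f"{row[k]:>12.2f}" for k in keys))
        lines.append(f"Mean PMAE (%): {self.mean_pmae:.2f}")
        if self.segmentation:
            seg = "  ".join(f"{k}={v * 100:.2f}%" for k, v in self.segmentation.items())
            lines.append(f"Segmentation: {seg}")
        return "\n".join(lines)

    def to_csv(self, path: str | Path) -> None:
        with Path(path).open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["nutrient", "pmae", "mae", "mse", "rmse", "r2"])
            for n in NUTRIENTS:
                row = self.per_nutrient[n]
                w.writerow([n] + [repr(row[k]) for k in ("pmae", "mae", "mse", "rmse", "r2")])
            w.writerow(["mean_pmae", repr(self.mean_pmae), "", "", "", ""])

    def export_scatter(self, out_dir: str | Path) -> None:
        """One CSV of (truth, prediction) pairs per nutrient, for scatter plots."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for n, pairs in self.scatter.items():
            with (out / f"scatter_{n}.csv").open("w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["truth", "prediction"])
                w.writerows(pairs.tolist())


def evaluate(y_hat: np.ndarray, y: np.ndarray,
             segmentation: dict[str, float] | None = None) -> EvalReport:
    """Full evaluation of an N x 5 prediction batch against N x 5 truths."""
    y_hat = np.asarray(y_hat, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if y_hat.shape != y.shape or y.ndim != 2 or y.shape[1] != len(NUTRIENTS):
        raise ValueError(f"expected matching N x {len(NUTRIENTS)} arrays, got {y_hat.shape} and {y.shape}")
    if (y < 0).any():
        raise ValueError("true nutrient values must be non-negative")
    per: dict[str, dict[str, float]] = {}
    scatter: dict[str, np.ndarray] = {}
    for m, name in enumerate(NUTRIENTS):
        yh, yt = y_hat[:, m], y[:, m]
        per[name] = {
            "pmae": pmae(yh, yt),
            "mae": mae(yh, yt),
            "mse": mse(yh, yt),
            "rmse": rmse(yh, yt),
            "r2": r2(yh, yt),
        }
        scatter[name] = np.stack([yt, yh], axis=1)
    mean_pmae = float(np.mean([per[n]["pmae"] for n in NUTRIENTS]))
    return EvalReport(per_nutrient=per, mean_pmae=mean_pmae, scatter=scatter,
                      segmentation=segmentation)
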