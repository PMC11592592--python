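"""Reconstruction and classification metrics.

Reconstruction quality of a bar image is measured three ways: mean
absolute error over all pixel-channel values of the 100x25x5 image,
nucleotide (color) accuracy over bars, and mean absolute bar-length error.
Color accuracy and length error are deliberately orthogonal: one ignores
lengths, the other ignores colors. Classification uses accuracy,
sensitivity (recall on the pre-miRNA class) and specificity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .encoding import BarSpec

__all__ = ["ReconstructionReport", "mae", "nucleotide_accuracy", "mae_length",
           "classification_report"]


@dataclass(frozen=True)
class ReconstructionReport:
    mae: float
    nucleotide_accuracy: float
    mae_length: float
    n_images: int
    n_bars: int

    def as_dict(self) -> dict[str, float]:
        return {"mae": self.mae, "nucleotide_accuracy": self.nucleotide_accuracy,
                "mae_length": self.mae_length, "n_images": self.n_images,
                "n_bars": self.n_bars}


def mae(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Mean absolute error over every pixel-channel value (background
    included)."""
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    return float(np.mean(np.abs(x - x_hat)))


def _check_alignment(bars: list[BarSpec], bars_hat: list[BarSpec]) -> None:
    if len(bars) != len(bars_hat):
        raise ValueError(
            f"bar alignment mismatch: {len(bars)} true vs {len(bars_hat)} "
            f"predicted bars"
        )


def nucleotide_accuracy(bars: list[BarSpec], bars_hat: list[BarSpec]) -> float:
    """Fraction of bars whose color matches (GAP counts as a fifth color)."""
    _check_alignment(bars, bars_hat)
    if not bars:
        raise ValueError("no bars to compare")
    return float(np.mean([b.color == bh.color for b, bh in zip(bars, bars_hat)]))


def mae_length(bars: list[BarSpec], bars_hat: list[BarSpec]) -> float:
    """Mean absolute difference of bar lengths in pixels."""
    _check_alignment(bars, bars_hat)
    if not bars:
        raise ValueError("no bars to compare")
    return float(np.mean([abs(b.length - bh.length) for b, bh in zip(bars, bars_hat)]))


def classification_report(y_true, y_pred) -> dict[str, float]:
    """Accuracy, sensitivity and specificity for binary labels.

    Sensitivity is recall on the positive (pre-miRNA) class. If only one
    class is present in ``y_true`` the undefined rate is NaN, with a
    warning.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays differ in shape")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    acc = (tp + tn) / len(y_true)
    if tp + fn == 0:
        warnings.warn("no positive examples: sensitivity undefined")
        sens = float("nan")
    else:
        sens = tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn("no negative examples: specificity undefined")
        spec = float("nan")
    else:
        spec = tn / (tn + fp)
    return {"accuracy": float(acc), "sensitivity": float(sens),
            "specificity": float(spec)}
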