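"""Fusion-quality metrics (SSIM sum, histogram entropy, gradient
consistency) and binary segmentation metrics (Dice, IoU, Precision,
Recall)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

from .dfrs import forward_diff
from .errors import ConfigurationError, ContractError

__all__ = [
    "MetricReport",
    "q_spatial",
    "q_info",
    "q_edge",
    "seg_metrics",
    "binarize",
]

SSIM_PARAMS = dict(win_size=11, gaussian_weights=True, sigma=1.5, K1=0.01, K2=0.03)


@dataclass
class MetricReport:
    values: dict[str, float]
    inputs: list[str] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.values[key]


def q_spatial(fused: np.ndarray, inputs, normalized: bool = False) -> float:
    """Sum over inputs of SSIM(fused, input).

    The raw sum has maximum N (one per input); ``normalized=True`` divides
    by N for a [0, 1]-scaled variant reported alongside the raw value.
    """
    fused = np.asarray(fused, dtype=np.float64)
    total = 0.0
    count = 0
    for img in inputs:
        img = np.asarray(img, dtype=np.float64)
        if img.shape != fused.shape:
            raise ContractError(f"input shape {img.shape} != fused shape {fused.shape}")
        total += structural_similarity(fused, img, data_range=1.0, **SSIM_PARAMS)
        count += 1
    if count == 0:
        raise ContractError("q_spatial requires at least one input image")
    return total / count if normalized else total


def q_info(image: np.ndarray, bins: int = 256) -> float:
    """Shannon entropy (bits) of the intensity histogram over [0, 1]."""
    if bins < 2:
        raise ConfigurationError(f"bins must be >= 2, got {bins}")
    image = np.asarray(image, dtype=np.float64)
    hist, _ = np.histogram(image.ravel(), bins=bins, range=(0.0, 1.0))
    p = hist[hist > 0] / image.size
    return float(-(p * np.log2(p)).sum())


def q_edge(fused: np.ndarray, inputs) -> float:
    """Sum over inputs of the squared L2 gradient discrepancy
    ||grad F - grad I_i||^2 (forward differences; lower is better)."""
    fused = np.asarray(fused, dtype=np.float64)
    gy_f, gx_f = forward_diff(fused, 0), forward_diff(fused, 1)
    total = 0.0
    count = 0
    for img in inputs:
        img = np.asarray(img, dtype=np.float64)
        if img.shape != fused.shape:
            raise ContractError(f"input shape {img.shape} != fused shape {fused.shape}")
        gy_i, gx_i = forward_diff(img, 0), forward_diff(img, 1)
        total += float(((gy_f - gy_i) ** 2).sum() + ((gx_f - gx_i) ** 2).sum())
        count += 1
    if count == 0:
        raise ContractError("q_edge requires at least one input image")
    return total


def binarize(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    return (np.asarray(probs) >= threshold).astype(np.uint8)


def _check_binary(mask: np.ndarray, name: str) -> np.ndarray:
    mask = np.asarray(mask)
    values = np.unique(mask)
    if not np.all(np.isin(values, (0, 1))):
        raise ContractError(f"{name} must be binary (0/1), found values {values[:5]}")
    return mask.astype(bool)


def seg_metrics(pred_mask: np.ndarray, truth_mask: np.ndarray) -> MetricReport:
    """Dice, IoU, Precision, Recall for a binary mask pair.

    Conventions: both masks empty -> all metrics 1.0; an empty denominator
    set otherwise -> 0.0 (keeps batch averages NaN-free).
    """
    pred = _check_binary(pred_mask, "pred_mask")
    truth = _check_binary(truth_mask, "truth_mask")
    if pred.shape != truth.shape:
        raise ContractError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = float(np.logical_and(pred, truth).sum())
    p = float(pred.sum())
    t = float(truth.sum())
    union = p + t - tp
    if p == 0 and t == 0:
        values = {"dice": 1.0, "iou": 1.0, "precision": 1.0, "recall": 1.0}
    else:
        values = {
            "dice": 2.0 * tp / (p + t) if (p + t) > 0 else 0.0,
            "iou": tp / union if union > 0 else 0.0,
            "precision": tp / p if p > 0 else 0.0,
            "recall": tp / t if t > 0 else 0.0,
        }
    return MetricReport(values=values, parameters={"threshold_convention": "empty/empty=1"})
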