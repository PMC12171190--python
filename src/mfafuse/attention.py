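"""Per-scale importance maps and residual attention modulation.

Functional reference implementations on channels-last numpy arrays
``(H, W, C)``. The network applies the same math through the autograd
layer; tests cross-check the two paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ContractError

__all__ = ["AttentionMap", "compute_attention", "apply_residual_attention"]


@dataclass
class AttentionMap:
    values: np.ndarray  # (H, W, C), entries in [0, 1], spatial sum 1 per channel
    scale: int = 0
    image_index: int = 0


def compute_attention(feature_map: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Channel-mix by a CxC matrix (a 1x1 convolution), then softmax over
    spatial locations independently per channel.

    Returns an (H, W, C) map whose entries lie in [0, 1] and sum to 1 over
    the spatial grid for every channel.
    """
    feature_map = np.asarray(feature_map, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if feature_map.ndim != 3:
        raise ContractError(f"feature map must be (H, W, C), got shape {feature_map.shape}")
    c = feature_map.shape[-1]
    if weights.shape != (c, c):
        raise ConfigurationError(
            f"attention weight matrix must be ({c}, {c}), got {weights.shape}"
        )
    logits = feature_map @ weights.T  # per-pixel linear transform
    # stabilized softmax over the spatial grid, per channel
    shifted = logits - logits.max(axis=(0, 1), keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=(0, 1), keepdims=True)


def apply_residual_attention(
    feature_map: np.ndarray, attention: np.ndarray, residual: bool = True
) -> np.ndarray:
    """Modulate features by attention: ``A * F``, or ``F + A * F`` in
    residual mode (the default consumed by fusion)."""
    feature_map = np.asarray(feature_map, dtype=np.float64)
    attention = attention.values if isinstance(attention, AttentionMap) else attention
    attention = np.asarray(attention, dtype=np.float64)
    if attention.shape != feature_map.shape:
        raise ContractError(
            f"attention shape {attention.shape} != feature shape {feature_map.shape}"
        )
    modulated = attention * feature_map
    return feature_map + modulated if residual else modulated
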