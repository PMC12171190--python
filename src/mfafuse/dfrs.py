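"""Dynamic feature refinement: saliency scores, softmax fusion weights,
global context aggregation, gated context attention, and alpha-gated
refinement.

Functional reference implementations on channels-last numpy arrays. The
saliency score is the mean absolute forward-difference gradient of a map
(raw L1 norms grow with map area and saturate the downstream softmax, so
scores are divided by the element count; ordering within a scale is
unchanged because all maps at a scale share their size).
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError, ContractError

__all__ = [
    "saliency",
    "saliency_weights",
    "global_context",
    "context_attention",
    "refine",
]


def forward_diff(arr: np.ndarray, axis: int) -> np.ndarray:
    """Forward difference along ``axis`` with replicate border (last slot 0)."""
    out = np.zeros_like(arr, dtype=np.float64)
    src = np.diff(arr, axis=axis)
    sl = [slice(None)] * arr.ndim
    sl[axis] = slice(0, arr.shape[axis] - 1)
    out[tuple(sl)] = src
    return out


def saliency(feature_map: np.ndarray) -> float:
    """Mean absolute spatial gradient (forward differences, both axes)."""
    arr = np.asarray(feature_map, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[..., None]
    if arr.ndim != 3:
        raise ContractError(f"feature map must be (H, W) or (H, W, C), got {arr.shape}")
    gy = forward_diff(arr, axis=0)
    gx = forward_diff(arr, axis=1)
    return float((np.abs(gy).sum() + np.abs(gx).sum()) / arr.size)


def saliency_weights(scores) -> np.ndarray:
    """Softmax of saliency scores (max-subtraction stabilized) -> simplex weights."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size == 0:
        raise ConfigurationError("saliency_weights requires at least one score")
    shifted = scores - scores.max()
    e = np.exp(shifted)
    return e / e.sum()


def global_context(maps) -> np.ndarray:
    """Elementwise arithmetic mean over the N input maps."""
    arrays = [np.asarray(m, dtype=np.float64) for m in maps]
    if len(arrays) == 0:
        raise ContractError("global_context requires at least one map")
    shape = arrays[0].shape
    for a in arrays[1:]:
        if a.shape != shape:
            raise ContractError(f"shape mismatch in global_context: {a.shape} != {shape}")
    return np.mean(arrays, axis=0)


def context_attention(
    fused: np.ndarray,
    context: np.ndarray,
    gate_weights: np.ndarray | None = None,
    gate_bias: np.ndarray | None = None,
) -> np.ndarray:
    """Concatenation-gated context injection.

    gate = logistic(1x1 conv over [fused; context]); G = gate * context.
    With zero gate parameters the gate is exactly 0.5 everywhere. |G| never
    exceeds |context| elementwise because the gate lies in (0, 1).
    """
    fused = np.asarray(fused, dtype=np.float64)
    context = np.asarray(context, dtype=np.float64)
    if fused.shape != context.shape:
        raise ContractError(f"shape mismatch: fused {fused.shape} vs context {context.shape}")
    if fused.ndim == 2:
        fused, context = fused[..., None], context[..., None]
        squeeze = True
    else:
        squeeze = False
    c = fused.shape[-1]
    if gate_weights is None:
        gate_weights = np.zeros((c, 2 * c))
    gate_weights = np.asarray(gate_weights, dtype=np.float64)
    if gate_weights.shape != (c, 2 * c):
        raise ContractError(f"gate weights must be ({c}, {2 * c}), got {gate_weights.shape}")
    bias = np.zeros(c) if gate_bias is None else np.asarray(gate_bias, dtype=np.float64)
    stacked = np.concatenate([fused, context], axis=-1)  # (H, W, 2C)
    logits = stacked @ gate_weights.T + bias
    gate = 1.0 / (1.0 + np.exp(-logits))
    out = gate * context
    return out[..., 0] if squeeze else out


def refine(fused: np.ndarray, refinement: np.ndarray, alpha: float) -> np.ndarray:
    """Alpha-gated refinement: fused + alpha * G (alpha initialized to 0)."""
    fused = np.asarray(fused, dtype=np.float64)
    refinement = np.asarray(refinement, dtype=np.float64)
    if fused.shape != refinement.shape:
        raise ContractError(
            f"shape mismatch: fused {fused.shape} vs refinement {refinement.shape}"
        )
    return fused + float(alpha) * refinement
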