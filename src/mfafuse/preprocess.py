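"""Intensity normalization and cross-modality calibration.

Two normalizers are exposed: a min-max map to [0, 1] for raw loading and a
z-score map (population standard deviation) used on the refinement path
before encoding. Calibration histogram-matches every image of a stack to
the pooled intensity distribution of the whole stack — a monotone,
rank-preserving remap that equalizes dynamic range across modalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DegenerateInputError

__all__ = [
    "NormalizedStack",
    "minmax_normalize",
    "zscore_normalize",
    "normalize_stack",
    "calibrate_stack",
]


@dataclass
class NormalizedStack:
    images: list[np.ndarray]
    method: str
    per_image_stats: list[tuple[float, float]] = field(default_factory=list)


def minmax_normalize(image: np.ndarray, index: int | None = None) -> np.ndarray:
    """Map an image linearly onto [0, 1]: (I - min) / (max - min)."""
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise DegenerateInputError("image contains non-finite values")
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        label = "image" if index is None else f"image {index}"
        raise DegenerateInputError(f"constant {label}: min == max == {lo}")
    return (image - lo) / (hi - lo)


def zscore_normalize(image: np.ndarray, index: int | None = None) -> np.ndarray:
    """Center and scale to zero mean, unit population standard deviation."""
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise DegenerateInputError("image contains non-finite values")
    mu = float(image.mean())
    sigma = float(image.std())  # population (ddof=0)
    if sigma == 0.0:
        label = "image" if index is None else f"image {index}"
        raise DegenerateInputError(f"constant {label}: zero standard deviation")
    return (image - mu) / sigma


def normalize_stack(images, method: str = "zscore") -> NormalizedStack:
    if method not in ("minmax", "zscore"):
        raise ConfigurationError(f"unknown normalization method {method!r}")
    out, stats = [], []
    for i, img in enumerate(images):
        img = np.asarray(img, dtype=np.float64)
        if method == "minmax":
            out.append(minmax_normalize(img, index=i))
            stats.append((float(img.min()), float(img.max())))
        else:
            out.append(zscore_normalize(img, index=i))
            stats.append((float(img.mean()), float(img.std())))
    return NormalizedStack(images=out, method=method, per_image_stats=stats)


def _match_to_sorted_reference(image: np.ndarray, reference_sorted: np.ndarray) -> np.ndarray:
    """Monotone rank-preserving remap of ``image`` onto a sorted reference."""
    flat = image.ravel()
    n = flat.size
    order = np.argsort(flat, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    quantiles = (ranks + 0.5) / n
    m = reference_sorted.size
    grid = (np.arange(m) + 0.5) / m
    return np.interp(quantiles, grid, reference_sorted).reshape(image.shape)


def calibrate_stack(stack: NormalizedStack | list[np.ndarray]) -> NormalizedStack:
    """Histogram-match every image to the pooled stack intensity distribution.

    The remap is monotone in each image's pixel values, so within-image rank
    order is preserved; a single-image stack is returned unchanged.
    """
    if isinstance(stack, NormalizedStack):
        images, method, stats = stack.images, stack.method, stack.per_image_stats
    else:
        images, method, stats = list(stack), "zscore", []
    if len(images) == 0:
        raise ConfigurationError("calibrate_stack requires a non-empty stack")
    if len(images) == 1:
        return NormalizedStack(
            images=[np.asarray(images[0], dtype=np.float64)],
            method=method,
            per_image_stats=list(stats),
        )
    pooled = np.sort(np.concatenate([np.asarray(im, dtype=np.float64).ravel() for im in images]))
    matched = [_match_to_sorted_reference(np.asarray(im, dtype=np.float64), pooled) for im in images]
    return NormalizedStack(images=matched, method=method, per_image_stats=list(stats))
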