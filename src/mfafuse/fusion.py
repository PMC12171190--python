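"""Per-scale convex fusion, learned simplex weights, and the classical
Laplacian-pyramid fusion baseline."""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .errors import ConfigurationError, ContractError

__all__ = [
    "fuse_scale",
    "learned_weights",
    "laplacian_pyramid",
    "reconstruct_laplacian",
    "laplacian_fuse",
]

_SIMPLEX_TOL = 1e-6


def fuse_scale(aligned_maps, weights) -> np.ndarray:
    """Convex combination of N aligned maps: sum_i w_i * F_i."""
    maps = [np.asarray(m, dtype=np.float64) for m in aligned_maps]
    w = np.asarray(weights, dtype=np.float64)
    if w.ndim != 1 or len(maps) != w.size:
        raise ContractError(f"got {len(maps)} maps but {w.size} weights")
    if np.any(w < -_SIMPLEX_TOL) or abs(w.sum() - 1.0) > _SIMPLEX_TOL:
        raise ContractError(f"weights must lie on the probability simplex, got {w}")
    shape = maps[0].shape
    for m in maps[1:]:
        if m.shape != shape:
            raise ContractError(f"shape mismatch among aligned maps: {m.shape} != {shape}")
    out = np.zeros(shape)
    for wi, m in zip(w, maps):
        out += wi * m
    return out


def learned_weights(params) -> np.ndarray:
    """Softmax of N free scalars — simplex weights by construction."""
    params = np.asarray(params, dtype=np.float64)
    shifted = params - params.max()
    e = np.exp(shifted)
    return e / e.sum()


# -- Laplacian-pyramid baseline ------------------------------------------------


def _smooth(img: np.ndarray) -> np.ndarray:
    return ndimage.gaussian_filter(img, sigma=1.0, mode="nearest")


def _down(img: np.ndarray) -> np.ndarray:
    h, w = img.shape
    return resize(
        _smooth(img), ((h + 1) // 2, (w + 1) // 2), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )


def _up(img: np.ndarray, shape) -> np.ndarray:
    return resize(img, shape, order=1, mode="edge", anti_aliasing=False, preserve_range=True)


def laplacian_pyramid(image: np.ndarray, levels: int) -> list[np.ndarray]:
    """Decompose into ``levels`` detail bands plus a lowpass residual.

    Reconstruction by :func:`reconstruct_laplacian` is exact by construction:
    each detail band stores the difference between a level and the upsampled
    next level.
    """
    image = np.asarray(image, dtype=np.float64)
    if levels < 1:
        raise ConfigurationError(f"levels must be >= 1, got {levels}")
    if min(image.shape) // (2**levels) < 2:
        raise ConfigurationError(
            f"{levels} levels too deep for image of shape {image.shape}"
        )
    pyramid = []
    current = image
    for _ in range(levels):
        smaller = _down(current)
        pyramid.append(current - _up(smaller, current.shape))
        current = smaller
    pyramid.append(current)  # lowpass residual
    return pyramid


def reconstruct_laplacian(pyramid: list[np.ndarray]) -> np.ndarray:
    current = pyramid[-1]
    for detail in reversed(pyramid[:-1]):
        current = detail + _up(current, detail.shape)
    return current


def laplacian_fuse(images, levels: int = 3) -> np.ndarray:
    """Classical multi-resolution fusion baseline.

    Every band — detail levels and the lowpass residual — takes the
    maximum-absolute coefficient across inputs; the fused pyramid is then
    inverted. (Selecting on the lowpass too keeps an all-zero input from
    diluting the other images' intensity.)
    """
    images = [np.asarray(im, dtype=np.float64) for im in images]
    if len(images) == 0:
        raise ContractError("laplacian_fuse requires at least one image")
    shape = images[0].shape
    for im in images[1:]:
        if im.shape != shape:
            raise ContractError(f"input shape mismatch: {im.shape} != {shape}")
    pyramids = [laplacian_pyramid(im, levels) for im in images]
    fused = []
    for lvl in range(levels + 1):
        bands = np.stack([p[lvl] for p in pyramids], axis=0)
        pick = np.abs(bands).argmax(axis=0)
        fused.append(np.take_along_axis(bands, pick[None], axis=0)[0])
    return reconstruct_laplacian(fused)
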