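"""Synthetic multi-pseudo-modality phantoms and degradation simulators.

Two structure families are provided: ``branching`` (random binary trees of
anti-aliased line segments, vessel-like) and ``blob`` (unions of random
anti-aliased ellipses, polyp-like). Every modality in a stack depicts the
same ground-truth structure; modalities differ by photometric offsets and —
optionally — by complementary rendering (modality 0 sharp, later modalities
blurred/gamma-shifted with background texture) so that fusion has something
to gain.

All randomness derives from the config seed through counter-based
sub-streams, so generation is a pure function of the config.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import ConfigurationError
from .seeding import child_seed, rng_for

__all__ = [
    "PhantomConfig",
    "DegradationSpec",
    "generate_phantom",
    "degrade",
    "make_dataset",
    "load_image",
    "save_image",
    "load_mask",
    "save_mask",
]

DEGRADATION_KINDS = ("none", "low_light", "jpeg", "motion_blur", "gaussian_noise")


@dataclass(frozen=True)
class PhantomConfig:
    """Configuration for one phantom stack."""

    height: int = 64
    width: int = 64
    n_modalities: int = 2
    structure: str = "branching"
    contrast: float = 0.8
    noise_sigma: float = 0.05
    modality_offsets: tuple[tuple[float, float], ...] | None = None
    seed: int = 0
    complementary: bool = True
    background_amp: float = 0.0
    background_sigma: float = 6.0
    visibility_dropout: float = 0.0
    visibility_sigma: float = 5.0
    # structure-specific knobs
    n_blobs: int = 3
    forced_ellipses: tuple[tuple[float, float, float, float, float], ...] | None = None
    branch_depth: int = 4

    def __post_init__(self):
        if self.height < 16 or self.width < 16:
            raise ConfigurationError(
                f"height and width must be >= 16, got {self.height}x{self.width}"
            )
        if self.n_modalities < 1:
            raise ConfigurationError(f"n_modalities must be >= 1, got {self.n_modalities}")
        if not (0.0 < self.contrast <= 1.0):
            raise ConfigurationError(f"contrast must be in (0, 1], got {self.contrast}")
        if not (0.0 <= self.visibility_dropout <= 1.0):
            raise ConfigurationError(
                f"visibility_dropout must be in [0, 1], got {self.visibility_dropout}"
            )
        if self.noise_sigma < 0:
            raise ConfigurationError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.structure not in ("branching", "blob"):
            raise ConfigurationError(f"unknown structure {self.structure!r}")
        if self.modality_offsets is not None and len(self.modality_offsets) != self.n_modalities:
            raise ConfigurationError(
                "modality_offsets length must equal n_modalities "
                f"({len(self.modality_offsets)} != {self.n_modalities})"
            )

    def offsets(self) -> list[tuple[float, float]]:
        if self.modality_offsets is not None:
            return [tuple(map(float, o)) for o in self.modality_offsets]
        base = [(1.0, 0.0), (0.7, 0.15), (0.85, 0.05), (0.6, 0.2)]
        return [base[i % len(base)] for i in range(self.n_modalities)]


@dataclass(frozen=True)
class DegradationSpec:
    """One degradation condition applied to a single image in [0, 1]."""

    kind: str = "none"
    jpeg_quality: int = 30
    blur_kernel: int = 5
    blur_sigma: float = 1.0
    noise_sigma: float = 0.05
    low_light_gain: float = 0.35
    low_light_gamma: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.kind not in DEGRADATION_KINDS:
            raise ConfigurationError(f"unknown degradation kind {self.kind!r}")
        if not (1 <= self.jpeg_quality <= 100):
            raise ConfigurationError(f"jpeg_quality must be in [1, 100], got {self.jpeg_quality}")
        if self.blur_kernel % 2 == 0 or self.blur_kernel < 1:
            raise ConfigurationError(f"blur_kernel must be odd, got {self.blur_kernel}")
        if self.blur_sigma <= 0:
            raise ConfigurationError(f"blur_sigma must be > 0, got {self.blur_sigma}")
        if self.noise_sigma < 0:
            raise ConfigurationError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if not (0.0 < self.low_light_gain <= 1.0):
            raise ConfigurationError(f"low_light_gain must be in (0, 1], got {self.low_light_gain}")


# -- structure rendering -------------------------------------------------------


def _segment_distance(yy, xx, p0, p1):
    """Distance of every pixel to segment p0-p1 (points as (y, x))."""
    v = np.array(p1) - np.array(p0)
    L2 = float(v @ v)
    if L2 == 0.0:
        return np.hypot(yy - p0[0], xx - p0[1])
    t = ((yy - p0[0]) * v[0] + (xx - p0[1]) * v[1]) / L2
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(yy - (p0[0] + t * v[0]), xx - (p0[1] + t * v[1]))


def _render_branching(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.height, cfg.width
    scale = min(h, w)
    segments: list[tuple[tuple, tuple, float]] = []

    def grow(p, angle, length, width_px, depth):
        p2 = (p[0] + length * np.sin(angle), p[1] + length * np.cos(angle))
        segments.append((p, p2, width_px))
        if depth <= 0:
            return
        for sign in (-1.0, 1.0):
            dtheta = rng.uniform(0.25, 0.7) * sign
            grow(p2, angle + dtheta, length * rng.uniform(0.6, 0.8), width_px * 0.75, depth - 1)

    root = (h * rng.uniform(0.75, 0.95), w * rng.uniform(0.3, 0.7))
    grow(root, rng.uniform(-2.0, -1.1), scale * 0.3, max(scale / 28.0, 1.2), cfg.branch_depth)

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    intensity = np.zeros((h, w))
    for p0, p1, width_px in segments:
        d = _segment_distance(yy, xx, p0, p1)
        # soft 1-px anti-aliased edge around the stroke of half-width width_px/2
        intensity = np.maximum(intensity, np.clip(width_px / 2.0 - d + 0.5, 0.0, 1.0))
    return intensity


def _render_ellipses(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.height, cfg.width
    if cfg.forced_ellipses is not None:
        ellipses = [tuple(map(float, e)) for e in cfg.forced_ellipses]
    else:
        ellipses = []
        for _ in range(cfg.n_blobs):
            cy = rng.uniform(0.25 * h, 0.75 * h)
            cx = rng.uniform(0.25 * w, 0.75 * w)
            a = rng.uniform(0.08, 0.2) * min(h, w)
            b = rng.uniform(0.08, 0.2) * min(h, w)
            theta = rng.uniform(0, np.pi)
            ellipses.append((cy, cx, a, b, theta))

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    intensity = np.zeros((h, w))
    for cy, cx, a, b, theta in ellipses:
        dy, dx = yy - cy, xx - cx
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        q = np.sqrt((u / a) ** 2 + (v / b) ** 2)
        # approximate signed distance (px) from the ellipse boundary
        sdist = (1.0 - q) * min(a, b)
        intensity = np.maximum(intensity, np.clip(sdist + 0.5, 0.0, 1.0))
    return intensity


def _render_modality(structure: np.ndarray, index: int, cfg: PhantomConfig) -> np.ndarray:
    """Per-modality structure view before photometric offsets and noise."""
    if index == 0 or not cfg.complementary:
        return structure
    blurred = ndimage.gaussian_filter(structure, sigma=1.0, mode="nearest")
    view = np.clip(blurred, 0.0, 1.0) ** 0.8
    tex_rng = rng_for(cfg.seed, "texture", index)
    texture = ndimage.gaussian_filter(tex_rng.standard_normal(structure.shape), sigma=3.0)
    span = np.ptp(texture)
    if span > 0:
        texture = (texture - texture.min()) / span - 0.5
    return np.clip(view + 0.16 * texture, 0.0, 1.0)


def _visibility_fields(config: PhantomConfig, shape) -> list[np.ndarray] | None:
    """Smooth per-modality visibility maps modelling complementary coverage.

    With dropout strength d, modality i sees the structure through
    ``1 - d * U_i`` where U_i is a smooth field in [0, 1]; modality 1 uses
    the complement of modality 0's field so that (for the common two-
    modality case) every region is visible somewhere in the stack.
    """
    d = config.visibility_dropout
    if d <= 0:
        return None
    fields = []
    for i in range(config.n_modalities):
        if i == 1:
            u = 1.0 - fields[0]
        else:
            raw = ndimage.gaussian_filter(
                rng_for(config.seed, "visibility", i).standard_normal(shape),
                sigma=config.visibility_sigma,
            )
            span = np.ptp(raw)
            u = (raw - raw.min()) / span if span > 0 else np.zeros(shape)
        fields.append(u)
    return [1.0 - d * u for u in fields]


def generate_phantom(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Generate a registered modality stack and its binary ground-truth mask.

    Returns ``(stack, mask)`` where ``stack`` has shape (N, H, W) with values
    in [0, 1] and ``mask`` is uint8 {0, 1} of shape (H, W).
    """
    rng = rng_for(config.seed, "structure")
    if config.structure == "branching":
        structure = _render_branching(config, rng)
    else:
        structure = _render_ellipses(config, rng)
    mask = (structure >= 0.5).astype(np.uint8)

    visibility = _visibility_fields(config, structure.shape)
    images = []
    for i, (gain, bias) in enumerate(config.offsets()):
        view = _render_modality(structure, i, config)
        if visibility is not None:
            view = view * visibility[i]
        if config.background_amp > 0:
            # smooth low-frequency confounder, distinct per modality
            bg_rng = rng_for(config.seed, "background", i)
            bg = ndimage.gaussian_filter(
                bg_rng.standard_normal(structure.shape), sigma=config.background_sigma
            )
            span = np.ptp(bg)
            if span > 0:
                bg = (bg - bg.min()) / span - 0.5
            view = view + config.background_amp * bg
        img = gain * (config.contrast * view) + bias
        if config.noise_sigma > 0:
            img = img + rng_for(config.seed, "noise", i).normal(
                0.0, config.noise_sigma, size=img.shape
            )
        images.append(np.clip(img, 0.0, 1.0))
    return np.stack(images, axis=0), mask


# -- degradations --------------------------------------------------------------


def _gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    ax = np.arange(size) - (size - 1) / 2.0
    k1 = np.exp(-0.5 * (ax / sigma) ** 2)
    k = np.outer(k1, k1)
    return k / k.sum()


def degrade(image: np.ndarray, spec: DegradationSpec) -> np.ndarray:
    """Apply one degradation condition to an image in [0, 1]."""
    image = np.asarray(image, dtype=np.float64)
    if spec.kind == "none":
        return image.copy()
    if spec.kind == "low_light":
        return np.clip(spec.low_light_gain * image**spec.low_light_gamma, 0.0, 1.0)
    if spec.kind == "jpeg":
        # JPEG is defined on 8-bit data: quantize, round-trip, rescale
        u8 = np.clip(np.round(image * 255.0), 0, 255).astype(np.uint8)
        buf = io.BytesIO()
        Image.fromarray(u8, mode="L").save(buf, format="JPEG", quality=spec.jpeg_quality)
        buf.seek(0)
        out = np.asarray(Image.open(buf), dtype=np.float64) / 255.0
        return out
    if spec.kind == "motion_blur":
        kernel = _gaussian_kernel(spec.blur_kernel, spec.blur_sigma)
        return np.clip(ndimage.convolve(image, kernel, mode="nearest"), 0.0, 1.0)
    if spec.kind == "gaussian_noise":
        if spec.noise_sigma == 0:
            return image.copy()
        noise = rng_for(spec.seed, "degrade_noise").normal(0.0, spec.noise_sigma, image.shape)
        return np.clip(image + noise, 0.0, 1.0)
    raise ConfigurationError(f"unknown degradation kind {spec.kind!r}")  # pragma: no cover


# -- image I/O (16-bit PNG images, 8-bit PNG masks) ----------------------------


def save_image(path: Path | str, image: np.ndarray) -> None:
    u16 = np.clip(np.round(np.asarray(image) * 65535.0), 0, 65535).astype(np.uint16)
    Image.fromarray(u16).save(str(path), format="PNG")


def load_image(path: Path | str) -> np.ndarray:
    img = Image.open(str(path))
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    if img.mode in ("I;16", "I"):
        return arr / 65535.0
    return arr / 255.0


def save_mask(path: Path | str, mask: np.ndarray) -> None:
    u8 = (np.asarray(mask) > 0).astype(np.uint8) * 255
    Image.fromarray(u8, mode="L").save(str(path), format="PNG")


def load_mask(path: Path | str) -> np.ndarray:
    return (np.asarray(Image.open(str(path)), dtype=np.float64) > 127).astype(np.uint8)


# -- dataset generation --------------------------------------------------------


def make_dataset(
    n_train: int,
    n_val: int,
    config: PhantomConfig,
    seed: int,
    out_dir: Path | str,
) -> dict:
    """Write a reproducible phantom dataset and return its manifest."""
    if n_train < 1 or n_val < 1:
        raise ConfigurationError("n_train and n_val must both be >= 1")
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise IOError(f"cannot create output directory {out}: {exc}") from exc

    entries = []
    for idx in range(n_train + n_val):
        split = "train" if idx < n_train else "val"
        sample_seed = child_seed(seed, "sample", idx)
        sample_cfg = replace(config, seed=sample_seed)
        stack, mask = generate_phantom(sample_cfg)
        image_paths = []
        for m in range(stack.shape[0]):
            rel = f"sample_{idx:04d}_mod{m}.png"
            save_image(out / rel, stack[m])
            image_paths.append(rel)
        mask_rel = f"sample_{idx:04d}_mask.png"
        save_mask(out / mask_rel, mask)
        entries.append(
            {
                "index": idx,
                "split": split,
                "seed": sample_seed,
                "images": image_paths,
                "mask": mask_rel,
            }
        )

    manifest = {
        "n_train": n_train,
        "n_val": n_val,
        "seed": seed,
        "config": asdict(config),
        "entries": entries,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def load_dataset(manifest_dir: Path | str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Load a written dataset back into (X_train, Y_train, X_val, Y_val) arrays."""
    root = Path(manifest_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    xs: dict[str, list] = {"train": [], "val": []}
    ys: dict[str, list] = {"train": [], "val": []}
    for entry in manifest["entries"]:
        stack = np.stack([load_image(root / p) for p in entry["images"]], axis=0)
        xs[entry["split"]].append(stack)
        ys[entry["split"]].append(load_mask(root / entry["mask"])[None])
    return (
        np.stack(xs["train"]),
        np.stack(ys["train"]).astype(np.float64),
        np.stack(xs["val"]),
        np.stack(ys["val"]).astype(np.float64),
    )


def dataset_checksum(manifest_dir: Path | str) -> str:
    """SHA-256 over all files in a dataset directory (sorted by name)."""
    root = Path(manifest_dir)
    digest = hashlib.sha256()
    for path in sorted(root.iterdir()):
        if path.is_file():
            digest.update(path.name.encode())
            digest.update(path.read_bytes())
    return digest.hexdigest()
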