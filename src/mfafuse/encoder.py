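"""Multi-scale convolutional feature extraction.

Level 1 is at full input resolution; each subsequent level halves the
spatial grid via a stride-2 convolution and doubles (by default) the
channel depth. Each level's block is convolution (stride 1) -> batch
normalization -> GELU. Inputs are reflection-padded to a multiple of
2**(L-1) before encoding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ContractError
from .nn import BatchNorm2d, Conv2d, Module, ModuleList, Tensor
from .seeding import rng_for

__all__ = [
    "EncoderConfig",
    "PAPER_ENCODER",
    "MultiScaleEncoder",
    "build_encoder",
    "extract_pyramid",
    "pad_to_multiple",
    "expected_parameter_count",
]


@dataclass(frozen=True)
class EncoderConfig:
    levels: int = 4
    base_channels: int = 8
    kernel_size: int = 3
    channel_growth: int = 2

    def __post_init__(self):
        if self.levels < 1:
            raise ConfigurationError(f"levels must be >= 1, got {self.levels}")
        if self.base_channels < 1:
            raise ConfigurationError(f"base_channels must be >= 1, got {self.base_channels}")
        if self.kernel_size % 2 == 0:
            raise ConfigurationError(f"kernel_size must be odd, got {self.kernel_size}")

    def channels(self, level: int) -> int:
        """Channel depth at 1-based ``level``."""
        return self.base_channels * self.channel_growth ** (level - 1)


#: The configuration reported for the full-scale model: four 3x3 blocks,
#: channels 64 -> 512, batch normalization + GELU.
PAPER_ENCODER = EncoderConfig(levels=4, base_channels=64, kernel_size=3, channel_growth=2)


class _Block(Module):
    """conv (stride 1) -> batch norm -> GELU."""

    def __init__(self, cin, cout, kernel, rng):
        super().__init__()
        self.conv = Conv2d(cin, cout, kernel, rng=rng)
        self.bn = BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).gelu()


class MultiScaleEncoder(Module):
    def __init__(self, config: EncoderConfig, in_channels: int = 1, seed: int = 0):
        super().__init__()
        self.config = config
        self.in_channels = in_channels
        blocks, downs = [], []
        for level in range(1, config.levels + 1):
            c = config.channels(level)
            rng = rng_for(seed, "encoder", "block", level)
            cin = in_channels if level == 1 else c
            blocks.append(_Block(cin, c, config.kernel_size, rng))
            if level < config.levels:
                rng_d = rng_for(seed, "encoder", "down", level)
                downs.append(
                    Conv2d(c, config.channels(level + 1), config.kernel_size, stride=2, rng=rng_d)
                )
        self.blocks = ModuleList(blocks)
        self.downs = ModuleList(downs)

    def forward(self, x: Tensor) -> list[Tensor]:
        """Return the feature pyramid [F^(1), ..., F^(L)] for x (B,C,H,W)."""
        div = 2 ** (self.config.levels - 1)
        if x.shape[2] % div or x.shape[3] % div:
            raise ContractError(
                f"input spatial size {x.shape[2:]} not divisible by {div}; pad first"
            )
        feats = []
        h = self.blocks[0](x)
        feats.append(h)
        for level in range(1, self.config.levels):
            h = self.blocks[level](self.downs[level - 1](h))
            feats.append(h)
        return feats


def build_encoder(config: EncoderConfig, seed: int = 0, in_channels: int = 1) -> MultiScaleEncoder:
    return MultiScaleEncoder(config, in_channels=in_channels, seed=seed)


def pad_to_multiple(image: np.ndarray, multiple: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Reflection-pad trailing rows/cols so H and W divide ``multiple``.

    Returns the padded image and the original (H, W) for later cropping.
    """
    h, w = image.shape[-2:]
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph == 0 and pw == 0:
        return image, (h, w)
    pad_spec = [(0, 0)] * (image.ndim - 2) + [(0, ph), (0, pw)]
    return np.pad(image, pad_spec, mode="reflect"), (h, w)


def extract_pyramid(encoder: MultiScaleEncoder, image: np.ndarray) -> list[np.ndarray]:
    """Extract the feature pyramid of one image, channels-last per level.

    Runs in evaluation mode (frozen normalization statistics) so the result
    is a deterministic, purely local function of the input.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ContractError(f"expected a single (H, W) image, got shape {image.shape}")
    padded, _ = pad_to_multiple(image, 2 ** (encoder.config.levels - 1))
    was_training = encoder.training
    encoder.eval()
    try:
        feats = encoder(Tensor(padded[None, None]))
    finally:
        if was_training:
            encoder.train()
    return [f.data[0].transpose(1, 2, 0) for f in feats]


def expected_parameter_count(config: EncoderConfig, in_channels: int = 1) -> int:
    """Closed-form weight/bias/normalization parameter count of the encoder."""
    k2 = config.kernel_size**2
    total = 0
    for level in range(1, config.levels + 1):
        c = config.channels(level)
        cin = in_channels if level == 1 else c
        total += c * cin * k2 + c  # block conv weights + biases
        total += 2 * c  # batch-norm gamma, beta
        if level < config.levels:
            cnext = config.channels(level + 1)
            total += cnext * c * k2 + cnext  # stride-2 downsampling conv
    return total
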