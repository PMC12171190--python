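"""The standard phantom benchmark: a fixed, fully seeded configuration
(32x32 blob phantoms, two complementary modalities, 160 train / 40 val,
4-level encoder at base width 8) used by the training, ablation, and
robustness harnesses so results are comparable across runs.

Everything here runs on one CPU in seconds-to-minutes; the full-scale
encoder preset remains available separately for configuration parity.
"""

from __future__ import annotations

import numpy as np

from .encoder import EncoderConfig
from .model import ModelConfig, build_model
from .phantoms import DegradationSpec, PhantomConfig, generate_phantom
from .seeding import child_seed
from .training import TrainConfig, evaluate, train

__all__ = [
    "BENCHMARK_SIZE",
    "ROBUSTNESS_CONDITIONS",
    "benchmark_phantom_config",
    "benchmark_model_config",
    "benchmark_train_config",
    "build_benchmark_data",
    "train_benchmark_variant",
]

BENCHMARK_SIZE = 32
BENCHMARK_N_TRAIN = 160
BENCHMARK_N_VAL = 40

#: The degradation conditions of the robustness harness (matching the
#: evaluated set: low light, JPEG Q=30, 5x5 Gaussian blur, sigma=0.05 noise).
ROBUSTNESS_CONDITIONS = (
    DegradationSpec(kind="low_light"),
    DegradationSpec(kind="jpeg", jpeg_quality=30),
    DegradationSpec(kind="motion_blur", blur_kernel=5, blur_sigma=1.0),
    DegradationSpec(kind="gaussian_noise", noise_sigma=0.05),
)


def benchmark_phantom_config(seed: int = 0) -> PhantomConfig:
    return PhantomConfig(
        height=BENCHMARK_SIZE,
        width=BENCHMARK_SIZE,
        n_modalities=2,
        structure="blob",
        contrast=0.6,
        noise_sigma=0.15,
        background_amp=1.0,
        background_sigma=5.0,
        visibility_dropout=0.9,
        visibility_sigma=5.0,
        seed=seed,
        complementary=True,
        n_blobs=3,
    )


def benchmark_model_config() -> ModelConfig:
    return ModelConfig(
        encoder=EncoderConfig(levels=4, base_channels=8, kernel_size=3, channel_growth=2),
        n_modalities=2,
    )


def benchmark_train_config(seed: int = 0) -> TrainConfig:
    return TrainConfig(
        lr=3e-3,
        warmup_epochs=5,
        max_epochs=18,
        early_stop_patience=10,
        batch_size=16,
        seed=seed,
    )


def build_benchmark_data(
    seed: int = 0,
    n_train: int = BENCHMARK_N_TRAIN,
    n_val: int = BENCHMARK_N_VAL,
    size: int = BENCHMARK_SIZE,
):
    """Generate the benchmark arrays (x_train, y_train, x_val, y_val) in memory."""
    xs, ys = [], []
    for idx in range(n_train + n_val):
        cfg = benchmark_phantom_config(seed=child_seed(seed, "benchmark_sample", idx))
        if size != BENCHMARK_SIZE:
            cfg = PhantomConfig(**{**cfg.__dict__, "height": size, "width": size})
        stack, mask = generate_phantom(cfg)
        xs.append(stack)
        ys.append(mask[None].astype(np.float64))
    x = np.stack(xs)
    y = np.stack(ys)
    return x[:n_train], y[:n_train], x[n_train:], y[n_train:]


def train_benchmark_variant(variant: str, seed: int, data=None) -> tuple:
    """Train one ablation variant on the standard benchmark.

    Returns ``(model_with_best_weights, history, val_metrics)``. The data
    seed is fixed (0) so every variant and training seed sees identical
    phantoms; ``seed`` controls initialization and batch order only.
    """
    if data is None:
        data = build_benchmark_data(seed=0)
    model = build_model(benchmark_model_config(), seed=seed, variant=variant)
    history = train(model, data, benchmark_train_config(seed=seed))
    model.load_state_dict(history["best_state"])
    metrics = evaluate(model, data[2], data[3])
    return model, history, metrics
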