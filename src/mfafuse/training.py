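"""Training loop (Adam, warm-up + cosine annealing, early stopping on
validation Dice), the combined Dice + cross-entropy loss, morphological
post-processing, and the ablation/robustness harnesses."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, ContractError
from .metrics import binarize, seg_metrics
from .model import ABLATION_VARIANTS, FusionNet, ModelConfig, build_model
from .nn import Adam, Tensor
from .phantoms import DegradationSpec, degrade
from .seeding import rng_for

__all__ = [
    "TrainConfig",
    "loss",
    "lr_at_epoch",
    "train",
    "postprocess",
    "evaluate",
    "run_ablation",
    "run_robustness",
]

_EPS = 1e-6


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    warmup_epochs: int = 5
    max_epochs: int = 100
    early_stop_patience: int = 10
    batch_size: int = 16
    loss_weights: tuple[float, float] = (0.5, 0.5)  # (dice, cross-entropy)
    seed: int = 0

    def __post_init__(self):
        if self.warmup_epochs >= self.max_epochs:
            raise ConfigurationError("warmup_epochs must be < max_epochs")
        if self.early_stop_patience < 1:
            raise ConfigurationError("early_stop_patience must be >= 1")


def loss(pred_probs, truth_mask, weights: tuple[float, float] = (0.5, 0.5)):
    """w_dice * (1 - soft Dice) + w_ce * binary cross-entropy, batch-averaged.

    Accepts Tensors (differentiable) or arrays (returns a float). Probabilities
    must lie in [0, 1] up to a small clamping tolerance.
    """
    as_array = not isinstance(pred_probs, Tensor)
    p = Tensor(pred_probs) if as_array else pred_probs
    t = Tensor(np.asarray(truth_mask, dtype=p.data.dtype))
    if p.shape != t.shape:
        raise ContractError(f"shape mismatch: probs {p.shape} vs mask {t.shape}")
    if p.data.min() < -1e-6 or p.data.max() > 1.0 + 1e-6:
        raise ContractError("predicted probabilities outside [0, 1]")
    w_dice, w_ce = weights
    pc = p.clip(_EPS, 1.0 - _EPS)
    ce = -(t * pc.log() + (1.0 - t) * (1.0 - pc).log()).mean()
    axes = tuple(range(1, len(p.shape)))  # per-sample reduction
    inter = (p * t).sum(axis=axes)
    denom = p.sum(axis=axes) + t.sum(axis=axes)
    dice = ((2.0 * inter + _EPS) / (denom + _EPS)).mean()
    total = w_dice * (1.0 - dice) + w_ce * ce
    return float(total.data) if as_array else total


def lr_at_epoch(epoch: int, config: TrainConfig) -> float:
    """Learning rate at 0-based ``epoch``: linear warm-up for the first
    ``warmup_epochs`` epochs, then cosine annealing to zero."""
    w, total = config.warmup_epochs, config.max_epochs
    if epoch < w:
        return config.lr * (epoch + 1) / w
    return config.lr * (1.0 + np.cos(np.pi * (epoch - w) / (total - w))) / 2.0


def _val_dice(model: FusionNet, x_val, y_val, batch_size: int, min_size: int = 0) -> float:
    model.eval()
    dices = []
    for start in range(0, len(x_val), batch_size):
        xb = x_val[start : start + batch_size]
        yb = y_val[start : start + batch_size]
        probs = model(xb)["seg_probs"].data
        for j in range(len(xb)):
            pred = binarize(probs[j, 0])
            if min_size > 0:
                pred = postprocess(pred, min_size=min_size)
            dices.append(seg_metrics(pred, yb[j, 0].astype(np.uint8))["dice"])
    model.train()
    return float(np.mean(dices))


def train(
    model: FusionNet, data, config: TrainConfig, quiet: bool = True, metric_fn=None
) -> dict:
    """Train on ``data = (x_train, y_train, x_val, y_val)`` and return a
    history dict with per-epoch train loss, validation Dice, learning rates,
    the best state dict, and the stopping epoch.

    ``metric_fn(model, epoch) -> float`` overrides the validation metric
    (used to exercise the early-stopping rule deterministically)."""
    x_train, y_train, x_val, y_val = data
    if len(x_train) == 0 or len(x_val) == 0:
        raise ConfigurationError("train and validation splits must be non-empty")
    optimizer = Adam(model.parameters(), lr=config.lr)
    history = {"train_loss": [], "val_dice": [], "lr": []}
    best_dice, best_state, best_epoch = -np.inf, None, -1
    stale = 0
    model.train()
    for epoch in range(config.max_epochs):
        optimizer.lr = lr_at_epoch(epoch, config)
        order = rng_for(config.seed, "shuffle", epoch).permutation(len(x_train))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            out = model(x_train[idx])
            batch_loss = loss(out["seg_probs"], y_train[idx], config.loss_weights)
            if not np.isfinite(batch_loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            optimizer.zero_grad()
            batch_loss.backward()
            optimizer.step()
            losses.append(float(batch_loss.data))
        if metric_fn is None:
            dice = _val_dice(model, x_val, y_val, config.batch_size)
        else:
            dice = metric_fn(model, epoch)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_dice"].append(dice)
        history["lr"].append(optimizer.lr)
        if not quiet:  # pragma: no cover
            print(f"epoch {epoch:3d}  loss {np.mean(losses):.4f}  val dice {dice:.4f}")
        if dice > best_dice:
            best_dice, best_epoch, stale = dice, epoch, 0
            best_state = model.state_dict()
        else:
            stale += 1
            if stale >= config.early_stop_patience:
                break
    history["best_val_dice"] = best_dice
    history["best_epoch"] = best_epoch
    history["stopped_epoch"] = epoch
    history["best_state"] = best_state
    return history


def postprocess(mask: np.ndarray, min_size: int = 0) -> np.ndarray:
    """Morphological closing (3x3) then removal of 8-connected components
    smaller than ``min_size`` pixels."""
    mask = np.asarray(mask) > 0
    square = np.ones((3, 3), dtype=bool)
    # dilation sees outside as empty, erosion as full: components touching
    # the image border are closed without being eaten away
    dilated = ndimage.binary_dilation(mask, structure=square)
    closed = ndimage.binary_erosion(dilated, structure=square, border_value=1)
    if min_size > 0:
        labels, _ = ndimage.label(closed, structure=square)  # 8-connectivity
        counts = np.bincount(labels.ravel())
        keep = counts >= min_size
        keep[0] = False
        closed = keep[labels]
    return closed.astype(np.uint8)


def evaluate(model: FusionNet, x_val, y_val, batch_size: int = 16, min_size: int = 0) -> dict:
    """Mean Dice/IoU/Precision/Recall of a model over a validation split."""
    model.eval()
    sums = {"dice": 0.0, "iou": 0.0, "precision": 0.0, "recall": 0.0}
    count = 0
    for start in range(0, len(x_val), batch_size):
        xb = x_val[start : start + batch_size]
        yb = y_val[start : start + batch_size]
        probs = model(xb)["seg_probs"].data
        for j in range(len(xb)):
            pred = binarize(probs[j, 0])
            if min_size > 0:
                pred = postprocess(pred, min_size=min_size)
            report = seg_metrics(pred, yb[j, 0].astype(np.uint8))
            for k in sums:
                sums[k] += report[k]
            count += 1
    return {k: v / count for k, v in sums.items()}


def run_ablation(
    data,
    model_config: ModelConfig,
    train_config: TrainConfig,
    variants=ABLATION_VARIANTS,
    seeds=(0, 1, 2),
) -> dict:
    """Train every variant with every seed on identical data; report
    mean +/- sd of the four segmentation metrics per variant and the
    full-vs-ablation Dice ordering."""
    if len(seeds) < 2:
        raise ConfigurationError("run_ablation requires at least 2 seeds")
    table: dict[str, dict] = {}
    for variant in variants:
        per_seed = []
        failures = []
        for seed in seeds:
            try:
                model = build_model(model_config, seed=seed, variant=variant)
                cfg = TrainConfig(**{**train_config.__dict__, "seed": seed})
                history = train(model, data, cfg)
                model.load_state_dict(history["best_state"])
                per_seed.append(evaluate(model, data[2], data[3], cfg.batch_size))
            except RuntimeError as exc:
                failures.append({"seed": seed, "error": str(exc)})
        row: dict = {"n_runs": len(per_seed), "failures": failures}
        if per_seed:
            for key in ("dice", "iou", "precision", "recall"):
                vals = np.array([r[key] for r in per_seed])
                row[f"{key}_mean"] = float(vals.mean())
                row[f"{key}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        table[variant] = row
    ordering = {}
    if "full" in table and "dice_mean" in table["full"]:
        for variant in variants:
            if variant == "full" or "dice_mean" not in table[variant]:
                continue
            ordering[variant] = bool(
                table["full"]["dice_mean"] >= table[variant]["dice_mean"]
            )
    return {"table": table, "full_beats_or_ties": ordering, "seeds": list(seeds)}


def degrade_stack_batch(x: np.ndarray, spec: DegradationSpec) -> np.ndarray:
    """Apply one degradation to every modality of every stack in a batch."""
    out = np.empty_like(x)
    for s in range(x.shape[0]):
        for m in range(x.shape[1]):
            per = DegradationSpec(**{**spec.__dict__, "seed": spec.seed + 1000 * s + m})
            out[s, m] = degrade(x[s, m], per)
    return out


def run_robustness(
    model: FusionNet, x_val, y_val, conditions, batch_size: int = 16, transform=None
) -> dict:
    """Evaluate a trained model on clean and per-condition degraded inputs.

    ``x_val`` holds raw [0, 1] stacks; degradation is applied to the raw
    images and ``transform`` (e.g. the normalization pipeline) afterwards.
    """
    if transform is None:
        transform = lambda arr: arr  # noqa: E731
    rows = {"clean": evaluate(model, transform(x_val), y_val, batch_size)}
    for spec in conditions:
        rows[spec.kind] = evaluate(
            model, transform(degrade_stack_batch(x_val, spec)), y_val, batch_size
        )
    return rows
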