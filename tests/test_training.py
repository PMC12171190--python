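import numpy as np
import pytest

from mfafuse.encoder import EncoderConfig
from mfafuse.errors import ConfigurationError, ContractError
from mfafuse.model import ModelConfig, build_model
from mfafuse.nn import Tensor
from mfafuse.phantoms import DegradationSpec, PhantomConfig, generate_phantom
from mfafuse.seeding import child_seed
from mfafuse.training import (
    TrainConfig,
    degrade_stack_batch,
    evaluate,
    loss,
    lr_at_epoch,
    postprocess,
    run_ablation,
    run_robustness,
    train,
)

TINY_MODEL = ModelConfig(encoder=EncoderConfig(levels=2, base_channels=4), n_modalities=2)


def tiny_data(n_train=6, n_val=2, size=16):
    xs, ys = [], []
    for i in range(n_train + n_val):
        cfg = PhantomConfig(
            height=size, width=size, structure="blob", noise_sigma=0.05,
            seed=child_seed(99, "tiny", i),
        )
        stack, mask = generate_phantom(cfg)
        xs.append(stack)
        ys.append(mask[None].astype(np.float64))
    x, y = np.stack(xs), np.stack(ys)
    return x[:n_train], y[:n_train], x[n_train:], y[n_train:]


class TestLoss:
    def test_perfect_prediction_vanishes(self):
        t = np.zeros((1, 1, 8, 8))
        t[0, 0, 2:5, 2:5] = 1.0
        p = np.where(t > 0, 1.0 - 1e-9, 1e-9)
        assert loss(p, t) == pytest.approx(0.0, abs=1e-4)

    def test_half_probs_balanced_ce_ln2(self):
        t = np.zeros((1, 1, 4, 4))
        t[0, 0, :2, :] = 1.0  # balanced mask
        p = np.full((1, 1, 4, 4), 0.5)
        value = loss(p, t, weights=(0.0, 1.0))  # cross-entropy only
        assert value == pytest.approx(np.log(2.0), abs=1e-5)

    def test_soft_dice_closed_form(self):
        # probs = p everywhere, mask fraction f: soft dice term = 1 - 2pf/(p+f)
        pconst, f = 0.3, 0.25
        t = np.zeros((1, 1, 8, 8))
        t[0, 0, :2, :] = 1.0  # 16 of 64 pixels
        p = np.full((1, 1, 8, 8), pconst)
        value = loss(p, t, weights=(1.0, 0.0))
        assert value == pytest.approx(1 - 2 * pconst * f / (pconst + f), abs=1e-5)

    def test_differentiable_path(self):
        t = np.zeros((2, 1, 4, 4))
        t[:, :, :2] = 1.0
        p = Tensor(np.full((2, 1, 4, 4), 0.5), requires_grad=True)
        out = loss(p, t)
        out.backward()
        assert p.grad is not None and np.all(np.isfinite(p.grad))

    def test_out_of_range_rejected(self):
        t = np.zeros((1, 1, 2, 2))
        with pytest.raises(ContractError):
            loss(np.full((1, 1, 2, 2), 1.5), t)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ContractError):
            loss(np.full((1, 1, 2, 2), 0.5), np.zeros((1, 1, 3, 2)))


class TestSchedule:
    def test_closed_form_everywhere(self):
        cfg = TrainConfig(lr=2e-3, warmup_epochs=5, max_epochs=30)
        for e in range(30):
            if e < 5:
                expected = 2e-3 * (e + 1) / 5
            else:
                expected = 2e-3 * (1 + np.cos(np.pi * (e - 5) / 25)) / 2
            assert lr_at_epoch(e, cfg) == pytest.approx(expected, rel=1e-12)

    def test_warmup_reaches_base_lr(self):
        cfg = TrainConfig(lr=1e-3, warmup_epochs=4, max_epochs=10)
        assert lr_at_epoch(3, cfg) == pytest.approx(1e-3)
        assert lr_at_epoch(4, cfg) == pytest.approx(1e-3)

    def test_invalid_config(self):
        with pytest.raises(ConfigurationError):
            TrainConfig(warmup_epochs=10, max_epochs=10)
        with pytest.raises(ConfigurationError):
            TrainConfig(early_stop_patience=0)


class TestTrain:
    def test_seeded_reproducibility(self):
        data = tiny_data()
        cfg = TrainConfig(lr=1e-3, warmup_epochs=1, max_epochs=3, batch_size=4, seed=7)
        h1 = train(build_model(TINY_MODEL, seed=7), data, cfg)
        h2 = train(build_model(TINY_MODEL, seed=7), data, cfg)
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_dice"] == h2["val_dice"]

    def test_early_stopping_patience_one(self):
        # metric never improves after the first epoch -> stop after epoch 2
        data = tiny_data()
        cfg = TrainConfig(
            lr=1e-4, warmup_epochs=1, max_epochs=50, early_stop_patience=1,
            batch_size=4, seed=0,
        )
        history = train(
            build_model(TINY_MODEL, seed=0), data, cfg,
            metric_fn=lambda model, epoch: 0.9 if epoch == 0 else 0.5,
        )
        assert history["stopped_epoch"] == 1
        assert len(history["val_dice"]) == 2
        assert history["best_epoch"] == 0

    def test_early_stopping_patience_respected(self):
        data = tiny_data()
        cfg = TrainConfig(
            lr=1e-4, warmup_epochs=1, max_epochs=50, early_stop_patience=3,
            batch_size=4, seed=0,
        )
        history = train(
            build_model(TINY_MODEL, seed=0), data, cfg,
            metric_fn=lambda model, epoch: -float(epoch),
        )
        # epoch 0 is best; 3 non-improving epochs follow
        assert history["stopped_epoch"] == 3

    def test_history_and_checkpoint(self):
        data = tiny_data()
        cfg = TrainConfig(lr=1e-3, warmup_epochs=1, max_epochs=2, batch_size=4, seed=1)
        history = train(build_model(TINY_MODEL, seed=1), data, cfg)
        assert history["lr"] == [lr_at_epoch(0, cfg), lr_at_epoch(1, cfg)]
        assert history["best_state"] is not None
        model = build_model(TINY_MODEL, seed=99)
        model.load_state_dict(history["best_state"])  # loadable

    def test_empty_split_rejected(self):
        x, y, xv, yv = tiny_data()
        with pytest.raises(ConfigurationError):
            train(
                build_model(TINY_MODEL, seed=0),
                (x[:0], y[:0], xv, yv),
                TrainConfig(max_epochs=2, warmup_epochs=1),
            )


class TestPostprocess:
    def test_small_island_removed(self):
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[4, 3:5] = 1  # 2-pixel interior island
        assert postprocess(mask, min_size=5).sum() == 0

    def test_clean_mask_fixed_point(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[2:7, 2:7] = 1
        np.testing.assert_array_equal(postprocess(mask, min_size=5), mask)

    def test_component_size_threshold(self):
        # components of sizes 2, 6, 9 with min_size=5 -> two survive
        mask = np.zeros((12, 12), dtype=np.uint8)
        mask[0, 0:2] = 1  # size 2
        mask[4:6, 4:7] = 1  # size 6
        mask[9:12, 0:3] = 1  # size 9
        out = postprocess(mask, min_size=5)
        from skimage.measure import label

        assert label(out, connectivity=2).max() == 2
        assert out.sum() == 15


@pytest.fixture(scope="module")
def quick_runs():
    data = tiny_data(n_train=8, n_val=4)
    cfg = TrainConfig(lr=2e-3, warmup_epochs=1, max_epochs=2, batch_size=4)
    return data, cfg


class TestHarnesses:

    def test_ablation_counting_and_table(self, quick_runs):
        data, cfg = quick_runs
        result = run_ablation(
            data, TINY_MODEL, cfg, variants=("full", "no_attention"), seeds=(0, 1)
        )
        assert set(result["table"]) == {"full", "no_attention"}
        for row in result["table"].values():
            assert row["n_runs"] == 2
            assert "dice_mean" in row and "dice_sd" in row
        assert set(result["full_beats_or_ties"]) == {"no_attention"}

    def test_ablation_needs_two_seeds(self, quick_runs):
        data, cfg = quick_runs
        with pytest.raises(ConfigurationError):
            run_ablation(data, TINY_MODEL, cfg, seeds=(0,))

    def test_robustness_clean_row_matches_evaluate(self, quick_runs):
        data, cfg = quick_runs
        model = build_model(TINY_MODEL, seed=0)
        history = train(model, data, cfg)
        model.load_state_dict(history["best_state"])
        conditions = [DegradationSpec(kind="none"), DegradationSpec(kind="gaussian_noise")]
        rows = run_robustness(model, data[2], data[3], conditions)
        assert set(rows) == {"clean", "none", "gaussian_noise"}
        direct = evaluate(model, data[2], data[3])
        assert rows["clean"] == direct
        assert rows["none"] == direct  # identity degradation

    def test_degrade_stack_batch_shapes(self, quick_runs):
        data, _ = quick_runs
        out = degrade_stack_batch(data[2], DegradationSpec(kind="motion_blur"))
        assert out.shape == data[2].shape
        assert out.min() >= 0 and out.max() <= 1
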