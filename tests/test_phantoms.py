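import numpy as np
import pytest

from mfafuse.errors import ConfigurationError
from mfafuse.phantoms import (
    DegradationSpec,
    PhantomConfig,
    dataset_checksum,
    degrade,
    generate_phantom,
    load_dataset,
    make_dataset,
)


class TestGeneratePhantom:
    def test_same_seed_bit_identical(self):
        cfg = PhantomConfig(seed=7)
        stack1, mask1 = generate_phantom(cfg)
        stack2, mask2 = generate_phantom(cfg)
        np.testing.assert_array_equal(stack1, stack2)
        np.testing.assert_array_equal(mask1, mask2)

    def test_identity_offsets_identical_modalities(self):
        cfg = PhantomConfig(
            noise_sigma=0.0,
            modality_offsets=((1.0, 0.0), (1.0, 0.0)),
            complementary=False,
            seed=3,
        )
        stack, _ = generate_phantom(cfg)
        np.testing.assert_array_equal(stack[0], stack[1])

    def test_forced_center_ellipse_area_matches_analytic(self):
        # mask area of a single anti-aliased ellipse vs pi*a*b, 2% margin
        h = w = 128
        a, b = 20.0, 12.0
        cfg = PhantomConfig(
            height=h, width=w, structure="blob",
            forced_ellipses=((h / 2, w / 2, a, b, 0.3),),
            noise_sigma=0.0, seed=0,
        )
        _, mask = generate_phantom(cfg)
        analytic = np.pi * a * b / (h * w)
        measured = mask.mean()
        assert abs(measured - analytic) / analytic < 0.02

    @pytest.mark.parametrize("structure", ["branching", "blob"])
    def test_range_and_binary_mask(self, structure):
        stack, mask = generate_phantom(PhantomConfig(structure=structure, seed=11))
        assert stack.min() >= 0.0 and stack.max() <= 1.0
        assert set(np.unique(mask)) <= {0, 1}
        assert mask.sum() > 0  # structure is present

    def test_invalid_dims_rejected(self):
        with pytest.raises(ConfigurationError):
            PhantomConfig(height=8)
        with pytest.raises(ConfigurationError):
            PhantomConfig(n_modalities=0)
        with pytest.raises(ConfigurationError):
            PhantomConfig(contrast=0.0)
        with pytest.raises(ConfigurationError):
            PhantomConfig(noise_sigma=-0.1)

    def test_counter_based_streams_stable(self):
        # identical structure regardless of modality count
        s2, m2 = generate_phantom(PhantomConfig(n_modalities=2, seed=5, noise_sigma=0))
        s3, m3 = generate_phantom(
            PhantomConfig(
                n_modalities=3, seed=5, noise_sigma=0,
                modality_offsets=((1.0, 0.0), (0.7, 0.15), (0.85, 0.05)),
            )
        )
        np.testing.assert_array_equal(m2, m3)
        np.testing.assert_array_equal(s2[0], s3[0])


class TestDegrade:
    def test_none_is_identity(self, rng):
        x = rng.random((32, 32))
        np.testing.assert_array_equal(degrade(x, DegradationSpec(kind="none")), x)

    def test_zero_noise_is_identity(self, rng):
        x = rng.random((32, 32))
        spec = DegradationSpec(kind="gaussian_noise", noise_sigma=0.0)
        np.testing.assert_array_equal(degrade(x, spec), x)

    def test_blur_preserves_constant(self):
        c = np.full((40, 40), 0.37)
        out = degrade(c, DegradationSpec(kind="motion_blur", blur_kernel=5, blur_sigma=1.0))
        np.testing.assert_allclose(out, c, atol=1e-12)

    def test_jpeg_quality_ordering(self):
        # derived: round-trip a ramp at Q=30 and Q=95, compare MAE
        ramp = np.tile(np.linspace(0, 1, 64), (64, 1))
        ramp = ramp + 0.05 * np.sin(np.linspace(0, 40, 64))[:, None]
        ramp = np.clip(ramp, 0, 1)
        mae30 = np.abs(degrade(ramp, DegradationSpec(kind="jpeg", jpeg_quality=30)) - ramp).mean()
        mae95 = np.abs(degrade(ramp, DegradationSpec(kind="jpeg", jpeg_quality=95)) - ramp).mean()
        assert mae30 > mae95

    def test_low_light_darkens_and_stays_in_range(self, rng):
        x = rng.random((32, 32))
        out = degrade(x, DegradationSpec(kind="low_light"))
        assert out.min() >= 0.0 and out.max() <= 1.0
        assert out.mean() < x.mean()

    def test_noise_mad_nondecreasing_in_sigma(self):
        # property: mean abs deviation vs clean is non-decreasing in sigma
        sigmas = [0.01, 0.03, 0.1]
        for seed in range(20):
            x, _ = generate_phantom(PhantomConfig(seed=seed, noise_sigma=0))
            mads = []
            for s in sigmas:
                spec = DegradationSpec(kind="gaussian_noise", noise_sigma=s, seed=seed)
                mads.append(np.abs(degrade(x[0], spec) - x[0]).mean())
            assert mads[0] <= mads[1] <= mads[2]

    def test_invalid_specs_rejected(self):
        with pytest.raises(ConfigurationError):
            DegradationSpec(kind="motion_blur", blur_kernel=4)
        with pytest.raises(ConfigurationError):
            DegradationSpec(kind="jpeg", jpeg_quality=0)
        with pytest.raises(ConfigurationError):
            DegradationSpec(kind="sepia")


class TestMakeDataset:
    def test_counts_and_splits(self, tmp_path):
        cfg = PhantomConfig(height=16, width=16, seed=0)
        manifest = make_dataset(8, 2, cfg, seed=1, out_dir=tmp_path / "d")
        assert len(manifest["entries"]) == 10
        splits = [e["split"] for e in manifest["entries"]]
        assert splits.count("train") == 8 and splits.count("val") == 2

    def test_rerun_bit_identical(self, tmp_path):
        cfg = PhantomConfig(height=16, width=16, seed=0)
        make_dataset(3, 1, cfg, seed=2, out_dir=tmp_path / "a")
        make_dataset(3, 1, cfg, seed=2, out_dir=tmp_path / "b")
        assert dataset_checksum(tmp_path / "a") == dataset_checksum(tmp_path / "b")

    def test_train_fraction_80_20(self, tmp_path):
        cfg = PhantomConfig(height=16, width=16, seed=0)
        manifest = make_dataset(80, 20, cfg, seed=3, out_dir=tmp_path / "d")
        n_train = sum(1 for e in manifest["entries"] if e["split"] == "train")
        assert n_train / len(manifest["entries"]) == 0.8

    def test_roundtrip_loadable(self, tmp_path):
        cfg = PhantomConfig(height=16, width=16, seed=0)
        make_dataset(2, 1, cfg, seed=4, out_dir=tmp_path / "d")
        xt, yt, xv, yv = load_dataset(tmp_path / "d")
        assert xt.shape == (2, 2, 16, 16) and xv.shape == (1, 2, 16, 16)
        assert yt.shape == (2, 1, 16, 16)
        assert xt.min() >= 0 and xt.max() <= 1
        assert set(np.unique(yt)) <= {0.0, 1.0}

    def test_invalid_counts(self, tmp_path):
        with pytest.raises(ConfigurationError):
            make_dataset(0, 1, PhantomConfig(), seed=0, out_dir=tmp_path)
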