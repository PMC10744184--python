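import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from virtualgrid import (GANConfig, Image2D, NoiseParams, add_noise, denoise,
                         desk_config, extract_patches, load_denoiser,
                         make_flat_field, make_phantom, make_training_pairs,
                         noise_grid, predict_noise, resize_bilinear,
                         save_denoiser, stitch_patches, train_gan)
from virtualgrid.denoiser import (TrainedDenoiser, build_discriminator,
                                  build_generator, discriminator_score)

from conftest import PHANTOM_KW, TEST_NOISE


class TestResize:
    def test_identity(self):
        img = Image2D(np.arange(4.0).reshape(2, 2), 1.0)
        assert (resize_bilinear(img, 2, 2).pixels == img.pixels).all()

    def test_constants_preserved(self):
        img = make_flat_field(10, 14, 3.5)
        out = resize_bilinear(img, 33, 7)
        assert np.allclose(out.pixels, 3.5)

    def test_three_halves_upscale_and_back(self):
        # the reference geometry is a 1.5x upscale on both axes
        assert 3300 * 3 // 2 == 4950 and 2432 * 3 // 2 == 3648
        rng = np.random.default_rng(0)
        from scipy.ndimage import gaussian_filter
        img = Image2D(gaussian_filter(rng.standard_normal((66, 48)), 4), 0.07)
        up = resize_bilinear(img, 99, 72)
        back = resize_bilinear(up, 66, 48)
        assert up.shape == (99, 72)
        # corner alignment: the four corners survive the round trip exactly
        for r, c in [(0, 0), (0, -1), (-1, 0), (-1, -1)]:
            assert back.pixels[r, c] == pytest.approx(img.pixels[r, c], rel=1e-9)
        assert np.abs(back.pixels - img.pixels).max() < 0.05 * np.ptp(img.pixels)

    def test_bad_target_rejected(self):
        with pytest.raises(ValueError):
            resize_bilinear(make_flat_field(4, 4, 1.0), 0, 4)


class TestPatching:
    def test_four_tiles_at_known_origins(self):
        cfg = GANConfig(patch_size=256, stride=256, channels=(8, 16))
        ps = extract_patches(make_flat_field(512, 512, 1.0), cfg)
        assert [(r, c) for _, r, c in ps.patches] == [
            (0, 0), (0, 256), (256, 0), (256, 256)]

    def test_reference_frame_padding_arithmetic(self):
        # 4950 x 3648 is not divisible by 256: padded to 5120 x 3840 -> 300 tiles
        cfg = GANConfig(patch_size=256, stride=256, channels=(8, 16))
        ps = extract_patches(Image2D(np.zeros((4950, 3648)), 0.07), cfg)
        assert ps.resized_shape == (5120, 3840)
        assert len(ps.patches) == 20 * 15

    def test_stitch_inverts_extract(self):
        rng = np.random.default_rng(1)
        img = Image2D(rng.standard_normal((130, 70)), 1.0)
        cfg = desk_config()
        back = stitch_patches(extract_patches(img, cfg))
        assert back.shape == img.shape
        assert (back.pixels == img.pixels).all()

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(h=st.integers(8, 150), w=st.integers(8, 150))
    def test_round_trip_any_shape(self, h, w):
        rng = np.random.default_rng(h * 1000 + w)
        img = Image2D(rng.standard_normal((h, w)), 1.0)
        cfg = GANConfig(patch_size=32, stride=32, channels=(4, 8))
        back = stitch_patches(extract_patches(img, cfg))
        assert (back.pixels == img.pixels).all()

    def test_missing_tile_detected(self):
        cfg = desk_config()
        ps = extract_patches(make_flat_field(128, 128, 1.0), cfg)
        ps.patches = ps.patches[:-1]
        with pytest.raises(Exception, match="cover|missing"):
            stitch_patches(ps)


class TestTrainingPairs:
    def test_residual_identity_and_count(self):
        clean = make_phantom(512, 512, 0.07, 0, seed=1).primary
        cfg = GANConfig(patch_size=256, stride=256, channels=(8, 16))
        grid = noise_grid(range(1, 8), range(6))
        pairs = make_training_pairs([clean], grid, cfg, seed=3)
        assert len(pairs) == 4 * 42
        # input - label = clean, pixel exact, for a spot-checked pair
        xin, lab = pairs[0]
        assert np.array_equal(xin - lab, clean.pixels[:256, :256])

    def test_labels_are_zero_mean_noise(self):
        clean = make_flat_field(128, 128, 200.0)
        cfg = desk_config()
        pairs = make_training_pairs([clean], noise_grid([2.0], [4.0]) * 10,
                                    cfg, seed=5)
        grand_mean = np.mean([lab.mean() for _, lab in pairs])
        assert abs(grand_mean) < 1.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            make_training_pairs([make_flat_field(64, 64, 1.0)], [], desk_config())


def _tiny_pairs(n=40, size=32, seed=0):
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n):
        clean = rng.uniform(50, 150) * np.ones((size, size))
        noise = rng.normal(0, 10, (size, size))
        pairs.append((clean + noise, noise))
    return pairs


def _tiny_config(**kw):
    base = dict(patch_size=32, stride=32, epochs=3, batch_size=8,
                channels=(8, 16), learning_rate=1e-3, adv_weight=1e-3, seed=0)
    base.update(kw)
    return GANConfig(**base)


class TestTraining:
    def test_seeded_determinism_of_first_epoch(self):
        a = train_gan(_tiny_pairs(), _tiny_config())
        b = train_gan(_tiny_pairs(), _tiny_config())
        assert a.training_log[0] == b.training_log[0]

    def test_supervised_mode_without_adversary(self):
        model = train_gan(_tiny_pairs(), _tiny_config(adv_weight=0.0))
        assert all(e["disc_loss"] == 0.0 for e in model.training_log)
        best = min(e["val_mse"] for e in model.training_log)
        assert best <= model.training_log[0]["val_mse"]

    def test_discriminator_outputs_probabilities(self):
        model = train_gan(_tiny_pairs(), _tiny_config())
        x = np.stack([p[1] for p in _tiny_pairs(8)])[:, None] / model.divisor
        scores = discriminator_score(model.discriminator, x)
        assert ((scores > 0) & (scores < 1)).all()

    def test_batch_larger_than_dataset_rejected(self):
        with pytest.raises(ValueError, match="batch"):
            train_gan(_tiny_pairs(4), _tiny_config(batch_size=64))


class TestInference:
    def test_fresh_generator_is_identity_denoiser(self):
        # the output layer starts at zero: predicted noise = 0, output = input
        cfg = _tiny_config()
        model = TrainedDenoiser(
            generator=build_generator(cfg, np.random.default_rng(0)),
            discriminator=build_discriminator(cfg, np.random.default_rng(1)),
            config=cfg)
        noisy = Image2D(np.random.default_rng(2).uniform(0, 100, (64, 48)), 1.0)
        out = denoise(model, noisy)
        assert np.allclose(out.pixels, noisy.pixels)

    def test_output_geometry_preserved(self, desk_model):
        noisy = make_flat_field(200, 150, 500.0, 0.5)
        out = denoise(desk_model, noisy)
        assert out.shape == noisy.shape
        assert out.pixel_size == noisy.pixel_size

    def test_trained_model_improves_rmse(self, desk_model, phantom_scene):
        clean = phantom_scene.primary
        noisy = add_noise(clean, TEST_NOISE, seed=99)
        den = denoise(desk_model, noisy)
        rmse_noisy = np.sqrt(np.mean((noisy.pixels - clean.pixels) ** 2))
        rmse_den = np.sqrt(np.mean((den.pixels - clean.pixels) ** 2))
        assert rmse_den < rmse_noisy

    def test_checkpoint_round_trip(self, desk_model, tmp_path):
        save_denoiser(desk_model, tmp_path / "model.npz")
        back = load_denoiser(tmp_path / "model.npz")
        noisy = add_noise(make_flat_field(128, 128, 800.0, 0.5), TEST_NOISE, 7)
        assert np.allclose(predict_noise(back, noisy).pixels,
                           predict_noise(desk_model, noisy).pixels)


class TestConfigValidation:
    def test_patch_size_divisibility(self):
        with pytest.raises(ValueError, match="divisible"):
            GANConfig(patch_size=100, stride=100, channels=(8, 16, 32))

    def test_stride_bound(self):
        with pytest.raises(ValueError):
            GANConfig(patch_size=64, stride=128, channels=(8,))

    def test_reference_defaults(self):
        cfg = GANConfig()
        assert cfg.patch_size == 256 and cfg.epochs == 200
        assert cfg.batch_size == 16 and cfg.learning_rate == 5e-4
        assert cfg.channels == (128, 256, 512, 1024)
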