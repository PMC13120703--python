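"""Readers, normalization, augmentation, CutMix and the synthetic generator."""

import numpy as np
import pytest

from medspectralnet.datapipe import (IMAGENET_MEAN, IMAGENET_STD, AugmentationConfig,
                                     SyntheticSpec, augment, cutmix, denormalize, normalize,
                                     read_medmnist, resize, synth_generate, synth_train_test,
                                     write_medmnist)


def identity_aug(**overrides):
    base = dict(hflip_prob=0, translate_frac=0, perspective_prob=0, brightness=0,
                contrast=0, saturation=0, hue=0, blur_prob=0, erase_prob=0)
    base.update(overrides)
    return AugmentationConfig(**base)


class TestReaders:
    def test_grayscale_replicated_and_labels_flattened(self, tmp_path):
        images = np.arange(3 * 5 * 5, dtype=np.uint8).reshape(3, 5, 5)
        labels = np.array([[0], [1], [2]])
        np.savez(tmp_path / "d.npz", train_images=images, train_labels=labels,
                 val_images=images[:1], val_labels=labels[:1],
                 test_images=images, test_labels=labels)
        out_images, out_labels = read_medmnist(tmp_path / "d.npz", "train")
        assert out_images.shape == (3, 5, 5, 3)
        np.testing.assert_array_equal(out_images[..., 0], out_images[..., 2])
        assert out_labels.shape == (3,)
        np.testing.assert_array_equal(out_labels, [0, 1, 2])

    def test_split_sizes_and_missing_key(self, tmp_path):
        images = np.zeros((7, 4, 4, 3), dtype=np.uint8)
        np.savez(tmp_path / "d.npz", test_images=images, test_labels=np.zeros((7, 1)))
        imgs, labs = read_medmnist(tmp_path / "d.npz", "test")
        assert len(imgs) == len(labs) == 7
        with pytest.raises(KeyError, match="train_images"):
            read_medmnist(tmp_path / "d.npz", "train")
        with pytest.raises(ValueError):
            read_medmnist(tmp_path / "d.npz", "bogus")

    def test_archive_roundtrip(self, tmp_path):
        spec = SyntheticSpec(num_classes=3, samples_per_class=4, image_size=8, seed=3)
        images, labels = synth_generate(spec)
        write_medmnist(tmp_path / "s.npz", {"train": (images, labels),
                                            "val": (images[:2], labels[:2]),
                                            "test": (images[:3], labels[:3])})
        back_images, back_labels = read_medmnist(tmp_path / "s.npz", "train")
        np.testing.assert_array_equal(back_images, images)
        np.testing.assert_array_equal(back_labels, labels)


class TestNormalize:
    def test_channel_means_map_to_zero(self):
        pixel = np.broadcast_to(IMAGENET_MEAN, (1, 2, 2, 3)).astype(np.float32)
        np.testing.assert_allclose(normalize(pixel), 0.0, atol=1e-6)

    def test_unit_pixel_arithmetic(self):
        out = normalize(np.ones((1, 1, 1, 3), dtype=np.float32))
        expected = (1.0 - IMAGENET_MEAN) / IMAGENET_STD
        np.testing.assert_allclose(out[0, :, 0, 0], expected, atol=1e-6)

    def test_uint8_roundtrip_through_denormalize(self, rng):
        raw = rng.integers(0, 256, (2, 6, 6, 3), dtype=np.uint8)
        back = denormalize(normalize(raw))
        np.testing.assert_allclose(back, raw.astype(np.float32) / 255.0, atol=1e-5)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError):
            normalize(np.zeros((1, 4, 4, 1)))


class TestResize:
    def test_identity_when_size_matches(self, rng):
        imgs = rng.random((2, 32, 32, 3)).astype(np.float32)
        np.testing.assert_array_equal(resize(imgs, 32), imgs)

    def test_upscale_shape_and_constant_preserved(self):
        imgs = np.full((1, 28, 28, 3), 0.37, dtype=np.float32)
        out = resize(imgs, 224)
        assert out.shape == (1, 224, 224, 3)
        np.testing.assert_allclose(out, 0.37, atol=1e-6)


class TestAugment:
    def test_disabled_stack_is_identity(self, rng):
        img = rng.random((16, 16, 3)).astype(np.float32)
        out = augment(img, identity_aug(), np.random.default_rng(0))
        np.testing.assert_allclose(out, img, atol=1e-6)

    def test_same_seed_same_output(self, rng):
        img = rng.random((16, 16, 3)).astype(np.float32)
        cfg = AugmentationConfig()
        a = augment(img, cfg, np.random.default_rng(7))
        b = augment(img, cfg, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_erase_modifies_exactly_one_rectangle(self, rng):
        img = rng.random((32, 32, 3)).astype(np.float32)
        cfg = identity_aug(erase_prob=1.0)
        out = augment(img, cfg, np.random.default_rng(3))
        diff = np.any(out != img, axis=-1)
        rows = np.where(diff.any(axis=1))[0]
        cols = np.where(diff.any(axis=0))[0]
        assert diff.sum() > 0
        # the changed pixels exactly tile one bounding rectangle
        assert diff.sum() == len(rows) * len(cols)
        assert np.array_equal(rows, np.arange(rows[0], rows[-1] + 1))
        assert np.array_equal(cols, np.arange(cols[0], cols[-1] + 1))
        area_frac = diff.sum() / (32 * 32)
        assert cfg.erase_area[0] * 0.5 <= area_frac <= cfg.erase_area[1] * 2.0


class TestCutMix:
    def setup_method(self):
        self.cfg = AugmentationConfig(cutmix_prob=1.0, mode="cutmix")

    def test_lam_one_returns_batch_unchanged(self, rng):
        imgs = rng.random((4, 3, 16, 16)).astype(np.float32)
        labels = np.arange(4)
        mixed, la, lb, lam = cutmix(imgs, labels, self.cfg, np.random.default_rng(0), lam=1.0)
        assert lam == 1.0
        np.testing.assert_array_equal(mixed, imgs)
        np.testing.assert_array_equal(la, labels)

    def test_forced_lam_replaces_expected_pixel_count(self):
        # lam = 0.75 on 32x32: box sqrt(0.25)*32 = 16 per side -> 256 pixels.
        # seed chosen such that the box lands fully interior.
        rng_mix = np.random.default_rng(6)
        imgs = np.zeros((2, 3, 32, 32), dtype=np.float32)
        imgs[1] = 1.0
        mixed, la, lb, lam = cutmix(imgs, np.array([0, 1]), self.cfg, rng_mix, lam=0.75)
        assert not np.array_equal(la, lb), "partner permutation must differ"
        changed = int((mixed != imgs).any(axis=1).sum(axis=(-2, -1)).max())
        assert changed == 256
        np.testing.assert_allclose(lam, 0.75)

    def test_lam_consistent_with_replaced_area(self):
        imgs = np.zeros((2, 3, 32, 32), dtype=np.float32)
        imgs[1] = 1.0
        evaluated = 0
        for seed in range(12):
            mixed, la, lb, lam = cutmix(imgs, np.array([0, 1]), self.cfg,
                                        np.random.default_rng(seed))
            if np.array_equal(la, lb):
                continue  # partner permutation was the identity; nothing pasted
            evaluated += 1
            diff_area = int((mixed[0] != imgs[0]).any(axis=0).sum())
            assert diff_area == pytest.approx((1 - lam) * 32 * 32, abs=1e-6)
        assert evaluated >= 3

    def test_label_weights_sum_to_one(self, rng):
        imgs = rng.random((4, 3, 8, 8)).astype(np.float32)
        _, _, _, lam = cutmix(imgs, np.arange(4), self.cfg, np.random.default_rng(1))
        assert 0.0 <= lam <= 1.0  # weights lam and 1-lam are convex by construction

    def test_single_image_batch_passthrough(self, rng):
        imgs = rng.random((1, 3, 8, 8)).astype(np.float32)
        mixed, la, lb, lam = cutmix(imgs, np.array([2]), self.cfg, np.random.default_rng(0))
        assert lam == 1.0
        np.testing.assert_array_equal(mixed, imgs)


class TestSyntheticGenerator:
    def test_seed_determinism(self):
        spec = SyntheticSpec(num_classes=4, samples_per_class=5, image_size=16, seed=11)
        a_images, a_labels = synth_generate(spec)
        b_images, b_labels = synth_generate(spec)
        np.testing.assert_array_equal(a_images, b_images)
        np.testing.assert_array_equal(a_labels, b_labels)

    def test_balanced_labels_and_count(self):
        spec = SyntheticSpec(num_classes=4, samples_per_class=50, image_size=16, seed=0)
        images, labels = synth_generate(spec)
        assert images.shape == (200, 16, 16, 3)
        np.testing.assert_array_equal(np.bincount(labels), [50, 50, 50, 50])

    def test_grating_frequency_separates_classes_spectrally(self):
        """With no noise and classes differing only in grating frequency, the
        high-frequency band energy (2-D FFT annulus) classifies perfectly."""
        spec = SyntheticSpec(
            num_classes=2, samples_per_class=20, image_size=32, noise_sigma=0.0,
            blob_positions=((0.5, 0.5), (0.5, 0.5)), blob_radii=(0.2, 0.2),
            grating_freqs=(4, 10), grating_orients=(0.3, 0.3), seed=5)
        images, labels = synth_generate(spec)
        gray = images[..., 0].astype(np.float64) / 255.0
        S = spec.image_size
        fy = np.fft.fftfreq(S)[:, None]
        fx = np.fft.fftfreq(S)[None, :]
        radius = np.sqrt(fy ** 2 + fx ** 2) * S
        band = (radius > 7) & (radius < 13)       # around the 10-cycle grating
        energy = np.array([np.abs(np.fft.fft2(g))[band].sum() for g in gray])
        threshold = (energy[labels == 0].max() + energy[labels == 1].min()) / 2
        predicted = (energy > threshold).astype(int)
        np.testing.assert_array_equal(predicted, labels)

    def test_train_test_split_sizes(self):
        spec = SyntheticSpec(num_classes=4, samples_per_class=75, image_size=16, seed=1)
        (tr_x, tr_y), (te_x, te_y) = synth_train_test(spec, test_fraction=1 / 3)
        assert len(tr_y) == 200 and len(te_y) == 100
        np.testing.assert_array_equal(np.bincount(tr_y), [50] * 4)
        np.testing.assert_array_equal(np.bincount(te_y), [25] * 4)

    def test_duplicate_class_parameters_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            SyntheticSpec(num_classes=2, blob_positions=((0.5, 0.5), (0.5, 0.5)),
                          blob_radii=(0.2, 0.2), grating_freqs=(5, 5),
                          grating_orients=(0.0, 0.0))


def test_probability_validation():
    with pytest.raises(ValueError):
        AugmentationConfig(hflip_prob=1.5)
    with pytest.raises(ValueError):
        AugmentationConfig(mode="sometimes")
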