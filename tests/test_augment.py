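"""The five augmentation operators and the 150-per-image scheme."""

import numpy as np
import pytest

from msnet import errors
from msnet.augment import (
    AugmentConfig,
    add_noise,
    augment_image,
    augment_training_set,
    gamma_correct,
    rescale,
    rotate,
    translate,
)
from msnet.preprocess import HC, MS, assemble_dataset


class TestOperators:
    def test_rotate_identity_and_shape(self, gradient_image):
        np.testing.assert_array_equal(rotate(gradient_image, 0.0), gradient_image)
        assert rotate(gradient_image, 17.0).shape == gradient_image.shape

    def test_rotate_inverse_pair_on_interior(self, gradient_image):
        back = rotate(rotate(gradient_image, 10.0), -10.0)
        inner = slice(10, -10)
        np.testing.assert_allclose(back[inner, inner], gradient_image[inner, inner],
                                   atol=0.02)

    def test_rotate_180_on_point_symmetric_image(self):
        yy, xx = np.mgrid[-15:16, -15:16]
        sym = np.exp(-(xx**2 + yy**2) / 50.0)
        np.testing.assert_allclose(rotate(sym, 180.0), sym, atol=1e-6)

    @pytest.mark.parametrize("factor", [0.7, 1.0, 1.3])
    def test_rescale_preserves_shape(self, gradient_image, factor):
        assert rescale(gradient_image, factor).shape == gradient_image.shape

    def test_rescale_identity_and_zeros(self, gradient_image):
        np.testing.assert_array_equal(rescale(gradient_image, 1.0), gradient_image)
        np.testing.assert_array_equal(rescale(np.zeros((16, 16)), 0.7), np.zeros((16, 16)))

    def test_rescale_rejects_nonpositive(self, gradient_image):
        with pytest.raises(errors.NonPositiveFactor):
            rescale(gradient_image, 0.0)

    def test_noise_variance_matches_request(self):
        # moment oracle on a mid-gray image, no clipping interference
        rng = np.random.default_rng(0)
        img = np.full((256, 256), 0.5)
        out = add_noise(img, 0.01, rng)
        assert abs((out - img).var() - 0.01) < 0.001
        assert abs((out - img).mean()) < 0.005

    def test_noise_zero_variance_and_determinism(self, gradient_image):
        np.testing.assert_array_equal(
            add_noise(gradient_image, 0.0, np.random.default_rng(1)), gradient_image
        )
        a = add_noise(gradient_image, 0.01, np.random.default_rng(5))
        b = add_noise(gradient_image, 0.01, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)
        with pytest.raises(errors.NegativeVariance):
            add_noise(gradient_image, -0.1, np.random.default_rng(0))

    def test_translate_identity_shift_and_mass(self, gradient_image):
        np.testing.assert_array_equal(translate(gradient_image, 0, 0), gradient_image)
        shifted = translate(gradient_image, 3, 0)
        back = translate(shifted, -3, 0)
        np.testing.assert_array_equal(back[:, 3:-3], gradient_image[:, 3:-3])
        assert shifted.sum() <= gradient_image.sum() + 1e-12

    def test_gamma_fixed_points_and_value(self):
        img = np.array([[0.0, 0.25], [1.0, 0.5]])
        out = gamma_correct(img, 0.5)
        assert out[0, 0] == 0.0 and out[1, 0] == 1.0
        assert out[0, 1] == pytest.approx(0.5)
        np.testing.assert_array_equal(gamma_correct(img, 1.0), img)
        with pytest.raises(errors.NonPositiveGamma):
            gamma_correct(img, 0.0)


class TestAugmentScheme:
    def test_default_grids_have_thirty_values_each(self):
        cfg = AugmentConfig()
        assert len(cfg.rotation_angles) == 30
        assert len(cfg.scale_factors) == 30
        assert len(cfg.gamma_values) == 30
        assert cfg.noise_count == cfg.translation_count == 30
        assert cfg.per_image_count == 150

    def test_identity_parameters_excluded(self):
        cfg = AugmentConfig()
        assert 0.0 not in cfg.rotation_angles
        assert 1.0 not in cfg.scale_factors
        assert 1.0 not in cfg.gamma_values

    def test_augment_image_count_shape_and_range(self, gradient_image):
        out = augment_image(gradient_image, AugmentConfig(), np.random.default_rng(0))
        assert len(out) == 150
        for _, img in out:
            assert img.shape == gradient_image.shape
            assert img.min() >= 0.0 and img.max() <= 1.0 + 1e-12

    def test_empty_config_yields_nothing(self, gradient_image):
        cfg = AugmentConfig(rotation_angles=(), scale_factors=(), noise_count=0,
                            translation_count=0, gamma_values=())
        assert augment_image(gradient_image, cfg, np.random.default_rng(0)) == []

    def test_deterministic_transforms_bit_reproducible(self, gradient_image):
        a = augment_image(gradient_image, AugmentConfig(seed=1), np.random.default_rng(3))
        b = augment_image(gradient_image, AugmentConfig(seed=1), np.random.default_rng(3))
        for (ta, ia), (tb, ib) in zip(a, b):
            assert ta == tb
            np.testing.assert_array_equal(ia, ib)

    def test_translation_draws_within_magnitude_bound(self, gradient_image):
        cfg = AugmentConfig(rotation_angles=(), scale_factors=(), noise_count=0,
                            translation_count=50, gamma_values=(), translation_max=15)
        import re

        tags = [t for t, _ in augment_image(gradient_image, cfg, np.random.default_rng(2))]
        for tag in tags:
            dx, dy = re.fullmatch(r"trans\d+:([+-]\d+)([+-]\d+)", tag).groups()
            assert abs(int(dx)) <= 15 and abs(int(dy)) <= 15


class TestTrainingSetExpansion:
    def test_151x_factor_and_label_inheritance(self, rng):
        ds = assemble_dataset([rng.random((16, 16)) for _ in range(2)],
                              [rng.random((16, 16)) for _ in range(2)])
        out = augment_training_set(ds, AugmentConfig(seed=0))
        assert len(out) == 151 * len(ds)
        assert out.class_counts() == {MS: 2 * 151, HC: 2 * 151}

    def test_derived_ids_encode_parent_and_transform(self, rng):
        ds = assemble_dataset([rng.random((8, 8))], [rng.random((8, 8))])
        cfg = AugmentConfig(rotation_angles=(10.0,), scale_factors=(), noise_count=0,
                            translation_count=0, gamma_values=())
        out = augment_training_set(ds, cfg)
        derived = sorted(out.sample_ids() - ds.sample_ids())
        assert derived == ["HC_0000|rot+10", "MS_0000|rot+10"]

    def test_empty_training_set_rejected(self):
        from msnet.preprocess import ImageDataset

        with pytest.raises(errors.EmptySource):
            augment_training_set(ImageDataset([]), AugmentConfig())
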