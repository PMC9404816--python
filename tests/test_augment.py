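"""Rotation and elastic-deformation augmentation: registration and cardinality."""

import numpy as np
import pytest
from scipy.signal import convolve2d

from tangleseg import (AugmentParams, ConfigurationError, FluorescenceImage,
                       InputError, MaskSet, augment_fold, elastic_deform_sample,
                       rotate_sample)
from tangleseg.augment import sample_displacement_field
from tangleseg.types import COMBOS


def _sample(size=16, seed=0):
    r = np.random.default_rng(seed)
    image = FluorescenceImage(r.random((size, size, 3)).astype(np.float32))
    masks = MaskSet({c: (r.random((size, size)) < 0.3).astype(np.uint8)
                     for c in COMBOS})
    return image, masks


class TestParams:
    @pytest.mark.parametrize("bad", [
        dict(rotation_angles=(45,)),
        dict(rotation_angles=()),
        dict(elastic_alpha=-1.0),
        dict(elastic_sigma=0.0),
    ])
    def test_invalid_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            AugmentParams(**bad)


class TestRotation:
    def test_four_quarter_turns_identity(self):
        image, masks = _sample()
        im, ms = image, masks
        for _ in range(4):
            im, ms = rotate_sample(im, ms, 90)
        np.testing.assert_array_equal(im.data, image.data)
        for c in COMBOS:
            np.testing.assert_array_equal(ms[c], masks[c])

    def test_two_half_turns_identity(self):
        image, masks = _sample(seed=1)
        im, ms = rotate_sample(*rotate_sample(image, masks, 180), 180)
        np.testing.assert_array_equal(im.data, image.data)

    def test_90_degree_index_permutation_oracle(self):
        # Independent oracle: pixel (r, c) of an SxS raster rotated 90 deg
        # counterclockwise lands at (S-1-c, r).
        S = 4
        labels = np.arange(S * S, dtype=np.float32).reshape(S, S)
        image = FluorescenceImage(np.stack([labels] * 3, axis=2) / (S * S))
        masks = MaskSet({c: np.zeros((S, S), np.uint8) for c in COMBOS})
        rot, _ = rotate_sample(image, masks, 90)
        expected = np.zeros_like(labels)
        for r in range(S):
            for c in range(S):
                expected[S - 1 - c, r] = labels[r, c]
        np.testing.assert_array_equal(rot.data[:, :, 0] * (S * S), expected)

    def test_masks_follow_image_rotation(self):
        image, masks = _sample(seed=2)
        rot_im, rot_ms = rotate_sample(image, masks, 270)
        for c in COMBOS:
            np.testing.assert_array_equal(rot_ms[c], np.rot90(masks[c], k=3))
        assert set(np.unique(rot_ms["RG"])) <= {0, 1}

    def test_non_right_angle_rejected(self):
        image, masks = _sample()
        with pytest.raises(InputError):
            rotate_sample(image, masks, 45)


class TestElastic:
    def test_zero_alpha_identity(self):
        image, masks = _sample(seed=3)
        params = AugmentParams(elastic_alpha=0.0, elastic_sigma=4.0)
        im, ms = elastic_deform_sample(image, masks, params,
                                       np.random.default_rng(0))
        np.testing.assert_allclose(im.data, image.data, atol=1e-6)
        for c in COMBOS:
            np.testing.assert_array_equal(ms[c], masks[c])

    def test_masks_stay_binary(self):
        image, masks = _sample(seed=4, size=32)
        params = AugmentParams(elastic_alpha=34.0, elastic_sigma=4.0)
        _, ms = elastic_deform_sample(image, masks, params,
                                      np.random.default_rng(1))
        for c in COMBOS:
            assert set(np.unique(ms[c])) <= {0, 1}

    def test_displacement_field_matches_direct_convolution(self):
        # Oracle: smooth the same uniform noise with an explicitly constructed
        # truncated Gaussian kernel and scale by alpha.
        params = AugmentParams(elastic_alpha=34.0, elastic_sigma=4.0, rng_seed=5)
        shape = (64, 64)
        d_row, d_col = sample_displacement_field(
            shape, params, np.random.default_rng(99))
        noise_rng = np.random.default_rng(99)
        noise_row = noise_rng.uniform(-1, 1, size=shape)
        radius = int(4 * params.elastic_sigma + 0.5)
        ax = np.arange(-radius, radius + 1)
        g1 = np.exp(-ax**2 / (2 * params.elastic_sigma**2))
        g1 /= g1.sum()
        kernel = np.outer(g1, g1)
        # scipy's "reflect" boundary duplicates the edge sample (numpy "symmetric")
        padded = np.pad(noise_row, radius, mode="symmetric")
        expected = convolve2d(padded, kernel, mode="valid") * params.elastic_alpha
        np.testing.assert_allclose(d_row, expected, atol=1e-8)

    def test_same_field_applied_to_image_and_masks(self):
        # A mask that thresholds a smooth image structure must still threshold
        # it after warping, since image and masks share one displacement field.
        size = 48
        rr, cc = np.mgrid[0:size, 0:size]
        disc = np.clip(1.2 - np.hypot(rr - 24, cc - 24) / 12, 0, 1)
        image = FluorescenceImage(
            np.stack([disc] * 3, axis=2).astype(np.float32))
        ch = (disc > 0.5).astype(np.uint8)
        masks = MaskSet({c: ch.copy() for c in COMBOS})
        params = AugmentParams(elastic_alpha=10.0, elastic_sigma=3.0)
        im, ms = elastic_deform_sample(image, masks, params,
                                       np.random.default_rng(2))
        # all four masks experienced the identical field
        for c in COMBOS:
            np.testing.assert_array_equal(ms[c], ms["RG"])
        # nearest-neighbour mask warp agrees with the re-thresholded bilinear
        # image warp except on the one-pixel interpolation boundary
        warped_thresh = (im.data[:, :, 0] > 0.5).astype(np.uint8)
        disagreement = int(np.sum(warped_thresh != ms["RG"]))
        assert disagreement <= ch.sum() * 0.2
        assert ms["RG"].sum() > 0  # structure survived the warp


class TestAugmentFold:
    def test_cardinality_quadruples(self):
        fold = [_sample(seed=s) for s in range(3)]
        out = augment_fold(fold, AugmentParams(rng_seed=0))
        assert len(out) == 12

    def test_single_sample_distinct_chains(self):
        out = augment_fold([_sample(seed=7)], AugmentParams(rng_seed=0))
        assert len(out) == 4
        chains = {o.transform_chain for o in out}
        assert len(chains) == 4
        assert ("identity",) in chains

    def test_shapes_preserved_and_provenance(self):
        fold = [_sample(seed=s, size=16) for s in range(2)]
        out = augment_fold(fold, AugmentParams(rng_seed=1))
        for s in out:
            assert s.image.data.shape == (16, 16, 3)
            assert s.source_index in (0, 1)

    def test_determinism(self):
        fold = [_sample(seed=s) for s in range(2)]
        out1 = augment_fold(fold, AugmentParams(rng_seed=5))
        out2 = augment_fold(fold, AugmentParams(rng_seed=5))
        for a, b in zip(out1, out2):
            np.testing.assert_array_equal(a.image.data, b.image.data)
            assert a.transform_chain == b.transform_chain

    def test_empty_fold_rejected(self):
        with pytest.raises(InputError):
            augment_fold([], AugmentParams())
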