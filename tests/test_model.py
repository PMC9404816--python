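"""Architecture contract of the semi-Siamese U-Net and its plain-U-Net reduction."""

import numpy as np
import pytest

from tangleseg import (ConfigurationError, InputError, ModelConfig,
                       build_model, count_parameters, decoder_parameters,
                       predict)
from tangleseg.types import COMBOS, FluorescenceImage


def conv_params(k, c_in, c_out):
    """Closed-form parameter count of one conv layer: k^2*c_in*c_out + c_out."""
    return k * k * c_in * c_out + c_out


def schedule_param_sum(cfg: ModelConfig) -> int:
    """Independent hand-enumerated sum over the layer schedule."""
    k = cfg.kernel_size
    total = 0
    c_in = cfg.input_channels
    filters = [cfg.base_filters * 2 ** (lvl - 1) for lvl in range(1, cfg.depth + 1)]
    for f in filters:
        total += conv_params(k, c_in, f) + conv_params(k, f, f)
        c_in = f
    for _ in range(cfg.n_outputs):
        c_prev = filters[-1]
        for f in reversed(filters[:-1]):
            total += conv_params(k, c_prev + f, f) + conv_params(k, f, f)
            c_prev = f
        total += conv_params(1, c_prev, 1)  # 1x1 sigmoid head
    return total


class TestConfig:
    def test_default_channel_schedule(self):
        cfg = ModelConfig()
        assert [cfg.filters_at(l) for l in range(1, 6)] == [16, 32, 64, 128, 256]

    def test_indivisible_input_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(input_size=250)

    @pytest.mark.parametrize("bad", [
        dict(dropout_rate=1.0), dict(threshold=0.0), dict(threshold=1.0),
        dict(n_outputs=0), dict(depth=1), dict(upsample_mode="bilinear"),
        dict(init_scheme="orthogonal"),
    ])
    def test_invalid_fields_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            ModelConfig(**bad)


class TestArchitecture:
    def test_default_maps_rgb256_to_four_masks(self):
        net = build_model(ModelConfig(), init_seed=0)
        x = np.random.default_rng(0).random((1, 256, 256, 3), dtype=np.float32)
        outs = net.forward(x)
        assert len(outs) == 4
        for p in outs:
            assert p.shape == (1, 256, 256)
            assert p.min() >= 0.0 and p.max() <= 1.0

    def test_bottleneck_width_256(self):
        net = build_model(ModelConfig(), init_seed=0)
        assert net.encoder[-1]["conv2"].c_out == 256

    def test_param_count_matches_layer_schedule_sum(self):
        cfg = ModelConfig()
        net = build_model(cfg, init_seed=0)
        assert count_parameters(net) == schedule_param_sum(cfg)

    def test_param_count_small_configs(self, tiny_model_config):
        net = build_model(tiny_model_config, init_seed=1)
        assert count_parameters(net) == schedule_param_sum(tiny_model_config)

    def test_four_decoders_cost_exactly_three_extra(self, tiny_model_config):
        import dataclasses
        cfg4 = tiny_model_config
        cfg1 = dataclasses.replace(cfg4, n_outputs=1)
        net4 = build_model(cfg4, init_seed=0)
        net1 = build_model(cfg1, init_seed=0)
        dec1 = decoder_parameters(net1, 0)
        assert count_parameters(net4) - count_parameters(net1) == 3 * dec1
        for d in range(4):
            assert decoder_parameters(net4, d) == dec1

    def test_doubling_base_filters_increases_params(self, tiny_model_config):
        import dataclasses
        small = build_model(tiny_model_config, init_seed=0)
        big = build_model(dataclasses.replace(tiny_model_config, base_filters=4),
                          init_seed=0)
        assert count_parameters(big) > count_parameters(small)

    def test_single_decoder_matches_classical_unet_shapes(self):
        # Enumerated by hand from the level/filter schedule at 32 px, depth 3,
        # base 4: encoder 32^2x4 -> 16^2x8 -> bottleneck 8^2x16, decoder
        # mirrors back to 32^2x4 and a single 1-channel head.
        cfg = ModelConfig(input_size=32, base_filters=4, depth=3, n_outputs=1)
        net = build_model(cfg, init_seed=0)
        assert [s["conv2"].c_out for s in net.encoder] == [4, 8, 16]
        steps = net.decoders[0]["path"]
        assert [s["conv1"].c_in for s in steps] == [16 + 8, 8 + 4]
        assert [s["conv2"].c_out for s in steps] == [8, 4]
        assert net.decoders[0]["head"].c_in == 4
        assert net.decoders[0]["head"].c_out == 1
        out, = net.forward(np.zeros((1, 32, 32, 3), np.float32))
        assert out.shape == (1, 32, 32)

    def test_encoder_shared_decoders_independent(self, tiny_model_config):
        # Perturbing decoder k's weights changes only output k.
        net = build_model(tiny_model_config, init_seed=0)
        x = np.random.default_rng(1).random(
            (1, tiny_model_config.input_size, tiny_model_config.input_size, 3),
            dtype=np.float32)
        base = [p.copy() for p in net.forward(x)]
        net.decoders[2]["head"].b += 0.5
        after = net.forward(x)
        for k in range(4):
            if k == 2:
                assert not np.allclose(after[k], base[k])
            else:
                np.testing.assert_array_equal(after[k], base[k])

    def test_summary_mentions_every_conv(self, tiny_model_config):
        net = build_model(tiny_model_config, init_seed=0)
        text = net.summary()
        assert "enc1/conv1" in text and "dec3_head" in text
        assert str(count_parameters(net)) in text


class TestPredict:
    def test_prob_range_and_binarization(self, tiny_model_config, tiny_sample):
        image, _ = tiny_sample
        net = build_model(tiny_model_config, init_seed=0)
        result = predict(net, image)
        for c in COMBOS:
            p = result.prob_maps[c]
            assert p.min() >= 0.0 and p.max() <= 1.0
            np.testing.assert_array_equal(result[c], (p > 0.5).astype(np.uint8))

    def test_threshold_is_strict(self):
        from tangleseg.types import SegmentationResult
        flat = np.full((4, 4), 0.5)
        res = SegmentationResult.from_probabilities([flat] * 4, threshold=0.5)
        for c in COMBOS:
            assert res[c].sum() == 0

    def test_binarization_idempotent(self, rng):
        p = rng.random((8, 8))
        b1 = (p > 0.5).astype(np.uint8)
        b2 = (b1.astype(float) > 0.5).astype(np.uint8)
        np.testing.assert_array_equal(b1, b2)

    def test_shape_mismatch_reported(self, tiny_model_config):
        net = build_model(tiny_model_config, init_seed=0)
        wrong = FluorescenceImage(np.zeros((8, 8, 3), np.float32))
        with pytest.raises(InputError, match="16"):
            predict(net, wrong)

    def test_inference_is_deterministic_dropout_off(self, tiny_model_config, tiny_sample):
        image, _ = tiny_sample
        net = build_model(tiny_model_config, init_seed=0)
        r1 = predict(net, image)
        r2 = predict(net, image)
        for c in COMBOS:
            np.testing.assert_array_equal(r1.prob_maps[c], r2.prob_maps[c])


class TestPersistence:
    def test_weight_roundtrip(self, tiny_model_config, tmp_path):
        net = build_model(tiny_model_config, init_seed=5)
        path = tmp_path / "w.npz"
        net.save_weights(path)
        other = build_model(tiny_model_config, init_seed=99)
        other.load_weights(path)
        for (_, a), (_, b) in zip(net.named_convs(), other.named_convs()):
            np.testing.assert_array_equal(a.W, b.W)
            np.testing.assert_array_equal(a.b, b.b)

    def test_same_seed_same_weights(self, tiny_model_config):
        a = build_model(tiny_model_config, init_seed=3)
        b = build_model(tiny_model_config, init_seed=3)
        for (_, la), (_, lb) in zip(a.named_convs(), b.named_convs()):
            np.testing.assert_array_equal(la.W, lb.W)

    def test_uniform_pm1_option(self, tiny_model_config):
        import dataclasses
        cfg = dataclasses.replace(tiny_model_config, init_scheme="uniform_pm1")
        net = build_model(cfg, init_seed=0)
        w = net.encoder[0]["conv1"].W
        assert w.min() < -0.5 and w.max() > 0.5  # fills the [-1, 1] range
        glorot = build_model(tiny_model_config, init_seed=0)
        assert np.abs(glorot.encoder[0]["conv1"].W).max() < 0.7
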