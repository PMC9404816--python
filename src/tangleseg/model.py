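"""The extended semi-Siamese U-Net: one shared encoder, several independent decoders.

The encoder is a classical U-Net contracting path (two same-padded 5x5
convolutions per level, 2x2 max-pooling and dropout between levels, channel
widths doubling from ``base_filters`` up to the bottleneck).  Instead of a
single expanding path, the network carries ``n_outputs`` parallel decoders:
each one nearest-upsamples, concatenates its own copy of the matching encoder
feature map, applies two convolutions and dropout, and ends in a 1x1 sigmoid
convolution producing one probability map.  The decoders share no weights with
one another; with ``n_outputs=1`` the builder reduces to a plain U-Net with the
same hyperparameters.

Each decoder output segments one channel combination (RG, RB, GB, RGB in
canonical order), so one forward pass yields the four colocalization masks
simultaneously from a single learned representation of the tangle.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError, InputError
from .types import COMBOS, FluorescenceImage, SegmentationResult


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults reproduce the published configuration: 256x256 RGB input, five
    encoder levels with 16/32/64/128/256 filters, 5x5 kernels, dropout 0.2,
    nearest upsampling, sigmoid heads thresholded at 0.5.
    """

    input_size: int = 256
    input_channels: int = 3
    n_outputs: int = 4
    depth: int = 5
    base_filters: int = 16
    kernel_size: int = 5
    dropout_rate: float = 0.2
    upsample_mode: str = "nearest"
    final_activation: str = "sigmoid"
    hidden_activation: str = "relu"
    threshold: float = 0.5
    init_scheme: str = "glorot_uniform"

    def __post_init__(self):
        stride = 2 ** (self.depth - 1)
        if self.input_size % stride:
            raise ConfigurationError(
                f"input_size={self.input_size} must be divisible by 2^(depth-1)={stride}")
        if self.depth < 2:
            raise ConfigurationError(f"depth must be >= 2, got {self.depth}")
        if self.n_outputs < 1:
            raise ConfigurationError(f"n_outputs must be >= 1, got {self.n_outputs}")
        if self.base_filters < 1:
            raise ConfigurationError(f"base_filters must be >= 1, got {self.base_filters}")
        if self.input_channels < 1:
            raise ConfigurationError(f"input_channels must be >= 1, got {self.input_channels}")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ConfigurationError(
                f"kernel_size must be odd and >= 1 for same padding, got {self.kernel_size}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if not 0.0 < self.threshold < 1.0:
            raise ConfigurationError(f"threshold must be in (0, 1), got {self.threshold}")
        if self.upsample_mode != "nearest":
            raise ConfigurationError(f"upsample_mode must be 'nearest', got {self.upsample_mode!r}")
        if self.init_scheme not in nn.INITIALIZERS:
            raise ConfigurationError(f"unknown init_scheme {self.init_scheme!r}")

    def filters_at(self, level: int) -> int:
        """Channel width at encoder level ``level`` (1-based): base * 2^(level-1)."""
        return self.base_filters * 2 ** (level - 1)

    @property
    def combo_order(self) -> tuple[str, ...]:
        return COMBOS if self.n_outputs == 4 else tuple(f"out{i}" for i in range(self.n_outputs))


class SemiSiameseUNet:
    """Network instance built from a :class:`ModelConfig`.

    Weights are materialized once from ``init_seed`` so the same initial state
    can be persisted and reloaded for every cross-validation fold.
    """

    def __init__(self, config: ModelConfig, init_seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(init_seed)
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=init_seed, spawn_key=(1,)))
        k = config.kernel_size
        act = config.hidden_activation
        mk = dict(rng=rng, init=config.init_scheme, dtype=dtype)

        self.encoder = []  # per level: dict(conv1, conv2); pooling below all but last
        c_in = config.input_channels
        for level in range(1, config.depth + 1):
            f = config.filters_at(level)
            conv1 = nn.Conv2D(c_in, f, k, act, **mk)
            conv2 = nn.Conv2D(f, f, k, act, **mk)
            stage = {"name": f"enc{level}", "conv1": conv1, "conv2": conv2}
            if level < config.depth:
                stage["pool"] = nn.MaxPool2()
                stage["dropout"] = nn.Dropout(config.dropout_rate, self._dropout_rng)
            self.encoder.append(stage)
            c_in = f

        self.decoders = []
        for d in range(config.n_outputs):
            path = []
            c_prev = config.filters_at(config.depth)
            for level in range(config.depth - 1, 0, -1):
                f = config.filters_at(level)
                path.append({
                    "name": f"dec{d}_l{level}",
                    "up": nn.UpsampleNearest2(),
                    "conv1": nn.Conv2D(c_prev + f, f, k, act, **mk),
                    "conv2": nn.Conv2D(f, f, k, act, **mk),
                    "dropout": nn.Dropout(config.dropout_rate, self._dropout_rng),
                })
                c_prev = f
            head = nn.Conv2D(c_prev, 1, 1, config.final_activation, **mk)
            self.decoders.append({"path": path, "head": head})

    # ------------------------------------------------------------------ layers

    def encoder_convs(self):
        for stage in self.encoder:
            yield stage["name"] + "/conv1", stage["conv1"]
            yield stage["name"] + "/conv2", stage["conv2"]

    def decoder_convs(self, d: int):
        for step in self.decoders[d]["path"]:
            yield step["name"] + "/conv1", step["conv1"]
            yield step["name"] + "/conv2", step["conv2"]
        yield f"dec{d}_head", self.decoders[d]["head"]

    def named_convs(self):
        yield from self.encoder_convs()
        for d in range(len(self.decoders)):
            yield from self.decoder_convs(d)

    def conv_layers(self):
        return [layer for _, layer in self.named_convs()]

    # ----------------------------------------------------------------- forward

    def forward(self, x: np.ndarray, training: bool = False) -> list[np.ndarray]:
        """Map an (N, H, W, C) batch to ``n_outputs`` probability maps (N, H, W)."""
        x = np.asarray(x, dtype=self.dtype)
        skips = []
        h = x
        for stage in self.encoder:
            h = stage["conv1"].forward(h, training)
            h = stage["conv2"].forward(h, training)
            if "pool" in stage:
                skips.append(h)
                h = stage["pool"].forward(h, training)
                h = stage["dropout"].forward(h, training)
        bottleneck = h

        outputs = []
        for dec in self.decoders:
            h = bottleneck
            for step, skip in zip(dec["path"], reversed(skips)):
                h = step["up"].forward(h, training)
                h = np.concatenate([h, skip], axis=3)
                h = step["conv1"].forward(h, training)
                h = step["conv2"].forward(h, training)
                h = step["dropout"].forward(h, training)
            p = dec["head"].forward(h, training)
            outputs.append(p[..., 0])
        return outputs

    def backward(self, d_logits: list[np.ndarray]) -> None:
        """Backpropagate per-output gradients w.r.t. the head pre-activations.

        ``d_logits[k]`` is dL/dz for decoder ``k``'s 1x1 head (the sigmoid+BCE
        gradient ``p - y`` scaled by the averaging constant).  Skip-connection
        gradients from every decoder are accumulated before the shared encoder
        is traversed once.
        """
        cfg = self.config
        n_skip = cfg.depth - 1
        skip_grads = [None] * n_skip
        d_bottleneck = None
        for dec, dl in zip(self.decoders, d_logits):
            g = dec["head"].backward(dl[..., None], from_logits=True)
            for i, step in enumerate(reversed(dec["path"])):
                level = i + 1  # encoder level this step concatenated
                g = step["dropout"].backward(g)
                g = step["conv2"].backward(g)
                g = step["conv1"].backward(g)
                c_skip = cfg.filters_at(level)
                g, g_skip = g[..., :-c_skip], g[..., -c_skip:]
                idx = level - 1
                skip_grads[idx] = g_skip if skip_grads[idx] is None else skip_grads[idx] + g_skip
                g = step["up"].backward(g)
            d_bottleneck = g if d_bottleneck is None else d_bottleneck + g

        g = d_bottleneck
        for idx in range(len(self.encoder) - 1, -1, -1):
            stage = self.encoder[idx]
            if "pool" in stage:
                g = stage["dropout"].backward(g)
                g = stage["pool"].backward(g)
                g = g + skip_grads[idx]
            g = stage["conv2"].backward(g)
            g = stage["conv1"].backward(g)

    # ------------------------------------------------------------ persistence

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in self.named_convs():
            out[name + "/W"] = layer.W.copy()
            out[name + "/b"] = layer.b.copy()
        return out

    def load_state_dict(self, state: dict) -> None:
        for name, layer in self.named_convs():
            W, b = state[name + "/W"], state[name + "/b"]
            if W.shape != layer.W.shape:
                raise InputError(f"shape mismatch for {name}: {W.shape} vs {layer.W.shape}")
            layer.W = np.asarray(W, dtype=self.dtype).copy()
            layer.b = np.asarray(b, dtype=self.dtype).copy()

    def save_weights(self, path) -> None:
        np.savez(path, **{k.replace("/", "__"): v for k, v in self.state_dict().items()})

    def load_weights(self, path) -> None:
        with np.load(path) as z:
            self.load_state_dict({k.replace("__", "/"): z[k] for k in z.files})

    # --------------------------------------------------------------- reporting

    def summary(self) -> str:
        """Plain-text architecture summary: layer name, output shape, parameters."""
        cfg = self.config
        buf = io.StringIO()
        size = cfg.input_size
        print(f"{'layer':<18}{'output shape':<26}{'params':>10}", file=buf)
        for level, stage in enumerate(self.encoder, start=1):
            f = cfg.filters_at(level)
            for key in ("conv1", "conv2"):
                print(f"{stage['name'] + '/' + key:<18}"
                      f"{str((size, size, f)):<26}{stage[key].n_params:>10}", file=buf)
            if "pool" in stage:
                size //= 2
                print(f"{stage['name'] + '/pool':<18}{str((size, size, f)):<26}{0:>10}", file=buf)
        for d, dec in enumerate(self.decoders):
            dsize = size
            for step in dec["path"]:
                dsize *= 2
                f = step["conv2"].c_out
                for key in ("conv1", "conv2"):
                    print(f"{step['name'] + '/' + key:<18}"
                          f"{str((dsize, dsize, f)):<26}{step[key].n_params:>10}", file=buf)
            head = dec["head"]
            print(f"{f'dec{d}_head':<18}{str((dsize, dsize, 1)):<26}{head.n_params:>10}", file=buf)
        print(f"total trainable parameters: {count_parameters(self)}", file=buf)
        return buf.getvalue()


def build_model(config: ModelConfig, init_seed: int = 0, dtype=np.float32) -> SemiSiameseUNet:
    """Construct a network from ``config`` with weights drawn from ``init_seed``."""
    return SemiSiameseUNet(config, init_seed=init_seed, dtype=dtype)


def count_parameters(network: SemiSiameseUNet) -> int:
    """Total trainable scalar parameter count (weights + biases)."""
    return sum(layer.n_params for layer in network.conv_layers())


def decoder_parameters(network: SemiSiameseUNet, d: int = 0) -> int:
    """Parameter count of one decoding path including its segmentation head."""
    return sum(layer.n_params for _, layer in network.decoder_convs(d))


def predict(network: SemiSiameseUNet, image: FluorescenceImage | np.ndarray,
            config: ModelConfig | None = None) -> SegmentationResult:
    """Run inference on one image and threshold the probability maps.

    Dropout is inactive; binarization uses a strict ``>`` comparison so pixels
    exactly at the threshold are excluded from the segmentation.
    """
    cfg = config or network.config
    data = image.data if isinstance(image, FluorescenceImage) else np.asarray(image)
    expected = (cfg.input_size, cfg.input_size, cfg.input_channels)
    if data.shape != expected:
        raise InputError(f"expected image of shape {expected}, received {data.shape}")
    if data.min() < 0 or data.max() > 1:
        raise InputError("image intensities must lie in [0, 1]")
    probs = network.forward(data[None], training=False)
    probs = [p[0] for p in probs]
    return SegmentationResult.from_probabilities(probs, cfg.threshold, cfg.combo_order)
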