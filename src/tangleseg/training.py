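"""Training protocol: 5-fold cross-validation with shared initial weights.

The experimental design keeps every fold comparable: the network weights are
materialized once from ``init_seed``, persisted, and reloaded at the start of
every fold, so differences between folds come only from the data split.  Each
fold's training set is (optionally) quadrupled by the augmentation stage,
shuffled per epoch, and optimized with Adam on the pixel-mean binary
cross-entropy averaged over the four outputs; probabilities are epsilon-
clipped before the logarithm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .augment import AugmentParams, AugmentedSample, augment_fold
from .errors import ConfigurationError, InputError, TangleSegError
from .metrics import MetricRecord, MetricsTable, aggregate, evaluate_sample
from .model import ModelConfig, SemiSiameseUNet, build_model, predict
from .nn import Adam
from .types import COMBOS, FluorescenceImage, MaskSet

logger = logging.getLogger("tangleseg")

BCE_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    """Optimization and cross-validation settings.

    Defaults follow the published protocol: 5 folds (80/20), Adam with
    learning rate 5e-4, 50 epochs, mini-batches of 4, inputs resized to 256.
    """

    k_folds: int = 5
    train_fraction: float = 0.8
    learning_rate: float = 5e-4
    epochs: int = 50
    batch_size: int = 4
    loss: str = "bce"
    optimizer: str = "adam"
    split_seed: int = 0
    init_seed: int = 0
    shuffle_seed: int = 0
    resize_to: int = 256

    def __post_init__(self):
        if self.k_folds < 2:
            raise ConfigurationError(f"k_folds must be >= 2, got {self.k_folds}")
        if self.learning_rate < 0:
            raise ConfigurationError(f"learning_rate must be >= 0, got {self.learning_rate}")
        if self.epochs < 1:
            raise ConfigurationError(f"epochs must be >= 1, got {self.epochs}")
        if self.batch_size < 1:
            raise ConfigurationError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.loss != "bce":
            raise ConfigurationError(f"loss must be 'bce', got {self.loss!r}")
        if self.optimizer != "adam":
            raise ConfigurationError(f"optimizer must be 'adam', got {self.optimizer!r}")


@dataclass
class FoldResult:
    """Outcome of one cross-validation fold."""

    fold_index: int
    weights_path: str | None
    loss_history: list[float]
    val_records: list[MetricRecord]


def kfold_split(n_items: int, config: TrainConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic k-fold partition: disjoint validation sets covering all items.

    Validation sizes differ by at most one when k does not divide n (97 items
    over 5 folds gives validation sizes 20/20/19/19/19, i.e. training sets of
    77 or 78).  Indices within each side are sorted.
    """
    k = config.k_folds
    if n_items < k:
        raise ConfigurationError(f"need n_items >= k_folds, got {n_items} < {k}")
    rng = np.random.default_rng(config.split_seed)
    perm = rng.permutation(n_items)
    chunks = np.array_split(perm, k)
    splits = []
    for i, chunk in enumerate(chunks):
        val = np.sort(chunk)
        train = np.sort(np.concatenate([c for j, c in enumerate(chunks) if j != i]))
        splits.append((train, val))
    return splits


def _truth_stack(masks: MaskSet, combo_order) -> np.ndarray:
    return np.stack([masks[c] for c in combo_order]).astype(np.float64)


def bce_loss(prediction, truth) -> float:
    """Pixel-mean binary cross-entropy, averaged over the output masks.

    ``prediction``: list/array of probability maps; ``truth``: a MaskSet or an
    aligned array of binary masks.  Probabilities are clipped to
    [eps, 1 - eps] with eps = 1e-7 before the logarithm.
    """
    if isinstance(truth, MaskSet):
        truth = _truth_stack(truth, COMBOS)
    pred = np.asarray(prediction, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise InputError(f"prediction shape {pred.shape} != truth shape {truth.shape}")
    p = np.clip(pred, BCE_EPS, 1.0 - BCE_EPS)
    per_pixel = -(truth * np.log(p) + (1.0 - truth) * np.log(1.0 - p))
    # mean over pixels within each output, then over outputs
    return float(per_pixel.reshape(pred.shape[0], -1).mean(axis=1).mean())


def _as_arrays(samples) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into X (N, H, W, 3) float32 and Y (N, 4, H, W) float32."""
    xs, ys = [], []
    for s in samples:
        if isinstance(s, AugmentedSample):
            image, masks = s.image, s.masks
        else:
            image, masks = s
        xs.append(image.data.astype(np.float32))
        ys.append(masks.stack().astype(np.float32))
    return np.stack(xs), np.stack(ys)


def train_network(network: SemiSiameseUNet, samples, config: TrainConfig) -> list[float]:
    """Optimize in place; returns the per-epoch mean training loss history."""
    if not samples:
        raise InputError("training set is empty")
    X, Y = _as_arrays(samples)
    n = len(X)
    n_out = network.config.n_outputs
    opt = Adam(network.conv_layers(), config.learning_rate)
    shuffle_rng = np.random.default_rng(config.shuffle_seed)
    history = []
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = X[idx], Y[idx]
            probs = network.forward(xb, training=True)
            batch_loss = 0.0
            d_logits = []
            npix = yb[:, 0].size  # batch * H * W, per output
            for k in range(n_out):
                p = np.clip(probs[k].astype(np.float64), BCE_EPS, 1.0 - BCE_EPS)
                y = yb[:, k].astype(np.float64)
                batch_loss += float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())
                # d(loss)/d(logit) for sigmoid + BCE, including both averages
                d_logits.append(((probs[k] - yb[:, k]) / (npix * n_out)
                                 ).astype(network.dtype))
            batch_loss /= n_out
            if config.learning_rate > 0:
                network.backward(d_logits)
                opt.step()
            losses.append(batch_loss)
        history.append(float(np.mean(losses)))
        logger.info("epoch %d/%d mean loss %.5f", epoch + 1, config.epochs, history[-1])
    return history


def evaluate_network(network: SemiSiameseUNet, samples, image_ids=None
                     ) -> list[MetricRecord]:
    """Per-image, per-output metrics of thresholded predictions on ``samples``."""
    records = []
    for i, (image, masks) in enumerate(samples):
        image_id = (image_ids[i] if image_ids is not None
                    else image.metadata.get("image_id", f"img{i}"))
        result = predict(network, image)
        records.extend(evaluate_sample(masks, result, image_id=image_id))
    return records


def train_fold(network: SemiSiameseUNet, train_samples, val_samples,
               config: TrainConfig, fold_index: int = 0,
               weights_path=None) -> FoldResult:
    """Train one fold from the network's current (shared) initial weights."""
    history = train_network(network, train_samples, config)
    if weights_path is not None:
        network.save_weights(weights_path)
    val_records = evaluate_network(network, val_samples)
    return FoldResult(fold_index=fold_index,
                      weights_path=str(weights_path) if weights_path else None,
                      loss_history=history, val_records=val_records)


def cross_validate(dataset: list[tuple[FluorescenceImage, MaskSet]],
                   model_config: ModelConfig, train_config: TrainConfig,
                   augment_params: AugmentParams | None = None,
                   out_dir=None) -> tuple[list[FoldResult], MetricsTable]:
    """Full k-fold protocol with shared initial weights.

    Initial weights are materialized once from ``init_seed``, persisted (when
    ``out_dir`` is given), and reloaded before every fold; each fold's
    training split is expanded fourfold when ``augment_params`` is provided.
    """
    splits = kfold_split(len(dataset), train_config)
    network = build_model(model_config, init_seed=train_config.init_seed)
    init_state = network.state_dict()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        network.save_weights(out_dir / "initial_weights.npz")

    fold_results = []
    for f, (train_idx, val_idx) in enumerate(splits):
        network.load_state_dict(init_state)
        train_samples = [dataset[i] for i in train_idx]
        val_samples = [dataset[i] for i in val_idx]
        if augment_params is not None:
            train_samples = augment_fold(train_samples, augment_params)
        weights_path = (out_dir / f"fold_{f}_weights.npz") if out_dir is not None else None
        try:
            result = train_fold(network, train_samples, val_samples, train_config,
                                fold_index=f, weights_path=weights_path)
        except TangleSegError as e:
            raise type(e)(f"fold {f}: {e}") from e
        fold_results.append(result)
        logger.info("fold %d done: final loss %.5f, %d validation records",
                    f, result.loss_history[-1], len(result.val_records))

    table = aggregate([r.val_records for r in fold_results])
    return fold_results, table
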