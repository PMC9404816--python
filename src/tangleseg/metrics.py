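"""Segmentation metrics (TP, FP, Dice, IoU) and their cross-validation aggregation.

All four metrics compare a ground-truth mask GT with a segmentation result SR
as pixel sets:

    TP  = |GT ∩ SR| / |GT|                (coverage of the target region)
    FP  = (|GT ∪ SR| − |GT|) / |GT|       (= |SR \\ GT| / |GT|; may exceed 1)
    DC  = 2|GT ∩ SR| / (|GT| + |SR|)      (Dice coefficient)
    IoU = |GT ∩ SR| / |GT ∪ SR|           (Jaccard index)

TP, DC and IoU lie in [0, 1]; FP is unbounded above and is reported as-is.
DC and IoU obey DC = 2·IoU / (1 + IoU) identically.

Empty-GT handling: TP and FP are undefined when |GT| = 0 and are reported as
NaN and excluded from fold means; DC/IoU are 1.0 when both masks are empty
(perfect agreement on absence) and 0.0 when exactly one is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .types import COMBOS, MaskSet, SegmentationResult

METRIC_NAMES = ("tp", "fp", "dc", "iou")


def _counts(gt: np.ndarray, sr: np.ndarray) -> tuple[int, int, int]:
    gt = np.asarray(gt)
    sr = np.asarray(sr)
    if gt.shape != sr.shape:
        raise InputError(f"mask shapes differ: {gt.shape} vs {sr.shape}")
    gt = gt.astype(bool)
    sr = sr.astype(bool)
    inter = int(np.count_nonzero(gt & sr))
    return int(np.count_nonzero(gt)), int(np.count_nonzero(sr)), inter


def true_positive_rate(gt: np.ndarray, sr: np.ndarray) -> float:
    """|GT ∩ SR| / |GT|; NaN when GT is empty."""
    n_gt, _, inter = _counts(gt, sr)
    if n_gt == 0:
        return float("nan")
    return inter / n_gt


def false_positive_rate(gt: np.ndarray, sr: np.ndarray) -> float:
    """|SR \\ GT| / |GT|; NaN when GT is empty.  Not clipped: can exceed 1."""
    n_gt, n_sr, inter = _counts(gt, sr)
    if n_gt == 0:
        return float("nan")
    return (n_sr - inter) / n_gt


def dice(gt: np.ndarray, sr: np.ndarray) -> float:
    """2|GT ∩ SR| / (|GT| + |SR|); 1.0 when both masks are empty."""
    n_gt, n_sr, inter = _counts(gt, sr)
    if n_gt + n_sr == 0:
        return 1.0
    return 2.0 * inter / (n_gt + n_sr)


def iou(gt: np.ndarray, sr: np.ndarray) -> float:
    """|GT ∩ SR| / |GT ∪ SR|; 1.0 when both masks are empty."""
    n_gt, n_sr, inter = _counts(gt, sr)
    union = n_gt + n_sr - inter
    if union == 0:
        return 1.0
    return inter / union


@dataclass
class MetricRecord:
    """One image x one channel-combination row of the evaluation table."""

    image_id: str
    combo: str
    tp: float
    fp: float
    dc: float
    iou: float


def evaluate_sample(gt: MaskSet, sr: SegmentationResult | MaskSet,
                    image_id: str = "") -> list[MetricRecord]:
    """All four metrics for every channel combination of one image."""
    records = []
    for combo in COMBOS:
        g = gt[combo]
        s = sr[combo]
        records.append(MetricRecord(
            image_id=image_id, combo=combo,
            tp=true_positive_rate(g, s), fp=false_positive_rate(g, s),
            dc=dice(g, s), iou=iou(g, s)))
    return records


@dataclass
class MetricsTable:
    """Mean and standard deviation of each metric across fold means.

    Each fold value is the unweighted mean over that fold's records (all
    validation images x all outputs, NaN records excluded); the table reports
    the mean and the sample (n-1) standard deviation over the fold means,
    zero when there is a single fold.
    """

    mean: dict[str, float]
    std: dict[str, float]
    fold_means: pd.DataFrame  # one row per fold, one column per metric

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "std": self.std}).loc[list(METRIC_NAMES)]

    def __str__(self) -> str:
        parts = [f"{m.upper()} {self.mean[m]:.4f} ± {self.std[m]:.4f}"
                 for m in METRIC_NAMES]
        return " | ".join(parts)


def records_frame(records: list[MetricRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def aggregate(records_per_fold: list[list[MetricRecord]]) -> MetricsTable:
    """Fold-wise means, then mean ± sample std across folds."""
    if not records_per_fold or any(not fold for fold in records_per_fold):
        raise InputError("aggregate needs at least one fold with at least one record")
    fold_rows = []
    for fold in records_per_fold:
        df = records_frame(fold)
        fold_rows.append({m: float(np.nanmean(df[m].to_numpy(dtype=float)))
                          for m in METRIC_NAMES})
    fold_means = pd.DataFrame(fold_rows)
    mean = {m: float(fold_means[m].mean()) for m in METRIC_NAMES}
    if len(fold_means) > 1:
        std = {m: float(fold_means[m].std(ddof=1)) for m in METRIC_NAMES}
    else:
        std = {m: 0.0 for m in METRIC_NAMES}
    return MetricsTable(mean=mean, std=std, fold_means=fold_means)
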