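"""Fluorescence quantification: segmented-pixel fraction per channel combination.

For each channel combination the segmentation (from the trained network or
directly from ground-truth labels) is a binary mask; the quantification counts
its positive pixels and divides by the total pixel count of the raster — for
the standard 256 x 256 images the denominator is 65,536 — reported as a
percentage.  The relative magnitudes of the four percentages are what carries
biological meaning (e.g. a larger RB than RG fraction indicating a more mature
fibrillar stage), so the arithmetic is kept exact: percentage x total / 100
is always the integer pixel count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .model import ModelConfig, SemiSiameseUNet, predict
from .types import COMBOS, FluorescenceImage, MaskSet, SegmentationResult


@dataclass
class QuantReport:
    """Per-combination pixel counts and percentages for one image."""

    image_id: str
    source: str  # "model" or "ground_truth"
    total_pixels: int
    counts: dict[str, int]
    percentages: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"image_id": self.image_id, "combo": c,
                 "pixel_count": self.counts[c], "total_pixels": self.total_pixels,
                 "percent": self.percentages[c]} for c in COMBOS]
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        lines = [f"{self.image_id or 'image'} ({self.source}, {self.total_pixels} px):"]
        lines += [f"  {c:<4} {self.percentages[c]:6.2f}%  ({self.counts[c]} px)"
                  for c in COMBOS]
        return "\n".join(lines)


def quantify_mask(mask: np.ndarray) -> tuple[int, float]:
    """Positive-pixel count and percentage of the raster area.

    The denominator is the mask's own H x W (65,536 for 256 x 256), so
    non-default sizes quantify correctly.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise InputError(f"mask must be 2-D, got shape {mask.shape}")
    if not np.all(np.isin(np.unique(mask), (0, 1))):
        raise InputError("mask must be binary {0,1}")
    count = int(np.count_nonzero(mask))
    return count, 100.0 * count / mask.size


def quantify_masks(masks: MaskSet | SegmentationResult, image_id: str = "",
                   source: str = "ground_truth") -> QuantReport:
    """Quantify all four combinations of an existing mask set (no model involved)."""
    counts, percents = {}, {}
    total = None
    for combo in COMBOS:
        m = masks[combo]
        counts[combo], percents[combo] = quantify_mask(m)
        total = m.size
    return QuantReport(image_id=image_id, source=source,
                       total_pixels=total, counts=counts, percentages=percents)


def quantify_image(network: SemiSiameseUNet, image: FluorescenceImage,
                   config: ModelConfig | None = None, image_id: str = "") -> QuantReport:
    """Segment one image with the trained network, then quantify each output."""
    result = predict(network, image, config)
    report = quantify_masks(result, image_id=image_id, source="model")
    return report


def render_panel(image: FluorescenceImage, masks: MaskSet | SegmentationResult,
                 report: QuantReport, out_path) -> None:
    """Side-by-side PNG: input image plus the four masks with their percentages."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 5, figsize=(15, 3.2))
    axes[0].imshow(image.data)
    axes[0].set_title("input")
    for ax, combo in zip(axes[1:], COMBOS):
        ax.imshow(masks[combo], cmap="gray", vmin=0, vmax=1)
        ax.set_title(f"{combo}: {report.percentages[combo]:.2f}%")
    for ax in axes:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
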