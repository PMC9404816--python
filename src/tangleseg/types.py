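"""Core data containers shared across the pipeline.

The canonical channel-combination order is RG, RB, GB, RGB everywhere: masks,
network outputs, CSV reports.  Rasters are row-major with the origin at the
top-left corner and 0-based indexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

#: Canonical order of the four channel-combination tasks.
COMBOS: tuple[str, ...] = ("RG", "RB", "GB", "RGB")

#: Channel index of each acquisition color in an (H, W, 3) raster.
CHANNEL_INDEX = {"R": 0, "G": 1, "B": 2}


def combo_channels(combo: str) -> tuple[int, ...]:
    """Channel indices participating in a combination, e.g. ``"RB" -> (0, 2)``."""
    return tuple(CHANNEL_INDEX[c] for c in combo)


@dataclass
class FluorescenceImage:
    """A three-channel fluorescence raster with intensities in [0, 1].

    ``metadata`` optionally carries acquisition context (disease label,
    physical pixel size in micrometres, native resolution) and, for synthetic
    samples, the generating core geometry.
    """

    data: np.ndarray  # (H, W, 3) float32 in [0, 1]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        a = np.asarray(self.data)
        if a.ndim != 3 or a.shape[2] != 3:
            raise InputError(f"expected an (H, W, 3) raster, got shape {a.shape}")
        self.data = a

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]


def _as_binary(mask: np.ndarray, name: str = "mask") -> np.ndarray:
    a = np.asarray(mask)
    if a.ndim != 2:
        raise InputError(f"{name} must be 2-D, got shape {a.shape}")
    vals = np.unique(a)
    if not np.all(np.isin(vals, (0, 1))):
        raise InputError(f"{name} must be binary {{0,1}}, found values {vals[:5]}")
    return a.astype(np.uint8)


@dataclass
class MaskSet:
    """Four aligned binary masks, one per channel combination."""

    masks: dict[str, np.ndarray]

    def __post_init__(self):
        if set(self.masks) != set(COMBOS):
            raise InputError(f"MaskSet needs exactly the combos {COMBOS}, got {sorted(self.masks)}")
        shapes = {self.masks[c].shape for c in COMBOS}
        if len(shapes) != 1:
            raise InputError(f"mask shapes disagree: {shapes}")
        self.masks = {c: _as_binary(self.masks[c], f"mask {c}") for c in COMBOS}

    def __getitem__(self, combo: str) -> np.ndarray:
        return self.masks[combo]

    @property
    def shape(self) -> tuple[int, int]:
        return self.masks[COMBOS[0]].shape

    def stack(self) -> np.ndarray:
        """Masks stacked (4, H, W) in canonical order."""
        return np.stack([self.masks[c] for c in COMBOS])


@dataclass
class SegmentationResult:
    """Network output: per-combination probability maps and thresholded masks.

    The binary masks satisfy ``binary == (prob > threshold)`` with a strict
    inequality, so probabilities exactly at the threshold are excluded.
    """

    prob_maps: dict[str, np.ndarray]
    binary_masks: dict[str, np.ndarray]
    combo_order: tuple[str, ...]
    threshold: float

    @classmethod
    def from_probabilities(cls, probs: list[np.ndarray], threshold: float,
                           combo_order: tuple[str, ...] | None = None) -> "SegmentationResult":
        if combo_order is None:
            combo_order = COMBOS if len(probs) == 4 else tuple(
                f"out{i}" for i in range(len(probs)))
        prob_maps = {c: np.asarray(p) for c, p in zip(combo_order, probs)}
        binary = {c: (p > threshold).astype(np.uint8) for c, p in prob_maps.items()}
        return cls(prob_maps, binary, tuple(combo_order), threshold)

    def __getitem__(self, combo: str) -> np.ndarray:
        return self.binary_masks[combo]

    def as_mask_set(self) -> MaskSet:
        if set(self.combo_order) != set(COMBOS):
            raise InputError("only a four-combination result converts to a MaskSet")
        return MaskSet({c: self.binary_masks[c] for c in COMBOS})
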