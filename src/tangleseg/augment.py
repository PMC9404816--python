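"""Training-set expansion: right-angle rotation plus random elastic deformation.

Each fold is quadrupled offline before training: for every sample the expanded
set contains the original, one rotated copy (angle drawn uniformly from
{90, 180, 270} degrees), and an elastically deformed version of each of those
two.  A 78-image fold therefore yields 312 training images.

Elastic deformation samples one per-pixel displacement field — uniform noise
in [-1, 1] per axis, Gaussian-smoothed with ``elastic_sigma`` and scaled by
``elastic_alpha`` — and applies it identically to the image (bilinear
resampling) and to all four masks (nearest-neighbour, then re-binarized), so
image-mask registration is preserved.  Out-of-border lookups replicate the
edge to avoid injecting dark borders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .errors import ConfigurationError, InputError
from .types import COMBOS, FluorescenceImage, MaskSet

RIGHT_ANGLES = (90, 180, 270)


@dataclass(frozen=True)
class AugmentParams:
    """Deformation magnitude/smoothness and the random stream seed.

    alpha = 34 px and sigma = 4 px are the classic values for elastic
    distortion of small images and are deliberately strong; sigma sets the
    spatial scale of the warp and alpha its amplitude before smoothing.
    """

    rotation_angles: tuple[int, ...] = RIGHT_ANGLES
    elastic_alpha: float = 34.0
    elastic_sigma: float = 4.0
    rng_seed: int = 0

    def __post_init__(self):
        if not set(self.rotation_angles) <= set(RIGHT_ANGLES):
            raise ConfigurationError(
                f"rotation_angles must be a subset of {RIGHT_ANGLES}, got {self.rotation_angles}")
        if not self.rotation_angles:
            raise ConfigurationError("rotation_angles must be non-empty")
        if self.elastic_alpha < 0:
            raise ConfigurationError(f"elastic_alpha must be >= 0, got {self.elastic_alpha}")
        if self.elastic_sigma <= 0:
            raise ConfigurationError(f"elastic_sigma must be > 0, got {self.elastic_sigma}")


@dataclass
class AugmentedSample:
    """One training sample with its provenance (source index and transform chain)."""

    image: FluorescenceImage
    masks: MaskSet
    source_index: int
    transform_chain: tuple[str, ...]


def rotate_sample(image: FluorescenceImage, masks: MaskSet, angle: int
                  ) -> tuple[FluorescenceImage, MaskSet]:
    """Rotate image and masks counterclockwise by a right angle, losslessly.

    Right-angle rotation of a square raster is a pure index permutation: no
    interpolation, masks stay binary.
    """
    if angle not in RIGHT_ANGLES:
        raise InputError(f"angle must be one of {RIGHT_ANGLES}, got {angle}")
    k = angle // 90
    data = np.rot90(image.data, k=k, axes=(0, 1)).copy()
    new_masks = MaskSet({c: np.rot90(masks[c], k=k).copy() for c in COMBOS})
    return FluorescenceImage(data, dict(image.metadata)), new_masks


def sample_displacement_field(shape: tuple[int, int], params: AugmentParams,
                              rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw the smoothed, scaled displacement field (d_row, d_col) in pixels."""
    d_row = gaussian_filter(rng.uniform(-1, 1, size=shape), params.elastic_sigma,
                            mode="reflect") * params.elastic_alpha
    d_col = gaussian_filter(rng.uniform(-1, 1, size=shape), params.elastic_sigma,
                            mode="reflect") * params.elastic_alpha
    return d_row, d_col


def elastic_deform_sample(image: FluorescenceImage, masks: MaskSet,
                          params: AugmentParams, rng: np.random.Generator
                          ) -> tuple[FluorescenceImage, MaskSet]:
    """Warp image and masks with one shared random displacement field."""
    shape = image.shape
    d_row, d_col = sample_displacement_field(shape, params, rng)
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]].astype(np.float64)
    coords = np.stack([rows + d_row, cols + d_col])

    warped = np.empty_like(image.data, dtype=np.float64)
    for ch in range(image.data.shape[2]):
        warped[:, :, ch] = map_coordinates(image.data[:, :, ch].astype(np.float64),
                                           coords, order=1, mode="nearest")
    warped = np.clip(warped, 0.0, 1.0).astype(np.float32)

    new_masks = {}
    for combo in COMBOS:
        m = map_coordinates(masks[combo].astype(np.float64), coords,
                            order=0, mode="nearest")
        new_masks[combo] = (m > 0.5).astype(np.uint8)
    return FluorescenceImage(warped, dict(image.metadata)), MaskSet(new_masks)


def augment_fold(fold: list[tuple[FluorescenceImage, MaskSet]],
                 params: AugmentParams) -> list[AugmentedSample]:
    """Expand a fold fourfold: original, rotated, elastic(original), elastic(rotated)."""
    if not fold:
        raise InputError("cannot augment an empty fold")
    rng = np.random.default_rng(params.rng_seed)
    angles = np.asarray(sorted(params.rotation_angles))
    out = []
    for i, (image, masks) in enumerate(fold):
        angle = int(rng.choice(angles))
        rot_img, rot_masks = rotate_sample(image, masks, angle)
        el_img, el_masks = elastic_deform_sample(image, masks, params, rng)
        el_rot_img, el_rot_masks = elastic_deform_sample(rot_img, rot_masks, params, rng)
        out.append(AugmentedSample(image, masks, i, ("identity",)))
        out.append(AugmentedSample(rot_img, rot_masks, i, (f"rot{angle}",)))
        out.append(AugmentedSample(el_img, el_masks, i, ("elastic",)))
        out.append(AugmentedSample(el_rot_img, el_rot_masks, i, (f"rot{angle}", "elastic")))
    return out
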