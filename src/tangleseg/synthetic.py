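"""Synthetic three-channel fluorescence images with four-way ground-truth masks.

Real triple-label immunofluorescence images of neurofibrillary tangles are
restricted clinical material, so this module emulates their essential
structure: bright blob-like "tangle cores" whose per-channel footprints
overlap partially, sitting on a dim noisy background.  Each core is an
isotropic 2-D Gaussian intensity profile; a core is bright in a channel with a
per-channel Bernoulli probability, with independent peak-intensity jitter, so
the joint-signal geometry differs between channels.

Ground truth follows the labelling rule used for the real data: a pixel
belongs to the mask of a channel combination iff it lies inside some core
footprint and every channel of the combination exceeds the significant-
intensity threshold there.  Because masks are computed from the final
(noisy, 8-bit-quantized) image, re-thresholding a stored sample reproduces its
masks exactly, and the RGB mask is always contained in each pairwise mask.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .types import COMBOS, FluorescenceImage, MaskSet, combo_channels


@dataclass(frozen=True)
class SyntheticParams:
    """Generator settings; defaults give moderate-difficulty samples at 256 px.

    ``intensity_threshold`` is the significant-intensity cutoff (fraction of
    dynamic range) standing in for the expert judgement that defined the
    manual labels; it is deliberately a parameter, not a constant.
    """

    image_size: int = 256
    n_cores: int = 6
    core_radius_range: tuple[float, float] = (10.0, 28.0)
    channel_presence_probs: tuple[float, float, float] = (0.8, 0.8, 0.8)
    core_intensity_range: tuple[float, float] = (0.7, 1.0)
    background_noise_sigma: float = 0.05
    intensity_threshold: float = 0.5
    rng_seed: int = 0

    def __post_init__(self):
        if self.image_size < 8:
            raise ConfigurationError(f"image_size must be >= 8, got {self.image_size}")
        if self.n_cores < 0:
            raise ConfigurationError(f"n_cores must be >= 0, got {self.n_cores}")
        lo, hi = self.core_radius_range
        if not (1 <= lo <= hi):
            raise ConfigurationError(
                f"core_radius_range must satisfy 1 <= min <= max, got {self.core_radius_range}")
        for p in self.channel_presence_probs:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"channel_presence_probs must lie in [0, 1], got {self.channel_presence_probs}")
        ilo, ihi = self.core_intensity_range
        if not (0.0 <= ilo <= ihi <= 1.0):
            raise ConfigurationError(
                f"core_intensity_range must satisfy 0 <= min <= max <= 1, "
                f"got {self.core_intensity_range}")
        if self.background_noise_sigma < 0:
            raise ConfigurationError(
                f"background_noise_sigma must be >= 0, got {self.background_noise_sigma}")
        if not 0.0 < self.intensity_threshold < 1.0:
            raise ConfigurationError(
                f"intensity_threshold must be in (0, 1), got {self.intensity_threshold}")


#: Conditions used for the scaled-down learning experiments: small rasters,
#: strong core/background contrast, little noise.
EASY_CONTRAST_64 = SyntheticParams(
    image_size=64,
    n_cores=5,
    core_radius_range=(6.0, 14.0),
    channel_presence_probs=(0.85, 0.85, 0.85),
    core_intensity_range=(0.85, 1.0),
    background_noise_sigma=0.02,
)


def _sample_rng(params: SyntheticParams, index: int) -> np.random.Generator:
    # Per-sample stream: independent of n_images and stable across runs.
    return np.random.default_rng(
        np.random.SeedSequence(entropy=params.rng_seed, spawn_key=(index,)))


def generate_sample(params: SyntheticParams, index: int = 0
                    ) -> tuple[FluorescenceImage, MaskSet]:
    """Generate one image/mask-set pair; identical inputs give identical pixels.

    The returned image metadata records the core geometry (``cores`` as
    (row, col, radius) triples) and the boolean union footprint
    (``core_footprint``) so the labelling rule can be re-applied externally.
    """
    rng = _sample_rng(params, index)
    s = params.image_size
    rows, cols = np.mgrid[0:s, 0:s].astype(np.float64)

    cores = []
    channel_intensity = np.zeros((s, s, 3), dtype=np.float64)
    footprint = np.zeros((s, s), dtype=bool)
    for _ in range(params.n_cores):
        r0 = rng.uniform(0, s)
        c0 = rng.uniform(0, s)
        radius = rng.uniform(*params.core_radius_range)
        # Bright-channel draws and per-channel peak jitter.
        bright = rng.random(3) < np.asarray(params.channel_presence_probs)
        peaks = rng.uniform(*params.core_intensity_range, size=3)
        d2 = (rows - r0) ** 2 + (cols - c0) ** 2
        footprint |= d2 <= radius ** 2
        sigma = radius / 2.0  # footprint radius ~ 2 sigma of the profile
        profile = np.exp(-d2 / (2.0 * sigma ** 2))
        for ch in range(3):
            if bright[ch]:
                np.maximum(channel_intensity[:, :, ch],
                           peaks[ch] * profile,
                           out=channel_intensity[:, :, ch])
        cores.append((r0, c0, radius))

    img = channel_intensity
    if params.background_noise_sigma > 0:
        img = img + rng.normal(0.0, params.background_noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    # Snap to the 8-bit grid so in-memory pixels equal the stored PNG exactly.
    img = np.round(img * 255.0) / 255.0

    masks = compute_masks(img, footprint, params.intensity_threshold)
    image = FluorescenceImage(
        img.astype(np.float32),
        metadata={"cores": cores, "core_footprint": footprint,
                  "index": index, "seed": params.rng_seed},
    )
    return image, masks


def compute_masks(image_data: np.ndarray, footprint: np.ndarray,
                  threshold: float) -> MaskSet:
    """Apply the labelling rule: joint strict-threshold exceedance inside the footprint."""
    above = image_data > threshold  # (H, W, 3)
    masks = {}
    for combo in COMBOS:
        joint = np.logical_and.reduce([above[:, :, ch] for ch in combo_channels(combo)])
        masks[combo] = (joint & footprint).astype(np.uint8)
    return MaskSet(masks)


def generate_dataset(params: SyntheticParams, n_images: int, out_dir) -> pd.DataFrame:
    """Write ``n_images`` samples as PNGs plus a CSV manifest; returns the manifest.

    Layout: ``img_{i:04d}.png`` (8-bit RGB) and ``img_{i:04d}_mask_{combo}.png``
    (single-channel, values {0, 255}).  The manifest columns are image_path,
    mask_RG, mask_RB, mask_GB, mask_RGB, seed, index; the generating parameters
    are stored alongside in ``params.yaml`` for auditability.
    """
    from . import io as tio  # local import: io pulls imageio

    if n_images < 1:
        raise InputError(f"n_images must be >= 1, got {n_images}")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as e:
        raise OSError(f"output directory {out_dir} is not writable: {e}") from e

    rows = []
    for i in range(n_images):
        image, masks = generate_sample(params, i)
        img_name = f"img_{i:04d}.png"
        tio.write_image(out_dir / img_name, image)
        row = {"image_path": img_name}
        for combo in COMBOS:
            mask_name = f"img_{i:04d}_mask_{combo}.png"
            tio.write_mask(out_dir / mask_name, masks[combo])
            row[f"mask_{combo}"] = mask_name
        row["seed"] = params.rng_seed
        row["index"] = i
        rows.append(row)

    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    with open(out_dir / "params.yaml", "w") as fh:
        import yaml
        yaml.safe_dump(asdict(params), fh)
    return manifest


def dataset_checksum(out_dir) -> str:
    """SHA-256 over the manifest and every file it references (determinism checks)."""
    out_dir = Path(out_dir)
    h = hashlib.sha256()
    manifest = pd.read_csv(out_dir / "manifest.csv")
    h.update(manifest.to_csv(index=False).encode())
    for _, row in manifest.iterrows():
        for col in ["image_path"] + [f"mask_{c}" for c in COMBOS]:
            h.update((out_dir / row[col]).read_bytes())
    return h.hexdigest()
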