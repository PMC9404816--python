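"""Image/mask readers and writers, run configuration, dataset loading.

Conventions: rasters are row-major with the origin top-left and 0-based
indices.  Images are three-channel and scaled to [0, 1] on read; masks are
binarized at 50% of the dynamic range so lossy JPEG labels (gray values
jittered around 0 and 255) recover their original binary content.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from skimage.transform import resize as _sk_resize

from .augment import AugmentParams
from .errors import ConfigurationError, FormatError
from .model import ModelConfig
from .synthetic import SyntheticParams
from .training import TrainConfig
from .types import COMBOS, FluorescenceImage, MaskSet

logger = logging.getLogger("tangleseg")


def _dtype_max(arr: np.ndarray) -> float:
    if np.issubdtype(arr.dtype, np.integer):
        return float(np.iinfo(arr.dtype).max)
    return float(max(arr.max(), 1.0))


def read_image(path, resize_to: int | None = None) -> FluorescenceImage:
    """Read a PNG/TIFF/JPEG as a three-channel [0, 1] raster.

    Grayscale files are rejected (the pipeline needs per-channel signal); an
    alpha channel, if present, is dropped.  ``resize_to`` downsamples with
    anti-aliased bilinear interpolation (e.g. native 512 -> training 256); the
    native size is kept in ``metadata["native_size"]``.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as e:  # undecodable content
        raise OSError(f"cannot decode image file {path}: {e}") from e
    if arr.ndim == 2 or (arr.ndim == 3 and arr.shape[2] == 1):
        raise FormatError(f"{path}: grayscale input; a three-channel image is required")
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise FormatError(f"{path}: unsupported shape {arr.shape}; expected (H, W, 3)")
    arr = arr[:, :, :3]
    data = arr.astype(np.float64) / _dtype_max(arr)
    meta = {"native_size": data.shape[:2], "path": str(path)}
    if resize_to is not None and data.shape[:2] != (resize_to, resize_to):
        data = _sk_resize(data, (resize_to, resize_to), order=1,
                          anti_aliasing=True, preserve_range=True)
        data = np.clip(data, 0.0, 1.0)
    return FluorescenceImage(data.astype(np.float32), metadata=meta)


def read_mask(path, resize_to: int | None = None) -> np.ndarray:
    """Read a single-channel (or luminance-collapsed RGB) mask, binarized at mid-range."""
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as e:
        raise OSError(f"cannot decode mask file {path}: {e}") from e
    if arr.ndim == 3:
        arr = arr[:, :, :3].mean(axis=2)
    mask = (arr.astype(np.float64) > 0.5 * _dtype_max(arr)).astype(np.uint8)
    if resize_to is not None and mask.shape != (resize_to, resize_to):
        resized = _sk_resize(mask.astype(np.float64), (resize_to, resize_to),
                             order=0, anti_aliasing=False, preserve_range=True)
        mask = (resized > 0.5).astype(np.uint8)
    return mask


def write_image(path, image: FluorescenceImage | np.ndarray) -> None:
    """Write a [0, 1] three-channel raster as 8-bit RGB PNG."""
    data = image.data if isinstance(image, FluorescenceImage) else np.asarray(image)
    iio.imwrite(Path(path), np.round(np.clip(data, 0, 1) * 255).astype(np.uint8))


def write_mask(path, mask: np.ndarray) -> None:
    """Write a {0, 1} mask as single-channel 8-bit PNG with values {0, 255}."""
    iio.imwrite(Path(path), (np.asarray(mask).astype(np.uint8) * 255))


def resize_sample(image: FluorescenceImage, masks: MaskSet, size: int
                  ) -> tuple[FluorescenceImage, MaskSet]:
    """Resize an image (bilinear, anti-aliased) and its masks (nearest, re-binarized)."""
    data = _sk_resize(image.data.astype(np.float64), (size, size), order=1,
                      anti_aliasing=True, preserve_range=True)
    data = np.clip(data, 0.0, 1.0).astype(np.float32)
    new_masks = {}
    for combo in COMBOS:
        m = _sk_resize(masks[combo].astype(np.float64), (size, size), order=0,
                       anti_aliasing=False, preserve_range=True)
        new_masks[combo] = (m > 0.5).astype(np.uint8)
    return FluorescenceImage(data, dict(image.metadata)), MaskSet(new_masks)


def load_dataset(data_dir, resize_to: int | None = None
                 ) -> list[tuple[FluorescenceImage, MaskSet]]:
    """Load every manifest entry of a generated/augmented dataset directory."""
    data_dir = Path(data_dir)
    manifest = pd.read_csv(data_dir / "manifest.csv")
    samples = []
    for _, row in manifest.iterrows():
        image = read_image(data_dir / row["image_path"], resize_to=resize_to)
        masks = MaskSet({c: read_mask(data_dir / row[f"mask_{c}"], resize_to=resize_to)
                         for c in COMBOS})
        image.metadata["image_id"] = Path(row["image_path"]).stem
        samples.append((image, masks))
    return samples


# --------------------------------------------------------------------- config


@dataclass
class RunConfig:
    """Fully serializable run configuration: paths plus every stage's settings.

    Round-trips exactly through YAML; unknown keys anywhere in the file are
    rejected so typos fail loudly instead of silently using defaults.
    """

    data_root: str = "data"
    output_root: str = "runs"
    weights_dir: str = "weights"
    log_level: str = "INFO"
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    augment: AugmentParams = field(default_factory=AugmentParams)
    synthetic: SyntheticParams = field(default_factory=SyntheticParams)

    _SECTIONS = {"model": ModelConfig, "train": TrainConfig,
                 "augment": AugmentParams, "synthetic": SyntheticParams}

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("data_root", "output_root", "weights_dir", "log_level")}
        for name in self._SECTIONS:
            d[name] = _plain(dataclasses.asdict(getattr(self, name)))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kwargs = {}
        for name, section_cls in cls._SECTIONS.items():
            section = d.pop(name, {})
            valid = {f.name for f in dataclasses.fields(section_cls)}
            unknown = set(section) - valid
            if unknown:
                raise ConfigurationError(
                    f"unknown keys in section {name!r}: {sorted(unknown)}")
            kwargs[name] = section_cls(**_tuplify(section_cls, section))
        scalar = {"data_root", "output_root", "weights_dir", "log_level"}
        unknown = set(d) - scalar
        if unknown:
            raise ConfigurationError(f"unknown top-level keys: {sorted(unknown)}")
        kwargs.update(d)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _plain(obj):
    """YAML-friendly copy: tuples to lists, numpy scalars to Python scalars."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _tuplify(section_cls, section: dict) -> dict:
    """Restore tuple-typed dataclass fields that YAML stored as lists."""
    out = {}
    defaults = section_cls()
    for k, v in section.items():
        if isinstance(v, list) and isinstance(getattr(defaults, k, None), tuple):
            v = tuple(v)
        out[k] = v
    return out


def setup_logging(log_path=None, level: str = "INFO") -> logging.Logger:
    """Configure the package logger with a timestamped plain-text format."""
    logger.setLevel(getattr(logging, level.upper(), logging.INFO))
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    logger.handlers = [h for h in logger.handlers
                       if not isinstance(h, (logging.FileHandler, logging.StreamHandler))]
    stream = logging.StreamHandler()
    stream.setFormatter(fmt)
    logger.addHandler(stream)
    if log_path is not None:
        fh = logging.FileHandler(log_path)
        fh.setFormatter(fmt)
        logger.addHandler(fh)
    return logger
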