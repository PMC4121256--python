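"""Image and label I/O, config files and run manifests."""

from __future__ import annotations

import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .errors import InvalidInputError

__all__ = [
    "load_image",
    "save_label_png",
    "load_label_png",
    "save_color_png",
    "write_manifest",
    "read_manifest",
]


def load_image(path) -> np.ndarray:
    """Read a PNG/TIFF image as a float (H, W, C) array scaled to [0, 1].

    Integer dtypes are divided by their maximum value; float inputs are
    assumed already scaled and are clipped (with a warning) if outside
    [0, 1].  An alpha channel is dropped with a warning.
    """
    arr = iio.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[..., None]
    if arr.ndim != 3:
        raise InvalidInputError(f"expected a 2-D image, got shape {arr.shape}")
    if arr.shape[-1] == 4:
        warnings.warn("dropping alpha channel", stacklevel=2)
        arr = arr[..., :3]
    if np.issubdtype(arr.dtype, np.integer):
        out = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        out = arr.astype(float)
        if out.min() < 0 or out.max() > 1:
            warnings.warn("float image outside [0,1]; clipping", stacklevel=2)
            out = np.clip(out, 0.0, 1.0)
    return out


def save_label_png(path, labels: np.ndarray) -> None:
    """Write an integer label image as single-channel 8-bit PNG."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > 255:
        raise InvalidInputError("labels must fit in uint8 for PNG export")
    iio.imwrite(Path(path), labels.astype(np.uint8))


def load_label_png(path) -> np.ndarray:
    """Read a label PNG back as an integer array."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr.astype(np.int64)


def save_color_png(path, image: np.ndarray) -> None:
    """Write a float [0,1] color image as 8-bit PNG."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 255).astype(np.uint8))


def write_manifest(path, manifest: dict) -> None:
    """Persist a run manifest as YAML (inputs, model, config, seed, outputs)."""
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
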