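"""Image and mask readers/writers.

Inputs are PNG or TIFF, 8- or 16-bit, 1/3/4 channels; everything is
normalized to float RGB in [0, 1] on read.  Masks are written as 8-bit
PNG with values {0, 255}.  Quantization back to integers happens only at
write time.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_image", "write_image", "read_mask", "write_mask"]

log = logging.getLogger("vesselab")


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as float RGB in [0, 1].

    Grayscale is replicated to three channels; an alpha channel is
    dropped with a logged warning.  Unsupported files raise ValueError
    with the file name and reason.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"cannot read {path}: {exc}") from exc
    arr = np.asarray(raw)
    if arr.dtype == np.uint8:
        img = arr.astype(float) / 255.0
    elif arr.dtype == np.uint16:
        img = arr.astype(float) / 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        img = arr.astype(float)
    else:
        raise ValueError(f"cannot read {path}: unsupported dtype {arr.dtype}")
    if img.ndim == 2:
        img = np.repeat(img[..., None], 3, axis=2)
    elif img.ndim == 3 and img.shape[2] == 4:
        log.warning("%s: dropping alpha channel", path)
        img = img[..., :3]
    elif img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"cannot read {path}: unsupported shape {arr.shape}")
    return np.clip(img, 0.0, 1.0)


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write a float [0, 1] RGB image as 8-bit PNG/TIFF."""
    path = Path(path)
    data = np.clip(np.asarray(img, float), 0.0, 1.0)
    iio.imwrite(path, np.round(data * 255).astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask (any nonzero pixel is foreground)."""
    img = read_image(path)
    return img[..., 0] > 0.5


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit {0, 255} PNG."""
    path = Path(path)
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    iio.imwrite(path, (mask.astype(bool) * np.uint8(255)))
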