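"""Raster image and binary-mask I/O.

Everything entering the pipeline is canonicalized to a 2-D float64 array
of intensities in [0, 1].  RGB inputs are collapsed to luminance with the
Rec. 601 weights (0.299, 0.587, 0.114); integer samples are divided by
their dtype maximum.  Binary masks travel as uint8 {0, 1} arrays and are
stored on disk as 8-bit PNGs with values {0, 255}.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np

REC601_WEIGHTS = np.array([0.299, 0.587, 0.114])

__all__ = [
    "load_image", "load_mask", "save_mask",
    "validate_image_field", "validate_mask", "to_grayscale",
]


def validate_image_field(values: np.ndarray) -> np.ndarray:
    """Check the internal image contract: 2-D, finite, in [0,1], >= 3x3."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"image field must be 2-D, got shape {arr.shape}")
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError(
            f"image must be at least 3x3 pixels, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image field contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError(
            f"image intensities must lie in [0, 1], "
            f"got range [{arr.min():.4g}, {arr.max():.4g}]")
    return arr


def validate_mask(values: np.ndarray, shape: tuple[int, int] | None = None
                  ) -> np.ndarray:
    """Check the binary-mask contract: 2-D, values exactly {0, 1}."""
    arr = np.asarray(values)
    if arr.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("mask values must be exactly 0 or 1")
    if shape is not None and arr.shape != tuple(shape):
        raise ValueError(
            f"mask shape {arr.shape} does not match image shape {shape}")
    return arr.astype(np.uint8)


def to_grayscale(arr: np.ndarray) -> np.ndarray:
    """Collapse an (H, W, 3|4) array to luminance; pass 2-D through."""
    if arr.ndim == 2:
        return arr.astype(np.float64)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        return arr[:, :, :3].astype(np.float64) @ REC601_WEIGHTS
    raise ValueError(f"unsupported image shape {arr.shape}")


def _normalize_dtype(arr: np.ndarray) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / np.iinfo(arr.dtype).max
    return arr.astype(np.float64)


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/TIFF/JPEG into a [0,1] grayscale float field."""
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - decoder errors vary by plugin
        raise OSError(f"cannot read image file {path!r}: {exc}") from exc
    if raw.size == 0:
        raise ValueError(f"image {path!r} has zero area")
    return validate_image_field(to_grayscale(_normalize_dtype(raw)))


def load_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a mask image; pixels above half the dtype maximum become 1."""
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise OSError(f"cannot read mask file {path!r}: {exc}") from exc
    if raw.ndim == 3:
        channels = raw[:, :, :3]
        if not (channels == channels[:, :, :1]).all():
            raise ValueError(
                f"mask {path!r} has unequal color channels; "
                "expected a single-channel (or replicated-gray) image")
        raw = channels[:, :, 0]
    if np.issubdtype(raw.dtype, np.integer):
        threshold = np.iinfo(raw.dtype).max / 2.0
    else:
        threshold = 0.5
    return (raw > threshold).astype(np.uint8)


def save_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a {0,1} mask as an 8-bit single-channel PNG with {0,255}."""
    arr = validate_mask(mask)
    iio.imwrite(path, (arr * 255).astype(np.uint8))
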