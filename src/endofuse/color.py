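"""Raster image I/O and RGB <-> HSI colour conversion.

Enhancement operates on the intensity plane only, so the colour model must
separate brightness from chromaticity exactly.  The classic geometric HSI
model is used: intensity is the plain channel mean ``I = (R+G+B)/3``, which
makes "adjust intensity, keep colour" a literal statement about the data.
Hue is stored in radians on ``[0, 2*pi)``; achromatic pixels (``R=G=B``)
get hue 0 and saturation 0 by convention so round trips are well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "HSIImage",
    "MIN_SIZE",
    "hsi_to_rgb",
    "read_image",
    "rgb_to_hsi",
    "validate_rgb",
    "write_image",
]

log = logging.getLogger(__name__)

#: Minimum height/width: room for 3x3 windows and one dyadic wavelet level.
MIN_SIZE = 8

_TWO_PI = 2.0 * np.pi


class ImageFormatError(ValueError):
    """Raised for unsupported channel layouts or invalid pixel data."""


def validate_rgb(img: np.ndarray, *, name: str = "image") -> np.ndarray:
    """Check an H x W x 3 float array in [0, 1] and return it as float64."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageFormatError(f"{name} must be H x W x 3, got shape {arr.shape}")
    if arr.shape[0] < MIN_SIZE or arr.shape[1] < MIN_SIZE:
        raise ImageFormatError(
            f"{name} must be at least {MIN_SIZE} x {MIN_SIZE}, got {arr.shape[:2]}"
        )
    if not np.all(np.isfinite(arr)):
        raise ImageFormatError(f"{name} contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ImageFormatError(f"{name} values must lie in [0, 1]")
    return arr


@dataclass(frozen=True)
class HSIImage:
    """Hue/saturation/intensity planes of one image.

    hue
        Radians in ``[0, 2*pi)``; 0 on achromatic pixels.
    saturation
        ``1 - min(R,G,B)/I`` in [0, 1]; 0 where intensity is 0.
    intensity
        Channel mean ``(R+G+B)/3`` in [0, 1].
    """

    hue: np.ndarray
    saturation: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        if not (self.hue.shape == self.saturation.shape == self.intensity.shape):
            raise ValueError("HSI planes must share one shape")


def read_image(path: str | Path) -> np.ndarray:
    """Read PNG/JPEG/TIFF/BMP into an H x W x 3 float64 array in [0, 1].

    8-bit data is divided by 255, 16-bit by 65535.  Grayscale is replicated
    to three channels; an alpha channel is dropped.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # imageio wraps decoder errors variously
        raise OSError(f"could not read image file {path}: {exc}") from exc

    arr = np.asarray(raw)
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        scale = 1.0
    else:
        raise ImageFormatError(f"unsupported pixel dtype {arr.dtype} in {path}")

    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim == 3 and arr.shape[2] == 3:
        pass
    else:
        raise ImageFormatError(
            f"unsupported channel count in {path}: shape {arr.shape}"
        )
    out = arr.astype(np.float64) / scale
    return validate_rgb(np.clip(out, 0.0, 1.0), name=str(path))


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write an RGB image as 8-bit, clipping to [0, 1] and rounding."""
    path = Path(path)
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageFormatError(f"expected H x W x 3 image, got shape {arr.shape}")
    quant = np.rint(np.clip(arr, 0.0, 1.0) * 255.0).astype(np.uint8)
    try:
        iio.imwrite(path, quant)
    except Exception as exc:
        raise OSError(f"could not write image file {path}: {exc}") from exc


def rgb_to_hsi(img: np.ndarray) -> HSIImage:
    """Convert RGB in [0, 1] to geometric HSI.

    ``I = (R+G+B)/3``; ``S = 1 - min/I`` (0 where I = 0); hue from the
    arccos formula, reflected to ``2*pi - H`` where ``B > G``, and set to 0
    wherever saturation is 0.
    """
    arr = validate_rgb(img)
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    intensity = (r + g + b) / 3.0

    mn = np.minimum(np.minimum(r, g), b)
    with np.errstate(divide="ignore", invalid="ignore"):
        sat = np.where(intensity > 0.0, 1.0 - mn / np.where(intensity > 0.0, intensity, 1.0), 0.0)
    sat = np.clip(sat, 0.0, 1.0)

    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    cosang = np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0), 1.0)
    ang = np.arccos(np.clip(cosang, -1.0, 1.0))
    hue = np.where(b > g, _TWO_PI - ang, ang)
    hue = np.where(sat > 0.0, hue, 0.0)
    hue = np.where(hue >= _TWO_PI, 0.0, hue)
    return HSIImage(hue=hue, saturation=sat, intensity=intensity)


def hsi_to_rgb(img: HSIImage) -> np.ndarray:
    """Invert the geometric HSI conversion, clipping out-of-gamut results."""
    h = np.asarray(img.hue, dtype=np.float64)
    s = np.asarray(img.saturation, dtype=np.float64)
    i = np.asarray(img.intensity, dtype=np.float64)

    third = _TWO_PI / 3.0
    sector = np.clip(np.floor(h / third).astype(np.int64), 0, 2)
    hprime = h - sector * third

    # In each sector one channel is the "low" I*(1-S), the next around the
    # wheel carries the cosine term, and the third closes the sum to 3I.
    with np.errstate(divide="ignore", invalid="ignore"):
        cos_term = np.cos(hprime) / np.cos(np.pi / 3.0 - hprime)
    low = i * (1.0 - s)
    high = i * (1.0 + s * cos_term)
    rest = 3.0 * i - (low + high)

    r = np.where(sector == 0, high, np.where(sector == 1, low, rest))
    g = np.where(sector == 0, rest, np.where(sector == 1, high, low))
    b = np.where(sector == 0, low, np.where(sector == 1, rest, high))

    out = np.stack([r, g, b], axis=-1)
    n_clip = int(np.sum((out < 0.0) | (out > 1.0)))
    if n_clip:
        log.debug("hsi_to_rgb clipped %d out-of-gamut values", n_clip)
    return np.clip(out, 0.0, 1.0)
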