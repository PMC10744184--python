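"""2D image container and grayscale TIFF/PNG I/O with pixel-pitch sidecars.

The pixel pitch travels with the array in :class:`Image2D` because every
physical quantity downstream (scatter range, noise power spectra) is expressed
in millimetres.  On disk the pitch lives in a small YAML sidecar next to the
image file; detectors of the class emulated here have a 70 um pitch, which is
the fallback when no sidecar is found.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .exceptions import FormatError

logger = logging.getLogger(__name__)

DEFAULT_PIXEL_SIZE_MM = 0.07


@dataclass
class Image2D:
    """A 2D grayscale image with a physical pixel pitch in millimetres."""

    pixels: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_MM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise FormatError(f"expected a 2D array, got shape {self.pixels.shape}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def copy(self) -> "Image2D":
        return Image2D(self.pixels.copy(), self.pixel_size)

    def same_grid(self, other: "Image2D", rtol: float = 1e-6) -> bool:
        return abs(self.pixel_size - other.pixel_size) <= rtol * self.pixel_size


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def read_image(path, pixel_size: float | None = None) -> Image2D:
    """Read an 8/16-bit grayscale TIFF or PNG (or float TIFF).

    Pixel pitch resolution order: explicit argument, YAML sidecar written by
    :func:`write_image`, then the 0.07 mm default (logged as a warning).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif suffix == ".png":
        arr = iio.imread(path)
    else:
        raise FormatError(f"unsupported image format: {suffix}")
    if arr.ndim != 2:
        raise FormatError(
            f"{path.name}: only single-channel grayscale images are supported "
            f"(got shape {arr.shape})"
        )
    if pixel_size is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = yaml.safe_load(sidecar.read_text())
            pixel_size = float(meta["pixel_size"])
        else:
            pixel_size = DEFAULT_PIXEL_SIZE_MM
            logger.warning(
                "%s: no pixel-size metadata found; defaulting to %.2f mm",
                path.name, pixel_size,
            )
    return Image2D(np.asarray(arr, dtype=np.float64), pixel_size)


def write_image(image: Image2D, path, metadata: dict | None = None) -> None:
    """Write a grayscale image plus a YAML sidecar with the pixel pitch.

    Integer-valued data in [0, 65535] is stored as 16-bit; other values go to
    a float32 TIFF (PNG cannot hold floats and raises a format error).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    arr = image.pixels
    integral = np.allclose(arr, np.round(arr), atol=1e-9)
    in_range = arr.min() >= 0 and arr.max() <= 65535
    if integral and in_range:
        out = np.round(arr).astype(np.uint16)
    elif suffix == ".png":
        raise FormatError("PNG output requires integer pixel values in [0, 65535]")
    else:
        out = arr.astype(np.float32)
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, out)
    elif suffix == ".png":
        iio.imwrite(path, out)
    else:
        raise FormatError(f"unsupported image format: {suffix}")
    meta = {"pixel_size": float(image.pixel_size)}
    if metadata:
        meta.update(metadata)
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))
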