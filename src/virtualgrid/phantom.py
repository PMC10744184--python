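"""Synthetic breast-like phantoms with known ground truth.

Every downstream stage (scatter simulation/correction, noise-level estimation,
denoiser training, quality metrics) is exercised against these scenes, so the
phantom carries: a smooth semi-elliptical tissue region with a thickness-like
intensity profile and band-limited texture, a dark background, optional bright
microcalcification-like dots of 0.1-1 mm diameter, and ROI rectangles for
signal and background measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .exceptions import SizeError
from .images import Image2D, write_image
from .quality import ROISpec

CALC_DIAMETER_RANGE_MM = (0.1, 1.0)
MIN_CALC_SEPARATION_PX = 10


@dataclass
class PhantomScene:
    """Noise-free, scatter-free synthetic scene plus its measurement layout."""

    primary: Image2D
    roi_signal: list[ROISpec]
    roi_background: list[ROISpec]
    calcification_mask: Image2D
    seed: int

    def all_rois(self) -> list[ROISpec]:
        return list(self.roi_signal) + list(self.roi_background)


def make_flat_field(height: int, width: int, value: float,
                    pixel_size: float = 1.0) -> Image2D:
    """Uniform image — the canonical input for kernel and NNPS oracles."""
    if value < 0:
        raise ValueError(f"flat-field value must be non-negative, got {value}")
    return Image2D(np.full((height, width), float(value)), pixel_size)


def _tissue_support(height: int, width: int) -> tuple[np.ndarray, np.ndarray]:
    """Half-ellipse support anchored to the left edge; returns (mask, rho)."""
    a = 0.45 * height          # semi-axis along rows
    b = 0.70 * width           # semi-axis along columns
    r = np.arange(height)[:, None]
    c = np.arange(width)[None, :]
    rho = np.sqrt(((r - height / 2.0) / a) ** 2 + (c / b) ** 2)
    return rho <= 1.0, rho


def _place_calcifications(rng: np.random.Generator, support: np.ndarray,
                          rho: np.ndarray, n: int, pixel_size: float
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample dot centres inside the tissue, >= 10 px apart."""
    mask = np.zeros(support.shape, dtype=np.uint8)
    bump = np.zeros(support.shape)
    centers: list[tuple[int, int]] = []
    h, w = support.shape
    lo, hi = CALC_DIAMETER_RANGE_MM
    attempts = 0
    while len(centers) < n:
        attempts += 1
        if attempts > 2000 * max(n, 1):
            raise SizeError(
                f"could not place {n} calcifications >= {MIN_CALC_SEPARATION_PX} px "
                f"apart inside a {h}x{w} tissue region"
            )
        d_px = rng.uniform(lo, hi) / pixel_size
        radius = max(1, int(round(d_px / 2.0)))
        i = int(rng.integers(radius + 1, h - radius - 1))
        j = int(rng.integers(radius + 1, w - radius - 1))
        if rho[i, j] > 0.8:          # stay well inside the tissue
            continue
        if any((i - ci) ** 2 + (j - cj) ** 2 < MIN_CALC_SEPARATION_PX ** 2
               for ci, cj in centers):
            continue
        centers.append((i, j))
        ii, jj = np.ogrid[-radius:radius + 1, -radius:radius + 1]
        disc = ii ** 2 + jj ** 2 <= radius ** 2
        mask[i - radius:i + radius + 1, j - radius:j + radius + 1] |= disc
        bump[i - radius:i + radius + 1, j - radius:j + radius + 1] += disc * 1.0
    return mask, bump


def _layout_rois(height: int, width: int, support: np.ndarray) -> tuple[list[ROISpec], list[ROISpec]]:
    size = max(8, min(32, height // 16))
    half = size // 2

    def rect(name, rc, cc, role):
        return ROISpec(name, rc - half, cc - half, size, size, role)

    signal = [
        rect("tissue_center", height // 2, int(0.30 * width), "signal"),
        rect("tissue_upper", int(0.35 * height), int(0.18 * width), "signal"),
        rect("tissue_lower", int(0.65 * height), int(0.18 * width), "signal"),
    ]
    background = [
        rect("background_upper", int(0.10 * height), int(0.88 * width), "background"),
        rect("background_lower", int(0.90 * height), int(0.88 * width), "background"),
    ]
    for roi in signal:
        if not support[roi.row0:roi.row0 + roi.height,
                       roi.col0:roi.col0 + roi.width].all():
            raise SizeError(f"signal ROI {roi.name} falls outside the tissue support")
    for roi in background:
        if support[roi.row0:roi.row0 + roi.height,
                   roi.col0:roi.col0 + roi.width].any():
            raise SizeError(f"background ROI {roi.name} intersects the tissue support")
    return signal, background


def make_phantom(height: int, width: int, pixel_size: float = 0.07,
                 n_calcifications: int = 0, seed: int = 0,
                 tissue_level: float = 1000.0, background_level: float = 50.0,
                 texture_sigma: float = 8.0, texture_amplitude: float = 0.05,
                 calc_amplitude: float = 0.8) -> PhantomScene:
    """Build a breast-like scene: half-elliptical tissue with a smooth
    thickness profile and band-limited texture over a dark background.

    ``texture_sigma`` is the Gaussian filter width (px) applied to white noise
    to create low-frequency internal density variation; ``texture_amplitude``
    and ``calc_amplitude`` are fractions of ``tissue_level``.  The same seed
    always reproduces the same scene bit for bit.
    """
    if height < 64 or width < 64:
        raise SizeError("phantom requires height and width >= 64")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if n_calcifications < 0:
        raise ValueError("n_calcifications must be >= 0")
    rng = np.random.default_rng(seed)
    support, rho = _tissue_support(height, width)

    # thickness-like profile: plateau at the chest wall, smooth falloff
    profile = np.sqrt(np.clip(1.0 - rho ** 2, 0.0, None))
    img = np.full((height, width), float(background_level))
    img += (tissue_level - background_level) * profile

    texture = ndimage.gaussian_filter(rng.standard_normal((height, width)),
                                      texture_sigma)
    texture /= max(texture.std(), 1e-12)
    img += support * texture * (texture_amplitude * tissue_level) * profile

    if n_calcifications > 0:
        mask, bump = _place_calcifications(rng, support, rho, n_calcifications,
                                           pixel_size)
        img += bump * (calc_amplitude * tissue_level)
    else:
        mask = np.zeros((height, width), dtype=np.uint8)

    img = np.clip(img, 0.0, None)
    signal, background = _layout_rois(height, width, support)
    return PhantomScene(
        primary=Image2D(img, pixel_size),
        roi_signal=signal,
        roi_background=background,
        calcification_mask=Image2D(mask.astype(np.float64), pixel_size),
        seed=seed,
    )


def count_calcifications(scene: PhantomScene) -> int:
    """Connected components of the calcification mask (8-connectivity)."""
    _, n = ndimage.label(scene.calcification_mask.pixels > 0,
                         structure=np.ones((3, 3)))
    return int(n)


def save_scene(scene: PhantomScene, directory, stem: str = "phantom") -> Path:
    """Write the primary image as 16-bit TIFF plus a YAML sidecar with ROIs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{stem}.tif"
    rois = [
        {"name": r.name, "row0": r.row0, "col0": r.col0,
         "height": r.height, "width": r.width, "role": r.role}
        for r in scene.all_rois()
    ]
    write_image(Image2D(np.round(scene.primary.pixels), scene.primary.pixel_size),
                path, metadata={"seed": scene.seed, "rois": rois})
    return path
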