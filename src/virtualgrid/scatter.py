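"""Scatter point-spread function, scatter simulation, and virtual-grid correction.

The forward model treats a measured X-ray image I as the primary signal P plus
a scattered component obtained by convolving P with a broad, radially symmetric
scatter kernel,

    I = P + P * S_k,     S_k(r) = [SF / (1 - SF)] * exp(-r / k) / (2 pi k r),

where SF is the scatter fraction (scatter over total signal at a point behind a
uniform object) and k the e-folding scatter range in mm.  The 2D integral of
S_k is SF/(1-SF), so a flat field of value c maps to c/(1-SF) and the interior
scatter fraction is exactly SF.  The delta (primary) term of the full sPSF is
carried implicitly by adding P back after the convolution.

Virtual-grid correction inverts the forward model spectrally,

    P_hat = IFFT[ FFT(I) / (1 + FFT(S_k)) ],    S_hat = I - P_hat,

which round-trips the simulation to within edge effects.  1 + FFT(S_k) >= 1
analytically; a small floor guards against float error only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .exceptions import SizeError, UnitError
from .images import Image2D

DEFAULT_SF = 0.39
DEFAULT_K_RANGE_MM = 40.2    # scatter range; 4.02 cm expressed in mm
SPECTRAL_FLOOR = 1e-3
MAX_KERNEL_SIDE = 4096


@dataclass
class ScatterKernel:
    """Discretized scatter part of the sPSF (the delta term is implicit)."""

    sf: float              # scatter fraction, in [0, 1)
    k_range: float         # e-folding range, mm
    pixel_size: float      # mm
    radius: int            # truncation radius, px
    kernel: np.ndarray     # (2*radius+1)^2 non-negative weights

    @property
    def spr(self) -> float:
        """Scatter-to-primary ratio SF / (1 - SF) = the kernel's target mass."""
        return self.sf / (1.0 - self.sf)


def build_spsf_kernel(sf: float = DEFAULT_SF, k_range: float = DEFAULT_K_RANGE_MM,
                      pixel_size: float = 0.07, radius_factor: float = 6.0,
                      max_side: int = MAX_KERNEL_SIDE) -> ScatterKernel:
    """Discretize the scatter term of the sPSF on a (2R+1)^2 pixel grid.

    R = ceil(radius_factor * k / pixel_size); the singular r -> 0 centre cell
    receives the analytic integral of S_k over an equal-area disc, every other
    cell the midpoint value times the pixel area.  Truncation leaves a mass
    fraction exp(-radius_factor) outside the grid, so radius_factor >= 3 keeps
    the kernel sum within [0.95, 1] x SF/(1-SF).
    """
    if not 0.0 <= sf < 1.0:
        raise ValueError(f"scatter fraction must lie in [0, 1), got {sf}")
    if k_range <= 0 or pixel_size <= 0:
        raise ValueError("k_range and pixel_size must be positive")
    if radius_factor < 3:
        raise ValueError("radius_factor must be >= 3 to bound truncation loss")
    radius = int(math.ceil(radius_factor * k_range / pixel_size))
    side = 2 * radius + 1
    if side > max_side:
        raise SizeError(
            f"kernel side {side} px exceeds the cap of {max_side}; increase "
            f"pixel_size or decrease k_range/radius_factor (the physics is "
            f"scale-invariant in r/k)"
        )
    if sf == 0.0:
        return ScatterKernel(sf, k_range, pixel_size, 0, np.zeros((1, 1)))
    spr = sf / (1.0 - sf)
    ax = np.arange(-radius, radius + 1) * pixel_size
    r = np.hypot(ax[:, None], ax[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        kern = spr * np.exp(-r / k_range) / (2.0 * math.pi * k_range * r)
    kern *= pixel_size ** 2
    # centre cell: exact mass of S_k over a disc with the pixel's area
    a_eq = pixel_size / math.sqrt(math.pi)
    kern[radius, radius] = spr * (1.0 - math.exp(-a_eq / k_range))
    return ScatterKernel(sf, k_range, pixel_size, radius, kern)


def _check_grid(image: Image2D, kernel: ScatterKernel) -> None:
    if abs(image.pixel_size - kernel.pixel_size) > 1e-6 * kernel.pixel_size:
        raise UnitError(
            f"pixel pitch mismatch: image {image.pixel_size} mm vs "
            f"kernel {kernel.pixel_size} mm"
        )


def apply_scatter(primary: Image2D, kernel: ScatterKernel) -> Image2D:
    """Simulate a scatter-corrupted image: primary + primary * S_k.

    Edges are padded by replication over one kernel radius before the FFT
    convolution, so interior pixels see the full scatter environment.
    """
    _check_grid(primary, kernel)
    if primary.pixels.min() < 0:
        raise ValueError("primary image must be non-negative")
    if kernel.sf == 0.0:
        return primary.copy()
    pad = kernel.radius
    padded = np.pad(primary.pixels, pad, mode="edge")
    scatter = fftconvolve(padded, kernel.kernel, mode="same")
    scatter = scatter[pad:pad + primary.shape[0], pad:pad + primary.shape[1]]
    return Image2D(primary.pixels + scatter, primary.pixel_size)


def _kernel_otf(kernel: ScatterKernel, shape: tuple[int, int]) -> np.ndarray:
    """FFT of the kernel embedded at the origin of a grid of the given shape."""
    if shape[0] < kernel.kernel.shape[0] or shape[1] < kernel.kernel.shape[1]:
        raise SizeError("image (with padding) is smaller than the scatter kernel")
    emb = np.zeros(shape)
    side = kernel.kernel.shape[0]
    emb[:side, :side] = kernel.kernel
    emb = np.roll(emb, (-kernel.radius, -kernel.radius), axis=(0, 1))
    return np.fft.fft2(emb)


def estimate_scatter(corrupted: Image2D, kernel: ScatterKernel,
                     clip: bool = False) -> Image2D:
    """Estimate the scatter map by spectral inversion of the forward model.

    P_hat = IFFT[FFT(I) / (1 + OTF)] on a replicate-padded grid, then
    S_hat = I - P_hat.  Small negative excursions from discretization are kept
    unless ``clip`` is set.
    """
    _check_grid(corrupted, kernel)
    if kernel.sf == 0.0:
        return Image2D(np.zeros(corrupted.shape), corrupted.pixel_size)
    pad = kernel.radius
    padded = np.pad(corrupted.pixels, pad, mode="edge")
    otf = _kernel_otf(kernel, padded.shape)
    den = 1.0 + otf
    small = np.abs(den) < SPECTRAL_FLOOR
    if small.any():
        den = np.where(small, SPECTRAL_FLOOR, den)
    primary_hat = np.real(np.fft.ifft2(np.fft.fft2(padded) / den))
    primary_hat = primary_hat[pad:pad + corrupted.shape[0],
                              pad:pad + corrupted.shape[1]]
    scatter_hat = corrupted.pixels - primary_hat
    if clip:
        scatter_hat = np.clip(scatter_hat, 0.0, None)
    return Image2D(scatter_hat, corrupted.pixel_size)


def correct_scatter(corrupted: Image2D, kernel: ScatterKernel) -> Image2D:
    """Virtual-grid correction: subtract the estimated scatter map."""
    scatter_hat = estimate_scatter(corrupted, kernel)
    return Image2D(corrupted.pixels - scatter_hat.pixels, corrupted.pixel_size)


def interior_slice(kernel: ScatterKernel, shape: tuple[int, int],
                   factor: float = 1.0) -> tuple[slice, slice]:
    """Slices selecting pixels at least ``factor`` kernel radii from the edges."""
    m = int(math.ceil(factor * kernel.radius))
    if 2 * m >= shape[0] or 2 * m >= shape[1]:
        raise SizeError(f"image {shape} has no interior at margin {m} px")
    return slice(m, shape[0] - m), slice(m, shape[1] - m)


def save_kernel(kernel: ScatterKernel, path) -> None:
    """Plain-text export: YAML header lines (commented) + the weight matrix."""
    import yaml

    header = yaml.safe_dump(
        {"sf": kernel.sf, "k_range_mm": kernel.k_range,
         "pixel_size_mm": kernel.pixel_size, "radius_px": kernel.radius},
        sort_keys=True,
    )
    with open(path, "w") as fh:
        for line in header.strip().splitlines():
            fh.write(f"# {line}\n")
        np.savetxt(fh, kernel.kernel)


def load_kernel(path) -> ScatterKernel:
    import yaml

    header_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header_lines.append(line[1:].strip())
            else:
                break
    meta = yaml.safe_load("\n".join(header_lines))
    kernel = np.loadtxt(path)
    if kernel.ndim == 0:
        kernel = kernel.reshape(1, 1)
    return ScatterKernel(sf=float(meta["sf"]), k_range=float(meta["k_range_mm"]),
                         pixel_size=float(meta["pixel_size_mm"]),
                         radius=int(meta["radius_px"]), kernel=np.atleast_2d(kernel))
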