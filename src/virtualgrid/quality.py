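"""Quantitative image-quality metrics: CNR, COV, and radially averaged NNPS.

Contrast-to-noise ratio compares a signal ROI A against a background ROI B,

    CNR = (S_A - S_B) / sqrt(sigma_A^2 + sigma_B^2),

the coefficient of variation is sigma/mean within one ROI, and the noise
power spectrum is estimated from detrended sub-patches of a uniform region,

    NPS(u, v) = (dx dy / (M Nx Ny)) sum_m |DFT2[I_m - S_m]|^2,

with S_m a fitted low-order polynomial surface per sub-patch.  NNPS divides by
the squared large-area signal, giving units of mm^2 against spatial frequency
in cycles/mm, capped at the Nyquist frequency 1/(2 * pixel pitch).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import SizeError
from .images import Image2D


@dataclass(frozen=True)
class ROISpec:
    """Axis-aligned rectangle, 0-based, half-open [row0, row0+height)."""

    name: str
    row0: int
    col0: int
    height: int
    width: int
    role: str = "signal"  # "signal" | "background"

    def __post_init__(self):
        if self.height < 2 or self.width < 2:
            raise ValueError(f"ROI {self.name}: height and width must be >= 2")
        if self.role not in ("signal", "background"):
            raise ValueError(f"ROI {self.name}: bad role {self.role!r}")

    def validate(self, shape: tuple[int, int]) -> None:
        if (self.row0 < 0 or self.col0 < 0
                or self.row0 + self.height > shape[0]
                or self.col0 + self.width > shape[1]):
            raise SizeError(f"ROI {self.name} does not fit inside image {shape}")

    def extract(self, image: Image2D) -> np.ndarray:
        self.validate(image.shape)
        return image.pixels[self.row0:self.row0 + self.height,
                            self.col0:self.col0 + self.width]

    def overlaps(self, other: "ROISpec") -> bool:
        return not (self.row0 + self.height <= other.row0
                    or other.row0 + other.height <= self.row0
                    or self.col0 + self.width <= other.col0
                    or other.col0 + other.width <= self.col0)


def cnr(image: Image2D, signal: ROISpec, background: ROISpec) -> float:
    """Contrast-to-noise ratio between a signal and a background ROI.

    Sign is preserved; a zero denominator (two constant ROIs) yields NaN.
    """
    a = signal.extract(image)
    b = background.extract(image)
    denom = math.sqrt(a.std(ddof=1) ** 2 + b.std(ddof=1) ** 2)
    if denom == 0.0:
        return float("nan")
    return float((a.mean() - b.mean()) / denom)


def cov(image: Image2D, roi: ROISpec) -> float:
    """Coefficient of variation sigma/mean within one ROI; NaN for zero mean."""
    a = roi.extract(image)
    m = a.mean()
    if m == 0.0:
        return float("nan")
    return float(a.std(ddof=1) / m)


@dataclass
class NPSpectrum:
    """2D noise power spectrum with physical frequency axes (cycles/mm)."""

    nps: np.ndarray          # (n, n), unshifted DFT ordering
    fx: np.ndarray           # row frequencies, np.fft.fftfreq ordering
    fy: np.ndarray           # column frequencies
    pixel_size: float
    n_subpatches: int
    large_area_signal: float


def _poly_basis(n: int, order: int) -> np.ndarray:
    """Design matrix of 2D monomials x^i y^j with i + j <= order on an n x n grid."""
    y, x = np.meshgrid(np.linspace(-1, 1, n), np.linspace(-1, 1, n), indexing="ij")
    cols = [x.ravel() ** i * y.ravel() ** j
            for i in range(order + 1) for j in range(order + 1 - i)]
    return np.stack(cols, axis=1)


def nps2d(image: Image2D, roi: ROISpec, subpatch: int = 64,
          detrend_order: int = 2) -> NPSpectrum:
    """2D NPS from half-overlapping detrended sub-patches of a uniform ROI.

    Each sub-patch has a polynomial surface of total degree ``detrend_order``
    removed before the DFT, absorbing the smooth background S(x, y) so that
    only noise power remains.
    """
    region = roi.extract(image)
    if region.shape[0] < subpatch or region.shape[1] < subpatch:
        raise SizeError(
            f"ROI {roi.name} ({region.shape}) is smaller than the {subpatch} px sub-patch"
        )
    step = max(1, subpatch // 2)
    basis = _poly_basis(subpatch, detrend_order)
    # projection onto the polynomial subspace, precomputed once
    proj = basis @ np.linalg.pinv(basis)
    dx = image.pixel_size
    acc = np.zeros((subpatch, subpatch))
    m = 0
    rows = list(range(0, region.shape[0] - subpatch + 1, step))
    cols = list(range(0, region.shape[1] - subpatch + 1, step))
    for r in rows:
        for c in cols:
            tile = region[r:r + subpatch, c:c + subpatch]
            resid = tile.ravel() - proj @ tile.ravel()
            ft = np.fft.fft2(resid.reshape(subpatch, subpatch))
            acc += np.abs(ft) ** 2
            m += 1
    nps = acc * (dx * dx) / (m * subpatch * subpatch)
    f = np.fft.fftfreq(subpatch, d=dx)
    return NPSpectrum(nps=nps, fx=f.copy(), fy=f.copy(), pixel_size=dx,
                      n_subpatches=m, large_area_signal=float(region.mean()))


def nnps_radial(spectrum: NPSpectrum,
                large_area_signal: float | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Radially averaged NNPS: (frequency in cycles/mm, NNPS in mm^2).

    The zero-frequency row and column are excluded (residual detrending
    leakage concentrates there); bins have the spectrum's frequency
    resolution as width and the axis is capped at Nyquist.
    """
    las = spectrum.large_area_signal if large_area_signal is None else large_area_signal
    if not las > 0:
        raise ValueError(f"large-area signal must be positive, got {las}")
    nnps = spectrum.nps / (las * las)
    fr, fc = np.meshgrid(spectrum.fx, spectrum.fy, indexing="ij")
    radius = np.hypot(fr, fc)
    keep = (fr != 0) & (fc != 0)
    n = len(spectrum.fx)
    df = 1.0 / (n * spectrum.pixel_size)
    nyquist = 1.0 / (2.0 * spectrum.pixel_size)
    edges = np.arange(0.0, nyquist + df, df)
    freqs, values = [], []
    idx = np.digitize(radius[keep], edges) - 1
    flat = nnps[keep]
    for b in range(len(edges) - 1):
        sel = idx == b
        if sel.any():
            freqs.append(0.5 * (edges[b] + edges[b + 1]))
            values.append(float(flat[sel].mean()))
    return np.asarray(freqs), np.asarray(values)


@dataclass
class QualityReport:
    """CNR/COV per ROI plus an optional radially averaged NNPS curve."""

    cnr: dict[str, float] = field(default_factory=dict)
    cov: dict[str, float] = field(default_factory=dict)
    means: dict[str, float] = field(default_factory=dict)
    stds: dict[str, float] = field(default_factory=dict)
    nnps_freq: np.ndarray | None = None
    nnps: np.ndarray | None = None

    def to_dict(self) -> dict:
        out = {
            "cnr": {k: float(v) for k, v in self.cnr.items()},
            "cov": {k: float(v) for k, v in self.cov.items()},
            "means": {k: float(v) for k, v in self.means.items()},
            "stds": {k: float(v) for k, v in self.stds.items()},
        }
        if self.nnps is not None:
            out["nnps"] = {"frequency_per_mm": self.nnps_freq.tolist(),
                           "nnps_mm2": self.nnps.tolist()}
        return out


def quality_report(image: Image2D, signal_rois: list[ROISpec],
                   background_rois: list[ROISpec],
                   nps_roi: ROISpec | None = None,
                   subpatch: int = 64) -> QualityReport:
    """Evaluate CNR (each signal ROI vs the first background ROI), COV for
    every signal ROI, and optionally the NNPS on a uniform ROI."""
    report = QualityReport()
    for roi in signal_rois + background_rois:
        patch = roi.extract(image)
        report.means[roi.name] = float(patch.mean())
        report.stds[roi.name] = float(patch.std(ddof=1))
    if background_rois:
        bg = background_rois[0]
        for roi in signal_rois:
            report.cnr[roi.name] = cnr(image, roi, bg)
    for roi in signal_rois:
        report.cov[roi.name] = cov(image, roi)
    if nps_roi is not None:
        spec = nps2d(image, nps_roi, subpatch=subpatch)
        report.nnps_freq, report.nnps = nnps_radial(spec)
    return report


def mean_percent_improvement(before, after, higher_is_better: bool = True) -> float:
    """Average per-entry percent improvement between two metric sequences.

    For higher-is-better metrics (CNR) this is mean((after-before)/before)*100;
    for lower-is-better ones (COV) the sign is flipped so improvements are
    positive either way.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.size == 0:
        raise ValueError("before/after must be equal-length, non-empty sequences")
    change = (after - before) / before
    if not higher_is_better:
        change = -change
    return float(change.mean() * 100.0)
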