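"""Noise-level function estimation from a single image.

The image is tiled into 16x16 blocks; blocks whose signal variation is small
relative to the noise ("homogeneous") are detected nonparametrically with
Kendall's tau on pairs of horizontally adjacent pixels — adjacent pixels share
the local signal but carry independent noise, so under homogeneity tau is a
rank correlation of i.i.d. noise and concentrates near zero.  The (mean,
variance) points of accepted blocks are then fitted with a first-degree L1
(least-absolute-deviation) trend

    variance = alpha * mean + beta^2,

whose slope and intercept recover the Poisson scale alpha and Gaussian sigma
beta of the noise-level function.  The L1 objective keeps occasional textured
blocks that slip through the screen from biasing the fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import EstimationError, SizeError
from .images import Image2D

DEFAULT_BLOCK_SIZE = 16
DEFAULT_SIGNIFICANCE = 0.05


@dataclass
class BlockStat:
    row: int                      # block index (not pixels)
    col: int
    mean: float
    variance: float               # unbiased (n-1) sample variance
    tau: float | None = None      # None = not screened yet; NaN = degenerate
    homogeneous: bool | None = None


@dataclass
class NLFEstimate:
    alpha_hat: float
    beta_hat: float
    n_homogeneous: int
    blocks: list[BlockStat] = field(default_factory=list)
    fit_residual: float = 0.0     # mean |variance - fitted| over used blocks


def partition_blocks(image: Image2D, block_size: int = DEFAULT_BLOCK_SIZE
                     ) -> list[BlockStat]:
    """Non-overlapping tiling from (0, 0); partial edge blocks are discarded."""
    h, w = image.shape
    if h < block_size or w < block_size:
        raise SizeError(
            f"image {image.shape} is smaller than one {block_size}x{block_size} block"
        )
    nr, nc = h // block_size, w // block_size
    tiles = (image.pixels[:nr * block_size, :nc * block_size]
             .reshape(nr, block_size, nc, block_size)
             .swapaxes(1, 2))
    means = tiles.mean(axis=(2, 3))
    varis = tiles.var(axis=(2, 3), ddof=1)
    return [BlockStat(r, c, float(means[r, c]), float(varis[r, c]))
            for r in range(nr) for c in range(nc)]


def kendall_tau(a, b, method: str = "fast") -> float:
    """Tie-corrected Kendall tau-b; NaN when either sequence is all ties.

    ``method="exact"`` enumerates all n(n-1)/2 pairs in O(n^2) and is the
    reference the fast path is checked against.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 2:
        raise ValueError("sequences must have equal length n >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    if method == "fast":
        return float(stats.kendalltau(a, b).statistic)
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    sa = np.sign(a[:, None] - a[None, :])
    sb = np.sign(b[:, None] - b[None, :])
    iu = np.triu_indices(a.size, k=1)
    num = float((sa[iu] * sb[iu]).sum())
    n0 = a.size * (a.size - 1) / 2.0
    ties_a = n0 - float((sa[iu] != 0).sum())
    ties_b = n0 - float((sb[iu] != 0).sum())
    return num / math.sqrt((n0 - ties_a) * (n0 - ties_b))


def tau_null_threshold(n_pairs: int, significance: float) -> float:
    """Two-sided acceptance bound for tau under the i.i.d. null.

    Var(tau) = 2(2n+5) / (9 n (n-1)) asymptotically; the bound is
    z_(1-sig/2) times that standard deviation.
    """
    sd = math.sqrt(2.0 * (2 * n_pairs + 5) / (9.0 * n_pairs * (n_pairs - 1)))
    return float(stats.norm.ppf(1.0 - significance / 2.0) * sd)


def is_homogeneous(block: np.ndarray, significance: float = DEFAULT_SIGNIFICANCE
                   ) -> tuple[bool, float]:
    """Screen one block: tau over horizontally adjacent pixel couples.

    Columns (2j, 2j+1) form the paired sequences (128 pairs per 16x16 block).
    A degenerate all-tied block is accepted as homogeneous with tau = NaN.
    """
    block = np.asarray(block, dtype=float)
    if block.size < 8:
        raise SizeError("homogeneity screening needs blocks of >= 8 pixels")
    w2 = (block.shape[1] // 2) * 2
    p = block[:, 0:w2:2].ravel()
    q = block[:, 1:w2:2].ravel()
    tau = kendall_tau(p, q, method="fast")
    if math.isnan(tau):
        return True, tau
    bound = tau_null_threshold(p.size, significance)
    return bool(abs(tau) <= bound), float(tau)


def screen_blocks(image: Image2D, block_size: int = DEFAULT_BLOCK_SIZE,
                  significance: float = DEFAULT_SIGNIFICANCE) -> list[BlockStat]:
    """Partition the image and fill in the homogeneity screen per block."""
    stats_list = partition_blocks(image, block_size)
    for s in stats_list:
        tile = image.pixels[s.row * block_size:(s.row + 1) * block_size,
                            s.col * block_size:(s.col + 1) * block_size]
        s.homogeneous, s.tau = is_homogeneous(tile, significance)
    return stats_list


def _l1_line_fit(m: np.ndarray, v: np.ndarray, eps: float = 1e-6,
                 max_iter: int = 100, tol: float = 1e-8) -> tuple[float, float]:
    """Least-absolute-deviation fit v ~ slope*m + intercept via IRLS.

    Deterministic: initialized from the L2 solution, reweighted by
    1/max(|residual|, eps) until the parameters move less than ``tol``.
    """
    design = np.column_stack([m, np.ones_like(m)])
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    for _ in range(max_iter):
        resid = v - design @ coef
        w = 1.0 / np.maximum(np.abs(resid), eps)
        sw = np.sqrt(w)
        new, *_ = np.linalg.lstsq(design * sw[:, None], v * sw, rcond=None)
        if np.max(np.abs(new - coef)) < tol * (1.0 + np.max(np.abs(new))):
            coef = new
            break
        coef = new
    return float(coef[0]), float(coef[1])


def fit_nlf(block_stats: list[BlockStat], min_blocks: int = 5) -> NLFEstimate:
    """First-degree L1 mean-variance fit over the homogeneous blocks.

    Slope and intercept are clamped at zero before reporting alpha_hat and
    beta_hat = sqrt(intercept).  With fewer than two distinct means no slope is
    identifiable and the estimate degenerates to pure Gaussian noise at the
    mean block variance.
    """
    hom = [s for s in block_stats if s.homogeneous]
    if len(hom) < min_blocks:
        raise EstimationError(
            f"only {len(hom)} homogeneous blocks (need >= {min_blocks}); relax "
            f"the significance level or supply flatter data"
        )
    m = np.array([s.mean for s in hom])
    v = np.array([s.variance for s in hom])
    if np.unique(m).size < 2:
        beta2 = max(0.0, float(v.mean()))
        return NLFEstimate(alpha_hat=0.0, beta_hat=math.sqrt(beta2),
                           n_homogeneous=len(hom), blocks=list(block_stats),
                           fit_residual=float(np.abs(v - beta2).mean()))
    slope, intercept = _l1_line_fit(m, v)
    alpha = max(0.0, slope)
    beta2 = max(0.0, intercept)
    resid = float(np.abs(v - (slope * m + intercept)).mean())
    return NLFEstimate(alpha_hat=alpha, beta_hat=math.sqrt(beta2),
                       n_homogeneous=len(hom), blocks=list(block_stats),
                       fit_residual=resid)


def estimate_noise_level(image: Image2D, block_size: int = DEFAULT_BLOCK_SIZE,
                         significance: float = DEFAULT_SIGNIFICANCE
                         ) -> NLFEstimate:
    """Full single-image pipeline: partition, screen, L1 fit."""
    return fit_nlf(screen_blocks(image, block_size, significance))
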