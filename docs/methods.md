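# Methods

This note documents the models implemented in `virtualgrid`, the parameter
choices that matter, the synthetic data the package is validated on, and the
numerical decisions a maintainer would want to know about.

## Scatter model and virtual-grid correction

The forward model treats the measured image as primary plus convolved
scatter, `I = P + P⊛S_k`, with a radially symmetric exponential kernel

    S_k(r) = [SF/(1−SF)] · exp(−r/k) / (2πkr).

The normalization is chosen so that the 2D integral of `S_k` equals the
scatter-to-primary ratio SF/(1−SF); a flat field then acquires an interior
scatter fraction of exactly SF, which is the defining property of SF. The
delta (primary) term of the full sPSF is carried implicitly by adding `P`
back after the convolution. Defaults: SF = 0.39 and k = 40.2 mm (the
reference scatter-range value of 4.02 cm, stored in mm because pixel pitches
are given in mm).

Discretization: the kernel is sampled at pixel centres times the pixel area
on a (2R+1)² grid with `R = ceil(radius_factor · k / pixel_size)`; the
singular centre cell receives the analytic mass of `S_k` over a disc of equal
area, `[SF/(1−SF)](1 − e^(−a/k))` with `a = Δ/√π`. Truncation at radius R
leaves a mass fraction `e^(−radius_factor)` outside the grid; the default
`radius_factor = 6` keeps the flat-field scatter fraction within 0.002 of SF.

Correction inverts the forward model spectrally,
`P̂ = F⁻¹[F(I)/(1 + F(S_k))]`, on a replicate-padded grid (pad width = one
kernel radius). Analytically `1 + F(S_k) ≥ 1`, so the 10⁻³ floor on the
denominator is inactive except under float error. This estimator is a
documented stand-in for proprietary virtual-grid software whose internals
are unknown; it is exact for the forward model used here, which is why the
round-trip test demands interior relative RMSE < 2% and observes ~10⁻⁸.

The physics is scale-invariant in r/k, so desk-scale experiments use a
coarser pitch (0.5 mm) and a proportionally smaller k (4–16 mm) to keep
kernels within a few hundred pixels; nothing else changes.

## Noise model

Noise is synthesized from the heteroscedastic Gaussian surrogate
`y = x + η(x)ε`, `η²(x) = αx + β²`, which is the model the estimator
assumes; exact Poisson sampling (`y = α·Poisson(x/α) + β·N(0,1)`) is
available behind a `poisson=True` flag for checks that rely on strict
Poisson variance additivity. α and β are in detector intensity units.

Variance amplification by scatter correction is measured by Monte Carlo:
repeat noisy scattered acquisitions, correct each, take the per-pixel
variance across repetitions at interior pixels, and compare with noise on
the scatter-free primary. For a flat field the ideal ratio is
`1 + S/P = 1/(1−SF)` (≈ 1.64 at SF = 0.39). The implemented
reading of the amplification exponent is `1 + S/P`; the alternative
`1 + (S/P)²` sometimes quoted for related setups is noted here as untested. The spectral inversion attenuates noise inside the small
low-frequency band occupied by the scatter kernel (the kernel's transform
falls off only as 1/f, so the deficit scales like (S/P)/k_px); at the test's
k = 32 px this biases the measured ratio ~2–3% below the ideal value, which
is why the test tolerance is ±0.08 around 1.639.

The denoiser trains on a grid of (α, β) combinations. The reference
configuration uses 42 levels; the actual values are not specified anywhere,
so the package ships a 7×6 default grid (α ∈ {0.5, 1, 2, 3, 4, 6, 8},
β ∈ {1, 2, 4, 6, 8, 12}) chosen to span weak to strong quantum and
electronic noise at the phantom's ~1000-unit tissue intensity.

## Noise-level-function estimation

The image is tiled into non-overlapping 16×16 blocks (edge remainders
dropped). Within each block, horizontally adjacent pixel couples (columns
2j, 2j+1; 128 pairs per block) form two sequences that share local signal
but carry independent noise; Kendall's τ-b between them concentrates near
zero when the block is noise-dominated. A block is accepted as homogeneous
when `|τ| ≤ z_(1−sig/2) · sqrt(2(2n+5)/(9n(n−1)))` (asymptotic null,
two-sided, default significance 0.05). All-tied degenerate blocks are
accepted with τ flagged as NaN. The pairing scheme, the significance level,
and the slope/intercept reading of the fit are package design decisions.

The (mean, unbiased variance) points of accepted blocks are fitted with a
first-degree least-absolute-deviation trend `v = αm + β²` via iteratively
reweighted least squares (ε = 10⁻⁶ smoothing, ≤ 100 iterations, 10⁻⁸
parameter tolerance, deterministic L2 initialization). Slope and intercept
are clamped at zero; β̂ = √intercept. The L1 objective keeps textured blocks
that survive the screen from biasing the fit (a 10% contamination with 10×
inflated variances moves α̂ by < 5% in the test suite). Degenerate inputs:
fewer than five homogeneous blocks raises an estimation error; fewer than
two distinct means (e.g. a constant image) yields α̂ = 0 and β̂ from the
mean block variance.

Identifiability: when β² is far below the Poisson floor α·min(x), the
intercept is statistically indistinguishable from zero and β̂ clamps to 0.
The recovery tests therefore assert grid-median tolerances (α within 10%,
β within 0.15β + 0.5), not per-cell ones.

## Residual GAN denoiser

Generator: a 4-stage reference encoder of stride-2 3×3 convolutions
(channels 128, 256, 512, 1024) with batch norm + ReLU, mirrored by a decoder
of stride-2 transposed convolutions (kernel 4, pad 1), no skip connections,
and a linear output layer. It consumes a noisy patch and outputs the
predicted noise; the clean estimate is input − prediction. The output layer
is zero-initialized so training starts at the identity denoiser and can only
improve on it — without this, short training runs struggle to beat the
zero-prediction baseline because the network must first learn to cancel the
signal content it leaks. Discriminator (a package design, since only the
generator architecture is pinned down by the reference configuration):
stride-2 convolutions with LeakyReLU, global average pooling, and a dense
logit; trained with binary cross-entropy on real (sampled) vs fake
(generated) noise patches. Generator loss: MSE to the noise label plus a
10⁻³-weighted non-saturating adversarial term (set `adv_weight=0` for pure
supervised residual regression).

Training data: for each clean image and each (α, β) level, input = clean +
noise and label = input − clean, pixel-exactly; both are tiled into patches
from origin (0,0) at the configured stride (reference: 256 px patches,
stride 256, after a bilinear 1.5× resize of the source frames; the frame is
reflect-padded on the bottom/right to the next multiple). A seeded 90/10
train/validation split tracks held-out generator MSE; the best epoch's
parameters are returned. Optimization: Adam at 5·10⁻⁴ (reference), batch 16.

All layers are numpy implementations with analytic backward passes verified
against central finite differences in `tests/test_nn.py`; training is bit-
reproducible under a fixed seed on a given platform.

Inference tiles the (optionally resized) image with non-overlapping patches,
predicts per patch, stitches, and crops. The stitched noise prediction is
then high-pass filtered (Gaussian sigma = patch_size/16 px by default):
patch-local inference cannot attribute noise at wavelengths comparable to
the patch, and unconstrained low-frequency predictions both add spurious
power below ~half the patch extent and produce inter-tile offsets. The band
limit guarantees the denoiser is conservative at low spatial frequencies;
set `highpass_sigma=0` to disable.

Desk-scale configuration (used throughout the tests): 64 px patches,
channels (16, 32), 20 epochs, learning rate 10⁻³ (the shorter schedule
needs the faster rate to converge; the reference-scale default remains
5·10⁻⁴), ~200 training pairs from two phantom scenes × a 3×2 noise grid.
Training takes ~20 s on one CPU.

## Quality metrics

CNR and COV are computed over axis-aligned ROIs (0-based, half-open
rectangles) with unbiased standard deviations; degenerate denominators
return NaN rather than raising. The NPS is estimated from 64×64
half-overlapping sub-patches of a uniform ROI, each detrended by a fitted
polynomial surface of total degree 2 (absorbing the smooth background), as
`NPS = ΔxΔy/(M·NxNy) · Σ|DFT₂(residual)|²`. NNPS divides by the squared
large-area signal, taken as the mean of the full ROI before detrending (the
conventional reading). Radial averaging uses
bins one frequency-resolution wide up to Nyquist and excludes the
zero-frequency row and column, where detrending leakage concentrates. For
white noise of variance σ² at pitch Δ on mean μ the NNPS is flat at
σ²Δ²/μ², which the tests verify to 5% (Parseval). NNPS comparisons between
a noisy image and its denoised version use a 512×512 uniform region:
detector-NPS practice favours large uniform areas, and the lowest-frequency
bins of a small region contain too few modes for a stable per-bin
comparison.

## Synthetic phantoms

`make_phantom` builds a half-elliptical "breast-like" tissue support
anchored to the left edge with a thickness-like profile
`background + (plateau − background)·sqrt(1 − ρ²)` (plateau 1000,
background 50 by default, arbitrary units chosen so Poisson-scale noise is
meaningful), plus band-limited texture (Gaussian-filtered white noise,
σ = 8 px, 5% amplitude) inside the support, and optional bright
microcalcification-like discs of 0.1–1 mm diameter placed by rejection
sampling ≥ 10 px apart. Signal ROIs sit inside the tissue, background ROIs
outside; their placement is validated at construction. Scenes are bitwise
reproducible from their seed.

What the phantom does *not* emulate: anatomical texture statistics, detector
blur/MTF, fixed-pattern or correlated electronic noise, polyenergetic or
thickness-dependent scatter, and detector non-linearity. Passing tests
therefore demonstrate that the algorithms are implemented correctly and
behave as designed under their stated models — not that the trained desk-
scale denoiser transfers to clinical images.

## Problem sizes

The test suite and examples run at deliberately small scale: 256² phantoms
at 0.5 mm pitch, scatter kernels of radius ≤ 192 px, 192–200 training pairs
of 64 px patches for 20 epochs, and 10–20 Monte-Carlo repetitions for
variance measurements. These sizes were chosen so the complete suite runs in
a few minutes on a single CPU while leaving every statistical assertion
comfortable margins; all algorithms accept reference-scale parameters
unchanged.

## Known limitations

- The scatter estimator is an exact inverse of this package's own forward
  model, not a reconstruction of any commercial algorithm.
- The GAN is CPU-bound numpy; reference-scale training (256 px patches,
  ~55k pairs, 200 epochs) is out of reach without a GPU framework, and the
  package makes no claim about behaviour at that scale.
- The NLF estimator assumes a single affine mean–variance relation across
  the image; spatially varying gain or multi-segment NLFs are out of scope.
- Bilinear resizing uses corner-aligned sampling; half-pixel-centre
  conventions would shift results by a sub-pixel phase.
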