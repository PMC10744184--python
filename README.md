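# virtualgrid

Software anti-scatter grids ("virtual grids") estimate and subtract the
scattered-radiation component of a projection X-ray image. Removing the
scatter *signal* does not remove the noise it carried, so the corrected image
is left with amplified noise: for scatter-to-primary ratio S/P the residual
noise variance grows by roughly

```
Var(n_corrected) / Var(n_no_scatter) ≈ 1 + S/P = 1 / (1 − SF)
```

where SF = S/(S+P) is the scatter fraction. This package implements, end to
end and fully testable on synthetic mammography-like phantoms, a pipeline
that (1) simulates scatter with an analytic scatter point-spread function,
(2) corrects it by spectral inversion of the forward model, (3) quantifies
the residual noise with a Poisson–Gaussian noise-level function estimated
from homogeneous image blocks, (4) suppresses the noise with a residual-
learning GAN, and (5) evaluates image quality with CNR, COV, and the
normalized noise power spectrum (NNPS). It is aimed at medical-physics and
image-processing researchers who want a reproducible desk-scale testbed for
virtual-grid noise behaviour.

## The models

**Scatter.** A point of primary signal spreads as
`sPSF(r) = δ(r) + [SF/(1−SF)] · e^(−r/k) / (2πkr)`
with scatter fraction SF (default 0.39) and scatter range k (default
4.02 cm). The scatter term integrates to SF/(1−SF), so a uniform field of
value c maps to c/(1−SF) and its interior scatter fraction is exactly SF.
Correction inverts `I = P + P⊛S_k` spectrally:
`P̂ = F⁻¹[F(I)/(1 + F(S_k))]`.

**Noise.** Image noise follows the heteroscedastic model `y = x + η(x)ε`
with `η²(x) = αx + β²` (α: Poisson/quantum scale, β: Gaussian electronic
sigma). The noise-level function (NLF) is estimated from a single image by
tiling it into 16×16 blocks, keeping blocks whose Kendall-τ rank correlation
over adjacent-pixel pairs is consistent with pure noise, and fitting the
(mean, variance) points of those blocks with a first-degree L1 trend whose
slope and intercept give α̂ and β̂².

**Denoising.** An encoder–decoder generator maps a noisy 2D patch to its
predicted *noise* map (the clean estimate is input − prediction), trained
with MSE to exact noise labels plus a small adversarial term from a
convolutional discriminator, over a grid of 42 (α, β) noise levels. The
network stack (strided convolutions, transposed convolutions, batch norm,
Adam) is implemented in numpy with analytic gradients that are
finite-difference-verified in the test suite.

**Evaluation.** `CNR = (S_A − S_B)/√(σ_A² + σ_B²)`, `COV = σ_A/S_A` per ROI,
and NNPS = NPS/(large-area signal)² from detrended, half-overlapping
sub-patches of a uniform region, radially averaged up to the Nyquist
frequency 1/(2·pixel pitch).

## Worked example

Run the full phantom pipeline (simulate scatter on a synthetic breast-like
scene, correct it, estimate the residual NLF, train a desk-scale GAN, denoise,
evaluate):

```
vgrid run-all --seed 1 --output-dir demo
```

or equivalently from Python:

```python
from virtualgrid import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(seed=1, output_dir="demo"))
print(result.nlf.alpha_hat, result.nlf.beta_hat)
print(result.report_noisy.cov, result.report_denoised.cov)
```

With the default configuration (256×256 phantom at 0.5 mm pitch, SF = 0.39,
measurement noise α = 4, β = 8, 20-epoch training on 192 pairs of 64 px
patches) this prints:

```
nlf alpha,beta: 6.762 5.306   (155 homogeneous blocks)
cov noisy:    {'tissue_center': 0.0860, 'tissue_upper': 0.1512, 'tissue_lower': 0.0911}
cov denoised: {'tissue_center': 0.0355, 'tissue_upper': 0.0814, 'tissue_lower': 0.0370}
cnr noisy:    {'tissue_center': 10.762, 'tissue_upper':  6.202, 'tissue_lower': 10.166}
cnr denoised: {'tissue_center': 24.632, 'tissue_upper': 11.410, 'tissue_lower': 23.690}
```

Two things are worth reading off these numbers. First, the estimated Poisson
scale α̂ ≈ 6.8 exceeds the α = 4 that was applied: scatter correction
amplified the noise variance by ≈ 1/(1−0.39) ≈ 1.64, exactly the
virtual-grid noise-amplification effect the pipeline exists to counter.
Second, the denoiser roughly halves the COV in every ROI and more than
doubles the CNR, while the NNPS report in `demo/quality.yaml` shows the
denoised spectrum at or below the noisy one in every frequency bin.

Each stage is also exposed individually (`vgrid phantom`,
`vgrid simulate-scatter`, `vgrid correct`, `vgrid nlf-estimate`,
`vgrid train`, `vgrid denoise`, `vgrid evaluate`); images travel as 16-bit
TIFF/PNG with YAML pixel-pitch sidecars.

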