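# Methods

This note records the models, parameter choices and numerical conventions
behind `endofuse`, and what the synthetic tests do and do not establish.

## Colour model

Enhancement operates on brightness only, so the colour model must make
"intensity" an independent coordinate. The classic geometric HSI model is
used: `I = (R+G+B)/3`, `S = 1 − min(R,G,B)/I`, hue from the arccos
formula reflected to `2π − H` where `B > G`. Achromatic pixels take
`H = 0, S = 0` by convention so RGB→HSI→RGB is an identity (verified to
1e−6 on in-gamut images). Out-of-gamut results of the inverse transform
are clipped rather than renormalized — clipping is monotone and cheap,
and the fused intensity rarely leaves gamut by more than quantization
noise; clip events are logged at debug level. HSV/HSL were rejected
because their "value"/"lightness" mixes channels with max/min operators,
so editing it does not leave perceived chroma alone the way the channel
mean does.

## Sub-image generation

The three generators and their defaults (none of these defaults encodes a
measured optimum; they are standard practice values, all configurable):

* **CLAHE** — tiles 8×8, clip limit 0.01 of the tile pixel count,
  256-bin histograms. The mapping uses the *midpoint-CDF* rule
  `m(v) = (cdf(v) − h(v)/2) / N`: unlike the plain CDF rule it maps a
  constant tile (almost) to itself for every clip limit, which keeps flat
  anatomy flat. Clipped excess is redistributed uniformly over all 256
  bins in one pass. Pixels are bilinearly interpolated between the
  mappings of the four surrounding tile centres; coordinates outside the
  centre lattice clamp to the nearest tile.
* **Entropy-maximizing brightening** — `I^γ` for γ on a grid
  0.30…1.00 step 0.05, scored by the Shannon entropy of the 256-bin
  histogram of the result. A transparent grid search is used instead of a
  black-box optimizer: the objective has plateaus and the grid makes the
  chosen γ reproducible and directly testable against exhaustive
  evaluation. Ties break toward γ = 1, then the smaller γ, so a constant
  image is returned unchanged. Only γ ≤ 1 (brightening) is searched —
  the method targets under-exposed frames.
* **Detail enhancement** — an exact local Laplacian filter,
  σ = 0.3, α = 0.25, 4 pyramid levels. The remapping
  `r(i) = g + sign(i−g)·σ·(|i−g|/σ)^α` amplifies deviations below σ and
  passes larger jumps through unchanged, so edges above σ survive within
  a fraction of a percent while texture is boosted. The *exact*
  formulation (every Laplacian coefficient rebuilt from an image remapped
  around its own Gaussian coefficient) was chosen over the fast
  interpolated variant because it is verifiable coefficient-by-
  coefficient against a literal oracle. To make it fast enough for
  routine use, the implementation exploits that each output coefficient
  is a *fixed linear functional* of the remapped image: the 1-D impulse
  responses of `down^l` and `up(down^{l+1})` are derived numerically once
  per level (per parity class — the up/down composite is 2-periodic) and
  the coefficients of a whole level are then accumulated by strided
  offset sums. This is algebraically identical to the literal evaluation
  (agreement ≈ 1e−16 in the tests) at about 1.7 s for a 256×256 plane.
  All code paths share one border convention: symmetric padding by a
  margin exceeding the deepest coefficient's support, zero extension
  beyond it.

## Decomposition

One DWT level (Haar by default; any orthogonal PyWavelets name works) —
one level is what the four-coefficient LL/LH/HL/HH structure implies, and
a `levels` hook is deliberately absent from the default path. Odd
dimensions use symmetric extension and the inverse is cropped.

The guided filter follows the classic box-filter formulation:
`a_k = cov(G, I)/(var(G) + ε)`, `b_k = mean(I) − a_k·mean(G)` per
(2r+1)² window, output averaged over all windows containing a pixel;
defaults r = 2, ε = 1e−3 on [0, 1] data (typical values from the
edge-preserving-filter literature). Windows where `var + ε = 0` fall
back to `a = 0, b = mean`, which keeps constant regions constant and the
ε = 0 self-guidance identity exact.

Two refinement modes exist because the decomposition scheme pairs a
full-resolution intensity with half-resolution coefficients and the
pairing is genuinely underdetermined:

* `cross` (default): each detail band, min-max rescaled to [0, 1]
  (constant band → all 0.5), guides a filter applied to the 2×2-block-
  mean intensity; the output is mean-centred before use so the detail
  slot keeps its zero-DC property and the inverse DWT suffers no
  brightness shift. The 2×2 block mean is the minimal resampling
  consistent with decimated DWT geometry. For wavelets longer than Haar
  the bands carry extra boundary coefficients; the half-resolution plane
  is edge-padded to the band shape.
* `self`: each band guided by itself — a numerically conservative
  edge-preserving refinement that reduces to the identity at ε = 0,
  which is what makes the end-to-end degenerate-identity test possible.

Structure transfer in `cross` mode is probed with a directional fixture
(localized horizontal stripes: strong LH, empty HH); on such input the
|LH|-guided refined component correlates with |LH| at ≈ 0.99 versus
≈ 0.08 with |HH|. On the phantom battery the transfer is present but
weak — low-light phantoms have little band energy — so the directional
fixture, not the phantom, carries this assertion.

## Fusion

LL fuses by element-wise maximum (brightest background wins). Detail
components fuse by per-pixel weights `W_k = γ₁·C_k + γ₂·E_k` with
γ₁ = 0.4, γ₂ = 0.6 (entropy prioritized), computed **on the refined
components** (they are what is fused). C is the absolute deviation of a
pixel from its 8-neighbour mean; E the base-2 entropy of the 3×3
neighbourhood quantized to 8 levels after min-max rescaling — 8 bins
because a 3×3 window holds only 9 samples and finer quantization
saturates entropy at log₂9 almost everywhere. Weights normalize to sum
to 1 per pixel; all-zero pixels (three locally constant components) get
1/3 each. The two-input weighted rule generalizes to the pipeline's
three sub-images as the natural n-image convex combination — without
normalization the weighted sum would scale band amplitudes arbitrarily,
while convexity bounds the fused value by the band extremes.

Two bit-level conventions are part of the contract, not accidents:

* every sum over the three sub-images (weight denominators, fused
  details) accumulates in per-pixel ascending value order, so fusion is
  bit-identical under permutation of the sub-image order;
* 3×3 neighbour sums accumulate as a balanced pairwise tree over the
  row-major offset order, which a literal per-pixel loop reproduces
  bit-for-bit and which is exactly zero-deviation on constant planes
  (power-of-two doublings are exact in binary floating point).

## Metrics

The evaluation battery is implemented from the metrics' source
definitions with their published defaults:

* **Entropy** — 256-bin histogram of the 8-bit-quantized intensity.
* **CII** — ratio of mean 3×3 local contrast `(max−min)/(max+min+1e−12)`
  after vs before; undefined (raises) for a constant original.
* **PSNR** — `10·log₁₀(1/MSE)` on [0, 1]; identical images return an
  `inf` sentinel rather than a cap (report writers print "inf").
* **SSIM** — 11×11 Gaussian window σ = 1.5, K₁ = 0.01, K₂ = 0.03,
  dynamic range 1 (scikit-image backend, cross-checked against a literal
  windowed oracle to 1e−8).
* **PCQI** — 11×11 Gaussian-weighted patches on the 0–255 scale, C = 3,
  L = 256; per patch the product of a signal-strength term
  `(4/π)·atan((σ₁₂+C)/(σ₁₁+C))`, a structure term
  `(σ₁₂+C)/(σ₁σ₂+C)` and a mean term `exp(−|μ₁−μ₂|/L)`.
* **PIQE** — MSCN coefficients (7×7 Gaussian local mean/std, +1
  stabilizer, 0–255 scale), 16×16 blocks, spatially active above MSCN
  variance 0.1. Active blocks are classified: *artifact-like* if any
  length-6 segment along a block edge has MSCN std < 0.1 (flat boundary
  inside an active block — contributes `1 − v`), and *noise-like* by the
  centre/surround std-ratio criterion (contributes `v`); the pooled
  score is `100·(Σ + 1)/(1 + N_active)`, clipped to [0, 100]. The
  block-level criteria follow the published block-classification scheme;
  only ordering, range and determinism are relied upon downstream.

Colour inputs are reduced to the intensity plane before single-plane
metrics, consistent with the intensity-only pipeline.

## Synthetic phantoms

A phantom stacks the degradations a single-illuminant endoscope frame
exhibits: a smooth reddish-pink base (coarse 8×8 random grids, cubic
upsampling), a radial vignette `1 − s·(r/r_max)²`, quadratic-Bezier
vessel strokes of ~1–2 px half-width darkened multiplicatively,
saturated highlight discs (which overwrite vessels, keeping the masks
disjoint), a global low-light exponent `I^γ` with γ ≥ 1, and additive
Gaussian sensor noise (σ = 0.01 by default). All randomness flows
through a counter-based Philox generator keyed on the seed, so phantoms
are bit-identical across platforms.

The default battery holds six phantoms — dark (γ = 2.5, vignette 0.5)
vs normal (γ = 1.0, vignette 0.3), low vs high vessel density, with and
without highlights, at 128² and 256². Dark members land around mean
intensity 0.17 and normal ones around 0.48, either side of the 0.35
battery split.

What passing tests show: on inputs with the stated degradations the
pipeline raises histogram entropy and mean local contrast, preserves
range, shape and colour, and is deterministic. What they do not show:
performance on real endoscopic optics (chromatic aberration, motion
blur, compression artifacts, genuine mucosal texture statistics), or
perceptual quality as judged by clinicians — the phantom is a test
harness, not a realism claim.

## Problem sizes and runtime

Test and acceptance workloads are sized for a single CPU: oracle
comparisons run at 8×8–16×16 (they are O(N²·window) loops), perfect-
reconstruction checks at 64×64, and end-to-end enhancement on the
battery's 128² and 256² phantoms (~1–2 s each, dominated by the local
Laplacian filter). `scripts/acceptance.py` completes in a few seconds.

## Known limitations

* The brightening grid searches γ ≤ 1 only; over-exposed frames pass
  through with γ = 1 rather than being darkened.
* `cross`-mode refinement injects a filtered intensity into detail
  slots; with very noisy guidance bands the transferred structure is
  weak and the component approaches a mean-centred smoothed intensity.
* PIQE on strongly enhanced dark frames reads high because amplified
  sensor noise is genuinely noise — the score is honest but should be
  read alongside CII/entropy, not alone.
* The CLI processes one image per invocation; there is no batch mode.
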