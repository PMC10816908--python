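# endofuse

Low-light endoscopic image enhancement by multi-sub-image wavelet /
guided-filter fusion, with the quality metrics used to evaluate it and a
synthetic endoscopy-phantom generator so everything is testable without any
dataset.

## The problem

Endoscopic frames are lit by a single on-scope source: the periphery is
dark, the mucus layer throws saturated specular highlights, and the
vessels and texture clinicians rely on sit in poorly exposed regions.
Re-exposing is impossible — there is only one frame. `endofuse`
manufactures an exposure bracket from that single frame and fuses it:

1. **Sub-images.** The RGB input is converted to HSI (hue–saturation–
   intensity, with I = (R+G+B)/3 so colour and brightness separate
   exactly). Three complementary versions of the intensity plane are
   generated: CLAHE (local contrast in visible regions),
   entropy-maximizing gamma brightening `I^γ` with γ chosen by grid search
   over histogram entropy (recovers dark regions), and an exact local
   Laplacian filter (amplifies fine detail without halos).
2. **Decomposition.** Each sub-image gets a one-level 2-D DWT into
   LL / LH / HL / HH. Each detail band then serves as the *guidance image*
   of a guided filter applied to the half-resolution intensity,
   transferring that band's directional structure into a refined,
   edge-enhanced detail component.
3. **Fusion.** Approximation bands fuse by element-wise maximum,
   `A_fused = max(A_1, A_2, A_3)`. Detail components fuse as a per-pixel
   convex combination with weights `W_k = γ₁·C_k + γ₂·E_k` built from 3×3
   local contrast C and local entropy E (entropy prioritized, γ₂ > γ₁),
   normalized to sum to 1 per pixel.
4. **Reconstruction.** Inverse DWT of the fused bands gives the enhanced
   intensity, recombined with the *original* hue and saturation.

The metrics module provides global entropy, CII (contrast improvement
index), PIQE, PCQI, PSNR and SSIM.

## Worked example

```python
from endofuse import (
    PipelineConfig, cii, default_battery, enhance_detailed,
    global_entropy, piqe,
)

bundle = default_battery(42)[0]          # 128x128 dark phantom
res = enhance_detailed(bundle.image, PipelineConfig())
print(f"chosen brightening gamma : {res.subimages.chosen_gamma:.2f}")
print(f"entropy (bits)  in/out   : {global_entropy(bundle.image):.3f}"
      f" -> {global_entropy(res.output):.3f}")
print(f"contrast improvement CII : {cii(res.output, bundle.image):.3f}")
```

prints

```
chosen brightening gamma : 0.50
entropy (bits)  in/out   : 6.156 -> 6.383
contrast improvement CII : 1.099
```

The brightening stage picked γ = 0.5 (strong brightening — the phantom is
a low-light frame), the enhanced image carries 0.23 bits more histogram
entropy (more usable tonal levels), and mean 3×3 local contrast grew by
~10 %.

The same pipeline is scriptable from the shell:

```sh
endofuse synth --seed 42 -o phantoms/          # write the phantom battery
endofuse enhance phantoms/phantom_00.png -o enhanced.png
endofuse metrics enhanced.png -r phantoms/phantom_00.png
```

## Scope

The package enhances single RGB frames (PNG/JPEG/TIFF/BMP, 8- or 16-bit).
It does not do video, DICOM streams, ICC colour management, or learned
no-reference quality models; the phantom generator emulates endoscopic
degradations for testing and makes no claim of photorealism.
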