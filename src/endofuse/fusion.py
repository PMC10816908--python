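"""Fusion of the three sub-images' wavelet bands and full-image enhancement.

The approximation bands are fused by an element-wise maximum, which keeps
the best-exposed background from whichever sub-image provides it.  Each
detail slot is fused as a per-pixel convex combination whose weights come
from two 3x3 local features of the competing components,

    W_k = gamma1 * C_k + gamma2 * E_k,

where C is the absolute deviation of a pixel from its 8-neighbour mean
(local contrast) and E the Shannon entropy of the quantized 3x3
neighbourhood (local information density).  Entropy gets the larger weight
(``gamma2 > gamma1``) to prioritize detail preservation.  Weights are
normalized to sum to one per pixel, so fusion never leaves the range
spanned by its inputs.

All reductions over the three sub-images use per-pixel sorted summation,
making every fused result invariant — bit for bit — under permutation of
the sub-image order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .color import hsi_to_rgb, rgb_to_hsi, validate_rgb
from .config import PipelineConfig
from .decomposition import BandSet, idwt2, mlwtgf_decompose
from .subimage import SubImageSet, make_subimages

__all__ = [
    "EnhanceResult",
    "WeightMaps",
    "compute_weights",
    "enhance",
    "enhance_detailed",
    "fuse_and_reconstruct",
    "fuse_detail",
    "fuse_ll",
    "local_contrast_map",
    "local_entropy_map",
    "quantize_plane",
]


def _symmetric_sum(stack: np.ndarray) -> np.ndarray:
    """Sum over axis 0 in per-pixel ascending order: permutation-invariant."""
    return np.sum(np.sort(stack, axis=0), axis=0)


#: 3x3 neighbourhood offsets, row-major with the centre excluded.  The
#: neighbour sum accumulates as a balanced pairwise tree over this order,
#: which is bit-reproducible by a literal per-pixel loop and exactly zero
#: -deviation on constant planes (power-of-two doublings are exact).
NEIGHBOUR_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)


def _shifted(padded: np.ndarray, dy: int, dx: int, shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    return padded[1 + dy : 1 + dy + h, 1 + dx : 1 + dx + w]


def local_contrast_map(plane: np.ndarray) -> np.ndarray:
    """|pixel - mean of its 8 neighbours|, reflective borders."""
    a = np.asarray(plane, dtype=np.float64)
    if a.ndim != 2 or min(a.shape) < 3:
        raise ValueError("expected a 2-D plane of size >= 3 x 3")
    padded = np.pad(a, 1, mode="symmetric")
    s = [_shifted(padded, dy, dx, a.shape) for dy, dx in NEIGHBOUR_OFFSETS]
    total = ((s[0] + s[1]) + (s[2] + s[3])) + ((s[4] + s[5]) + (s[6] + s[7]))
    return np.abs(a - total / 8.0)


def quantize_plane(plane: np.ndarray, bins: int) -> np.ndarray:
    """Min-max rescale then quantize into ``bins`` levels (constant -> bin 0)."""
    a = np.asarray(plane, dtype=np.float64)
    lo, hi = float(a.min()), float(a.max())
    if hi <= lo:
        return np.zeros(a.shape, dtype=np.intp)
    return np.clip(np.floor((a - lo) / (hi - lo) * bins), 0, bins - 1).astype(np.intp)


def local_entropy_map(plane: np.ndarray, bins: int = 8) -> np.ndarray:
    """Shannon entropy (bits) of the quantized 3x3 neighbourhood of each pixel.

    The plane is min-max rescaled to [0, 1] before quantization into
    ``bins`` levels (a constant plane occupies a single bin and scores 0).
    Borders reflect.
    """
    a = np.asarray(plane, dtype=np.float64)
    if a.ndim != 2 or min(a.shape) < 3:
        raise ValueError("expected a 2-D plane of size >= 3 x 3")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    q = quantize_plane(a, bins)
    padded = np.pad(q, 1, mode="symmetric")
    ent = np.zeros(a.shape)
    for level in range(bins):
        hits = (padded == level).astype(np.int64)
        count = _shifted(hits, 0, 0, a.shape).copy()
        for dy, dx in NEIGHBOUR_OFFSETS:
            count += _shifted(hits, dy, dx, a.shape)
        p = count / 9.0
        with np.errstate(divide="ignore", invalid="ignore"):
            ent += np.where(count > 0, -p * np.log2(np.where(count > 0, p, 1.0)), 0.0)
    return ent


def fuse_ll(a1: np.ndarray, a2: np.ndarray, a3: np.ndarray) -> np.ndarray:
    """Element-wise maximum of the three approximation bands."""
    if not (a1.shape == a2.shape == a3.shape):
        raise ValueError("approximation bands must share one shape")
    return np.maximum(np.maximum(a1, a2), a3)


@dataclass(frozen=True)
class WeightMaps:
    """Per-pixel normalized fusion weights for the three detail components."""

    w1: np.ndarray
    w2: np.ndarray
    w3: np.ndarray
    gamma1: float
    gamma2: float

    @property
    def stack(self) -> np.ndarray:
        return np.stack([self.w1, self.w2, self.w3])


def compute_weights(
    bands: tuple[np.ndarray, np.ndarray, np.ndarray],
    gamma1: float,
    gamma2: float,
    bins: int = 8,
) -> WeightMaps:
    """Local contrast/entropy weighted fusion weights, normalized per pixel.

    Pixels where all three raw weights vanish (e.g. three locally constant
    components) fall back to equal weights 1/3.
    """
    if gamma1 < 0 or gamma2 < 0 or (gamma1 == 0 and gamma2 == 0):
        raise ValueError("gamma1, gamma2 must be >= 0 and not both 0")
    b1, b2, b3 = (np.asarray(b, dtype=np.float64) for b in bands)
    if not (b1.shape == b2.shape == b3.shape):
        raise ValueError("detail components must share one shape")
    raw = np.stack(
        [gamma1 * local_contrast_map(b) + gamma2 * local_entropy_map(b, bins) for b in (b1, b2, b3)]
    )
    total = _symmetric_sum(raw)
    zero = total == 0.0
    den = np.where(zero, 1.0, total)
    w = np.where(zero, 1.0 / 3.0, raw / den)
    return WeightMaps(w1=w[0], w2=w[1], w3=w[2], gamma1=gamma1, gamma2=gamma2)


def fuse_detail(
    bands: tuple[np.ndarray, np.ndarray, np.ndarray], weights: WeightMaps
) -> np.ndarray:
    """Per-pixel convex combination of the three detail components."""
    stack = np.stack([np.asarray(b, dtype=np.float64) for b in bands])
    if stack.shape[1:] != weights.w1.shape:
        raise ValueError("band and weight shapes differ")
    return _symmetric_sum(stack * weights.stack)


def fuse_and_reconstruct(
    bandsets: tuple[BandSet, BandSet, BandSet],
    gamma1: float = 0.4,
    gamma2: float = 0.6,
    bins: int = 8,
) -> np.ndarray:
    """Fuse three band sets and invert the wavelet transform.

    LL by element-wise max; each detail slot by contrast/entropy weighted
    combination of the guided-filter-refined components.  The result is
    cropped to the source shape and clipped to [0, 1].
    """
    names = {bs.wavelet_name for bs in bandsets}
    shapes = {bs.original_shape for bs in bandsets}
    if len(names) != 1 or len(shapes) != 1:
        raise ValueError("band sets must share wavelet and source shape")
    ll = fuse_ll(bandsets[0].ll, bandsets[1].ll, bandsets[2].ll)
    fused_details = []
    for slot in ("refined_lh", "refined_hl", "refined_hh"):
        components = tuple(getattr(bs, slot) for bs in bandsets)
        w = compute_weights(components, gamma1, gamma2, bins)
        fused_details.append(fuse_detail(components, w))
    out = idwt2(
        ll,
        *fused_details,
        wavelet_name=names.pop(),
        original_shape=shapes.pop(),
    )
    return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class EnhanceResult:
    """Full pipeline output plus the intermediates useful for inspection."""

    output: np.ndarray
    fused_intensity: np.ndarray
    subimages: SubImageSet
    bandsets: tuple[BandSet, BandSet, BandSet]
    config: PipelineConfig


def enhance_detailed(img: np.ndarray, config: PipelineConfig | None = None) -> EnhanceResult:
    """Run the full pipeline, returning intermediates alongside the output."""
    config = config or PipelineConfig()
    rgb = validate_rgb(img)
    hsi = rgb_to_hsi(rgb)
    subs = make_subimages(hsi, config.subimage_params())
    bandsets = tuple(
        mlwtgf_decompose(
            plane,
            wavelet_name=config.wavelet_name,
            gf=config.gf_params(),
            detail_mode=config.detail_mode,
        )
        for plane in subs.planes
    )
    fused = fuse_and_reconstruct(
        bandsets, gamma1=config.gamma1, gamma2=config.gamma2, bins=config.entropy_bins
    )
    out = hsi_to_rgb(
        type(hsi)(hue=hsi.hue, saturation=hsi.saturation, intensity=fused)
    )
    return EnhanceResult(
        output=out,
        fused_intensity=fused,
        subimages=subs,
        bandsets=bandsets,
        config=config,
    )


def enhance(img: np.ndarray, config: PipelineConfig | None = None) -> np.ndarray:
    """Enhance a low-light RGB image; colour is preserved, intensity fused."""
    return enhance_detailed(img, config).output
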