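"""Image quality metrics used to evaluate enhancement.

Two no-reference scores — global histogram entropy and PIQE — and four
comparative scores: the contrast improvement index CII (mean 3x3 Michelson
contrast after / before), the patch-based contrast quality index PCQI,
PSNR and SSIM.  Colour images are reduced to the intensity plane
(channel mean) first, consistent with the intensity-only pipeline.

PIQE follows the block-based perception model of Venkatanath et al.:
mean-subtracted contrast-normalized (MSCN) coefficients, 16x16 blocks,
spatial-activity gating by MSCN variance, then per-block classification
into blockiness-like artifacts (flat boundary segments inside an active
block) or Gaussian-noise-like distortion; the pooled score is 0-100 with
lower meaning better perceived quality.  PCQI follows Wang et al.: an
11x11 Gaussian-windowed product of signal-strength, structure and mean
comparison terms, averaged over the quality map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, maximum_filter, minimum_filter
from skimage.metrics import structural_similarity

from .subimage import histogram_entropy

__all__ = [
    "MetricsReport",
    "cii",
    "full_report",
    "global_entropy",
    "pcqi",
    "piqe",
    "psnr",
    "ssim",
]

_EPS = 1e-12


def _to_plane(img: np.ndarray) -> np.ndarray:
    a = np.asarray(img, dtype=np.float64)
    if a.ndim == 3 and a.shape[2] == 3:
        a = a.mean(axis=2)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D plane or H x W x 3 image, got {a.shape}")
    return a


def global_entropy(img: np.ndarray) -> float:
    """Shannon entropy (bits) of the 8-bit-quantized intensity histogram."""
    return histogram_entropy(_to_plane(img))


def cii(enhanced: np.ndarray, original: np.ndarray) -> float:
    """Contrast improvement index: mean 3x3 local contrast ratio.

    Local contrast per window is ``(max - min) / (max + min + 1e-12)``.
    Raises on a constant original (no contrast to improve).
    """
    e = _to_plane(enhanced)
    o = _to_plane(original)
    if e.shape != o.shape:
        raise ValueError("shapes differ")

    def mean_contrast(a: np.ndarray) -> float:
        mx = maximum_filter(a, size=3, mode="reflect")
        mn = minimum_filter(a, size=3, mode="reflect")
        return float(((mx - mn) / (mx + mn + _EPS)).mean())

    denom = mean_contrast(o)
    if denom == 0.0:
        raise ValueError("original image is constant; CII undefined")
    return mean_contrast(e) / denom


def psnr(enhanced: np.ndarray, reference: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB on [0, 1] data; inf for identical."""
    e = np.asarray(enhanced, dtype=np.float64)
    r = np.asarray(reference, dtype=np.float64)
    if e.shape != r.shape:
        raise ValueError("shapes differ")
    mse = float(np.mean((e - r) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(1.0 / mse)


def ssim(enhanced: np.ndarray, reference: np.ndarray) -> float:
    """Mean SSIM: 11x11 Gaussian window sigma=1.5, K1=0.01, K2=0.03."""
    e = _to_plane(enhanced)
    r = _to_plane(reference)
    if e.shape != r.shape:
        raise ValueError("shapes differ")
    if min(e.shape) < 11:
        raise ValueError("images must be at least 11 x 11")
    return float(
        structural_similarity(
            e,
            r,
            data_range=1.0,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
        )
    )


def _gaussian_window(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    half = (size - 1) / 2.0
    y, x = np.mgrid[-half : half + 1, -half : half + 1]
    w = np.exp(-(x * x + y * y) / (2.0 * sigma * sigma))
    return w / w.sum()


def pcqi(enhanced: np.ndarray, reference: np.ndarray) -> tuple[float, np.ndarray]:
    """Patch-based contrast quality index and its quality map.

    Per 11x11 Gaussian-weighted patch (valid positions only), the score is
    the product of a signal-strength comparison ``(4/pi) * atan((s12+C)/(s11+C))``,
    a structure comparison ``(s12+C)/(s1*s2+C)`` and a mean-intensity
    comparison ``exp(-|mu1-mu2|/L)``, with C=3 and L=256 on the 0-255
    scale; identical images score exactly 1.
    """
    r = _to_plane(reference) * 255.0
    e = _to_plane(enhanced) * 255.0
    if r.shape != e.shape:
        raise ValueError("shapes differ")
    size = 11
    if min(r.shape) < size:
        raise ValueError("images must be at least 11 x 11")
    w = _gaussian_window(size, 1.5)
    C, L = 3.0, 256.0

    def wmaps(a: np.ndarray, b: np.ndarray):
        va = np.lib.stride_tricks.sliding_window_view(a, (size, size))
        vb = np.lib.stride_tricks.sliding_window_view(b, (size, size))
        mu_a = np.tensordot(va, w, axes=([2, 3], [0, 1]))
        mu_b = np.tensordot(vb, w, axes=([2, 3], [0, 1]))
        ab = np.tensordot(va * vb, w, axes=([2, 3], [0, 1]))
        return mu_a, mu_b, ab

    mu1, mu2, m12 = wmaps(r, e)
    _, _, m11 = wmaps(r, r)
    _, _, m22 = wmaps(e, e)
    s11 = np.maximum(m11 - mu1 * mu1, 0.0)
    s22 = np.maximum(m22 - mu2 * mu2, 0.0)
    s12 = m12 - mu1 * mu2
    term_strength = (4.0 / np.pi) * np.arctan((s12 + C) / (s11 + C))
    term_structure = (s12 + C) / (np.sqrt(s11) * np.sqrt(s22) + C)
    term_mean = np.exp(-np.abs(mu1 - mu2) / L)
    qmap = term_strength * term_structure * term_mean
    return float(qmap.mean()), qmap


_BLOCK = 16
_ACTIVITY_T = 0.1
_SEGMENT_T = 0.1
_SEGMENT_LEN = 6


def _mscn(plane255: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sigma_g = 7.0 / 6.0
    mu = gaussian_filter(plane255, sigma_g, radius=3, mode="nearest")
    var = gaussian_filter(plane255 * plane255, sigma_g, radius=3, mode="nearest") - mu * mu
    sigma = np.sqrt(np.abs(var))
    return (plane255 - mu) / (sigma + 1.0), sigma


def _flat_boundary_segment(block: np.ndarray) -> bool:
    edges = (block[0, :], block[-1, :], block[:, 0], block[:, -1])
    for edge in edges:
        view = np.lib.stride_tricks.sliding_window_view(edge, _SEGMENT_LEN)
        if np.any(view.std(axis=1) < _SEGMENT_T):
            return True
    return False


def _noise_like(mscn_block: np.ndarray) -> bool:
    """Gaussian-noise criterion: high MSCN spread with a centre/surround
    std ratio near the block spread itself (no dominant structure)."""
    block_sigma = float(mscn_block.std())
    n = mscn_block.shape[1]
    c0 = n // 2 - 1
    center = mscn_block[:, c0 : c0 + 2]
    surround = np.delete(mscn_block, [c0, c0 + 1], axis=1)
    sur_std = float(surround.std())
    cen_sur = float(center.std()) / sur_std if sur_std > 0 else 0.0
    beta = abs(block_sigma - cen_sur) / (max(block_sigma, cen_sur) + _EPS)
    return block_sigma > 2.0 * beta


def piqe(img: np.ndarray) -> float:
    """Perception-based no-reference quality score in [0, 100]; lower is better."""
    plane = _to_plane(img)
    if min(plane.shape) < _BLOCK:
        raise ValueError(f"image must be at least {_BLOCK} x {_BLOCK}")
    mscn, _ = _mscn(plane * 255.0)
    h = (plane.shape[0] // _BLOCK) * _BLOCK
    w = (plane.shape[1] // _BLOCK) * _BLOCK

    n_active = 0
    dist_score = 0.0
    for i in range(0, h, _BLOCK):
        for j in range(0, w, _BLOCK):
            blk = mscn[i : i + _BLOCK, j : j + _BLOCK]
            v = float(blk.var())
            if v <= _ACTIVITY_T:
                continue
            n_active += 1
            # blockiness-like artifacts sit in mostly-flat blocks (low v);
            # noise fills the block (high v) — each contributes accordingly
            if _flat_boundary_segment(blk):
                dist_score += 1.0 - v
            if _noise_like(blk):
                dist_score += v
    score = 100.0 * (dist_score + 1.0) / (1.0 + n_active)
    return float(np.clip(score, 0.0, 100.0))


@dataclass(frozen=True)
class MetricsReport:
    """The evaluation battery for one enhanced image.

    ``cii``, ``pcqi``, ``psnr`` and ``ssim`` are None when no reference
    image was supplied.
    """

    entropy: float
    piqe: float
    cii: float | None = None
    pcqi: float | None = None
    psnr: float | None = None
    ssim: float | None = None

    def to_dict(self) -> dict:
        d = {"entropy": self.entropy, "piqe": self.piqe}
        for key in ("cii", "pcqi", "psnr", "ssim"):
            val = getattr(self, key)
            if val is not None:
                d[key] = "inf" if val == float("inf") else val
        return d


def full_report(img: np.ndarray, reference: np.ndarray | None = None) -> MetricsReport:
    """All applicable metrics for an image, optionally against a reference."""
    if reference is None:
        return MetricsReport(entropy=global_entropy(img), piqe=piqe(img))
    return MetricsReport(
        entropy=global_entropy(img),
        piqe=piqe(img),
        cii=cii(img, reference),
        pcqi=pcqi(img, reference)[0],
        psnr=psnr(np.asarray(img, dtype=np.float64), np.asarray(reference, dtype=np.float64)),
        ssim=ssim(img, reference),
    )
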