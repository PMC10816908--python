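"""Wavelet/guided-filter decomposition of an intensity plane.

Each sub-image's intensity layer is split by a one-level 2-D discrete
wavelet transform into the approximation band LL and the horizontal,
vertical and diagonal detail bands LH/HL/HH.  The detail bands then act as
*guidance images* for a guided filter applied to the (half-resolution)
intensity, which transfers each band's directional structure into an
edge-enhanced detail component used at fusion time.

The guided filter output is locally a linear function of the guidance:
per window of radius ``radius``, ``a = cov(G, I) / (var(G) + eps)`` and
``b = mean(I) - a * mean(G)``; a pixel's output averages ``a * G + b``
over every window containing it.  All window means are box filters with
reflective borders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.ndimage import uniform_filter

__all__ = [
    "BandSet",
    "GuidedFilterParams",
    "dwt2",
    "guided_filter",
    "idwt2",
    "mlwtgf_decompose",
]

DETAIL_MODES = ("cross", "self")


@dataclass(frozen=True)
class GuidedFilterParams:
    """Guided filter window half-width and regularization."""

    radius: int = 2
    eps: float = 1e-3

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.eps < 0:
            raise ValueError("eps must be >= 0")


@dataclass(frozen=True)
class BandSet:
    """One plane's wavelet bands plus guided-filter-refined detail components."""

    ll: np.ndarray
    lh: np.ndarray
    hl: np.ndarray
    hh: np.ndarray
    refined_lh: np.ndarray
    refined_hl: np.ndarray
    refined_hh: np.ndarray
    wavelet_name: str
    original_shape: tuple[int, int]

    @property
    def refined(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.refined_lh, self.refined_hl, self.refined_hh)


def _wavelet(name: str) -> pywt.Wavelet:
    try:
        return pywt.Wavelet(name)
    except ValueError as exc:
        raise ValueError(f"unknown wavelet name {name!r}") from exc


def dwt2(
    plane: np.ndarray, wavelet_name: str = "haar"
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One-level separable 2-D DWT -> (ll, lh, hl, hh), symmetric extension.

    lh/hl hold horizontal/vertical detail, hh diagonal.  Band shapes are
    ``ceil(H/2) x ceil(W/2)``.
    """
    w = _wavelet(wavelet_name)
    a = np.asarray(plane, dtype=np.float64)
    if a.ndim != 2:
        raise ValueError("expected a 2-D plane")
    ll, (lh, hl, hh) = pywt.dwt2(a, w, mode="symmetric")
    return ll, lh, hl, hh


def idwt2(
    ll: np.ndarray,
    lh: np.ndarray,
    hl: np.ndarray,
    hh: np.ndarray,
    wavelet_name: str = "haar",
    original_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Inverse of :func:`dwt2`, cropped to ``original_shape`` when given."""
    shapes = {np.asarray(b).shape for b in (ll, lh, hl, hh)}
    if len(shapes) != 1:
        raise ValueError(f"band shapes differ: {shapes}")
    w = _wavelet(wavelet_name)
    out = pywt.idwt2((ll, (lh, hl, hh)), w, mode="symmetric")
    if original_shape is not None:
        h, wd = original_shape
        if out.shape[0] < h or out.shape[1] < wd:
            raise ValueError(
                f"bands of shape {next(iter(shapes))} cannot reconstruct {original_shape}"
            )
        out = out[:h, :wd]
    return out


def _box(a: np.ndarray, radius: int) -> np.ndarray:
    # scipy 'reflect' == symmetric edge-repeating reflection
    return uniform_filter(a, size=2 * radius + 1, mode="reflect")


def guided_filter(
    input_plane: np.ndarray, guidance: np.ndarray, params: GuidedFilterParams
) -> np.ndarray:
    """Classic guided filter (He et al. box-filter formulation)."""
    p = np.asarray(input_plane, dtype=np.float64)
    g = np.asarray(guidance, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"input {p.shape} and guidance {g.shape} shapes differ")
    if p.ndim != 2:
        raise ValueError("expected 2-D planes")
    r, eps = params.radius, params.eps
    if min(p.shape) < 2 * r + 1:
        raise ValueError(f"plane {p.shape} smaller than window {2 * r + 1}")

    mean_g = _box(g, r)
    mean_p = _box(p, r)
    cov_gp = _box(g * p, r) - mean_g * mean_p
    var_g = _box(g * g, r) - mean_g * mean_g
    den = var_g + eps
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(den > 0.0, cov_gp / np.where(den > 0.0, den, 1.0), 0.0)
    b = mean_p - a * mean_g
    return _box(a, r) * g + _box(b, r)


def _half_res(plane: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    """2x2 block mean, padded symmetrically when a dimension is odd."""
    a = np.asarray(plane, dtype=np.float64)
    ph = a.shape[0] % 2
    pw = a.shape[1] % 2
    if ph or pw:
        a = np.pad(a, ((0, ph), (0, pw)), mode="symmetric")
    out = a.reshape(a.shape[0] // 2, 2, a.shape[1] // 2, 2).mean(axis=(1, 3))
    # longer wavelets carry extra boundary coefficients; edge-pad to match
    dh = target_shape[0] - out.shape[0]
    dw = target_shape[1] - out.shape[1]
    if dh < 0 or dw < 0:
        raise ValueError(f"half-resolution shape {out.shape} exceeds bands {target_shape}")
    if dh or dw:
        out = np.pad(out, ((dh // 2, dh - dh // 2), (dw // 2, dw - dw // 2)), mode="edge")
    return out


def _normalize01(band: np.ndarray) -> np.ndarray:
    lo, hi = float(band.min()), float(band.max())
    if hi <= lo:
        return np.full_like(band, 0.5)
    return (band - lo) / (hi - lo)


def mlwtgf_decompose(
    intensity: np.ndarray,
    wavelet_name: str = "haar",
    gf: GuidedFilterParams | None = None,
    detail_mode: str = "cross",
) -> BandSet:
    """Wavelet decomposition with guided-filter-refined detail components.

    In mode ``"cross"`` (the default) each detail band, rescaled to [0, 1],
    guides a filter applied to the 2x2-block-mean intensity; the output is
    mean-centred so it remains a legitimate zero-DC detail component.  In
    mode ``"self"`` each band is guided by itself (plain edge-preserving
    refinement).  The approximation band LL is never filtered.
    """
    if detail_mode not in DETAIL_MODES:
        raise ValueError(f"detail_mode must be one of {DETAIL_MODES}")
    gf = gf or GuidedFilterParams()
    plane = np.asarray(intensity, dtype=np.float64)
    ll, lh, hl, hh = dwt2(plane, wavelet_name)

    refined = []
    if detail_mode == "cross":
        half = _half_res(plane, ll.shape)
        for band in (lh, hl, hh):
            out = guided_filter(half, _normalize01(band), gf)
            refined.append(out - out.mean())
    else:
        for band in (lh, hl, hh):
            refined.append(guided_filter(band, band, gf))

    return BandSet(
        ll=ll,
        lh=lh,
        hl=hl,
        hh=hh,
        refined_lh=refined[0],
        refined_hl=refined[1],
        refined_hh=refined[2],
        wavelet_name=wavelet_name,
        original_shape=plane.shape,
    )
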