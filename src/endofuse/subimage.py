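"""The three complementary sub-images generated from one intensity plane.

A single low-light endoscopic frame cannot be re-exposed, so the pipeline
manufactures its own exposure bracket from the intensity layer:

* **CLAHE** — contrast-limited adaptive histogram equalization lifts local
  contrast in already-visible regions without over-amplifying noise;
* **entropy-maximizing brightening** — a gamma mapping ``I**gamma`` chosen
  by grid search to maximize the histogram entropy of the result, which
  recovers structure in the dark regions;
* **edge-aware detail enhancement** — an exact local Laplacian filter that
  amplifies fine texture while leaving strong edges untouched.

Hue and saturation are never touched; they are carried alongside so the
fused intensity can be recombined with the original colour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._llf import local_laplacian_filter
from .color import HSIImage

__all__ = [
    "SubImageParams",
    "SubImageSet",
    "brighten_max_entropy",
    "clahe_enhance",
    "detail_enhance_llf",
    "histogram_entropy",
    "make_subimages",
]

_N_BINS = 256


def _default_gamma_grid() -> tuple[float, ...]:
    # brightening regime only: gamma <= 1
    return tuple(np.round(np.arange(0.30, 1.0001, 0.05), 2))


@dataclass(frozen=True)
class SubImageParams:
    """Tunables for the three sub-image generators.

    clahe_clip_limit
        Histogram clip as a fraction of the tile pixel count.
    clahe_tiles
        (rows, cols) of the CLAHE tile grid.
    gamma_grid
        Candidate exponents for the brightening search, in (0, 2].
    llf_sigma, llf_alpha, llf_levels
        Local Laplacian filter detail threshold, remap exponent (< 1 for
        amplification) and pyramid depth.
    """

    clahe_clip_limit: float = 0.01
    clahe_tiles: tuple[int, int] = (8, 8)
    gamma_grid: tuple[float, ...] = field(default_factory=_default_gamma_grid)
    llf_sigma: float = 0.3
    llf_alpha: float = 0.25
    llf_levels: int = 4

    def __post_init__(self) -> None:
        if self.clahe_clip_limit <= 0:
            raise ValueError("clahe_clip_limit must be > 0")
        if min(self.clahe_tiles) < 1:
            raise ValueError("clahe_tiles must be positive")
        grid = tuple(float(g) for g in self.gamma_grid)
        if not grid or any(not 0 < g <= 2 for g in grid):
            raise ValueError("gamma_grid entries must lie in (0, 2]")
        if list(grid) != sorted(set(grid)):
            raise ValueError("gamma_grid must be strictly increasing")
        object.__setattr__(self, "gamma_grid", grid)
        if not 0 < self.llf_sigma <= 1:
            raise ValueError("llf_sigma must lie in (0, 1]")
        if not 0 < self.llf_alpha < 1:
            raise ValueError("llf_alpha must lie in (0, 1)")
        if self.llf_levels < 2:
            raise ValueError("llf_levels must be >= 2")


@dataclass(frozen=True)
class SubImageSet:
    """The three enhanced intensity planes plus the parameters used."""

    clahe: np.ndarray
    brightened: np.ndarray
    detail: np.ndarray
    chosen_gamma: float
    params: SubImageParams

    @property
    def planes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.clahe, self.brightened, self.detail)


def _quantize255(plane: np.ndarray) -> np.ndarray:
    return np.rint(np.clip(plane, 0.0, 1.0) * 255.0).astype(np.intp)


def histogram_entropy(plane: np.ndarray) -> float:
    """Shannon entropy (bits) of the 256-bin histogram of an 8-bit quantized plane."""
    counts = np.bincount(_quantize255(plane).ravel(), minlength=_N_BINS)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _tile_mapping(tile: np.ndarray, clip_limit: float) -> np.ndarray:
    """Equalization lookup (256 entries in [0, 1]) from one tile's clipped histogram."""
    n = tile.size
    hist = np.bincount(_quantize255(tile).ravel(), minlength=_N_BINS).astype(np.float64)
    clip = max(clip_limit * n, 1.0)
    excess = np.maximum(hist - clip, 0.0).sum()
    hist = np.minimum(hist, clip) + excess / _N_BINS
    cdf = np.cumsum(hist)
    # midpoint-CDF rule: a constant tile maps (almost) to itself whatever the clip
    return (cdf - hist / 2.0) / n


def clahe_enhance(
    intensity: np.ndarray, clip_limit: float, tiles: tuple[int, int]
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on [0, 1] data.

    Per-tile 256-bin histograms are clipped at ``clip_limit * tile_pixels``,
    the excess is redistributed uniformly, and each pixel is mapped by
    bilinear interpolation between the equalization lookups of the four
    surrounding tile centres.
    """
    plane = np.asarray(intensity, dtype=np.float64)
    if plane.ndim != 2:
        raise ValueError("expected a 2-D intensity plane")
    rows, cols = tiles
    h, w = plane.shape
    if rows > h or cols > w:
        raise ValueError(f"tile grid {tiles} larger than image {plane.shape}")
    if clip_limit <= 0:
        raise ValueError("clip_limit must be > 0")

    row_edges = np.linspace(0, h, rows + 1).astype(int)
    col_edges = np.linspace(0, w, cols + 1).astype(int)
    maps = np.empty((rows, cols, _N_BINS))
    centers_r = np.empty(rows)
    centers_c = np.empty(cols)
    for i in range(rows):
        for j in range(cols):
            tile = plane[row_edges[i] : row_edges[i + 1], col_edges[j] : col_edges[j + 1]]
            maps[i, j] = _tile_mapping(tile, clip_limit)
    centers_r[:] = (row_edges[:-1] + row_edges[1:]) / 2.0 - 0.5
    centers_c[:] = (col_edges[:-1] + col_edges[1:]) / 2.0 - 0.5

    q = _quantize255(plane)
    yy = np.arange(h, dtype=np.float64)
    xx = np.arange(w, dtype=np.float64)
    i0 = np.clip(np.searchsorted(centers_r, yy, side="right") - 1, 0, rows - 1)
    j0 = np.clip(np.searchsorted(centers_c, xx, side="right") - 1, 0, cols - 1)
    i1 = np.minimum(i0 + 1, rows - 1)
    j1 = np.minimum(j0 + 1, cols - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fy = np.where(i1 > i0, (yy - centers_r[i0]) / (centers_r[i1] - centers_r[i0]), 0.0)
        fx = np.where(j1 > j0, (xx - centers_c[j0]) / (centers_c[j1] - centers_c[j0]), 0.0)
    fy = np.clip(fy, 0.0, 1.0)[:, None]
    fx = np.clip(fx, 0.0, 1.0)[None, :]

    I0 = i0[:, None]
    I1 = i1[:, None]
    J0 = j0[None, :]
    J1 = j1[None, :]
    v00 = maps[I0, J0, q]
    v01 = maps[I0, J1, q]
    v10 = maps[I1, J0, q]
    v11 = maps[I1, J1, q]
    out = (
        (1 - fy) * ((1 - fx) * v00 + fx * v01)
        + fy * ((1 - fx) * v10 + fx * v11)
    )
    return np.clip(out, 0.0, 1.0)


def brighten_max_entropy(
    intensity: np.ndarray, gamma_grid: tuple[float, ...] | list[float]
) -> tuple[np.ndarray, float]:
    """Gamma mapping chosen to maximize the 256-bin histogram entropy.

    Ties are broken toward the gamma closest to 1 (then the smaller gamma),
    so a constant image comes back unchanged.
    """
    plane = np.asarray(intensity, dtype=np.float64)
    grid = [float(g) for g in gamma_grid]
    if not grid:
        raise ValueError("gamma_grid must be non-empty")
    best_plane = None
    best_key = None
    best_gamma = None
    for g in grid:
        mapped = np.clip(plane, 0.0, 1.0) ** g
        # lexicographic: entropy first, then proximity to identity, then small g
        key = (histogram_entropy(mapped), -abs(g - 1.0), -g)
        if best_key is None or key > best_key:
            best_key, best_plane, best_gamma = key, mapped, g
    return best_plane, best_gamma


def detail_enhance_llf(
    intensity: np.ndarray, sigma: float, alpha: float, levels: int
) -> np.ndarray:
    """Edge-aware detail amplification (exact local Laplacian filter)."""
    return local_laplacian_filter(intensity, sigma, alpha, levels)


def make_subimages(img: HSIImage, params: SubImageParams | None = None) -> SubImageSet:
    """Build the three complementary sub-images from an HSI image's intensity."""
    params = params or SubImageParams()
    intensity = np.asarray(img.intensity, dtype=np.float64)
    clahe = clahe_enhance(intensity, params.clahe_clip_limit, params.clahe_tiles)
    brightened, gamma = brighten_max_entropy(intensity, params.gamma_grid)
    detail = detail_enhance_llf(
        intensity, params.llf_sigma, params.llf_alpha, params.llf_levels
    )
    return SubImageSet(
        clahe=clahe,
        brightened=brightened,
        detail=detail,
        chosen_gamma=gamma,
        params=params,
    )
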