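"""Independent brute-force oracles used to cross-check the implementation.

Every function here recomputes a quantity by literal per-pixel /
per-window / per-coefficient evaluation, sharing no code path with the
vectorised implementations it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import convolve2d

# 3x3 neighbourhood in the package's documented accumulation order
_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)


def contrast_map_loop(plane: np.ndarray) -> np.ndarray:
    """Literal |centre - neighbour mean| with symmetric borders.

    Neighbours sum as a balanced pairwise tree over the row-major order —
    the accumulation contract the package documents."""
    a = np.asarray(plane, dtype=np.float64)
    p = np.pad(a, 1, mode="symmetric")
    out = np.empty_like(a)
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            n = [p[1 + i + dy, 1 + j + dx] for dy, dx in _OFFSETS]
            total = ((n[0] + n[1]) + (n[2] + n[3])) + ((n[4] + n[5]) + (n[6] + n[7]))
            out[i, j] = abs(a[i, j] - total / 8.0)
    return out


def entropy_map_loop(plane: np.ndarray, bins: int) -> np.ndarray:
    """Literal per-window histogram entropy of the quantized plane."""
    a = np.asarray(plane, dtype=np.float64)
    lo, hi = a.min(), a.max()
    if hi > lo:
        q = np.clip(np.floor((a - lo) / (hi - lo) * bins), 0, bins - 1).astype(int)
    else:
        q = np.zeros(a.shape, dtype=int)
    p = np.pad(q, 1, mode="symmetric")
    out = np.empty(a.shape)
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            counts = np.bincount(p[i : i + 3, j : j + 3].ravel(), minlength=bins)
            ent = 0.0
            for c in counts:
                if c > 0:
                    prob = c / 9.0
                    ent += -prob * np.log2(prob)
            out[i, j] = ent
    return out


def weights_loop(
    bands: tuple[np.ndarray, np.ndarray, np.ndarray],
    gamma1: float,
    gamma2: float,
    bins: int,
) -> np.ndarray:
    """Per-pixel weighted-feature normalization, ascending-order sums."""
    features = [
        gamma1 * contrast_map_loop(b) + gamma2 * entropy_map_loop(b, bins)
        for b in bands
    ]
    h, w = features[0].shape
    out = np.empty((3, h, w))
    for i in range(h):
        for j in range(w):
            raws = [f[i, j] for f in features]
            total = 0.0
            for v in sorted(raws):
                total += v
            if total == 0.0:
                out[:, i, j] = 1.0 / 3.0
            else:
                for k in range(3):
                    out[k, i, j] = raws[k] / total
    return out


def guided_filter_loop(
    input_plane: np.ndarray, guidance: np.ndarray, radius: int, eps: float
) -> np.ndarray:
    """Literal per-window least-squares guided filter with reflective borders."""
    p = np.asarray(input_plane, dtype=np.float64)
    g = np.asarray(guidance, dtype=np.float64)
    r = radius
    gp = np.pad(g, r, mode="symmetric")
    pp = np.pad(p, r, mode="symmetric")
    h, w = p.shape
    a = np.empty((h, w))
    b = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            wg = gp[i : i + 2 * r + 1, j : j + 2 * r + 1]
            wp = pp[i : i + 2 * r + 1, j : j + 2 * r + 1]
            mg, mp = wg.mean(), wp.mean()
            cov = (wg * wp).mean() - mg * mp
            var = (wg * wg).mean() - mg * mg
            den = var + eps
            a[i, j] = cov / den if den > 0 else 0.0
            b[i, j] = mp - a[i, j] * mg
    ap = np.pad(a, r, mode="symmetric")
    bp = np.pad(b, r, mode="symmetric")
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            am = ap[i : i + 2 * r + 1, j : j + 2 * r + 1].mean()
            bm = bp[i : i + 2 * r + 1, j : j + 2 * r + 1].mean()
            out[i, j] = am * g[i, j] + bm
    return out


def clahe_loop(
    plane: np.ndarray, clip_limit: float, tiles: tuple[int, int]
) -> np.ndarray:
    """Literal CLAHE: per-tile clipped histograms, midpoint-CDF mappings,
    scalar bilinear interpolation between the four surrounding tiles."""
    a = np.asarray(plane, dtype=np.float64)
    rows, cols = tiles
    h, w = a.shape
    redges = np.linspace(0, h, rows + 1).astype(int)
    cedges = np.linspace(0, w, cols + 1).astype(int)

    def mapping(tile):
        q = np.rint(np.clip(tile, 0, 1) * 255).astype(int)
        hist = np.bincount(q.ravel(), minlength=256).astype(float)
        clip = max(clip_limit * tile.size, 1.0)
        excess = np.maximum(hist - clip, 0.0).sum()
        hist = np.minimum(hist, clip) + excess / 256
        cdf = np.cumsum(hist)
        return (cdf - hist / 2.0) / tile.size

    maps = [
        [
            mapping(a[redges[i] : redges[i + 1], cedges[j] : cedges[j + 1]])
            for j in range(cols)
        ]
        for i in range(rows)
    ]
    cr = [(redges[i] + redges[i + 1]) / 2.0 - 0.5 for i in range(rows)]
    cc = [(cedges[j] + cedges[j + 1]) / 2.0 - 0.5 for j in range(cols)]

    out = np.empty((h, w))
    for y in range(h):
        i0 = 0
        while i0 + 1 < rows and cr[i0 + 1] <= y:
            i0 += 1
        i1 = min(i0 + 1, rows - 1)
        fy = (y - cr[i0]) / (cr[i1] - cr[i0]) if i1 > i0 else 0.0
        fy = min(max(fy, 0.0), 1.0)
        for x in range(w):
            j0 = 0
            while j0 + 1 < cols and cc[j0 + 1] <= x:
                j0 += 1
            j1 = min(j0 + 1, cols - 1)
            fx = (x - cc[j0]) / (cc[j1] - cc[j0]) if j1 > j0 else 0.0
            fx = min(max(fx, 0.0), 1.0)
            v = int(round(min(max(a[y, x], 0.0), 1.0) * 255))
            v00 = maps[i0][j0][v]
            v01 = maps[i0][j1][v]
            v10 = maps[i1][j0][v]
            v11 = maps[i1][j1][v]
            out[y, x] = (1 - fy) * ((1 - fx) * v00 + fx * v01) + fy * (
                (1 - fx) * v10 + fx * v11
            )
    return np.clip(out, 0.0, 1.0)


# --- local Laplacian filter, literal per-coefficient ----------------------

_K1 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0
_K2 = np.outer(_K1, _K1)


def _down(a: np.ndarray) -> np.ndarray:
    return convolve2d(a, _K2, mode="same", boundary="fill")[::2, ::2]


def _up(a: np.ndarray) -> np.ndarray:
    z = np.zeros((a.shape[0] * 2, a.shape[1] * 2))
    z[::2, ::2] = a
    return 4.0 * convolve2d(z, _K2, mode="same", boundary="fill")


def _pad_sym(a: np.ndarray, pads) -> np.ndarray:
    out = a
    remaining = [list(p) for p in pads]
    while any(v > 0 for p in remaining for v in p):
        step = []
        for ax, (lo, hi) in enumerate(remaining):
            cap = out.shape[ax]
            t = (min(lo, cap), min(hi, cap))
            step.append(t)
            remaining[ax][0] -= t[0]
            remaining[ax][1] -= t[1]
        out = np.pad(out, step, mode="symmetric")
    return out


def llf_loop(img: np.ndarray, sigma: float, alpha: float, levels: int) -> np.ndarray:
    """Literal local Laplacian filter: remap the whole image around every
    Gaussian coefficient and rebuild the output pyramid one coefficient at
    a time."""
    a = np.asarray(img, dtype=np.float64)
    h, w = a.shape
    block = 2**levels
    margin = 6 * block
    ph = (-(h + 2 * margin)) % block
    pw = (-(w + 2 * margin)) % block
    p = _pad_sym(a, ((margin, margin + ph), (margin, margin + pw)))

    gp = [p]
    for _ in range(levels):
        gp.append(_down(gp[-1]))

    laps = []
    for level in range(levels):
        gmap = gp[level]
        lap = np.zeros_like(gmap)
        for u in range(gmap.shape[0]):
            for v in range(gmap.shape[1]):
                g = gmap[u, v]
                d = p - g
                mag = np.abs(d)
                q = np.where(
                    mag <= sigma, g + np.sign(d) * sigma * (mag / sigma) ** alpha, p
                )
                for _ in range(level):
                    q = _down(q)
                lap[u, v] = q[u, v] - _up(_down(q))[u, v]
        laps.append(lap)

    out = gp[levels]
    for level in range(levels - 1, -1, -1):
        out = _up(out) + laps[level]
    return np.clip(out[margin : margin + h, margin : margin + w], 0.0, 1.0)


# --- windowed quality metrics, literal ------------------------------------


def _gauss_win(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    half = (size - 1) // 2
    x = np.arange(-half, half + 1)
    k = np.exp(-(x[:, None] ** 2 + x[None, :] ** 2) / (2 * sigma**2))
    return k / k.sum()


def ssim_loop(x: np.ndarray, y: np.ndarray) -> float:
    """Literal Gaussian-windowed SSIM over valid window positions."""
    w = _gauss_win()
    c1 = (0.01) ** 2
    c2 = (0.03) ** 2
    h, wid = x.shape
    vals = []
    for i in range(5, h - 5):
        for j in range(5, wid - 5):
            wx = x[i - 5 : i + 6, j - 5 : j + 6]
            wy = y[i - 5 : i + 6, j - 5 : j + 6]
            mx = (w * wx).sum()
            my = (w * wy).sum()
            sxx = (w * wx * wx).sum() - mx * mx
            syy = (w * wy * wy).sum() - my * my
            sxy = (w * wx * wy).sum() - mx * my
            vals.append(
                ((2 * mx * my + c1) * (2 * sxy + c2))
                / ((mx * mx + my * my + c1) * (sxx + syy + c2))
            )
    return float(np.mean(vals))


def pcqi_loop(enhanced: np.ndarray, reference: np.ndarray) -> float:
    """Literal per-patch contrast quality index (0-255 scale, C=3, L=256)."""
    w = _gauss_win()
    r = reference * 255.0
    e = enhanced * 255.0
    C, L = 3.0, 256.0
    h, wid = r.shape
    vals = []
    for i in range(h - 10):
        for j in range(wid - 10):
            wr = r[i : i + 11, j : j + 11]
            we = e[i : i + 11, j : j + 11]
            mu1 = (w * wr).sum()
            mu2 = (w * we).sum()
            s11 = max((w * wr * wr).sum() - mu1 * mu1, 0.0)
            s22 = max((w * we * we).sum() - mu2 * mu2, 0.0)
            s12 = (w * wr * we).sum() - mu1 * mu2
            t1 = (4.0 / np.pi) * np.arctan((s12 + C) / (s11 + C))
            t2 = (s12 + C) / (np.sqrt(s11) * np.sqrt(s22) + C)
            t3 = np.exp(-abs(mu1 - mu2) / L)
            vals.append(t1 * t2 * t3)
    return float(np.mean(vals))


def cii_loop(enhanced: np.ndarray, original: np.ndarray) -> float:
    """Literal 3x3 (max-min)/(max+min) contrast ratio with symmetric borders."""

    def cmap(a):
        p = np.pad(a, 1, mode="symmetric")
        out = np.empty(a.shape)
        for i in range(a.shape[0]):
            for j in range(a.shape[1]):
                win = p[i : i + 3, j : j + 3]
                out[i, j] = (win.max() - win.min()) / (win.max() + win.min() + 1e-12)
        return out

    return float(cmap(enhanced).mean() / cmap(original).mean())
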