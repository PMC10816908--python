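"""Deterministic endoscopy-like phantom images for testing without data.

A phantom emulates the degradations a single-illuminant endoscope frame
shows: a smooth reddish-pink mucosal base, a radial vignette from the
on-axis light source, dark curvilinear vessels (the structures enhancement
must preserve), saturated specular highlights on the mucus layer, a global
low-light gamma and sensor noise.  Every random field is drawn from a
counter-based (Philox) generator keyed on the seed, so identical
parameters reproduce bit-identical phantoms on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import zoom as ndzoom

__all__ = ["PhantomBundle", "PhantomParams", "default_battery", "generate_phantom"]


@dataclass(frozen=True)
class PhantomParams:
    """Phantom recipe.

    vignette_strength
        Peak corner attenuation of the radial falloff in [0, 1].
    n_vessels / vessel_contrast
        Number of curvilinear dark strokes and their multiplicative
        darkening in [0, 1].
    n_highlights / highlight_radius
        Saturated white discs (specular reflections) and their radius, px.
    darkening_gamma
        Global low-light exponent (>= 1; 1 = normally lit).
    noise_sigma
        Additive Gaussian sensor noise standard deviation.
    """

    height: int = 128
    width: int = 128
    vignette_strength: float = 0.5
    n_vessels: int = 6
    vessel_contrast: float = 0.5
    n_highlights: int = 0
    highlight_radius: int = 5
    darkening_gamma: float = 2.5
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ValueError("phantom must be at least 8 x 8")
        if not 0.0 <= self.vignette_strength <= 1.0:
            raise ValueError("vignette_strength must lie in [0, 1]")
        if self.n_vessels < 0 or self.n_highlights < 0:
            raise ValueError("counts must be >= 0")
        if not 0.0 <= self.vessel_contrast <= 1.0:
            raise ValueError("vessel_contrast must lie in [0, 1]")
        if self.highlight_radius < 1:
            raise ValueError("highlight_radius must be >= 1")
        if self.darkening_gamma < 1.0:
            raise ValueError("darkening_gamma must be >= 1 (low-light regime)")
        if self.noise_sigma < 0.0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class PhantomBundle:
    """Phantom image plus the ground-truth structure masks."""

    image: np.ndarray
    vessel_mask: np.ndarray
    highlight_mask: np.ndarray
    params: PhantomParams


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.Philox(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))
    )


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], cells: int = 8) -> np.ndarray:
    """Low-frequency random field in [0, 1]: coarse grid, cubic upsampling."""
    coarse = rng.random((cells, cells))
    zoomed = ndzoom(coarse, (shape[0] / cells, shape[1] / cells), order=3, mode="nearest")
    zoomed = zoomed[: shape[0], : shape[1]]
    lo, hi = zoomed.min(), zoomed.max()
    if hi <= lo:
        return np.full(shape, 0.5)
    return (zoomed - lo) / (hi - lo)


def _vessel_mask(
    rng: np.random.Generator, shape: tuple[int, int], n_vessels: int
) -> np.ndarray:
    """Union of smooth curvilinear strokes, each ~1.5 px half-width."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_vessels):
        # quadratic Bezier with random endpoints and control point
        pts = rng.random((3, 2)) * [h - 1, w - 1]
        t = np.linspace(0.0, 1.0, 4 * max(h, w))[:, None]
        curve = ((1 - t) ** 2) * pts[0] + 2 * t * (1 - t) * pts[1] + (t**2) * pts[2]
        width = 1.0 + rng.random()
        for cy, cx in curve:
            y0, y1 = max(int(cy - 2), 0), min(int(cy + 3), h)
            x0, x1 = max(int(cx - 2), 0), min(int(cx + 3), w)
            sub = (yy[y0:y1, x0:x1] - cy) ** 2 + (xx[y0:y1, x0:x1] - cx) ** 2
            mask[y0:y1, x0:x1] |= sub <= width**2
    return mask


def generate_phantom(params: PhantomParams) -> PhantomBundle:
    """Deterministic phantom from the recipe; see module docstring for stages."""
    h, w = params.height, params.width
    shape = (h, w)

    base_rng = _rng(params.seed, 0)
    vessel_rng = _rng(params.seed, 1)
    highlight_rng = _rng(params.seed, 2)
    noise_rng = _rng(params.seed, 3)

    # 1. smooth reddish-pink mucosal base
    f_r = _smooth_field(base_rng, shape)
    f_g = _smooth_field(base_rng, shape)
    f_b = _smooth_field(base_rng, shape)
    img = np.stack(
        [
            0.70 + 0.20 * f_r,
            0.40 + 0.15 * f_g,
            0.35 + 0.12 * f_b,
        ],
        axis=-1,
    )

    # 2. radial vignette (single on-axis illuminant)
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / (cy**2 + cx**2)
    img *= (1.0 - params.vignette_strength * r2)[..., None]

    # 3. dark curvilinear vessels
    vessel_mask = _vessel_mask(vessel_rng, shape, params.n_vessels)
    img[vessel_mask] *= 1.0 - params.vessel_contrast

    # 4. saturated specular highlights (overwrite vessels where they overlap)
    highlight_mask = np.zeros(shape, dtype=bool)
    for _ in range(params.n_highlights):
        py = highlight_rng.integers(0, h)
        px = highlight_rng.integers(0, w)
        disc = (yy - py) ** 2 + (xx - px) ** 2 <= params.highlight_radius**2
        highlight_mask |= disc
    img[highlight_mask] = 0.98
    vessel_mask &= ~highlight_mask

    # 5. global low-light exponent, 6. sensor noise
    img = np.clip(img, 0.0, 1.0) ** params.darkening_gamma
    if params.noise_sigma > 0:
        img = img + noise_rng.normal(0.0, params.noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0)

    return PhantomBundle(
        image=img,
        vessel_mask=vessel_mask,
        highlight_mask=highlight_mask,
        params=params,
    )


#: (size, dark, high_texture, highlights) for the six battery phantoms.
_BATTERY_PLAN = (
    (128, True, True, 0),
    (128, True, False, 3),
    (256, True, True, 4),
    (128, False, True, 0),
    (128, False, False, 3),
    (256, False, True, 4),
)


def default_battery(seed: int) -> list[PhantomBundle]:
    """Six phantoms: dark/normal light x low/high texture x highlights.

    Dark phantoms use darkening_gamma 2.5 and a strong vignette; normal
    ones gamma 1.0 and a mild vignette.  Per-phantom seeds derive
    deterministically from the battery seed.
    """
    battery = []
    for idx, (size, dark, textured, n_high) in enumerate(_BATTERY_PLAN):
        params = PhantomParams(
            height=size,
            width=size,
            vignette_strength=0.5 if dark else 0.3,
            n_vessels=8 if textured else 2,
            vessel_contrast=0.5,
            n_highlights=n_high,
            highlight_radius=5,
            darkening_gamma=2.5 if dark else 1.0,
            noise_sigma=0.01,
            seed=seed * 10 + idx,
        )
        battery.append(generate_phantom(params))
    return battery


def is_dark(bundle: PhantomBundle) -> bool:
    """Battery split: dark phantoms carry the low-light gamma."""
    return bundle.params.darkening_gamma > 1.0


def _replace_params(bundle: PhantomBundle, **kwargs) -> PhantomBundle:
    return generate_phantom(replace(bundle.params, **kwargs))
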