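"""Pipeline configuration: every tunable, with plain-YAML persistence."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .decomposition import DETAIL_MODES, GuidedFilterParams
from .subimage import SubImageParams, _default_gamma_grid

__all__ = ["ConfigError", "PipelineConfig"]


class ConfigError(ValueError):
    """Invalid or inconsistent configuration."""


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the enhancement pipeline.

    Sub-image stage
        ``clahe_clip_limit`` (fraction of tile pixels), ``clahe_tiles``,
        ``gamma_grid`` (brightening search grid), ``llf_sigma`` /
        ``llf_alpha`` / ``llf_levels`` (detail enhancement).
    Decomposition stage
        ``wavelet_name``, ``gf_radius`` / ``gf_eps`` (guided filter),
        ``detail_mode`` ("cross": detail bands guide the intensity;
        "self": bands refine themselves).
    Fusion stage
        ``gamma1`` / ``gamma2`` weight the local-contrast and local-entropy
        terms (entropy is prioritized: gamma2 > gamma1), ``entropy_bins``
        quantization levels for the 3x3 local entropy.
    """

    clahe_clip_limit: float = 0.01
    clahe_tiles: tuple[int, int] = (8, 8)
    gamma_grid: tuple[float, ...] = field(default_factory=_default_gamma_grid)
    llf_sigma: float = 0.3
    llf_alpha: float = 0.25
    llf_levels: int = 4
    wavelet_name: str = "haar"
    gf_radius: int = 2
    gf_eps: float = 1e-3
    detail_mode: str = "cross"
    gamma1: float = 0.4
    gamma2: float = 0.6
    entropy_bins: int = 8
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        try:
            self.subimage_params()
            self.gf_params()
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
        if self.detail_mode not in DETAIL_MODES:
            raise ConfigError(f"detail_mode must be one of {DETAIL_MODES}")
        if self.gamma1 < 0 or self.gamma2 < 0:
            raise ConfigError("gamma1 and gamma2 must be >= 0")
        if not self.gamma2 > self.gamma1:
            raise ConfigError("gamma2 must exceed gamma1 (entropy priority)")
        if self.entropy_bins < 2:
            raise ConfigError("entropy_bins must be >= 2")

    def subimage_params(self) -> SubImageParams:
        return SubImageParams(
            clahe_clip_limit=self.clahe_clip_limit,
            clahe_tiles=tuple(self.clahe_tiles),
            gamma_grid=tuple(self.gamma_grid),
            llf_sigma=self.llf_sigma,
            llf_alpha=self.llf_alpha,
            llf_levels=self.llf_levels,
        )

    def gf_params(self) -> GuidedFilterParams:
        return GuidedFilterParams(radius=self.gf_radius, eps=self.gf_eps)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        """New config with the given fields replaced (validation re-runs)."""
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["clahe_tiles"] = list(self.clahe_tiles)
        d["gamma_grid"] = [float(g) for g in self.gamma_grid]
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"unparseable config file {path}: {exc}") from exc
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "clahe_tiles" in kwargs:
            kwargs["clahe_tiles"] = tuple(int(v) for v in kwargs["clahe_tiles"])
        if "gamma_grid" in kwargs:
            kwargs["gamma_grid"] = tuple(float(v) for v in kwargs["gamma_grid"])
        return cls(**kwargs)
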