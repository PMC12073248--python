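"""Structured configuration shared by the command-line entry points.

Two significance levels are exposed: ``alpha`` for binder screening and a
stricter ``strict_alpha`` for reporting "differentiating" features; both act
on BH-adjusted q-values.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["ScreenConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a configuration fails validation."""


@dataclass
class ScreenConfig:
    tol_ppm: float = 10.0
    tol_rt: float = 0.3
    min_area_fraction: float = 0.01
    alpha: float = 0.05
    strict_alpha: float = 0.001
    min_abs_log2fc: float = 0.585
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        problems = []
        if self.tol_ppm <= 0:
            problems.append("tol_ppm must be > 0")
        if self.tol_rt <= 0:
            problems.append("tol_rt must be > 0")
        if not (0 <= self.min_area_fraction < 1):
            problems.append("min_area_fraction must be in [0, 1)")
        if not (0 < self.alpha < 1):
            problems.append("alpha must be in (0, 1)")
        if not (0 < self.strict_alpha <= self.alpha):
            problems.append("strict_alpha must be in (0, alpha]")
        if self.min_abs_log2fc < 0:
            problems.append("min_abs_log2fc must be >= 0")
        if problems:
            raise ConfigError("; ".join(problems))

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "ScreenConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} must be a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: "str | Path") -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=True)

    def asdict(self) -> dict:
        return asdict(self)
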