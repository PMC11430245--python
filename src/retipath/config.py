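"""Run configuration: dataclasses, validation, (de)serialization.

Validation collects every problem before raising, so a bad config reports
all offending fields together instead of failing on the first one.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigurationError

__all__ = ["FieldSpec", "GeometrySpec", "FixtureSpec", "RunConfig", "load_config"]

_VALID_ENGINES = ("batch", "stream")
_VALID_FIXTURES = ("uniform", "disc", "bipartite", "random")


@dataclass
class FieldSpec:
    """Receptive-field parameters for one pathway."""

    size: int = 3
    center_radius: float = 0.5
    sigma_center: float | None = None
    sigma_surround: float | None = None

    def validate(self, prefix: str, errors: list[str]) -> None:
        if self.size < 1 or self.size % 2 == 0:
            errors.append(f"{prefix}.size: must be odd >= 1, got {self.size}")
        if self.center_radius < 0:
            errors.append(f"{prefix}.center_radius: must be >= 0, got {self.center_radius}")
        for name in ("sigma_center", "sigma_surround"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                errors.append(f"{prefix}.{name}: must be > 0, got {v}")


@dataclass
class GeometrySpec:
    """Fixation and eccentricity parameters.

    fovea_deg is the FULL foveal angle (default 5 degrees; the half-angle
    2.5 is what the mask uses). fixation defaults to the image center.
    """

    fixation: tuple[float, float] | None = None
    pixels_per_degree: float = 10.0
    fovea_deg: float = 5.0
    viewing_distance_mm: float | None = None
    rf_intercept: float = 3.0
    rf_slope: float = 0.5

    def validate(self, errors: list[str]) -> None:
        if self.pixels_per_degree <= 0:
            errors.append(f"geometry.pixels_per_degree: must be > 0, got {self.pixels_per_degree}")
        if self.fovea_deg < 0:
            errors.append(f"geometry.fovea_deg: must be >= 0, got {self.fovea_deg}")
        if self.viewing_distance_mm is not None and self.viewing_distance_mm < 0:
            errors.append("geometry.viewing_distance_mm: must be >= 0")
        if self.rf_intercept < 1:
            errors.append(f"geometry.rf_intercept: must be >= 1, got {self.rf_intercept}")
        if self.rf_slope < 0:
            errors.append(f"geometry.rf_slope: must be >= 0, got {self.rf_slope}")


@dataclass
class FixtureSpec:
    """Synthetic input used instead of an image file."""

    kind: str = "disc"
    size: int = 64
    value: tuple[int, int, int] = (128, 128, 128)
    fg: tuple[int, int, int] = (0, 0, 255)
    bg: tuple[int, int, int] = (255, 255, 0)
    radius: float | None = None

    def validate(self, errors: list[str]) -> None:
        if self.kind not in _VALID_FIXTURES:
            errors.append(f"fixture.kind: unknown kind {self.kind!r}, expected one of {_VALID_FIXTURES}")
        if self.size < 1:
            errors.append(f"fixture.size: must be >= 1, got {self.size}")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; validated before any computation."""

    input: str | None = None
    fixture: FixtureSpec | None = None
    out_dir: str = "retipath_out"
    geometry: GeometrySpec = field(default_factory=GeometrySpec)
    k_field: FieldSpec = field(default_factory=FieldSpec)
    m_field: FieldSpec = field(default_factory=FieldSpec)
    fixed_point: int | None = None  # None = floating point; else fraction bits
    engine: str = "batch"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        errors: list[str] = []
        if (self.input is None) == (self.fixture is None):
            errors.append("exactly one of input (image path) or fixture must be set")
        if self.input is not None and not Path(self.input).is_file():
            errors.append(f"input: file not found: {self.input}")
        if self.fixture is not None:
            self.fixture.validate(errors)
        self.geometry.validate(errors)
        self.k_field.validate("k_field", errors)
        self.m_field.validate("m_field", errors)
        if self.fixed_point is not None and not 1 <= self.fixed_point <= 24:
            errors.append(f"fixed_point: fraction bits must be in [1, 24], got {self.fixed_point}")
        if self.engine not in _VALID_ENGINES:
            errors.append(f"engine: must be one of {_VALID_ENGINES}, got {self.engine!r}")
        if errors:
            raise ConfigurationError(
                "invalid configuration:\n  - " + "\n  - ".join(errors)
            )

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def digest(self) -> str:
        """Stable hash of the configuration (recorded in the run report)."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _tupled(d: dict, key: str) -> None:
    if key in d and d[key] is not None:
        d[key] = tuple(d[key])


def config_from_dict(raw: dict[str, Any]) -> RunConfig:
    raw = dict(raw)
    if "geometry" in raw and raw["geometry"] is not None:
        g = dict(raw["geometry"])
        _tupled(g, "fixation")
        raw["geometry"] = GeometrySpec(**g)
    for key in ("k_field", "m_field"):
        if key in raw and raw[key] is not None:
            raw[key] = FieldSpec(**dict(raw[key]))
    if "fixture" in raw and raw["fixture"] is not None:
        f = dict(raw["fixture"])
        for c in ("value", "fg", "bg"):
            _tupled(f, c)
        raw["fixture"] = FixtureSpec(**f)
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigurationError(f"invalid configuration: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config file into a RunConfig (not yet validated)."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return config_from_dict(raw)
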