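"""Fovea and eccentricity geometry.

The fovea — the high-acuity retinal center — spans roughly 5 degrees of
visual angle (half-angle 2.5 deg). At viewing distance d it therefore
subtends a physical extent of d * tan(2.5 deg): about 43.7 mm at 1 m,
56.8 mm at 1.3 m. Whether that figure is a radius or a diameter is left
to the caller; the API names it "extent" deliberately.

Eccentricity is angular distance from the fixation point. Receptive-field
size grows with eccentricity; the default profile is linear in degrees,
``a + b * ecc``, snapped up to the nearest odd integer (kernels need a
center pixel), with a hook for user-supplied tabulated profiles. Only
monotone growth is biologically fixed; the slope is configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import DomainError

__all__ = [
    "LinearRFProfile",
    "RetinalGeometry",
    "fovea_extent",
    "eccentricity_deg",
    "eccentricity_map",
    "fovea_mask",
    "rf_size_at",
    "snap_to_odd",
]


def fovea_extent(distance_mm: float, half_angle_deg: float = 2.5) -> float:
    """Physical extent (mm) the fovea subtends at a viewing distance.

    distance * tan(half_angle); e.g. 1000 mm -> 43.66 mm for the default
    2.5 deg half-angle. Rounding to one decimal is left to reporting.
    """
    if distance_mm < 0:
        raise DomainError(f"viewing distance must be >= 0, got {distance_mm}")
    if half_angle_deg <= 0:
        raise DomainError(f"half angle must be > 0, got {half_angle_deg}")
    return distance_mm * math.tan(math.radians(half_angle_deg))


def snap_to_odd(x: float) -> int:
    """Smallest odd integer >= x (at least 1)."""
    n = max(1, math.ceil(x))
    return n if n % 2 == 1 else n + 1


@dataclass(frozen=True)
class LinearRFProfile:
    """Receptive-field size (pixels) as a + b * eccentricity (degrees)."""

    intercept: float = 3.0
    slope: float = 0.5

    def __post_init__(self) -> None:
        if self.slope < 0:
            raise DomainError("profile slope must be >= 0 (sizes grow with eccentricity)")
        if self.intercept < 1:
            raise DomainError("profile intercept must be >= 1")

    def __call__(self, ecc_deg: float) -> float:
        return self.intercept + self.slope * ecc_deg


@dataclass(frozen=True)
class RetinalGeometry:
    """Spatial layout of the model retina over an image.

    fixation : (x, y) pixel coordinates of the foveal center.
    pixels_per_degree : image sampling density; links pixel distance to
        visual angle (no standard exists for plain images, so this is an
        explicit required parameter; default 10 px/deg).
    fovea_half_angle : degrees; default 2.5 (a 5-degree fovea).
    viewing_distance_mm : optional, only used for physical-extent reports.
    rf_size_profile : callable mapping eccentricity (deg) to a raw field
        size, snapped to odd by :func:`rf_size_at`.
    """

    fixation: tuple[float, float] = (0.0, 0.0)
    pixels_per_degree: float = 10.0
    fovea_half_angle: float = 2.5
    viewing_distance_mm: float | None = None
    rf_size_profile: Callable[[float], float] = field(default_factory=LinearRFProfile)

    def __post_init__(self) -> None:
        if self.pixels_per_degree <= 0:
            raise DomainError("pixels_per_degree must be > 0")
        if self.fovea_half_angle < 0:
            raise DomainError("fovea_half_angle must be >= 0")

    @property
    def fovea_radius_px(self) -> float:
        return self.fovea_half_angle * self.pixels_per_degree


def eccentricity_deg(pixel: tuple[float, float], geometry: RetinalGeometry) -> float:
    """Angular distance (degrees) of a pixel from the fixation point."""
    dx = pixel[0] - geometry.fixation[0]
    dy = pixel[1] - geometry.fixation[1]
    return math.hypot(dx, dy) / geometry.pixels_per_degree


def eccentricity_map(geometry: RetinalGeometry, shape: tuple[int, int]) -> np.ndarray:
    """Per-pixel eccentricity (degrees) for an image of the given (H, W)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    fx, fy = geometry.fixation
    return np.hypot(xx - fx, yy - fy) / geometry.pixels_per_degree


def fovea_mask(geometry: RetinalGeometry, shape: tuple[int, int]) -> np.ndarray:
    """Boolean grid: True where eccentricity <= the fovea half-angle."""
    return eccentricity_map(geometry, shape) <= geometry.fovea_half_angle


def rf_size_at(ecc_deg: float, geometry: RetinalGeometry) -> int:
    """Receptive-field side length (odd pixels) at an eccentricity."""
    if ecc_deg < 0:
        raise DomainError(f"eccentricity must be >= 0, got {ecc_deg}")
    return snap_to_odd(geometry.rf_size_profile(ecc_deg))
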