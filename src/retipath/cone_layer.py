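"""Photoreceptor layer: RGB pixels to L/M/S cone planes, plus synthetic fixtures.

The three cone classes (long-, medium- and short-wavelength) are read off
an 8-bit RGB image. By default the mapping is the identity — R feeds L,
G feeds M, B feeds S — mirroring how a camera's color channels stand in
for the cone mosaic; a configurable 3x3 matrix hook allows a colorimetric
LMS transform for users who want one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DomainError, FormatError
from . import io as _io

logger = logging.getLogger(__name__)

__all__ = ["ConePlanes", "rgb_to_cone_planes", "generate_fixture", "load_cone_planes"]


@dataclass(frozen=True)
class ConePlanes:
    """Three aligned cone-response planes derived from an RGB image.

    L, M, S are height x width uint8 grids (values in [0, 255] at ingest;
    downstream filtering promotes them to floats).
    """

    L: np.ndarray
    M: np.ndarray
    S: np.ndarray

    def __post_init__(self) -> None:
        if not (self.L.shape == self.M.shape == self.S.shape):
            raise FormatError("cone planes must share identical dimensions")
        for name in ("L", "M", "S"):
            plane = getattr(self, name)
            if plane.ndim != 2:
                raise FormatError(f"plane {name} must be 2-D, got shape {plane.shape}")

    @property
    def height(self) -> int:
        return self.L.shape[0]

    @property
    def width(self) -> int:
        return self.L.shape[1]

    def as_float(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (
            self.L.astype(np.float64),
            self.M.astype(np.float64),
            self.S.astype(np.float64),
        )


def rgb_to_cone_planes(image: np.ndarray, mapping: np.ndarray | None = None) -> ConePlanes:
    """Map an 8-bit RGB raster onto L/M/S cone planes.

    Parameters
    ----------
    image : HxWx3 uint8 array (or HxW grayscale, replicated with a warning).
    mapping : optional 3x3 real matrix applied per pixel to (R, G, B);
        identity by default so L=R, M=G, S=B. Outputs are clipped to [0, 255].
    """
    image = np.asarray(image)
    if image.ndim == 2:
        logger.warning("grayscale input: replicating single channel into R=G=B")
        image = np.repeat(image[:, :, None], 3, axis=2)
    if image.ndim != 3 or image.shape[2] != 3:
        raise FormatError(
            f"expected a 3-channel image, got {image.shape[2] if image.ndim == 3 else 1} channel(s)"
        )
    if image.dtype != np.uint8:
        raise FormatError(f"expected 8-bit samples, got dtype {image.dtype}")

    if mapping is None:
        l_plane, m_plane, s_plane = image[:, :, 0], image[:, :, 1], image[:, :, 2]
        return ConePlanes(l_plane.copy(), m_plane.copy(), s_plane.copy())

    mapping = np.asarray(mapping, dtype=np.float64)
    if mapping.shape != (3, 3):
        raise DomainError(f"mapping must be 3x3, got {mapping.shape}")
    mixed = np.einsum("ij,hwj->hwi", mapping, image.astype(np.float64))
    mixed = np.clip(np.rint(mixed), 0, 255).astype(np.uint8)
    return ConePlanes(mixed[:, :, 0].copy(), mixed[:, :, 1].copy(), mixed[:, :, 2].copy())


def _as_color(value) -> np.ndarray:
    color = np.asarray(value, dtype=np.int64).reshape(-1)
    if color.size == 1:
        color = np.repeat(color, 3)
    if color.size != 3 or color.min() < 0 or color.max() > 255:
        raise DomainError(f"color must be 3 bytes in [0,255], got {value!r}")
    return color.astype(np.uint8)


def generate_fixture(
    kind: str,
    size: int,
    *,
    value=(128, 128, 128),
    fg=(0, 0, 255),
    bg=(255, 255, 0),
    radius: float | None = None,
    center: tuple[int, int] | None = None,
    axis: str = "vertical",
    seed: int | None = None,
) -> np.ndarray:
    """Generate a deterministic synthetic RGB test image.

    Kinds
    -----
    uniform   : every pixel is `value`.
    disc      : filled circle of color `fg` (radius, optional center,
                default image center) on a `bg` field.
    bipartite : half-plane split into `fg` | `bg` along `axis`
                ("vertical" splits left/right, "horizontal" top/bottom).
    random    : independent uniform bytes from `seed`.

    Pure function of its arguments: identical calls return byte-identical
    images.
    """
    if size < 1:
        raise DomainError(f"size must be >= 1, got {size}")
    if kind == "uniform":
        return np.broadcast_to(_as_color(value), (size, size, 3)).copy()
    if kind == "disc":
        if radius is None:
            radius = size / 4
        if radius > size / 2:
            raise DomainError(f"disc radius {radius} exceeds size/2 = {size / 2}")
        cy, cx = center if center is not None else (size // 2, size // 2)
        yy, xx = np.mgrid[0:size, 0:size]
        inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        img = np.empty((size, size, 3), dtype=np.uint8)
        img[:] = _as_color(bg)
        img[inside] = _as_color(fg)
        return img
    if kind == "bipartite":
        img = np.empty((size, size, 3), dtype=np.uint8)
        img[:] = _as_color(bg)
        if axis == "vertical":
            img[:, : size // 2] = _as_color(fg)
        elif axis == "horizontal":
            img[: size // 2, :] = _as_color(fg)
        else:
            raise DomainError(f"unknown bipartite axis {axis!r}")
        return img
    if kind == "random":
        if seed is None:
            raise DomainError("random fixture requires a seed")
        rng = np.random.default_rng(seed)
        return rng.integers(0, 256, size=(size, size, 3), dtype=np.uint8)
    raise DomainError(f"unknown fixture kind {kind!r}")


def load_cone_planes(path: str | Path, mapping: np.ndarray | None = None) -> ConePlanes:
    """Read an image file and map it to cone planes in one step."""
    return rgb_to_cone_planes(_io.read_image(path), mapping)
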