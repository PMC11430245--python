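"""Color-opponent pathway responses (K, M, P).

Retinal ganglion cells compare a receptive field's center against its
surround across cone types. Three parallel pathways carry the result to
the LGN:

* **K (koniocellular)** — blue-yellow: S-cone center against the
  L+M ("yellow") surround, active across the whole retina::

      K = Scen - (Mper + Lper) / 2
        = (Scen - Mper)/2 + (Scen - Lper)/2     (primitive form)

* **M (here: the foveal two-color red-green pathway)** — L-cone center
  against M-cone surround, confined to the fovea::

      M = (Lcen - Mper) / 2

* **P (peripheral homochromatic pathway)** — same-cone center/surround
  for both L and M, outside the fovea, with receptive fields growing
  with eccentricity::

      P = (Lcen - Lper)/2 + (Mcen - Mper)/2
        = (Lcen - Mper)/2 + (Mcen - Lper)/2     (primitive form)

All three decompose into four shared computational primitives — R-G, B-G,
B-R, G-R — each of the form (Xcen - Yper)/2. The R-G primitive is computed
once and consumed by both M and P; the resource model counts it once.

Xcen denotes the center-weighted sum of plane X, Yper the
surround-weighted sum of plane Y; with both regions normalized to unit
gain, every response is exactly zero on a uniform stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .cone_layer import ConePlanes
from .errors import ConfigurationError, ShapeError
from .geometry import RetinalGeometry, eccentricity_map, fovea_mask, rf_size_at
from .receptive_field import ReceptiveField, default_field
from . import datapath

__all__ = [
    "ChannelMaps",
    "primitive_response",
    "k_response",
    "m_response",
    "p_response",
    "channel_maps",
]

_IDENTITY_TOL = 1e-9  # direct vs primitive decomposition, magnitude <= 510


@dataclass(frozen=True)
class ChannelMaps:
    """One pathway's signed response map over the image frame.

    ``map`` is zero wherever ``valid_mask`` is False (outside the
    pathway's retinal region or where the receptive field would leave the
    image).
    """

    channel: str
    map: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.map.shape != self.valid_mask.shape:
            raise ShapeError("map and valid_mask must share a shape")

    def summary(self) -> dict:
        vals = self.map[self.valid_mask]
        if vals.size == 0:
            return {"channel": self.channel, "valid_pixels": 0,
                    "min": 0.0, "max": 0.0, "mean": 0.0}
        return {
            "channel": self.channel,
            "valid_pixels": int(vals.size),
            "min": float(vals.min()),
            "max": float(vals.max()),
            "mean": float(vals.mean()),
        }


def _check_patch(patch: np.ndarray, field: ReceptiveField, name: str) -> np.ndarray:
    patch = np.asarray(patch, dtype=np.float64)
    if patch.shape != (field.size, field.size):
        raise ShapeError(
            f"{name} patch shape {patch.shape} != field {field.size}x{field.size}"
        )
    return patch


def _cen(patch: np.ndarray, field: ReceptiveField) -> float:
    return float(np.sum(field.center_weights * patch))


def _per(patch: np.ndarray, field: ReceptiveField) -> float:
    return float(np.sum(field.surround_weights * patch))


def primitive_response(
    center_plane: np.ndarray, surround_plane: np.ndarray, field: ReceptiveField
) -> float:
    """One computational primitive: (Xcen - Yper) / 2.

    The four primitives R-G, B-G, B-R, G-R are this applied to the plane
    pairs (L,M), (S,M), (S,L), (M,L).
    """
    x = _check_patch(center_plane, field, "center")
    y = _check_patch(surround_plane, field, "surround")
    return (_cen(x, field) - _per(y, field)) / 2.0


def k_response(L: np.ndarray, M: np.ndarray, S: np.ndarray, field: ReceptiveField) -> float:
    """Blue-yellow opponent response: Scen - (Mper + Lper)/2.

    Computed both directly and as the sum of the B-G and B-R primitives;
    the two forms are asserted equal (an algebraic identity).
    """
    l = _check_patch(L, field, "L")
    m = _check_patch(M, field, "M")
    s = _check_patch(S, field, "S")
    direct = _cen(s, field) - (_per(m, field) + _per(l, field)) / 2.0
    primitive = primitive_response(s, m, field) + primitive_response(s, l, field)
    assert abs(direct - primitive) <= _IDENTITY_TOL, "B-G + B-R decomposition diverged"
    return direct


def m_response(L: np.ndarray, M: np.ndarray, field: ReceptiveField) -> float:
    """Foveal red-green two-color opponent: (Lcen - Mper)/2 — the R-G primitive."""
    return primitive_response(L, M, field)


def p_response(L: np.ndarray, M: np.ndarray, field: ReceptiveField) -> float:
    """Peripheral homochromatic opponent: (Lcen - Lper)/2 + (Mcen - Mper)/2.

    Also evaluated in primitive form (R-G + G-R); both reduce to
    (Lcen + Mcen - Lper - Mper)/2 and are asserted equal.
    """
    l = _check_patch(L, field, "L")
    m = _check_patch(M, field, "M")
    homochromatic = (
        (_cen(l, field) - _per(l, field)) / 2.0
        + (_cen(m, field) - _per(m, field)) / 2.0
    )
    primitive = primitive_response(l, m, field) + primitive_response(m, l, field)
    assert abs(homochromatic - primitive) <= _IDENTITY_TOL, "R-G + G-R decomposition diverged"
    return homochromatic


def _embed(valid: np.ndarray, shape: tuple[int, int], border: int) -> np.ndarray:
    """Place a valid-region response grid into a full-frame zero array."""
    full = np.zeros(shape, dtype=np.float64)
    h, w = shape
    full[border : h - border, border : w - border] = valid
    return full


def _interior_mask(shape: tuple[int, int], border: int) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    h, w = shape
    if h > 2 * border and w > 2 * border:
        mask[border : h - border, border : w - border] = True
    return mask


class _ConvCache:
    """Memoizes per-(plane, kernel-region, size) convolutions.

    This is the structural analogue of multiplexing a primitive circuit:
    e.g. the surround-weighted M plane feeds both the K and the M pathway
    but is convolved once.
    """

    def __init__(self, convolve: Callable[[np.ndarray, np.ndarray], np.ndarray]):
        self._convolve = convolve
        self._store: dict = {}

    def __call__(self, plane: np.ndarray, plane_key: str, field: ReceptiveField,
                 region: str) -> np.ndarray:
        key = (plane_key, region, field.size, field.center_radius,
               field.sigma_center, field.sigma_surround)
        if key not in self._store:
            kernel = field.center_weights if region == "cen" else field.surround_weights
            self._store[key] = self._convolve(plane, kernel)
        return self._store[key]


def channel_maps(
    cones: ConePlanes,
    geometry: RetinalGeometry,
    k_field: ReceptiveField | None = None,
    m_field: ReceptiveField | None = None,
    p_field_factory: Callable[[int], ReceptiveField] | None = None,
    convolve: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
) -> dict[str, ChannelMaps]:
    """Assemble full-image K/M/P maps gated by retinal region.

    K is computed everywhere, M only inside the fovea, P only outside it;
    P's receptive-field size follows the geometry's eccentricity profile.
    ``convolve`` defaults to the package's batch engine
    (:func:`retipath.datapath.direct_convolve`); passing a streaming
    wrapper yields bit-identical maps.

    Maps are full-frame; positions outside a pathway's valid mask are
    zero. An empty fovea simply yields an all-invalid M map.
    """
    if k_field is None:
        k_field = default_field(3)
    if m_field is None:
        m_field = default_field(3)
    if p_field_factory is None:
        p_field_factory = default_field
    conv = _ConvCache(convolve or datapath.direct_convolve)

    Lp, Mp, Sp = cones.as_float()
    shape = (cones.height, cones.width)
    if min(shape) < max(k_field.size, m_field.size):
        raise ConfigurationError("image smaller than the configured receptive fields")

    fovea = fovea_mask(geometry, shape)
    ecc = eccentricity_map(geometry, shape)

    # K: blue-yellow everywhere
    bk = k_field.border
    k_valid_grid = (
        conv(Sp, "S", k_field, "cen")
        - (conv(Mp, "M", k_field, "per") + conv(Lp, "L", k_field, "per")) / 2.0
    )
    k_mask = _interior_mask(shape, bk)
    k_map = _embed(k_valid_grid, shape, bk) * k_mask

    # M: red-green two-color, fovea only (the R-G primitive map)
    bm = m_field.border
    rg_grid = (conv(Lp, "L", m_field, "cen") - conv(Mp, "M", m_field, "per")) / 2.0
    m_mask = _interior_mask(shape, bm) & fovea
    m_map = _embed(rg_grid, shape, bm) * m_mask

    # P: homochromatic, outside the fovea, eccentricity-dependent size
    p_mask = np.zeros(shape, dtype=bool)
    p_map = np.zeros(shape, dtype=np.float64)
    periphery = ~fovea
    if periphery.any():
        sizes = np.vectorize(lambda e: rf_size_at(e, geometry))(ecc[periphery])
        for s in sorted(set(int(v) for v in sizes)):
            if min(shape) < s:
                continue  # field too large for the image at this eccentricity
            pf = p_field_factory(s)
            grid = (
                (conv(Lp, "L", pf, "cen") - conv(Lp, "L", pf, "per")) / 2.0
                + (conv(Mp, "M", pf, "cen") - conv(Mp, "M", pf, "per")) / 2.0
            )
            here = periphery & _interior_mask(shape, pf.border)
            size_map = np.zeros(shape, dtype=bool)
            size_map[periphery] = sizes == s
            here &= size_map
            p_map[here] = _embed(grid, shape, pf.border)[here]
            p_mask |= here

    return {
        "K": ChannelMaps("K", k_map, k_mask),
        "M": ChannelMaps("M", m_map, m_mask),
        "P": ChannelMaps("P", p_map, p_mask),
    }
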