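"""Center-surround Gaussian receptive fields.

A ganglion-cell receptive field is modeled after Rodieck's
difference-of-Gaussians: an excitatory center and an antagonistic
surround, each carrying Gaussian weights

    g(x, y; sigma) ∝ exp(-(x² + y²) / (2 sigma²))

over integer offsets from the field center. The default construction
assigns disjoint regions — center pixels inside ``center_radius``, the
surround ring outside — with each region renormalized to unit sum, so a
uniform stimulus produces exactly zero opponent response. The classical
overlapping variant (both Gaussians span the full grid) is available via
``overlapping=True``.

Radial symmetry means the weight at offset (x, y) depends only on
x² + y²; a 3x3 field therefore stores just three distinct weights
(radii² 0, 1, 2), the compression a hardware datapath exploits for
weight storage. ``quantize_to_shifts`` converts weights to fixed-point
shift-add schedules (sums of signed powers of two) so a multiplier-free
datapath can apply them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import ConfigurationError, DomainError, IntegrityError

__all__ = [
    "ReceptiveField",
    "WeightStorage",
    "ShiftWeight",
    "ShiftWeightSet",
    "gaussian_weights",
    "make_receptive_field",
    "default_field",
    "weight_storage",
    "distinct_weight_count",
    "quantize_weight",
    "quantize_to_shifts",
]


# Region weights are snapped to dyadic rationals (numerator / 2^40) whose
# numerators sum to exactly 2^40. Products with 8-bit samples and all partial
# sums are then exactly representable in double precision, so unit gain is
# exact: a uniform stimulus yields a response of exactly zero in any
# summation order, and streaming/batch engines agree bit-for-bit.
_SNAP_BITS = 40


def _snap_unit_sum(w: np.ndarray, mask: np.ndarray) -> np.ndarray:
    scale = 1 << _SNAP_BITS
    n = np.rint(w * scale).astype(np.int64)
    delta = int(scale - n.sum())
    if delta:
        size = w.shape[0]
        half = (size - 1) // 2
        if mask[half, half]:
            # the origin is its own radius class: absorbing the rounding
            # residual there keeps radial symmetry intact
            n[half, half] += delta
        else:
            # off-origin radius classes have 4 or 8 members, so the residual
            # is a multiple of 4; the corner class (always 4 members, always
            # in the surround) absorbs it symmetrically
            yy, xx = _offset_grids(size)
            r2 = xx**2 + yy**2
            corner = r2 == r2.max()
            assert delta % 4 == 0 and corner.sum() == 4
            n[corner] += delta // 4
    return n / float(scale)


def _check_size(size: int) -> None:
    if not isinstance(size, (int, np.integer)) or size < 1 or size % 2 == 0:
        raise DomainError(f"field size must be an odd integer >= 1, got {size!r}")


def _offset_grids(size: int) -> tuple[np.ndarray, np.ndarray]:
    half = (size - 1) // 2
    return np.mgrid[-half : half + 1, -half : half + 1]


def gaussian_weights(size: int, sigma: float) -> np.ndarray:
    """Normalized isotropic Gaussian weights on a size x size offset grid.

    Entries are proportional to exp(-(x²+y²)/(2σ²)) for offsets
    x, y in [-(size-1)/2, (size-1)/2] and sum to 1.
    """
    _check_size(size)
    if sigma <= 0:
        raise DomainError(f"sigma must be > 0, got {sigma}")
    yy, xx = _offset_grids(size)
    # subtract the max exponent before exp so tiny sigmas don't underflow to all-zero
    expo = -(xx.astype(np.float64) ** 2 + yy.astype(np.float64) ** 2) / (2.0 * sigma**2)
    w = np.exp(expo - expo.max())
    return w / w.sum()


@dataclass(frozen=True)
class ReceptiveField:
    """Center/surround Gaussian weight masks for one ganglion cell.

    Invariants: masks are disjoint and cover the grid (default
    construction); each region's weights sum to 1 and vanish off its
    mask; weights are radially symmetric.
    """

    size: int
    sigma_center: float
    sigma_surround: float
    center_radius: float
    center_mask: np.ndarray
    surround_mask: np.ndarray
    center_weights: np.ndarray
    surround_weights: np.ndarray
    overlapping: bool = False

    @property
    def combined_kernel(self) -> np.ndarray:
        """Signed DoG kernel: center minus surround (unit gain each)."""
        return self.center_weights - self.surround_weights

    @property
    def border(self) -> int:
        return (self.size - 1) // 2


def make_receptive_field(
    size: int,
    sigma_center: float | None = None,
    sigma_surround: float | None = None,
    center_radius: float = 0.5,
    *,
    overlapping: bool = False,
) -> ReceptiveField:
    """Build a center-surround receptive field.

    Parameters
    ----------
    size : odd side length in pixels.
    sigma_center, sigma_surround : Gaussian widths; defaults are
        ``max(0.5 * center_radius, 0.25)`` and ``size / 3``. Any positive
        values satisfy the model — unit-sum normalization per region is
        the binding constraint. Requires sigma_surround > sigma_center.
    center_radius : offsets with x²+y² <= center_radius² form the center;
        0.5 (the default) wires a single-pixel center, the midget-cell
        configuration. Must leave the surround non-empty.
    overlapping : if True, build the classical overlapping DoG (both
        Gaussians span the full grid, masks all-true) instead of disjoint
        regions.
    """
    _check_size(size)
    if center_radius < 0 or center_radius >= size / 2 * math.sqrt(2):
        raise DomainError(
            f"center_radius must be in [0, size/2*sqrt(2)), got {center_radius}"
        )
    if sigma_center is None:
        sigma_center = max(0.5 * center_radius, 0.25)
    if sigma_surround is None:
        sigma_surround = size / 3.0
    if sigma_center <= 0 or sigma_surround <= 0:
        raise DomainError("sigmas must be positive")
    if sigma_surround <= sigma_center:
        raise DomainError(
            f"sigma_surround ({sigma_surround}) must exceed sigma_center ({sigma_center})"
        )

    yy, xx = _offset_grids(size)
    r2 = xx**2 + yy**2

    if overlapping:
        full = np.ones((size, size), dtype=bool)
        return ReceptiveField(
            size, sigma_center, sigma_surround, center_radius,
            full, full.copy(),
            _snap_unit_sum(gaussian_weights(size, sigma_center), full),
            _snap_unit_sum(gaussian_weights(size, sigma_surround), full),
            overlapping=True,
        )

    center_mask = r2 <= center_radius**2
    surround_mask = ~center_mask
    if not center_mask.any():
        raise ConfigurationError("center region is empty")
    if not surround_mask.any():
        raise ConfigurationError(
            f"surround region is empty for size={size}, center_radius={center_radius}"
        )

    cw = gaussian_weights(size, sigma_center) * center_mask
    sw = gaussian_weights(size, sigma_surround) * surround_mask
    cw = _snap_unit_sum(cw / cw.sum(), center_mask)
    sw = _snap_unit_sum(sw / sw.sum(), surround_mask)
    return ReceptiveField(
        size, sigma_center, sigma_surround, center_radius,
        center_mask, surround_mask, cw, sw,
    )


def default_field(size: int) -> ReceptiveField:
    """Single-pixel-center field with default sigmas (the 3x3 default)."""
    return make_receptive_field(size, center_radius=0.5)


@dataclass(frozen=True)
class WeightStorage:
    """Compressed storage for a radially symmetric kernel.

    ``values[k]`` is the weight shared by every offset whose squared
    radius ranks k-th; ``slot_index`` maps each grid offset to its slot.
    ``expand()`` reconstructs the full kernel exactly.
    """

    values: np.ndarray
    slot_index: np.ndarray
    radii_squared: np.ndarray

    @property
    def count(self) -> int:
        return int(self.values.size)

    def expand(self) -> np.ndarray:
        return self.values[self.slot_index]


def _kernel_of(field_or_kernel, kernel: str = "combined") -> np.ndarray:
    if isinstance(field_or_kernel, ReceptiveField):
        return {
            "combined": field_or_kernel.combined_kernel,
            "center": field_or_kernel.center_weights,
            "surround": field_or_kernel.surround_weights,
        }[kernel]
    arr = np.asarray(field_or_kernel, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1] or arr.shape[0] % 2 == 0:
        raise DomainError(f"kernel must be odd square, got shape {arr.shape}")
    return arr


def weight_storage(field_or_kernel, kernel: str = "combined", *, tol: float = 1e-12) -> WeightStorage:
    """Group a symmetric kernel's weights by squared radius.

    Raises IntegrityError if two offsets at the same radius carry weights
    differing by more than ``tol`` — the symmetry the compact storage
    relies on.
    """
    k = _kernel_of(field_or_kernel, kernel)
    size = k.shape[0]
    yy, xx = _offset_grids(size)
    r2 = (xx**2 + yy**2).ravel()
    radii = np.unique(r2)
    values = np.empty(radii.size)
    slot = np.searchsorted(radii, r2).reshape(size, size)
    flat = k.ravel()
    for i, r in enumerate(radii):
        group = flat[r2 == r]
        if group.max() - group.min() > tol:
            raise IntegrityError(
                f"weights at squared radius {r} differ by {group.max() - group.min():.3g} > {tol}"
            )
        values[i] = group[0]
    return WeightStorage(values, slot, radii)


def distinct_weight_count(field_or_kernel, kernel: str = "combined") -> int:
    """Number of distinct stored weights = number of distinct squared radii.

    A 3x3 field stores 3 weights (radii² {0, 1, 2}); a 5x5 stores 6.
    """
    return weight_storage(field_or_kernel, kernel).count


@dataclass(frozen=True)
class ShiftWeight:
    """One fixed-point weight as a shift-add schedule.

    ``numerator`` is the signed integer round-half-even(w * 2^f);
    ``exponents`` are the set-bit positions of |numerator|, so
    numerator = sign * sum(2^e for e in exponents) exactly and the
    applied weight is numerator / 2^f (each term a single shift).
    """

    original: float
    numerator: int
    exponents: tuple[int, ...]

    @property
    def sign(self) -> int:
        return -1 if self.numerator < 0 else 1

    def quantized(self, fraction_bits: int) -> float:
        return self.numerator / (1 << fraction_bits)


def quantize_weight(w: float, fraction_bits: int) -> ShiftWeight:
    """Quantize one real weight to f fractional bits (round half to even).

    The reconstruction error |quantized - original| is at most 2^(-f-1).
    """
    if not 1 <= fraction_bits <= 24:
        raise DomainError(f"fraction_bits must be in [1, 24], got {fraction_bits}")
    numerator = int(np.rint(w * (1 << fraction_bits)))
    mag = abs(numerator)
    exponents = tuple(i for i in range(mag.bit_length()) if mag >> i & 1)
    return ShiftWeight(float(w), numerator, exponents)


@dataclass(frozen=True)
class ShiftWeightSet:
    """All distinct weights of a kernel in shift-add form.

    Pairs the symmetric storage (one entry per distinct radius) with the
    quantization, so the full fixed-point kernel reconstructs as
    ``numerators[slot_index] / 2^f``.
    """

    fraction_bits: int
    weights: tuple[ShiftWeight, ...]
    storage: WeightStorage = dc_field(repr=False)

    def numerator_grid(self) -> np.ndarray:
        nums = np.array([w.numerator for w in self.weights], dtype=np.int64)
        return nums[self.storage.slot_index]

    def quantized_kernel(self) -> np.ndarray:
        return self.numerator_grid() / float(1 << self.fraction_bits)

    def max_error(self) -> float:
        return max(
            abs(w.quantized(self.fraction_bits) - w.original) for w in self.weights
        )


def quantize_to_shifts(
    field_or_kernel, fraction_bits: int, kernel: str = "combined"
) -> ShiftWeightSet:
    """Quantize a field's distinct weights to shift-add schedules.

    ``kernel`` selects the signed combined DoG kernel (default) or the
    center / surround region kernel.
    """
    storage = weight_storage(field_or_kernel, kernel)
    weights = tuple(quantize_weight(w, fraction_bits) for w in storage.values)
    return ShiftWeightSet(fraction_bits, weights, storage)
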