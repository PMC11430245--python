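"""Algorithm-level emulation of the hardware datapath.

Three pieces of a streaming retinal-coding circuit are modeled at the
level of their arithmetic and stage structure (no HDL, no clocks):

* **Line-buffer streaming convolution** — pixels arrive one per cycle in
  raster order; (size-1) full-width line buffers plus a size x size
  register window expose a whole receptive field in parallel every cycle
  once filled. The first valid output appears after (size-1)*width + size
  ingested pixels, and the streamed output is bit-identical to batch
  convolution computed with the same accumulation order.

* **Vector-product trees** — a dot product evaluated either sequentially
  (one multiply stage, then one accumulate per element: n+1 stages) or as
  one parallel multiply level feeding a balanced binary adder tree
  (1 + ceil(log2 n) stages; 5 instead of 10 for a 9-tap field). With
  shift-quantized weights the multiplies are fixed-point shift-adds and
  both modes agree exactly.

* **Resource accounting** — unit costs (LUT-equivalents) are configuration
  inputs; sharing a primitive between pathways removes its duplicate from
  the total, and the model reports the percent saved.

Stage counts in reports are measured from the structures actually built,
not from closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigurationError, ShapeError
from .receptive_field import ReceptiveField, ShiftWeightSet

__all__ = [
    "DatapathReport",
    "direct_convolve",
    "stream_convolve",
    "vector_product_tree",
    "resource_report",
    "percent_decrease",
    "default_unit_costs",
]


@dataclass
class DatapathReport:
    """Stage/latency/cost accounting for one datapath configuration."""

    mode: str
    n: int = 0
    multiply_levels: int = 0
    adder_levels: int = 0
    critical_path: int = 0
    latency: int | None = None
    unit_costs: dict[str, float] = field(default_factory=dict)
    with_sharing: float | None = None
    without_sharing: float | None = None
    savings_percent: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v not in (None, {}, [])}


def _kernel_array(kernel) -> np.ndarray:
    if isinstance(kernel, ReceptiveField):
        return kernel.combined_kernel
    arr = np.asarray(kernel, dtype=np.float64)
    if arr.ndim != 2:
        raise ShapeError(f"kernel must be 2-D, got shape {arr.shape}")
    return arr


def direct_convolve(plane: np.ndarray, kernel) -> np.ndarray:
    """Valid-region correlation accumulated in row-major kernel order.

    The accumulation order (kernel offsets scanned row-major, one
    fused-off multiply-add per offset) is the same order the streaming
    engine uses per window, which is what makes the two paths
    bit-identical in floating point.
    """
    plane = np.asarray(plane, dtype=np.float64)
    k = _kernel_array(kernel)
    s = k.shape[0]
    h, w = plane.shape
    if h < s or w < k.shape[1]:
        raise ConfigurationError(
            f"plane {plane.shape} smaller than kernel {k.shape}"
        )
    oh, ow = h - s + 1, w - k.shape[1] + 1
    out = np.zeros((oh, ow), dtype=np.float64)
    for dy in range(s):
        for dx in range(k.shape[1]):
            out += k[dy, dx] * plane[dy : dy + oh, dx : dx + ow]
    return out


def stream_convolve(
    plane: np.ndarray, kernel, image_width: int | None = None
) -> tuple[np.ndarray, int]:
    """Raster-scan line-buffer convolution of one plane.

    Emulates the streaming datapath: (size-1) line buffers of length
    ``image_width`` plus a size x size register window, fed one pixel per
    cycle in row-major order. Returns the valid-region response grid and
    the latency in ingested pixels until the first valid output,
    (size-1)*width + size.
    """
    plane = np.asarray(plane, dtype=np.float64)
    k = _kernel_array(kernel)
    s = k.shape[0]
    if k.shape[0] != k.shape[1]:
        raise ShapeError(f"streaming window requires a square kernel, got {k.shape}")
    h, w = plane.shape
    if image_width is not None and image_width != w:
        raise ConfigurationError(
            f"declared image_width {image_width} != plane width {w}"
        )
    if w < s or h < s:
        raise ConfigurationError(f"image {h}x{w} smaller than field size {s}")

    latency = (s - 1) * w + s
    out = np.zeros((h - s + 1, w - s + 1), dtype=np.float64)
    # (s-1) line buffers, one full image row each, plus the register window
    line_bufs = [[0.0] * w for _ in range(s - 1)]
    window = [[0.0] * s for _ in range(s)]
    kflat = [float(v) for v in k.ravel()]
    ingested = 0
    for y in range(h):
        row = plane[y]
        for x in range(w):
            p = float(row[x])
            # column entering the window: the (s-1) buffered rows above, then p
            for r in range(s):
                win_row = window[r]
                win_row.pop(0)
                win_row.append(line_bufs[r][x] if r < s - 1 else p)
            # shift the column of line buffers down by one row
            for r in range(s - 2):
                line_bufs[r][x] = line_bufs[r + 1][x]
            if s > 1:
                line_bufs[s - 2][x] = p
            ingested += 1
            if ingested >= latency and x >= s - 1:
                acc = 0.0
                i = 0
                for r in range(s):
                    win_row = window[r]
                    for c in range(s):
                        acc += kflat[i] * win_row[c]
                        i += 1
                out[y - s + 1, x - s + 1] = acc
    return out, latency


def _tree_reduce(items: list) -> tuple[object, int]:
    """Balanced pairwise reduction; returns (sum, number of adder levels)."""
    levels = 0
    while len(items) > 1:
        nxt = []
        for i in range(0, len(items) - 1, 2):
            nxt.append(items[i] + items[i + 1])
        if len(items) % 2:
            nxt.append(items[-1])
        items = nxt
        levels += 1
    return items[0], levels


def vector_product_tree(
    values: Sequence[float] | np.ndarray,
    weights: Sequence[float] | np.ndarray | ShiftWeightSet,
    mode: str = "parallel_tree",
) -> tuple[float, DatapathReport]:
    """Dot product via the parallel multiply/adder tree or sequentially.

    ``weights`` may be a plain vector or a :class:`ShiftWeightSet`, in
    which case the computation runs in fixed point: products are integer
    shift-adds of the quantized numerators and the result is rescaled by
    2^-f at the end, so tree and sequential modes agree bit-exactly.

    Returns (dot product, report). The report's stage counts are measured
    from the reduction actually performed: one multiply level plus the
    adder-tree depth in parallel mode, one multiply stage plus n
    accumulate stages in sequential mode.
    """
    if mode not in ("parallel_tree", "sequential"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    vals = np.asarray(values, dtype=np.float64).ravel()
    n = vals.size
    if n < 1:
        raise ShapeError("need at least one element")

    fixed_point = isinstance(weights, ShiftWeightSet)
    if fixed_point:
        nums = weights.numerator_grid().ravel()
        f = weights.fraction_bits
        if nums.size != n:
            raise ShapeError(f"weight grid has {nums.size} taps, values have {n}")
        ivals = [int(v) for v in vals]
        if any(float(i) != float(v) for i, v in zip(ivals, vals)):
            raise ShapeError("fixed-point mode requires integer sample values")
        products = [iv * int(m) for iv, m in zip(ivals, nums)]
    else:
        wts = np.asarray(weights, dtype=np.float64).ravel()
        if wts.size != n:
            raise ShapeError(f"length mismatch: {n} values vs {wts.size} weights")
        products = [float(v) * float(w) for v, w in zip(vals, wts)]

    if mode == "parallel_tree":
        total, adder_levels = _tree_reduce(list(products))
    else:
        total = products[0] - products[0]  # zero of the right type
        adder_levels = 0
        for p in products:
            total = total + p
            adder_levels += 1

    if fixed_point:
        # accumulator width for 8-bit samples: f + 8 + ceil(log2 n) + 1 bits
        width = f + 8 + math.ceil(math.log2(n)) + 1 if n > 1 else f + 9
        assert abs(int(total)) < (1 << width), "fixed-point accumulator overflow"
        result = total / float(1 << f)
    else:
        result = float(total)

    report = DatapathReport(
        mode=mode,
        n=n,
        multiply_levels=1,
        adder_levels=adder_levels,
        critical_path=1 + adder_levels,
    )
    return result, report


def resource_report(
    unit_costs: Mapping[str, float],
    instantiated_units: Sequence[str],
    shared_units: Sequence[str] = (),
) -> DatapathReport:
    """LUT-equivalent cost totals with and without primitive sharing.

    ``instantiated_units`` are the units actually built (with sharing);
    ``shared_units`` are the duplicates that sharing saved. Savings are
    100 * saved / (with + saved); rounding to integer percent is left to
    the reporting layer.
    """
    for name in list(instantiated_units) + list(shared_units):
        if name not in unit_costs:
            raise ConfigurationError(f"unknown unit {name!r} (no cost entry)")
    with_sharing = float(sum(unit_costs[u] for u in instantiated_units))
    saved = float(sum(unit_costs[u] for u in shared_units))
    without_sharing = with_sharing + saved
    savings = 100.0 * saved / without_sharing if without_sharing else 0.0
    return DatapathReport(
        mode="resource",
        unit_costs=dict(unit_costs),
        with_sharing=with_sharing,
        without_sharing=without_sharing,
        savings_percent=savings,
    )


def percent_decrease(before: float, after: float) -> float:
    """100 * (before - after) / before."""
    if before == 0:
        raise ConfigurationError("percent decrease undefined for before == 0")
    return 100.0 * (before - after) / before


def default_unit_costs(group: str | None = None) -> dict:
    """Bundled LUT-cost table (published synthesis figures, not computed here).

    Groups: rf3x3, rf3x3_optimized, rf5x5_optimized, vector_product.
    """
    text = resources.files("retipath.data").joinpath("resource_costs.yaml").read_text()
    table = yaml.safe_load(text)
    if group is None:
        return table
    if group not in table:
        raise ConfigurationError(f"unknown cost group {group!r}; have {sorted(table)}")
    return table[group]
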