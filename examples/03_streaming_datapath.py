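"""Stream a plane through the line-buffer datapath and count tree stages.

A raster-scan pipeline holding (size-1) image rows plus a size x size
register window delivers a full receptive field every cycle; its output
is bit-identical to batch convolution. The per-field dot product costs
5 stages as a parallel multiply/adder tree versus 10 sequentially.
"""

import numpy as np

from retipath import (
    default_field,
    default_unit_costs,
    direct_convolve,
    resource_report,
    stream_convolve,
    vector_product_tree,
)

rng = np.random.default_rng(42)
plane = rng.integers(0, 256, (16, 16)).astype(float)
field = default_field(3)

streamed, latency = stream_convolve(plane, field)
batch = direct_convolve(plane, field)
print(f"streaming == batch, bit for bit: {np.array_equal(streamed, batch)}")
print(f"first valid output after {latency} ingested pixels "
      f"(= 2 rows x 16 + 3 for a 3x3 window)")

values = rng.integers(0, 256, 9).astype(float)
weights = rng.random(9)
_, tree = vector_product_tree(values, weights, "parallel_tree")
_, seq = vector_product_tree(values, weights, "sequential")
print(f"9-tap dot product: parallel tree {tree.critical_path} stages, "
      f"sequential {seq.critical_path} stages")

sharing = resource_report(default_unit_costs("rf3x3"), ["project"], ["R_G_text"])
print(f"primitive sharing: {sharing.with_sharing:.0f} LUTs with sharing, "
      f"{sharing.without_sharing:.0f} without -> {round(sharing.savings_percent)}% saved")
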