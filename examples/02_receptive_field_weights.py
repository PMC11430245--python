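"""Build a center-surround receptive field and its compressed, quantized weights.

Radial symmetry lets a 3x3 field store only 3 distinct weights (squared
radii 0, 1, 2); quantizing them to 8 fractional bits turns each multiply
into a short shift-add schedule with error at most 2^-9.
"""

from retipath import default_field, quantize_to_shifts, weight_storage

field = default_field(3)
print("combined center-surround kernel:")
print(field.combined_kernel)

storage = weight_storage(field)
print(f"\ndistinct stored weights: {storage.count} "
      f"(radii^2 = {[int(r) for r in storage.radii_squared]})")
for r2, v in zip(storage.radii_squared, storage.values):
    print(f"  r^2={int(r2)}: weight {v:+.6f}")

sw = quantize_to_shifts(field, fraction_bits=8)
print("\nshift-add schedules (numerator / 2^8):")
for w in sw.weights:
    shifts = " + ".join(f"2^{e - 8}" for e in w.exponents) or "0"
    sign = "-" if w.numerator < 0 else ""
    print(f"  {w.original:+.6f} -> {w.numerator:+4d}/256 = {sign}({shifts})")
print(f"max quantization error: {sw.max_error():.3e} (bound 2^-9 = {2**-9:.3e})")
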