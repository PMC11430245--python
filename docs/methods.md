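# Methods

## Model

An 8-bit RGB image stands in for the photoreceptor mosaic: R, G and B
feed the L, M and S cone planes directly (identity mapping by default; a
3×3 colorimetric matrix can be supplied, but the model itself is defined
on the identity). Each ganglion cell sees a square receptive field of odd
side `s` with Gaussian weights

    g(x, y; σ) ∝ exp(−(x² + y²) / 2σ²),

split into a **center** (offsets with x² + y² ≤ r_c²) and a disjoint
**surround** (the rest of the grid), each region renormalized to unit
sum. The disjoint split mirrors the circuit wiring, where center cells and
surround cells feed different adder inputs; the classical overlapping
difference-of-Gaussians is available via `overlapping=True` but is not the
default. With unit gain per region, a uniform stimulus produces zero
response and adding a constant to all planes changes nothing.

Per receptive field the three pathway responses are

    K = S_cen − (M_per + L_per)/2          (whole retina)
    M = (L_cen − M_per)/2                  (inside the fovea)
    P = (L_cen − L_per)/2 + (M_cen − M_per)/2   (outside the fovea)

each also expressible in the four shared primitives `(X_cen − Y_per)/2`;
the code computes both forms and asserts their equality (an exact
algebraic identity, checked to 1e-12 in floating point). The homochromatic
P channel measures luminance contrast; the two-color K and M channels
measure blue–yellow and red–green opposition. Full-image maps gate each
pathway by retinal region: the fovea mask (eccentricity ≤ half-angle)
selects M pixels, its complement selects P pixels, and K is computed
everywhere. P's field size follows the eccentricity profile. Map values
are signed reals; positions where the field would leave the image, or
outside the pathway's region, are flagged invalid and stored as zero.

## Parameters

| parameter | default | meaning |
|---|---|---|
| field size `s` | 3 px | odd side length; 3 at zero eccentricity for all pathways |
| center radius `r_c` | 0.5 px | single-pixel (midget) center |
| σ_center | max(0.5·r_c, 0.25) px | degenerate for a single-pixel center |
| σ_surround | s/3 px | any value > σ_center is admissible; normalization binds |
| fovea half-angle | 2.5° | a 5° fovea |
| pixels per degree | 10 | no standard links plain images to visual angle, so explicit |
| RF profile | 3 + 0.5·ecc, snapped to odd | only monotone growth is biologically fixed |
| fraction bits `f` | 8 (when fixed point is on) | quantization error ≤ 2^(−f−1) |

The Gaussian widths are not biologically pinned down; what the model fixes
is radial symmetry and unit-gain normalization, and those are the
properties the tests enforce. The linear eccentricity profile with slope
0.5 px/deg is a deliberate minimal choice (the underlying growth curve is
qualitative); users can pass any monotone callable.

## Numerical choices

**Dyadic weight storage.** After normalization, each region's weights are
snapped to dyadic rationals n_i/2^40 whose numerators sum to exactly 2^40
(the rounding residual goes to the origin offset when the region contains
it, otherwise it is spread over the 4-member corner radius class, which
preserves radial symmetry; off-origin radius classes have 4 or 8 members,
so the residual is always divisible by 4). Products with 8-bit samples and
all partial sums are then exactly representable in double precision, so
unit gain is *exact*: uniform integer input nulls every response in any
summation order, and the streaming and batch engines agree bit for bit.
The perturbation per weight is at most 2^−41 plus the shared residual —
far below any biological meaning of the weights.

**Convolution order.** The batch engine accumulates over kernel offsets in
row-major order, the same order the streaming window uses, which is what
makes the two engines (and the CLI artifacts they produce) byte-identical
even for non-integer inputs. This is also why convolution is implemented
in-package rather than delegated to a generic signal-processing routine,
whose summation order is unspecified.

**Streaming datapath.** The line-buffer emulator maintains (s−1) buffers
of one image row each plus an s×s register window, ingesting one pixel per
cycle; latency to the first valid output is (s−1)·width + s pixels. No
clock or energy modeling is attempted.

**Fixed point.** Weight quantization uses round-half-to-even on w·2^f
(bias-free, reproducible); each quantized weight is stored as its set-bit
shift schedule. In fixed-point mode the vector-product tree operates on
integers; the accumulator needs at most f + 8 + ⌈log2 n⌉ + 1 bits for
8-bit samples, which is asserted rather than saturated. Tree and
sequential modes are exactly equal in fixed point and within
n·ε·Σ|v·w| in floating point.

**Stage counting.** The parallel tree's critical path is measured from the
reduction actually performed (1 multiply level + the number of pairwise
adder rounds, which equals 1 + ⌈log2 n⌉); the sequential path is one
multiply stage plus one accumulate per element, n + 1. These are the only
definitions consistent with the reference stage counts of 5 and 10 for
n = 9, which quote endpoints rather than formulas.

**Resource model.** LUT-equivalent unit costs are *inputs*, bundled in
`retipath/data/resource_costs.yaml` as published synthesis figures — this
package accounts with them, it does not synthesize. The source quotes the
R-G primitive at 313 LUTs in its text but 316 in its table; both are kept,
with the text value (`R_G_text`) driving the canonical sharing computation
1397 + 313 = 1710, an 18% saving (integer rounding at the reporting layer
only). Savings are invariant under uniform cost scaling.

**Fovea extent.** `fovea_extent(d)` returns d·tan(half-angle) verbatim
(43.7 mm at 1 m). Whether that quantity is a radius or a diameter is
ambiguous in the literature the figure comes from; the API calls it
"extent" and leaves the interpretation to the caller.

## Design decisions that were genuinely open

* **Channel taxonomy.** Descriptions of which formula belongs to which
  pathway are inconsistent across sources; this package fixes P as the
  homochromatic pair-sum, M as the two-color `(L_cen − M_per)/2`, and K as
  the blue–yellow form above, with region assignments fovea→M,
  periphery→P, everywhere→K.
* **K's decomposition** is implemented with the corrected sign,
  `(S_cen − M_per)/2 + (S_cen − L_per)/2`, the only form equal to the
  direct expression.
* **Primitive sharing** is structural, not just accounting: within a map
  assembly every (plane, kernel-region, field) convolution is memoized, so
  the R-G output feeding both M and P is computed once.
* **Size-1 fields** cannot exist in disjoint center/surround form (the
  surround would be empty — a configuration error); symmetric-storage
  queries accept raw 1×1 kernels instead.

## What the synthetic fixtures do and do not show

The generator produces uniform fields, color discs, half-plane edges and
seeded uniform noise. These exercise every code path deterministically:
uniform fields pin the exact-null property, discs give known opponent
signs and extrema at known locations, edges probe border validity, noise
drives the equivalence and property tests. They do not emulate natural
images — no 1/f spectra, no camera noise, no chromatic correlations — so
passing tests certify the arithmetic and gating of the model, not its
perceptual performance on photographs. Problem sizes in the test suite
(images up to 64×64, fields 3–9, 200 random images for the
streaming/batch equivalence, 10,000 random weights for the quantization
bound) were chosen so the full suite runs in seconds while still covering
every size class the model distinguishes.

## Known limitations

* No temporal dynamics, adaptation, rod/scotopic input, or LGN-to-cortex
  processing; responses are instantaneous linear functionals.
* Hardware emulation is algorithm-level only: no HDL emission, synthesis,
  timing closure, power or throughput estimation.
* The eccentricity profile is a placeholder shape (linear, odd-snapped);
  real ganglion-cell density data would replace it via the profile hook.
* The identity RGB→LMS mapping ignores colorimetry; camera primaries are
  not cone fundamentals, and users wanting physiological accuracy should
  supply a transform matrix.
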