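"""Gaussian receptive fields, symmetric weight storage, shift quantization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retipath import (
    ConfigurationError,
    DomainError,
    IntegrityError,
    default_field,
    distinct_weight_count,
    gaussian_weights,
    make_receptive_field,
    quantize_to_shifts,
    quantize_weight,
    weight_storage,
)


class TestGaussianWeights:
    def test_single_cell_normalizes_to_one(self):
        assert gaussian_weights(1, 2.7)[0, 0] == 1.0

    def test_flat_limit_for_huge_sigma(self):
        w = gaussian_weights(3, 1e6)
        assert np.allclose(w, 1.0 / 9.0, atol=1e-9)

    def test_center_entry_matches_brute_force_normalization(self):
        # independent oracle: sum exp(-r^2/2) over the nine offsets
        total = sum(
            math.exp(-(x * x + y * y) / 2.0)
            for x in (-1, 0, 1)
            for y in (-1, 0, 1)
        )
        w = gaussian_weights(3, 1.0)
        assert w[1, 1] == pytest.approx(1.0 / total, rel=1e-12)
        assert w[0, 1] == pytest.approx(math.exp(-0.5) / total, rel=1e-12)

    @pytest.mark.parametrize("size", [0, 2, 4, -3])
    def test_even_or_nonpositive_size_rejected(self, size):
        with pytest.raises(DomainError):
            gaussian_weights(size, 1.0)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(DomainError):
            gaussian_weights(3, 0.0)


class TestMakeReceptiveField:
    def test_single_pixel_center_masks(self, field3):
        assert field3.center_mask.sum() == 1
        assert field3.center_mask[1, 1]
        assert field3.surround_mask.sum() == 8
        assert field3.center_weights[1, 1] == pytest.approx(1.0)

    def test_5x5_center_radius_1_5_region_counts(self):
        # offsets with x^2+y^2 <= 2.25 on the 5x5 grid: 9 of 25
        f = make_receptive_field(5, center_radius=1.5)
        assert f.center_mask.sum() == 9
        assert f.surround_mask.sum() == 16

    def test_masks_partition_grid_and_weights_respect_masks(self, field5):
        assert not (field5.center_mask & field5.surround_mask).any()
        assert (field5.center_mask | field5.surround_mask).all()
        assert (field5.center_weights[field5.surround_mask] == 0).all()
        assert (field5.surround_weights[field5.center_mask] == 0).all()

    @pytest.mark.parametrize("size,radius", [(3, 0.5), (5, 1.5), (7, 2.0), (9, 0.5)])
    def test_each_region_sums_to_one(self, size, radius):
        f = make_receptive_field(size, center_radius=radius)
        assert f.center_weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert f.surround_weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_uniform_rejection_on_constant_input(self, field5):
        # unit-gain regions: center and surround responses cancel exactly
        c = 37.0
        assert np.sum(field5.combined_kernel * c) == pytest.approx(0.0, abs=1e-12)

    def test_empty_surround_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="surround"):
            make_receptive_field(1, center_radius=0.0)

    def test_sigma_ordering_enforced(self):
        with pytest.raises(DomainError, match="sigma_surround"):
            make_receptive_field(3, sigma_center=2.0, sigma_surround=1.0)

    def test_center_radius_domain(self):
        with pytest.raises(DomainError):
            make_receptive_field(3, center_radius=3.0)

    def test_overlapping_variant_spans_full_grid(self):
        f = make_receptive_field(5, sigma_center=0.8, sigma_surround=2.0,
                                 center_radius=1.5, overlapping=True)
        assert f.center_mask.all() and f.surround_mask.all()
        assert f.center_weights.sum() == pytest.approx(1.0)
        assert np.sum(f.combined_kernel) == pytest.approx(0.0, abs=1e-12)


class TestWeightStorage:
    @pytest.mark.parametrize("size,expected", [(3, 3), (5, 6)])
    def test_distinct_counts_for_small_fields(self, size, expected):
        assert distinct_weight_count(default_field(size)) == expected

    def test_1x1_kernel_stores_one_weight(self):
        assert distinct_weight_count(gaussian_weights(1, 1.0)) == 1

    @pytest.mark.parametrize("size", [3, 5, 7, 9])
    def test_count_matches_brute_force_unique_values(self, size):
        f = default_field(size)
        k = f.combined_kernel
        brute = np.unique(np.round(k / 1e-12).astype(np.int64)).size
        assert distinct_weight_count(f) == brute

    def test_count_matches_enumerated_radii(self):
        # independent oracle: enumerate x^2+y^2 over offsets {-2..2}^2
        radii = {x * x + y * y for x in range(-2, 3) for y in range(-2, 3)}
        assert distinct_weight_count(default_field(5)) == len(radii) == 6

    def test_storage_reconstructs_kernel_exactly(self, field5):
        st_ = weight_storage(field5)
        assert np.array_equal(st_.expand(), field5.combined_kernel)

    def test_symmetry_violation_is_integrity_error(self):
        k = default_field(3).combined_kernel.copy()
        k[0, 1] += 1e-6
        with pytest.raises(IntegrityError, match="radius"):
            weight_storage(k)


class TestShiftQuantization:
    @pytest.mark.parametrize(
        "w,f,numerator,exponents",
        [(0.5, 8, 128, (7,)), (0.75, 8, 192, (6, 7)), (1 / 9, 8, 28, (2, 3, 4))],
    )
    def test_known_schedules(self, w, f, numerator, exponents):
        q = quantize_weight(w, f)
        assert q.numerator == numerator
        assert q.exponents == exponents
        assert abs(q.quantized(f) - w) <= 2 ** (-f - 1)

    def test_exact_dyadic_has_zero_error(self):
        assert quantize_weight(0.5, 8).quantized(8) == 0.5

    def test_one_ninth_quantizes_to_28_over_256(self):
        q = quantize_weight(1 / 9, 8)
        assert q.quantized(8) == pytest.approx(0.109375)

    @pytest.mark.parametrize("f", [4, 8, 12])
    def test_error_bound_on_10000_random_weights(self, f, rng):
        bound = 2.0 ** (-f - 1)
        for w in rng.random(10_000):
            q = quantize_weight(float(w), f)
            assert abs(q.quantized(f) - w) <= bound

    @given(w=st.floats(-1, 1, allow_nan=False), f=st.integers(1, 24))
    @settings(derandomize=True, max_examples=200)
    def test_shift_schedule_reproduces_numerator_exactly(self, w, f):
        q = quantize_weight(w, f)
        assert q.sign * sum(2**e for e in q.exponents) == q.numerator

    def test_field_quantization_applies_to_all_kernels(self, field3):
        for kernel in ("combined", "center", "surround"):
            sw = quantize_to_shifts(field3, 8, kernel)
            assert sw.max_error() <= 2 ** (-9)
            assert sw.numerator_grid().shape == (3, 3)

    def test_fraction_bits_domain(self):
        with pytest.raises(DomainError):
            quantize_weight(0.5, 0)
        with pytest.raises(DomainError):
            quantize_weight(0.5, 25)
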