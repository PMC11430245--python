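"""K/M/P opponent responses, primitives, and region-gated channel maps."""

import numpy as np
import pytest

from retipath import (
    RetinalGeometry,
    ShapeError,
    channel_maps,
    default_field,
    k_response,
    m_response,
    p_response,
    primitive_response,
    rgb_to_cone_planes,
    generate_fixture,
)
from conftest import brute_force_valid_convolve


def patches(rng, size=3, n=3):
    return [rng.uniform(0, 255, (size, size)) for _ in range(n)]


class TestPrimitive:
    def test_constant_input_cancels(self, field3):
        c = np.full((3, 3), 42.0)
        assert primitive_response(c, c, field3) == pytest.approx(0.0, abs=1e-12)

    def test_full_scale_contrast(self, field3):
        x = np.full((3, 3), 255.0)
        y = np.zeros((3, 3))
        assert primitive_response(x, y, field3) == pytest.approx(127.5)

    def test_matches_double_loop_weighted_sum_oracle(self, rng, field3):
        x, y = patches(rng, n=2)
        xcen = sum(
            field3.center_weights[i, j] * x[i, j] for i in range(3) for j in range(3)
        )
        yper = sum(
            field3.surround_weights[i, j] * y[i, j] for i in range(3) for j in range(3)
        )
        assert primitive_response(x, y, field3) == pytest.approx(
            (xcen - yper) / 2, abs=1e-12
        )

    def test_shape_mismatch_rejected(self, field3):
        with pytest.raises(ShapeError):
            primitive_response(np.zeros((5, 5)), np.zeros((3, 3)), field3)


class TestChannelResponses:
    def test_uniform_gray_gives_zero_everywhere(self, field3):
        c = np.full((3, 3), 99.0)
        assert k_response(c, c, c, field3) == pytest.approx(0.0, abs=1e-12)
        assert m_response(c, c, field3) == pytest.approx(0.0, abs=1e-12)
        assert p_response(c, c, field3) == pytest.approx(0.0, abs=1e-12)

    def test_k_blue_center_on_dark(self, field3):
        s = np.zeros((3, 3))
        s[1, 1] = 255.0  # S-cone stimulus at the single-pixel center
        z = np.zeros((3, 3))
        assert k_response(z, z, s, field3) == pytest.approx(255.0)

    def test_m_full_red_field(self, field3):
        l = np.full((3, 3), 255.0)
        m = np.zeros((3, 3))
        assert m_response(l, m, field3) == pytest.approx(127.5)

    def test_m_is_the_rg_primitive(self, rng, field3):
        l, m = patches(rng, n=2)
        assert m_response(l, m, field3) == primitive_response(l, m, field3)

    def test_p_homochromatic_center_vs_surround(self, field3):
        # L = M, center value a, surround value b -> response a - b
        a, b = 200.0, 50.0
        plane = np.full((3, 3), b)
        plane[1, 1] = a
        assert p_response(plane, plane.copy(), field3) == pytest.approx(a - b)

    def test_direct_and_primitive_decompositions_agree(self, rng, field5):
        for _ in range(100):
            l, m, s = patches(rng, size=5)
            scen = float(np.sum(field5.center_weights * s))
            lper = float(np.sum(field5.surround_weights * l))
            mper = float(np.sum(field5.surround_weights * m))
            k_primitive = (
                primitive_response(s, m, field5) + primitive_response(s, l, field5)
            )
            assert k_response(l, m, s, field5) == pytest.approx(
                scen - (mper + lper) / 2, abs=1e-12
            )
            assert k_primitive == pytest.approx(k_response(l, m, s, field5), abs=1e-12)
            p_primitive = (
                primitive_response(l, m, field5) + primitive_response(m, l, field5)
            )
            assert p_response(l, m, field5) == pytest.approx(p_primitive, abs=1e-12)

    def test_linearity_in_stimulus(self, rng, field3):
        l, m, s = patches(rng)
        alpha = 0.37
        for fn, args in ((k_response, (l, m, s)), (m_response, (l, m)), (p_response, (l, m))):
            full = fn(*args, field3)
            scaled = fn(*(alpha * a for a in args), field3)
            assert scaled == pytest.approx(alpha * full, abs=1e-9)

    def test_offset_invariance(self, rng, field3):
        l, m, s = patches(rng, n=3)
        c = 17.0
        assert k_response(l + c, m + c, s + c, field3) == pytest.approx(
            k_response(l, m, s, field3), abs=1e-9
        )
        assert p_response(l + c, m + c, field3) == pytest.approx(
            p_response(l, m, field3), abs=1e-9
        )


class TestChannelMaps:
    def geometry(self, shape, half_angle=2.5, ppd=10.0, fixation=None):
        h, w = shape
        if fixation is None:
            fixation = ((w - 1) / 2, (h - 1) / 2)
        return RetinalGeometry(fixation=fixation, pixels_per_degree=ppd,
                               fovea_half_angle=half_angle)

    def test_uniform_image_gives_identically_zero_maps(self):
        cones = rgb_to_cone_planes(generate_fixture("uniform", 40, value=(90, 90, 90)))
        maps = channel_maps(cones, self.geometry((40, 40)))
        for cm in maps.values():
            assert (cm.map == 0).all()

    def test_empty_fovea_disables_m_and_frees_p(self):
        cones = rgb_to_cone_planes(generate_fixture("uniform", 20, value=(10, 20, 30)))
        g = RetinalGeometry(fixation=(0.5, 0.5), pixels_per_degree=10, fovea_half_angle=0.0)
        maps = channel_maps(cones, g)
        assert not maps["M"].valid_mask.any()
        # P covers the whole interior frame (all sizes 3 near fixation)
        assert maps["P"].valid_mask[1:-1, 1:-1].any()

    def test_fovea_covering_image_disables_p(self):
        cones = rgb_to_cone_planes(generate_fixture("uniform", 20, value=(10, 20, 30)))
        maps = channel_maps(cones, self.geometry((20, 20), half_angle=10.0))
        assert not maps["P"].valid_mask.any()
        assert maps["M"].valid_mask[1:-1, 1:-1].all()

    def test_region_partition_and_k_superset(self):
        cones = rgb_to_cone_planes(generate_fixture("random", 48, seed=5))
        maps = channel_maps(cones, self.geometry((48, 48)))
        m, p, k = maps["M"].valid_mask, maps["P"].valid_mask, maps["K"].valid_mask
        assert not (m & p).any()
        assert (k | ~(m | p)).all()  # K covers everything M or P covers
        assert m.any() and p.any()

    def test_maps_zero_outside_valid_mask(self):
        cones = rgb_to_cone_planes(generate_fixture("random", 32, seed=9))
        maps = channel_maps(cones, self.geometry((32, 32)))
        for cm in maps.values():
            assert (cm.map[~cm.valid_mask] == 0).all()

    def test_blue_disc_on_yellow_k_map_structure(self, field3):
        img = generate_fixture("disc", 33, fg=(0, 0, 255), bg=(255, 255, 0), radius=8)
        cones = rgb_to_cone_planes(img)
        maps = channel_maps(cones, self.geometry((33, 33)))
        k = maps["K"]
        # oracle: batch convolution with the same field
        L, M, S = cones.as_float()
        oracle = (
            brute_force_valid_convolve(S, field3.center_weights)
            - (
                brute_force_valid_convolve(M, field3.surround_weights)
                + brute_force_valid_convolve(L, field3.surround_weights)
            )
            / 2
        )
        assert np.allclose(k.map[1:-1, 1:-1], oracle, atol=1e-9)
        # maximal inside the disc, negative on the yellow side of the boundary
        assert k.map[16, 16] == pytest.approx(255.0)
        iy, ix = np.unravel_index(np.argmax(k.map), k.map.shape)
        assert (iy - 16) ** 2 + (ix - 16) ** 2 <= 64
        assert k.map[16, 26] < 0  # just outside the disc edge

    def test_scaling_all_planes_scales_maps(self):
        from retipath import ConePlanes

        img = generate_fixture("random", 24, seed=11)
        cones = rgb_to_cone_planes(img)
        alpha = 0.5
        scaled = ConePlanes(*(p * alpha for p in cones.as_float()))
        g = self.geometry((24, 24))
        full_maps = channel_maps(cones, g)
        half_maps = channel_maps(scaled, g)
        for name in ("K", "M", "P"):
            assert np.array_equal(full_maps[name].valid_mask, half_maps[name].valid_mask)
            assert np.allclose(half_maps[name].map, alpha * full_maps[name].map, atol=1e-9)
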