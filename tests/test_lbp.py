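import numpy as np
import pytest

from ffirst.errors import DegenerateInputError
from ffirst.lbp import (
    build_scale_stack,
    lbp_pair,
    magnitude_lbp_image,
    magnitude_thresholds,
    neighbor_offsets,
    radii_schedule,
    sample_circle,
    sign_lbp_image,
    to_gray,
)
from ffirst.patterns import NeighborhoodSpec, rotate_code

SPEC8 = NeighborhoodSpec(P=8, R=1.0)


def naive_neighbor_value(level, r, c, dr, dc):
    """Plain bilinear interpolation oracle."""
    rs, cs = r + dr, c + dc
    H, W = level.shape
    r0, c0 = int(np.floor(rs)), int(np.floor(cs))
    fr, fc = rs - r0, cs - c0
    val = 0.0
    for ro, wr in ((0, 1 - fr), (1, fr)):
        for co, wc in ((0, 1 - fc), (1, fc)):
            w = wr * wc
            if w == 0:
                continue
            rr, cc = r0 + ro, c0 + co
            if not (0 <= rr < H and 0 <= cc < W):
                return None
            val += w * level[rr, cc]
    return val


def naive_sign_lbp(level, spec):
    """Per-pixel double-loop oracle for sign-LBP."""
    offs = neighbor_offsets(spec)
    H, W = level.shape
    codes = np.zeros((H, W), dtype=int)
    valid = np.zeros((H, W), dtype=bool)
    for r in range(H):
        for c in range(W):
            code = 0
            ok = True
            for p, (dr, dc) in enumerate(offs):
                v = naive_neighbor_value(level, r, c, dr, dc)
                if v is None:
                    ok = False
                    break
                if level[r, c] - v <= 0:
                    code |= 1 << p
            if ok:
                codes[r, c] = code
                valid[r, c] = True
    return codes, valid


class TestToGray:
    def test_rgb_luma(self):
        rgb = np.zeros((4, 4, 3))
        rgb[..., 0] = 1.0
        assert np.allclose(to_gray(rgb), 0.299)

    def test_too_small(self):
        with pytest.raises(DegenerateInputError):
            to_gray(np.zeros((2, 2)))


class TestScaleStack:
    def test_constant_image_unchanged(self):
        img = np.full((40, 40), 7.0)
        stack = build_scale_stack(img, SPEC8, 4)
        for level in stack:
            np.testing.assert_allclose(level.image, img, atol=1e-12)

    def test_small_sigma_is_identity(self, rng):
        img = rng.uniform(0, 1, (20, 20))
        stack = build_scale_stack(img, SPEC8, 1)
        # sigma_1 = sin(pi/8)/2 = 0.19 < 0.3 cutoff
        assert stack[0].sigma < 0.3
        np.testing.assert_array_equal(stack[0].image, img)

    def test_impulse_mass_conserved(self):
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        stack = build_scale_stack(img, SPEC8, 6)
        for level in stack:
            assert abs(level.image.sum() - 1.0) < 1e-6

    def test_radii_schedule(self):
        sched = radii_schedule(4, P=8)
        np.testing.assert_allclose(
            [R for R, _, _ in sched], [1, np.sqrt(2), 2, 2 * np.sqrt(2)], atol=1e-9
        )
        for R, r, sigma in sched:
            assert abs(r - R * np.sin(np.pi / 8)) < 1e-12
            assert abs(sigma - r / 2) < 1e-12

    def test_too_small_for_coarse_scale(self):
        with pytest.raises(DegenerateInputError):
            build_scale_stack(np.zeros((10, 10)), SPEC8, 8)


class TestSampleCircle:
    def test_constant_image(self):
        img = np.full((9, 9), 3.5)
        np.testing.assert_allclose(sample_circle(img, 4, 4, SPEC8), 3.5)

    def test_p4_on_grid(self, rng):
        img = rng.uniform(0, 1, (9, 9))
        spec = NeighborhoodSpec(P=4, R=1.0)
        vals = sample_circle(img, 4, 4, spec)
        # neighbor 0 east, CCW: east, north, west, south
        expected = [img[4, 5], img[3, 4], img[4, 3], img[5, 4]]
        np.testing.assert_allclose(vals, expected, atol=1e-12)

    def test_linear_ramp_exact(self):
        xx = np.tile(np.arange(20.0), (20, 1))
        spec = NeighborhoodSpec(P=8, R=1.7)
        vals = sample_circle(xx, 9.0, 9.0, spec)
        expected = 9.0 + 1.7 * np.cos(2 * np.pi * np.arange(8) / 8)
        np.testing.assert_allclose(vals, expected, atol=1e-9)


class TestSignLbp:
    def test_constant_image_all_ones_code(self):
        img = np.full((12, 12), 2.0)
        ci = sign_lbp_image(img, SPEC8, np.ones((12, 12), bool))
        assert np.all(ci.codes[ci.valid] == 255)

    def test_single_bright_pixel(self):
        img = np.zeros((9, 9))
        img[4, 4] = 10.0
        ci = sign_lbp_image(img, SPEC8, np.ones((9, 9), bool))
        assert ci.valid[4, 4]
        assert ci.codes[4, 4] == 0

    def test_matches_naive_oracle(self, rng):
        img = rng.uniform(0, 1, (16, 16))
        for R in (1.0, 2.3):
            spec = NeighborhoodSpec(P=8, R=R)
            ci = sign_lbp_image(img, spec, np.ones((16, 16), bool))
            codes, valid = naive_sign_lbp(img, spec)
            np.testing.assert_array_equal(ci.valid, valid)
            np.testing.assert_array_equal(ci.codes[valid], codes[valid])


class TestMagnitudeLbp:
    def test_constant_image_thresholds_zero(self):
        img = np.full((12, 12), 5.0)
        t = magnitude_thresholds(img, SPEC8, np.ones((12, 12), bool))
        np.testing.assert_allclose(t.t, 0.0, atol=1e-12)
        ci = magnitude_lbp_image(img, SPEC8, t, np.ones((12, 12), bool))
        assert np.all(ci.codes[ci.valid] == 255)

    def test_thresholds_scale_linearly(self, rng):
        img = rng.uniform(0, 1, (14, 14))
        centers = np.ones((14, 14), bool)
        t1 = magnitude_thresholds(img, SPEC8, centers)
        t2 = magnitude_thresholds(3.0 * img, SPEC8, centers)
        np.testing.assert_allclose(t2.t, 3.0 * t1.t, rtol=1e-12)

    def test_matches_naive_oracle(self, rng):
        img = rng.uniform(0, 1, (16, 16))
        spec = NeighborhoodSpec(P=8, R=1.4)
        centers = np.ones((16, 16), bool)
        offs = neighbor_offsets(spec)
        t = magnitude_thresholds(img, spec, centers)
        # brute-force threshold accumulation
        _, valid = naive_sign_lbp(img, spec)
        for p, (dr, dc) in enumerate(offs):
            diffs = [
                abs(img[r, c] - naive_neighbor_value(img, r, c, dr, dc))
                for r in range(16)
                for c in range(16)
                if valid[r, c]
            ]
            assert abs(t.t[p] - np.mean(diffs)) < 1e-12
        ci = magnitude_lbp_image(img, spec, t, centers)
        for r in range(16):
            for c in range(16):
                if not ci.valid[r, c]:
                    continue
                code = 0
                for p, (dr, dc) in enumerate(offs):
                    v = naive_neighbor_value(img, r, c, dr, dc)
                    if abs(img[r, c] - v) - t.t[p] <= 0:
                        code |= 1 << p
                assert ci.codes[r, c] == code

    def test_lbp_pair_consistency(self, rng):
        img = rng.uniform(0, 1, (16, 16))
        spec = NeighborhoodSpec(P=8, R=2.0)
        centers = np.ones((16, 16), bool)
        s, m, t = lbp_pair(img, spec, centers)
        s2 = sign_lbp_image(img, spec, centers)
        t2 = magnitude_thresholds(img, spec, centers)
        m2 = magnitude_lbp_image(img, spec, t2, centers)
        np.testing.assert_array_equal(s.codes, s2.codes)
        np.testing.assert_array_equal(m.codes, m2.codes)
        np.testing.assert_allclose(t.t, t2.t, rtol=1e-14)


class TestInvariances:
    def test_affine_intensity_invariance(self, rng):
        img = rng.uniform(0, 1, (18, 18))
        centers = np.ones((18, 18), bool)
        spec = NeighborhoodSpec(P=8, R=1.8)
        s1, m1, _ = lbp_pair(img, spec, centers)
        s2, m2, _ = lbp_pair(1.7 * img + 11.0, spec, centers)
        np.testing.assert_array_equal(s1.codes, s2.codes)
        np.testing.assert_array_equal(m1.codes, m2.codes)

    @pytest.mark.parametrize("R", [1.0, np.sqrt(2), 2.8])
    def test_rot90_code_equivariance(self, rng, R):
        img = rng.uniform(0, 1, (15, 15))
        spec = NeighborhoodSpec(P=8, R=R)
        centers = np.ones((15, 15), bool)
        s0, _, _ = lbp_pair(img, spec, centers)
        s1, _, _ = lbp_pair(np.rot90(img), spec, centers)
        N = 15
        for r in range(N):
            for c in range(N):
                if s1.valid[r, c]:
                    orig = int(s0.codes[c, N - 1 - r])
                    assert s1.codes[r, c] == rotate_code(orig, 2, 8)

    def test_validity_matches_geometric_oracle(self, rng):
        img = rng.uniform(0, 1, (14, 14))
        mask = np.zeros((14, 14), bool)
        mask[3:11, 2:12] = True
        spec = NeighborhoodSpec(P=8, R=2.1)
        ci = sign_lbp_image(img, spec, mask, sample_region=mask)
        offs = neighbor_offsets(spec)
        for r in range(14):
            for c in range(14):
                if not mask[r, c]:
                    assert not ci.valid[r, c]
                    continue
                inside = True
                for dr, dc in offs:
                    # membership: all bilinear-support pixels in mask
                    rs, cs = r + dr, c + dc
                    r0, c0 = int(np.floor(rs)), int(np.floor(cs))
                    for ro, wr in ((0, 1 - (rs - r0)), (1, rs - r0)):
                        for co, wc in ((0, 1 - (cs - c0)), (1, cs - c0)):
                            if wr * wc == 0:
                                continue
                            rr, cc = r0 + ro, c0 + co
                            if not (0 <= rr < 14 and 0 <= cc < 14) or not mask[rr, cc]:
                                inside = False
                assert ci.valid[r, c] == inside
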