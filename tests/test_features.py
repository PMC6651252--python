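"""Descriptor encodings vs naive reference implementations."""

import colorsys

import numpy as np
import pytest

from bananagrade.features import (
    FEATURE_DIMS,
    color_feature,
    hog_descriptor,
    lab_to_lch,
    lbp_code,
    lbp_codes,
    rgb_to_hsv,
    rgb_to_lab,
    shape_feature,
    texture_feature,
    to_gray,
    uniform_lookup,
    uplbp_histogram,
)
from bananagrade.roi import ROITriplet

from conftest import random_rgb_patch


def make_triplet(*patches) -> ROITriplet:
    return ROITriplet(
        patches=tuple(np.asarray(p, dtype=np.uint8) for p in patches),
        origins=((0, 0), (0, 48), (0, 96)),
    )


def uniform_patch(r, g, b) -> np.ndarray:
    return np.tile(np.array([r, g, b], dtype=np.uint8), (48, 48, 1))


# ---------------------------------------------------------------------------
# color conversions
# ---------------------------------------------------------------------------

class TestColorSpaces:
    @pytest.mark.parametrize(
        "rgb, h, s, v",
        [((255, 0, 0), 0.0, 1.0, 1.0),
         ((0, 255, 0), 120.0, 1.0, 1.0),
         ((128, 128, 128), 0.0, 0.0, 128 / 255)],
    )
    def test_hsv_definitions(self, rgb, h, s, v):
        patch = uniform_patch(*rgb)
        hh, ss, vv = rgb_to_hsv(patch)
        assert hh[0, 0] == pytest.approx(h, abs=1e-6)
        assert ss[0, 0] == pytest.approx(s, abs=1e-6)
        assert vv[0, 0] == pytest.approx(v, abs=1e-6)

    def test_hsv_matches_colorsys(self, rng):
        patch = random_rgb_patch(rng)
        h, s, v = rgb_to_hsv(patch)
        for r, c in [(0, 0), (7, 31), (40, 12)]:
            hh, ss, vv = colorsys.rgb_to_hsv(*(patch[r, c] / 255.0).tolist())
            assert h[r, c] == pytest.approx(hh * 360.0, abs=1e-9)
            assert s[r, c] == pytest.approx(ss, abs=1e-9)
            assert v[r, c] == pytest.approx(vv, abs=1e-9)

    def test_lab_white_and_black(self):
        _l, a, b = rgb_to_lab(uniform_patch(255, 255, 255))
        assert abs(a[0, 0]) < 0.5 and abs(b[0, 0]) < 0.5
        l0, _, _ = rgb_to_lab(uniform_patch(0, 0, 0))
        assert l0[0, 0] == pytest.approx(0.0, abs=1e-6)

    def test_lab_matches_published_reference_formulas(self, rng):
        """Cross-check against an explicit sRGB(D65) -> XYZ -> L*a*b* chain."""

        def reference_lab(rgb255):
            srgb = np.asarray(rgb255, dtype=float) / 255.0
            lin = np.where(
                srgb <= 0.04045, srgb / 12.92, ((srgb + 0.055) / 1.055) ** 2.4
            )
            M = np.array(
                [[0.4124564, 0.3575761, 0.1804375],
                 [0.2126729, 0.7151522, 0.0721750],
                 [0.0193339, 0.1191920, 0.9503041]]
            )
            xyz = M @ lin
            white = np.array([0.95047, 1.0, 1.08883])  # D65
            t = xyz / white
            f = np.where(t > (6 / 29) ** 3, np.cbrt(t), t / (3 * (6 / 29) ** 2) + 4 / 29)
            return 116 * f[1] - 16, 500 * (f[0] - f[1]), 200 * (f[1] - f[2])

        patch = random_rgb_patch(rng)
        lab_l, lab_a, lab_b = rgb_to_lab(patch)
        # the published forward and inverse sRGB<->XYZ matrices are rounded
        # independently (7 digits), so agreement is limited to ~5e-3
        for r, c in [(0, 0), (10, 20), (47, 47)]:
            L, a, b = reference_lab(patch[r, c])
            assert lab_l[r, c] == pytest.approx(L, abs=5e-3)
            assert lab_a[r, c] == pytest.approx(a, abs=5e-3)
            assert lab_b[r, c] == pytest.approx(b, abs=5e-3)

    @pytest.mark.parametrize(
        "a, b, c, h",
        [(3.0, 4.0, 5.0, None), (0.0, 0.0, 0.0, 0.0), (-5.0, 0.0, 5.0, 180.0)],
    )
    def test_lch(self, a, b, c, h):
        cc, hh = lab_to_lch(np.array([a]), np.array([b]))
        assert cc[0] == pytest.approx(c)
        if h is not None:
            assert hh[0] == pytest.approx(h)


class TestColorFeature:
    def test_constant_patch_recovers_components(self):
        patch = uniform_patch(200, 180, 40)
        trip = make_triplet(patch, patch, patch)
        f = color_feature(trip).values
        assert f.shape == (FEATURE_DIMS["color"],)
        h, s, _ = rgb_to_hsv(patch)
        _, a, b = rgb_to_lab(patch)
        c, hl = lab_to_lch(a, b)
        expected = [h[0, 0], s[0, 0], a[0, 0], b[0, 0], c[0, 0], hl[0, 0]]
        for block in range(3):
            assert f[6 * block : 6 * block + 6] == pytest.approx(expected)

    def test_two_tone_patch_means(self):
        """Half green / half yellow ROI: means equal the two-value average."""
        patch = uniform_patch(0, 255, 0)
        patch[24:] = (255, 255, 0)
        trip = make_triplet(patch, patch, patch)
        f = color_feature(trip).values
        h1, s1, _ = rgb_to_hsv(uniform_patch(0, 255, 0))
        h2, s2, _ = rgb_to_hsv(uniform_patch(255, 255, 0))
        assert f[0] == pytest.approx((h1[0, 0] + h2[0, 0]) / 2)
        assert f[1] == pytest.approx((s1[0, 0] + s2[0, 0]) / 2)


# ---------------------------------------------------------------------------
# LBP / UP-LBP
# ---------------------------------------------------------------------------

def transitions(code: int) -> int:
    bits = [(code >> k) & 1 for k in range(8)]
    return sum(bits[k] != bits[(k + 1) % 8] for k in range(8))


def naive_uplbp_histogram(gray: np.ndarray) -> np.ndarray:
    """Per-pixel double-loop recount with an independently built lookup."""
    uniform_codes = sorted(c for c in range(256) if transitions(c) <= 2)
    bin_of = {c: i for i, c in enumerate(uniform_codes)}
    hist = np.zeros(59)
    H, W = gray.shape
    for r in range(1, H - 1):
        for c in range(1, W - 1):
            code = lbp_code(gray[r - 1 : r + 2, c - 1 : c + 2])
            hist[bin_of.get(code, 58)] += 1
    return hist / hist.sum()


class TestLBP:
    def test_all_equal_gives_255(self):
        assert lbp_code(np.full((3, 3), 7)) == 255

    def test_center_strictly_greater_gives_0(self):
        p = np.zeros((3, 3), dtype=int)
        p[1, 1] = 10
        assert lbp_code(p) == 0

    def test_worked_patch_matches_bitwise_evaluation(self):
        p = np.array([[60, 120, 80], [75, 90, 110], [130, 40, 95]])
        neighbors = [p[0, 0], p[0, 1], p[0, 2], p[1, 2],
                     p[2, 2], p[2, 1], p[2, 0], p[1, 0]]
        expected = sum(
            2 ** k for k, ik in enumerate(neighbors) if ik >= p[1, 1]
        )
        assert lbp_code(p) == expected

    def test_vectorized_codes_match_scalar(self, rng):
        gray = rng.integers(0, 256, size=(12, 12))
        codes = lbp_codes(gray)
        for r in range(1, 11):
            for c in range(1, 11):
                assert codes[r - 1, c - 1] == lbp_code(gray[r - 1 : r + 2, c - 1 : c + 2])

    def test_uniform_split_58_plus_198(self):
        table = uniform_lookup()
        assert (table < 58).sum() == 58
        assert (table == 58).sum() == 198
        # spot checks from the transition rule
        assert table[0] < 58  # 00000000, 0 transitions
        assert table[85] == 58  # 01010101, 8 transitions

    def test_uniform_bins_are_distinct_and_canonical(self):
        table = uniform_lookup()
        uniform_codes = np.flatnonzero(table < 58)
        assert sorted(table[uniform_codes]) == list(range(58))
        # ascending code order
        assert np.all(np.diff(table[uniform_codes]) > 0)


class TestTextureFeature:
    def test_constant_roi_single_bin(self):
        patch = uniform_patch(90, 90, 90)
        hist = uplbp_histogram(to_gray(patch))
        table = uniform_lookup()
        assert hist[table[255]] == pytest.approx(1.0)
        assert np.count_nonzero(hist) == 1

    def test_length_and_block_normalization(self, rng):
        trip = make_triplet(*(random_rgb_patch(rng) for _ in range(3)))
        f = texture_feature(trip).values
        assert f.shape == (FEATURE_DIMS["texture"],)
        for b in range(3):
            assert f[59 * b : 59 * (b + 1)].sum() == pytest.approx(1.0)
        assert (f >= 0).all()

    def test_matches_naive_recount(self, rng):
        gray = rng.integers(0, 256, size=(48, 48))
        assert uplbp_histogram(gray) == pytest.approx(naive_uplbp_histogram(gray))

    def test_invariant_to_intensity_shift(self, rng):
        gray = rng.integers(30, 200, size=(48, 48))
        assert uplbp_histogram(gray) == pytest.approx(uplbp_histogram(gray + 40))


# ---------------------------------------------------------------------------
# HOG
# ---------------------------------------------------------------------------

def naive_hog(gray: np.ndarray) -> np.ndarray:
    """Explicit-loop HOG: Prewitt, hard votes, 2x2-cell blocks, L1 norm."""
    g = np.asarray(gray, dtype=float)
    padded = np.pad(g, 1, mode="edge")
    H, W = g.shape
    mag = np.zeros((H, W))
    ori = np.zeros((H, W))
    for r in range(H):
        for c in range(W):
            win = padded[r : r + 3, c : c + 3]
            gx = (win[:, 2] - win[:, 0]).sum()
            gy = (win[2, :] - win[0, :]).sum()
            mag[r, c] = np.hypot(gx, gy)
            ori[r, c] = np.arctan2(gy, gx) % np.pi
    cells = np.zeros((4, 4, 9))
    for ci in range(4):
        for cj in range(4):
            for r in range(ci * 12, ci * 12 + 12):
                for c in range(cj * 12, cj * 12 + 12):
                    b = min(int(ori[r, c] / (np.pi / 9)), 8)
                    cells[ci, cj, b] += mag[r, c]
    out = []
    for bi in range(3):
        for bj in range(3):
            v = cells[bi : bi + 2, bj : bj + 2].ravel()
            out.append(v / (np.abs(v).sum() + 1e-12))
    return np.concatenate(out)


class TestHOG:
    def test_length_and_block_count(self, rng):
        d = hog_descriptor(rng.integers(0, 256, size=(48, 48)))
        assert d.shape == (324,)
        norms = d.reshape(9, 36).sum(axis=1)
        assert np.all((np.isclose(norms, 1.0)) | (np.isclose(norms, 0.0)))

    def test_constant_patch_all_zero(self):
        assert not hog_descriptor(np.full((48, 48), 123)).any()

    def test_horizontal_gradient_step_lands_at_pi_over_2(self):
        """A step across rows puts all energy in the bin containing pi/2."""
        gray = np.zeros((48, 48))
        gray[24:, :] = 200.0
        d = hog_descriptor(gray).reshape(9, 36)
        bins = d.reshape(9, 2, 2, 9)
        energy = bins.sum(axis=(0, 1, 2))
        target = int((np.pi / 2) / (np.pi / 9))  # bin 4
        assert energy[target] == pytest.approx(energy.sum())

    def test_matches_naive_reference(self, rng):
        gray = rng.integers(0, 256, size=(48, 48))
        assert hog_descriptor(gray) == pytest.approx(naive_hog(gray), abs=1e-9)

    def test_invariant_to_intensity_shift(self, rng):
        gray = rng.integers(0, 200, size=(48, 48)).astype(float)
        assert hog_descriptor(gray) == pytest.approx(hog_descriptor(gray + 37.0))

    def test_wrong_size_rejected(self):
        with pytest.raises(ValueError):
            hog_descriptor(np.zeros((32, 32)))


class TestShapeFeature:
    def test_length_and_identical_blocks(self, rng):
        patch = random_rgb_patch(rng)
        trip = make_triplet(patch, patch, patch)
        f = shape_feature(trip).values
        assert f.shape == (FEATURE_DIMS["shape"],)
        assert f[:324] == pytest.approx(f[324:648])
        assert f[:324] == pytest.approx(f[648:])

    def test_concatenation_order(self, rng):
        patches = [random_rgb_patch(rng) for _ in range(3)]
        f = shape_feature(make_triplet(*patches)).values
        for i, p in enumerate(patches):
            assert f[324 * i : 324 * (i + 1)] == pytest.approx(
                hog_descriptor(to_gray(p))
            )
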