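"""Texture representations vs independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from stubbletex import Patch, requantize
from stubbletex.texture import (
    ANGLES,
    GLCM_STAT_NAMES,
    GLRLM_STAT_NAMES,
    RI_CODES_P8,
    compute_glcm,
    compute_glrlm,
    glcm_feature_vector,
    glcm_stats,
    glrlm_feature_vector,
    glrlm_stats,
    lbp_feature_vector,
    lbp_ri_codes,
)

from ._oracles import (
    brute_glcm,
    brute_glcm_stats,
    brute_glrlm,
    brute_glrlm_stats,
    brute_lbp_codes,
)

pytestmark = pytest.mark.timeout(300)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

class TestGLCM:
    def test_worked_example_counts(self, glcm_toy):
        """At 0 degrees, d=1: pair (1,1) once, pair (1,2) twice."""
        g = compute_glcm(glcm_toy, distance=1, angle=0, normalize=False)
        assert g.counts[1, 1] == 1
        assert g.counts[1, 2] == 2

    def test_constant_patch_is_point_mass(self):
        p = Patch(np.full((4, 7), 3), levels=8)
        for angle in ANGLES:
            g = compute_glcm(p, 1, angle, normalize=True)
            assert g.counts[3, 3] == pytest.approx(1.0)
            assert g.counts.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("angle", ANGLES)
    @pytest.mark.parametrize("distance", [1, 2])
    def test_matches_bruteforce_enumeration(self, angle, distance):
        rng = np.random.default_rng(7 * distance + angle)
        for _ in range(100):
            p = Patch(rng.integers(0, 4, (6, 6)), levels=4)
            ours = compute_glcm(p, distance, angle, normalize=False).counts
            np.testing.assert_array_equal(ours, brute_glcm(p.pixels, 4, distance, angle))

    @pytest.mark.parametrize("angle", ANGLES)
    def test_pair_count_conservation(self, angle):
        """Unnormalized counts sum to the number of valid ordered pairs."""
        rng = np.random.default_rng(3)
        p = Patch(rng.integers(0, 8, (10, 20)), levels=8)
        g = compute_glcm(p, 1, angle, normalize=False)
        h, w = p.shape
        expected = {0: h * (w - 1), 90: (h - 1) * w,
                    45: (h - 1) * (w - 1), 135: (h - 1) * (w - 1)}[angle]
        assert g.counts.sum() == expected
        gn = compute_glcm(p, 1, angle, normalize=True)
        assert gn.counts.sum() == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_flag_adds_transpose(self):
        rng = np.random.default_rng(0)
        p = Patch(rng.integers(0, 4, (5, 5)), levels=4)
        g = compute_glcm(p, 1, 0, normalize=False)
        gs = compute_glcm(p, 1, 0, normalize=False, symmetric=True)
        np.testing.assert_array_equal(gs.counts, g.counts + g.counts.T)

    def test_degenerate_geometry_raises(self):
        p = Patch(np.array([[1, 2]]), levels=4)
        with pytest.raises(ValueError, match="degenerate"):
            compute_glcm(p, 1, 90)
        with pytest.raises(ValueError, match="degenerate"):
            compute_glcm(p, 5, 0)

    def test_invalid_angle_raises(self):
        p = Patch(np.zeros((3, 3), dtype=int), levels=2)
        with pytest.raises(ValueError, match="angle"):
            compute_glcm(p, 1, 30)


class TestGLCMStats:
    def test_point_mass(self):
        m = np.zeros((8, 8))
        m[2, 2] = 1.0
        from stubbletex.texture import GLCMMatrix

        s = glcm_stats(GLCMMatrix(m, 8, 1, 0, True))
        assert s.asm == pytest.approx(1.0)
        assert s.ent == pytest.approx(0.0)
        assert s.con == pytest.approx(0.0)
        assert s.dis == pytest.approx(0.0)
        assert s.hom == pytest.approx(1.0)
        assert s.cor == 0.0  # zero marginal std sentinel

    def test_uniform_matrix_entropy_bits(self):
        from stubbletex.texture import GLCMMatrix

        m = np.full((8, 8), 1 / 64)
        s = glcm_stats(GLCMMatrix(m, 8, 1, 0, True))
        assert s.asm == pytest.approx(1 / 64)
        assert s.ent == pytest.approx(6.0)  # log2(64)

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(11)
        from stubbletex.texture import GLCMMatrix

        for _ in range(50):
            m = rng.random((8, 8))
            m /= m.sum()
            ours = glcm_stats(GLCMMatrix(m, 8, 1, 0, True))
            ref = brute_glcm_stats(m)
            for name in GLCM_STAT_NAMES:
                assert getattr(ours, name) == pytest.approx(ref[name], abs=1e-10)

    def test_unnormalized_input_normalized_internally(self):
        rng = np.random.default_rng(2)
        p = Patch(rng.integers(0, 4, (6, 6)), levels=4)
        a = glcm_stats(compute_glcm(p, 1, 0, normalize=False))
        b = glcm_stats(compute_glcm(p, 1, 0, normalize=True))
        assert a.as_array() == pytest.approx(b.as_array(), abs=1e-12)

    def test_all_zero_matrix_raises(self):
        from stubbletex.texture import GLCMMatrix

        with pytest.raises(ValueError):
            glcm_stats(GLCMMatrix(np.zeros((4, 4)), 4, 1, 0, False))


class TestGLCMVector:
    def test_length_and_layout(self):
        rng = np.random.default_rng(5)
        p = Patch(rng.integers(0, 256, (10, 20)), levels=256)
        fv = glcm_feature_vector(p)
        assert len(fv) == 24
        assert fv.layout[0] == ("original", "asm", 0)
        assert fv.layout[-1] == ("original", "hom", 135)

    def test_constant_patch_entries(self):
        fv = glcm_feature_vector(Patch(np.full((10, 20), 9), levels=256))
        by_stat = {
            stat: [v for v, (_, s, _) in zip(fv.values, fv.layout) if s == stat]
            for stat in GLCM_STAT_NAMES
        }
        assert by_stat["asm"] == pytest.approx([1.0] * 4)
        assert by_stat["ent"] == pytest.approx([0.0] * 4)
        assert by_stat["con"] == pytest.approx([0.0] * 4)
        assert by_stat["dis"] == pytest.approx([0.0] * 4)

    def test_entries_compose_independently(self):
        rng = np.random.default_rng(8)
        p = Patch(rng.integers(0, 16, (10, 20)), levels=16)
        fv = glcm_feature_vector(p, distance=1)
        idx = fv.layout.index(("original", "con", 90))
        expected = glcm_stats(compute_glcm(p, 1, 90)).con
        assert fv.values[idx] == pytest.approx(expected)

    def test_agrees_with_skimage_at_zero_degrees(self):
        """Independent library cross-check where the offset conventions align."""
        from skimage.feature import graycomatrix, graycoprops

        rng = np.random.default_rng(21)
        p = Patch(rng.integers(0, 16, (10, 20)), levels=16)
        ours = glcm_stats(compute_glcm(p, 1, 0))
        ref = graycomatrix(p.pixels.astype(np.uint8), [1], [0], levels=16,
                           symmetric=False, normed=True)
        for name, sk in [("asm", "ASM"), ("con", "contrast"), ("dis", "dissimilarity"),
                         ("hom", "homogeneity"), ("cor", "correlation")]:
            assert getattr(ours, name) == pytest.approx(
                float(graycoprops(ref, sk)[0, 0]), abs=1e-8)


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

class TestGLRLM:
    def test_worked_example_runs(self, glrlm_toy):
        """Gray 3 at 0 degrees: 4 runs of length 1, one of length 2, none longer."""
        q = compute_glrlm(glrlm_toy, angle=0)
        assert q.runs[3, 0] == 4
        assert q.runs[3, 1] == 1
        assert q.runs[3, 2] == 0
        assert q.runs[3, 3] == 0

    def test_single_row_single_run(self):
        p = Patch(np.full((1, 6), 2), levels=4)
        q = compute_glrlm(p, angle=0)
        assert q.runs[2, 5] == 1
        assert q.runs.sum() == 1

    @pytest.mark.parametrize("angle", ANGLES)
    def test_matches_bruteforce_and_conserves_pixels(self, angle):
        rng = np.random.default_rng(angle + 1)
        for _ in range(100):
            p = Patch(rng.integers(0, 3, (5, 5)), levels=3)
            q = compute_glrlm(p, angle)
            ref = brute_glrlm(p.pixels, 3, angle)
            np.testing.assert_array_equal(q.runs, ref)
            j = np.arange(1, q.runs.shape[1] + 1)
            assert (q.runs * j).sum() == p.height * p.width

    def test_stats_single_run_values(self):
        from stubbletex.texture import GLRLMMatrix

        runs = np.zeros((4, 4), dtype=int)
        runs[1, 2] = 1  # gray bin i=2, run length j=3
        s = glrlm_stats(GLRLMMatrix(runs, 0, 4, n_pixels_scanned=3))
        assert s.sr == pytest.approx(1 / 9)
        assert s.lr == pytest.approx(9)
        assert s.gln == pytest.approx(1)
        assert s.rln == pytest.approx(1)

    def test_stats_darkest_shortest_run_weights_are_one(self):
        from stubbletex.texture import GLRLMMatrix

        runs = np.zeros((4, 4), dtype=int)
        runs[0, 0] = 1  # i=1, j=1
        s = glrlm_stats(GLRLMMatrix(runs, 0, 4, n_pixels_scanned=1))
        assert s.lgr == pytest.approx(1)
        assert s.hgr == pytest.approx(1)
        assert s.srlg == pytest.approx(1)

    def test_stats_match_double_loop_oracle(self):
        from stubbletex.texture import GLRLMMatrix

        rng = np.random.default_rng(17)
        for _ in range(50):
            runs = rng.integers(0, 5, (6, 8))
            if runs.sum() == 0:
                continue
            n_px = int((runs * np.arange(1, 9)).sum())
            ours = glrlm_stats(GLRLMMatrix(runs, 0, 6, n_pixels_scanned=n_px))
            ref = brute_glrlm_stats(runs, n_px)
            for name in GLRLM_STAT_NAMES:
                assert getattr(ours, name) == pytest.approx(ref[name], abs=1e-10), name

    def test_empty_matrix_raises(self):
        from stubbletex.texture import GLRLMMatrix

        with pytest.raises(ValueError):
            glrlm_stats(GLRLMMatrix(np.zeros((3, 3), dtype=int), 0, 3, 9))

    def test_vector_length_and_constant_patch_gln(self):
        p = Patch(np.full((10, 20), 7), levels=256)
        fv = glrlm_feature_vector(p)
        assert len(fv) == 44
        idx = fv.layout.index(("original", "gln", 0))
        # one run per row, all the same gray: gln = rows^2 / rows = rows
        assert fv.values[idx] == pytest.approx(10)

    def test_vector_entries_compose_independently(self):
        rng = np.random.default_rng(23)
        p = Patch(rng.integers(0, 8, (10, 20)), levels=8)
        fv = glrlm_feature_vector(p)
        idx = fv.layout.index(("original", "lr", 45))
        expected = glrlm_stats(compute_glrlm(p, 45)).lr
        assert fv.values[idx] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# Rotation-invariant LBP
# ---------------------------------------------------------------------------

class TestLBP:
    def test_flat_neighborhood_gives_code_255(self):
        p = Patch(np.full((5, 5), 7), levels=8)
        codes = lbp_ri_codes(p).codes
        assert (codes == 255).all()

    def test_single_set_bit_collapses_to_one(self):
        """One neighbour >= centre yields ri code 1 at every placement."""
        offsets = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]
        for dr, dc in offsets:
            px = np.full((3, 3), 3)  # all neighbours below the centre ...
            px[1, 1] = 4
            px[1 + dr, 1 + dc] = 9  # ... except one
            p = Patch(px, levels=10)
            assert lbp_ri_codes(p).codes[1, 1] == 1

    def test_codes_match_bruteforce_rotation_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            p = Patch(rng.integers(0, 16, (7, 7)), levels=16)
            np.testing.assert_array_equal(lbp_ri_codes(p).codes,
                                          brute_lbp_codes(p.pixels))

    def test_codes_are_rotation_minimal(self):
        rng = np.random.default_rng(9)
        p = Patch(rng.integers(0, 256, (7, 7)), levels=256)
        for code in np.unique(lbp_ri_codes(p).codes):
            rotations = [((int(code) >> s) | (int(code) << (8 - s))) & 0xFF
                         for s in range(8)]
            assert code == min(rotations)

    def test_rotating_square_patch_preserves_interior_code_multiset(self):
        rng = np.random.default_rng(13)
        p = Patch(rng.integers(0, 32, (9, 9)), levels=32)
        codes = lbp_ri_codes(p).codes[1:-1, 1:-1]
        rotated = Patch(np.rot90(p.pixels).copy(), levels=32)
        codes_rot = lbp_ri_codes(rotated).codes[1:-1, 1:-1]
        assert sorted(codes.ravel()) == sorted(codes_rot.ravel())

    def test_too_small_patch_raises(self):
        with pytest.raises(ValueError):
            lbp_ri_codes(Patch(np.zeros((2, 2), dtype=int), levels=2))

    def test_histogram_vector_shape_and_conservation(self):
        rng = np.random.default_rng(6)
        p = Patch(rng.integers(0, 256, (10, 20)), levels=256)
        fv = lbp_feature_vector(p)
        assert len(fv) == 8 * 36 == 288
        blocks = fv.values.reshape(8, 36)
        # every 5x5 block contributes exactly its 25 pixels
        np.testing.assert_array_equal(blocks.sum(axis=1), np.full(8, 25))

    def test_flat_patch_histograms_concentrate_on_255(self):
        fv = lbp_feature_vector(Patch(np.full((10, 20), 3), levels=8))
        blocks = fv.values.reshape(8, 36)
        bin255 = RI_CODES_P8.index(255)
        assert (blocks[:, bin255] == 25).all()
        assert blocks.sum() == 200

    def test_non_partitionable_patch_raises(self):
        with pytest.raises(ValueError, match="partition"):
            lbp_feature_vector(Patch(np.zeros((9, 20), dtype=int), levels=2))

    def test_ri_code_alphabet_has_36_symbols(self):
        assert len(RI_CODES_P8) == 36


# ---------------------------------------------------------------------------
# Cross-cutting properties
# ---------------------------------------------------------------------------

@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    arrays(np.int64, (6, 8), elements=st.integers(0, 7)),
)
def test_all_statistics_finite_on_arbitrary_patches(pixels):
    """No NaN/Inf escapes any descriptor on any valid patch."""
    p = Patch(pixels, levels=8)
    assert np.all(np.isfinite(glcm_feature_vector(p).values))
    assert np.all(np.isfinite(glrlm_feature_vector(p).values))
    assert np.all(np.isfinite(lbp_ri_codes(p).codes))


def test_requantize_uniform_binning():
    p = Patch(np.arange(256).reshape(16, 16), levels=256)
    q = requantize(p, 4)
    assert q.levels == 4
    np.testing.assert_array_equal(np.unique(q.pixels), [0, 1, 2, 3])
    # equal-width bins of 64 source levels each
    assert q.pixels.ravel()[63] == 0 and q.pixels.ravel()[64] == 1
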