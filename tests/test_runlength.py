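"""Run-length matrices on the quantized co-occurrence matrix and the 11 indicators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from cooctex import (
    CooccurrenceMatrix,
    GrayImage,
    gl_descriptor,
    glcm_set,
    quantize_glcm,
    rl_indicators,
    runlength_matrix,
)
from cooctex.runlength import RL_THETAS, gl_feature_names
from conftest import rl_indicators_oracle, runs_oracle

IDX = {"SRE": 0, "LRE": 1, "RP": 4}


class TestQuantizeGlcm:
    def test_all_zero_matrix_maps_to_zero_image(self):
        m = CooccurrenceMatrix(np.zeros((8, 8), dtype=np.int64), 1, 0, (0, 0))
        assert np.all(quantize_glcm(m).pixels == 0)

    def test_endpoints_of_the_log_map(self):
        c = np.zeros((8, 8), dtype=np.int64)
        c[2, 2] = 1000
        q = quantize_glcm(CooccurrenceMatrix(c, 1, 0, (0, 0)), 16)
        assert q.pixels[2, 2] == 15
        assert q.pixels.sum() == 15  # all other cells at level 0

    def test_two_value_matrix_gives_exactly_two_levels(self):
        c = np.zeros((8, 8), dtype=np.int64)
        c[::2, ::2] = 500
        q = quantize_glcm(CooccurrenceMatrix(c, 1, 0, (0, 0)), 16)
        assert set(np.unique(q.pixels)) == {0, 15}

    def test_too_few_levels_rejected(self):
        m = CooccurrenceMatrix(np.ones((4, 4), dtype=np.int64), 1, 0, (0, 0))
        with pytest.raises(ValueError):
            quantize_glcm(m, 1)


class TestRunLengthMatrix:
    def test_constant_image_one_run_per_row(self):
        img = GrayImage(np.full((5, 7), 3, dtype=np.int64), 16)
        P = runlength_matrix(img, 0)
        assert P.p[3, 6] == 5  # 5 runs of length 7
        assert P.n_r == 5 and P.n_p == 35

    def test_alternating_image_all_runs_length_one(self):
        px = np.indices((6, 6)).sum(axis=0) % 2  # checkerboard, levels {0,1}
        P = runlength_matrix(GrayImage(px.astype(np.int64), 16), 0)
        assert P.p[:, 1:].sum() == 0
        assert P.n_r == P.n_p

    @pytest.mark.parametrize("theta_gl", RL_THETAS)
    def test_matches_scan_oracle_all_directions(self, rng, theta_gl):
        px = rng.integers(0, 4, size=(12, 12))
        P = runlength_matrix(GrayImage(px, 16), theta_gl)
        expected = np.zeros_like(P.p)
        for g, L in runs_oracle(px, theta_gl):
            expected[g, L - 1] += 1
        assert np.array_equal(P.p, expected)

    @pytest.mark.parametrize("theta_gl", RL_THETAS)
    def test_pixel_conservation(self, rng, theta_gl):
        px = rng.integers(0, 6, size=(9, 14))
        P = runlength_matrix(GrayImage(px, 16), theta_gl)
        j = np.arange(1, P.p.shape[1] + 1)
        assert (P.p * j).sum() == P.n_p


class TestRlIndicators:
    def test_all_length_one_runs(self):
        px = (np.indices((6, 6)).sum(axis=0) % 2).astype(np.int64)
        v = rl_indicators(runlength_matrix(GrayImage(px, 16), 0))
        assert v[IDX["SRE"]] == pytest.approx(1.0)
        assert v[IDX["LRE"]] == pytest.approx(1.0)
        assert v[IDX["RP"]] == pytest.approx(1.0)

    def test_single_run_closed_form(self):
        # 2x4 constant image: rows give 2 runs of length 4
        img = GrayImage(np.full((2, 4), 2, dtype=np.int64), 16)
        v = rl_indicators(runlength_matrix(img, 0))
        assert v[IDX["LRE"]] == pytest.approx(16.0)
        assert v[IDX["RP"]] == pytest.approx(2 / 8)

    @pytest.mark.parametrize("theta_gl", RL_THETAS)
    def test_matches_literal_formula_oracle(self, rng, theta_gl):
        px = rng.integers(0, 5, size=(10, 10))
        P = runlength_matrix(GrayImage(px, 16), theta_gl)
        expected = rl_indicators_oracle(runs_oracle(px, theta_gl), px.size)
        np.testing.assert_allclose(rl_indicators(P), expected, atol=1e-10)

    def test_sre_lre_product_bound(self, rng):
        # Cauchy-Schwarz on the run-length distribution
        for _ in range(10):
            px = rng.integers(0, 4, size=(12, 12))
            v = rl_indicators(runlength_matrix(GrayImage(px, 16), 0))
            assert v[0] * v[1] >= 1.0 - 1e-12


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    px=hnp.arrays(np.int64, hnp.array_shapes(min_dims=2, max_dims=2, min_side=2, max_side=10),
                  elements=st.integers(0, 15)),
    theta_gl=st.sampled_from(RL_THETAS),
)
def test_property_every_pixel_in_exactly_one_run(px, theta_gl):
    P = runlength_matrix(GrayImage(px, 16), theta_gl)
    j = np.arange(1, P.p.shape[1] + 1)
    assert (P.p * j).sum() == P.n_p == px.size


class TestGlDescriptor:
    def test_length_352_and_names(self, rng):
        img = GrayImage(rng.integers(0, 256, size=(16, 16)))
        v = gl_descriptor(glcm_set(img))
        assert v.shape == (352,)
        assert len(gl_feature_names()) == 352

    def test_deterministic_repeat(self, rng):
        px = rng.integers(0, 256, size=(16, 16))
        s = glcm_set(GrayImage(px))
        assert np.array_equal(gl_descriptor(s), gl_descriptor(s))

    def test_anisotropic_fixture_separates_run_directions(self):
        # a correlated texture concentrates the GLCM along its main diagonal,
        # so row runs (theta_GL=0) differ from diagonal runs (theta_GL=135);
        # note 0 vs 90 are always equal on a symmetric matrix
        from cooctex import TextureSpec, make_image

        img = make_image(TextureSpec("correlated_noise", rho=0.9, size=(32, 32), seed=2))
        v = gl_descriptor(glcm_set(img))
        block = v.reshape(2, 4, 4, 11)  # d, theta, theta_GL, stat
        assert np.allclose(block[0, 0, 0], block[0, 0, 2])  # row/column symmetry
        assert not np.allclose(block[0, 0, 0], block[0, 0, 3])  # rows vs diagonals
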