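"""GLCM construction and texture features, checked against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemotex.glcm import (
    FEATURE_NAMES,
    GLCMatrix,
    Offset,
    compute_features,
    compute_glcm,
)
from chemotex.image_io import GrayPatch

from conftest import random_patch

ANGLE_STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def oracle_glcm(pixels: np.ndarray, G: int, distance: int, angle: int, symmetric: bool):
    """Naive pair-enumeration GLCM: explicit double loop over every pixel."""
    n = pixels.shape[0]
    dr, dc = ANGLE_STEPS[angle]
    dr, dc = dr * distance, dc * distance
    counts = np.zeros((G, G))
    for r in range(n):
        for c in range(n):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < n and 0 <= c2 < n:
                counts[pixels[r, c], pixels[r2, c2]] += 1
                if symmetric:
                    counts[pixels[r2, c2], pixels[r, c]] += 1
    return counts / counts.sum(), int(counts.sum())


def oracle_features(C: np.ndarray):
    """Features from an explicit double loop over every (i, j) cell."""
    G = C.shape[0]
    contrast = energy = homogeneity = entropy = 0.0
    for i in range(G):
        for j in range(G):
            c = C[i, j]
            contrast += c * (i - j) ** 2
            energy += c * c
            homogeneity += c / (1 + abs(i - j))
            if c > 0:
                entropy -= c * np.log2(c)
    return contrast, energy, homogeneity, entropy


class TestComputeGlcm:
    def test_hand_enumerated_asymmetric(self):
        patch = GrayPatch(pixels=np.array([[0, 1], [0, 1]]), gray_levels=2)
        g = compute_glcm(patch, Offset(1, 0, symmetric=False))
        assert g.pair_count == 2
        expected = np.array([[0.0, 1.0], [0.0, 0.0]])
        np.testing.assert_array_equal(g.C, expected)

    def test_hand_enumerated_symmetric(self):
        patch = GrayPatch(pixels=np.array([[0, 1], [0, 1]]), gray_levels=2)
        g = compute_glcm(patch, Offset(1, 0, symmetric=True))
        assert g.pair_count == 4
        np.testing.assert_array_equal(g.C, np.array([[0.0, 0.5], [0.5, 0.0]]))

    @pytest.mark.parametrize("angle", [0, 45, 90, 135])
    def test_constant_patch_single_cell(self, angle):
        patch = GrayPatch(pixels=np.full((8, 8), 3), gray_levels=5)
        g = compute_glcm(patch, Offset(2, angle))
        assert g.C[3, 3] == 1.0
        assert g.C.sum() == 1.0

    def test_offset_too_large_raises(self):
        patch = GrayPatch(pixels=np.zeros((4, 4), dtype=int), gray_levels=2)
        with pytest.raises(ValueError):
            compute_glcm(patch, Offset(4, 0))

    @pytest.mark.parametrize("angle", [0, 45, 90, 135])
    @pytest.mark.parametrize("symmetric", [True, False])
    def test_matches_pair_enumeration_oracle(self, rng, angle, symmetric):
        for _ in range(5):
            side = int(rng.integers(5, 31))
            G = int(rng.integers(2, 17))
            d = int(rng.integers(1, 5))
            patch = random_patch(rng, side, G)
            got = compute_glcm(patch, Offset(d, angle, symmetric))
            want_C, want_n = oracle_glcm(patch.pixels, G, d, angle, symmetric)
            assert got.pair_count == want_n
            np.testing.assert_allclose(got.C, want_C, atol=1e-14)

    def test_matches_scikit_image(self, rng):
        """Independent library cross-check at 0 and 90 degrees (symmetric)."""
        from skimage.feature import graycomatrix

        patch = random_patch(rng, 25, 8)
        for angle, sk_angle in ((0, 0.0), (90, np.pi / 2)):
            got = compute_glcm(patch, Offset(3, angle, symmetric=True))
            ref = graycomatrix(
                patch.pixels.astype(np.uint8), distances=[3], angles=[sk_angle],
                levels=8, symmetric=True, normed=True,
            )[:, :, 0, 0]
            np.testing.assert_allclose(got.C, ref, atol=1e-14)


class TestComputeFeatures:
    def test_constant_patch_features(self):
        patch = GrayPatch(pixels=np.full((10, 10), 7), gray_levels=16)
        f = compute_features(compute_glcm(patch, Offset(1, 0)))
        assert (f.contrast, f.energy, f.homogeneity, f.entropy) == (0.0, 1.0, 1.0, 0.0)

    def test_checkerboard_pair_matrix(self):
        """Symmetric two-level checkerboard: C(0,1)=C(1,0)=0.5."""
        C = np.array([[0.0, 0.5], [0.5, 0.0]])
        f = compute_features(GLCMatrix(C=C, gray_levels=2, offset=Offset(1, 0), pair_count=4))
        assert f.contrast == pytest.approx(1.0)
        assert f.energy == pytest.approx(0.5)
        assert f.homogeneity == pytest.approx(0.5)
        assert f.entropy == pytest.approx(1.0)  # one bit

    def test_matches_cellwise_oracle(self, rng):
        patch = random_patch(rng, 20, 8)
        g = compute_glcm(patch, Offset(2, 45))
        f = compute_features(g)
        contrast, energy, homogeneity, entropy = oracle_features(g.C)
        assert f.contrast == pytest.approx(contrast, abs=1e-10)
        assert f.energy == pytest.approx(energy, abs=1e-10)
        assert f.homogeneity == pytest.approx(homogeneity, abs=1e-10)
        assert f.entropy == pytest.approx(entropy, abs=1e-10)

    def test_entropy_base_e(self, rng):
        patch = random_patch(rng, 15, 6)
        g = compute_glcm(patch, Offset(1, 0))
        bits = compute_features(g, entropy_base=2.0).entropy
        nats = compute_features(g, entropy_base=np.e).entropy
        assert nats == pytest.approx(bits * np.log(2.0), rel=1e-12)

    def test_uniform_mass_extremes(self):
        """k equal-mass cells: entropy log2 k (maximal), energy 1/k (minimal)."""
        G = 6
        for k in (1, 3, 8):
            C = np.zeros((G, G))
            for i, j in [(n // G, n % G) for n in range(k)]:
                C[i, j] = 1.0 / k
            f = compute_features(GLCMatrix(C=C, gray_levels=G, offset=Offset(1, 0), pair_count=k))
            assert f.entropy == pytest.approx(np.log2(k), abs=1e-12)
            assert f.energy == pytest.approx(1.0 / k, abs=1e-12)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    side=st.integers(4, 20),
    G=st.integers(2, 12),
    d=st.integers(1, 3),
    angle=st.sampled_from([0, 45, 90, 135]),
    seed=st.integers(0, 2**31 - 1),
)
def test_glcm_normalization_and_feature_bounds(side, G, d, angle, seed):
    """Sum C = 1; energy, homogeneity in (0,1]; entropy <= 2 log2 G;
    contrast <= (G-1)^2 — for arbitrary random patches and offsets."""
    rng = np.random.default_rng(seed)
    patch = GrayPatch(pixels=rng.integers(0, G, size=(side, side)), gray_levels=G)
    g = compute_glcm(patch, Offset(d, angle))
    assert abs(g.C.sum() - 1.0) < 1e-12
    if g.offset.symmetric:
        np.testing.assert_array_equal(g.C, g.C.T)
    f = compute_features(g)
    assert 0.0 < f.energy <= 1.0
    assert 0.0 < f.homogeneity <= 1.0
    assert 0.0 <= f.entropy <= 2.0 * np.log2(G) + 1e-12
    assert 0.0 <= f.contrast <= (G - 1) ** 2


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1), d=st.integers(1, 4))
def test_gray_level_reversal_invariance(seed, d):
    """Mapping v -> G-1-v preserves all four features of a symmetric GLCM."""
    rng = np.random.default_rng(seed)
    G = 8
    px = rng.integers(0, G, size=(16, 16))
    f1 = compute_features(compute_glcm(GrayPatch(pixels=px, gray_levels=G), Offset(d, 0)))
    f2 = compute_features(
        compute_glcm(GrayPatch(pixels=G - 1 - px, gray_levels=G), Offset(d, 0))
    )
    for name in FEATURE_NAMES:
        assert getattr(f1, name) == pytest.approx(getattr(f2, name), abs=1e-12)
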