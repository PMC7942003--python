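"""Texture, shape and sharpness features against brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

from nodvess.errors import EmptyMaskError, InsufficientDataError
from nodvess.nodule_features import (
    DIRECTIONS_13,
    GLCMatrix,
    SHAPE_NAMES,
    SHARPNESS_NAMES,
    TextureBankConfig,
    bank_manifest,
    compute_glcm,
    correlation_std,
    diagonal_gradient_kurtosis,
    extract_texture_bank,
    glcm_correlation,
    quantize,
    shape_features,
    sharpness_features,
)
from nodvess.volume_io import BinaryMask, Volume

from conftest import digital_sphere


def _brute_force_glcm(q, offset, ng):
    """O(N) pair enumeration with explicit python loops (the oracle)."""
    counts = np.zeros((ng, ng))
    nz, ny, nx = q.shape
    dz, dy, dx = offset
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                z2, y2, x2 = z + dz, y + dy, x + dx
                if not (0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx):
                    continue
                a, b = q[z, y, x], q[z2, y2, x2]
                if a >= 0 and b >= 0:
                    counts[a, b] += 1
                    counts[b, a] += 1
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------

def test_quantize_equal_width_binning():
    vol = Volume(np.array([[[-100.0, 0.0, 100.0]]]), (1, 1, 1))
    mask = BinaryMask(np.ones((1, 1, 3), dtype=bool), (1, 1, 1))
    q, flag = quantize(vol, mask, ng=2)
    assert not flag
    np.testing.assert_array_equal(q[0, 0], [0, 0, 1])


def test_quantize_constant_region_flags_zero_variance():
    vol = Volume(np.full((3, 3, 3), 42.0), (1, 1, 1))
    mask = BinaryMask(np.ones((3, 3, 3), dtype=bool), (1, 1, 1))
    q, flag = quantize(vol, mask, ng=8)
    assert flag
    assert set(np.unique(q)) == {0}


def test_quantize_uniform_noise_fills_bins_evenly():
    rng = np.random.default_rng(0)
    vol = Volume(rng.uniform(-500, 500, size=(47, 47, 47)), (1, 1, 1))
    mask = BinaryMask(np.ones(vol.shape, dtype=bool), (1, 1, 1))
    q, _ = quantize(vol, mask, ng=8)
    counts = np.bincount(q.ravel(), minlength=8)
    expected = q.size / 8
    chi2 = np.sum((counts - expected) ** 2 / expected)
    assert chi2 < stats.chi2.ppf(0.999, df=7)


def test_quantize_out_of_mask_is_ignored():
    vol = Volume(np.zeros((3, 3, 3)), (1, 1, 1))
    mask = np.zeros((3, 3, 3), dtype=bool)
    mask[1, 1, 1] = True
    q, _ = quantize(vol, BinaryMask(mask, (1, 1, 1)), ng=4)
    assert q[0, 0, 0] == -1 and q[1, 1, 1] == 0


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", range(5))
def test_glcm_matches_brute_force_enumeration(seed):
    rng = np.random.default_rng(seed)
    ng = 4
    q = rng.integers(0, ng, size=(5, 6, 5)).astype(np.int32)
    q[rng.random(q.shape) < 0.3] = -1  # random mask holes
    for off in [(0, 0, 1), (1, 0, 0), (1, -1, 1), (0, 1, -1)]:
        got = compute_glcm(q, off, ng)
        expected = _brute_force_glcm(q, off, ng)
        np.testing.assert_allclose(got.p, expected, atol=1e-12)


def test_glcm_constant_region_single_entry():
    q = np.zeros((4, 4, 4), dtype=np.int32)
    g = compute_glcm(q, (0, 0, 1), ng=4)
    assert g.p[0, 0] == 1.0
    assert np.isclose(g.p.sum(), 1.0)


def test_glcm_stripe_pattern_off_diagonal():
    q = np.tile(np.array([0, 1, 0, 1], dtype=np.int32), (4, 4, 1))
    g = compute_glcm(q, (0, 0, 1), ng=2)
    assert np.isclose(g.p[0, 1] + g.p[1, 0], 1.0)


def test_glcm_no_valid_pairs_raises():
    q = np.full((3, 3, 3), -1, dtype=np.int32)
    q[1, 1, 1] = 0
    with pytest.raises(InsufficientDataError):
        compute_glcm(q, (0, 0, 1), ng=2)


def test_glcm_correlation_analytic_cases():
    ng = 4
    diag = GLCMatrix(np.eye(ng) / ng, (0, 0, 1), ng)
    assert np.isclose(glcm_correlation(diag), 1.0)
    marg = np.array([0.1, 0.2, 0.3, 0.4])
    indep = GLCMatrix(np.outer(marg, marg), (0, 0, 1), ng)
    assert abs(glcm_correlation(indep)) < 1e-10


def test_glcm_correlation_matches_direct_summation():
    p = np.array([[0.4, 0.1], [0.1, 0.4]])
    g = GLCMatrix(p, (0, 0, 1), 2)
    # direct summation over the 4 cells
    mu = 0.5
    sigma = np.sqrt(0.25)
    expected = sum(
        (i - mu) * (j - mu) * p[i, j] for i in range(2) for j in range(2)
    ) / sigma**2
    assert np.isclose(glcm_correlation(g), expected)


def test_glcm_correlation_bounded(textured_case):
    vol, labels, _ = textured_case
    mask = BinaryMask(labels == 1, vol.spacing)
    q, _ = quantize(vol, mask, 16)
    for off in DIRECTIONS_13:
        c = glcm_correlation(compute_glcm(q, off, 16))
        assert -1.0 <= c <= 1.0


def test_correlation_std_detects_anisotropy():
    rng = np.random.default_rng(1)
    mask = BinaryMask(np.ones((24, 24, 24), dtype=bool), (1, 1, 1))
    iso = Volume(rng.normal(size=(24, 24, 24)), (1, 1, 1))
    # stripes correlated along z only
    stripes = rng.normal(size=(24, 24, 24))
    stripes = np.repeat(stripes[::4].copy(), 4, axis=0) + 0.1 * rng.normal(
        size=(24, 24, 24))
    aniso = Volume(stripes, (1, 1, 1))
    assert correlation_std(aniso, mask) > correlation_std(iso, mask)
    assert correlation_std(iso, mask) >= 0.0


def test_diagonal_gradient_kurtosis_gaussian_reference():
    rng = np.random.default_rng(2)
    vol = Volume(rng.normal(size=(50, 50, 50)), (1, 1, 1))
    mask = BinaryMask(np.ones(vol.shape, dtype=bool), (1, 1, 1))
    k = diagonal_gradient_kurtosis(vol, mask)
    assert abs(k - 3.0) < 0.2


def test_diagonal_gradient_kurtosis_heavy_tails_increase():
    rng = np.random.default_rng(3)
    base = rng.normal(size=(40, 40, 40))
    spiky = base.copy()
    spiky[rng.random(spiky.shape) < 0.01] += 25.0
    mask = BinaryMask(np.ones(base.shape, dtype=bool), (1, 1, 1))
    k0 = diagonal_gradient_kurtosis(Volume(base, (1, 1, 1)), mask)
    k1 = diagonal_gradient_kurtosis(Volume(spiky, (1, 1, 1)), mask)
    assert k1 > k0


def test_diagonal_gradient_kurtosis_constant_volume_sentinel():
    vol = Volume(np.zeros((8, 8, 8)), (1, 1, 1))
    mask = BinaryMask(np.ones((8, 8, 8), dtype=bool), (1, 1, 1))
    assert diagonal_gradient_kurtosis(vol, mask) == 0.0


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

def test_sphere_shape_descriptors_near_analytic():
    mask = digital_sphere(radius_mm=10.0, spacing=0.5)
    feats = shape_features(mask)
    assert 0.97 <= feats["sphericity"] <= 1.0
    assert 0.97 <= feats["convexity"] <= 1.0
    assert abs(feats["equivalent_diameter_mm"] - 20.0) < 0.5
    assert len(feats) == 13 and set(feats) == set(SHAPE_NAMES)


def test_spiculation_raises_roughness_lowers_sphericity():
    from nodvess.phantoms import PhantomSpec, generate_case

    base = dict(nodule_diameter_mm=12.0, n_vessels=0, noise_sigma_hu=0,
                texture_std_hu=0, volume_shape=(64, 64, 64))
    _, smooth_labels, _ = generate_case(PhantomSpec(**base), 1)
    _, spic_labels, _ = generate_case(
        PhantomSpec(**base, spiculation_count=8, spiculation_amplitude=0.3), 1)
    f_smooth = shape_features(BinaryMask(smooth_labels == 1, (0.7,) * 3))
    f_spic = shape_features(BinaryMask(spic_labels == 1, (0.7,) * 3))
    assert f_spic["roughness"] > f_smooth["roughness"]
    assert f_spic["sphericity"] < f_smooth["sphericity"]


def test_sphericity_scale_invariant():
    small = shape_features(digital_sphere(5.0, 0.25))
    large = shape_features(digital_sphere(10.0, 0.5))
    assert abs(small["sphericity"] - large["sphericity"]) < 0.02


def test_shape_axis_permutation_invariance():
    from nodvess.phantoms import PhantomSpec, generate_case

    _, labels, _ = generate_case(
        PhantomSpec(nodule_diameter_mm=10, n_vessels=0, noise_sigma_hu=0,
                    spiculation_count=5, spiculation_amplitude=0.2,
                    volume_shape=(48, 48, 48)), 4)
    m = labels == 1
    f1 = shape_features(BinaryMask(m, (0.7,) * 3))
    f2 = shape_features(BinaryMask(np.transpose(m, (2, 0, 1)), (0.7,) * 3))
    assert f1["volume_mm3"] == f2["volume_mm3"]  # voxel count: exact
    for name in ("sphericity", "convexity", "roughness"):
        # meshing is not exactly permutation-symmetric; discretization-level
        assert np.isclose(f1[name], f2[name], rtol=0.02)


def test_shape_error_paths():
    with pytest.raises(EmptyMaskError):
        shape_features(BinaryMask(np.zeros((4, 4, 4), dtype=bool), (1, 1, 1)))
    two = np.zeros((8, 8, 8), dtype=bool)
    two[1, 1, 1] = True
    two[6, 6, 6] = True
    with pytest.raises(ValueError):
        shape_features(BinaryMask(two, (1, 1, 1)))


# ---------------------------------------------------------------------------
# sharpness
# ---------------------------------------------------------------------------

def test_sharp_edge_scores_higher_than_smoothed():
    from scipy import ndimage as ndi

    mask = digital_sphere(6.0, 0.7, pad_mm=6.0)
    hard = np.where(mask.data, -30.0, -900.0)
    soft = ndi.gaussian_filter(hard, sigma=2.0 / 0.7)
    f_hard, _ = sharpness_features(Volume(hard, (0.7,) * 3), mask)
    f_soft, _ = sharpness_features(Volume(soft, (0.7,) * 3), mask)
    assert f_hard["sharpness_mean"] > f_soft["sharpness_mean"]


def test_sharpness_contract_and_degenerate():
    mask = digital_sphere(4.0, 1.0)
    uniform = Volume(np.zeros(mask.shape), (1, 1, 1))
    feats, flags = sharpness_features(uniform, mask)
    assert set(feats) == set(SHARPNESS_NAMES) and len(feats) == 12
    assert feats["sharpness_mean"] == 0.0
    assert {"sharpness_skewness", "sharpness_kurtosis"} <= flags


# ---------------------------------------------------------------------------
# texture bank
# ---------------------------------------------------------------------------

def test_bank_manifest_is_830_unique_names():
    manifest = bank_manifest()
    names = [n for _, n in manifest]
    assert len(names) == 830
    assert len(set(names)) == 830
    assert "correlation_std" in names
    assert "diagonal_gradient_kurtosis" in names


def test_texture_bank_extraction_deterministic(textured_case):
    vol, labels, _ = textured_case
    mask = BinaryMask(labels == 1, vol.spacing)
    fv1 = extract_texture_bank(vol, mask)
    fv2 = extract_texture_bank(vol, mask)
    assert fv1.names == fv2.names
    np.testing.assert_array_equal(fv1.values, fv2.values)
    assert len(fv1) == 830


def test_texture_bank_constant_input_keeps_length(textured_case):
    vol, labels, _ = textured_case
    mask = BinaryMask(labels == 1, vol.spacing)
    flat = Volume(np.zeros(vol.shape), vol.spacing)
    fv = extract_texture_bank(flat, mask)
    assert len(fv) == 830          # length invariant under degeneracy
    assert len(fv.flags) > 0       # degenerate features flagged, not dropped
    assert fv["correlation_std"] == 0.0


def test_texture_bank_named_features_match_standalone(textured_case):
    vol, labels, _ = textured_case
    mask = BinaryMask(labels == 1, vol.spacing)
    fv = extract_texture_bank(vol, mask)
    cfg = TextureBankConfig()
    # the bank computes on a bbox crop; standalone on the full grid must agree
    assert np.isclose(fv["diagonal_gradient_kurtosis"],
                      diagonal_gradient_kurtosis(vol, mask), rtol=1e-6)
    assert np.isclose(fv["correlation_std"],
                      correlation_std(vol, mask, cfg), rtol=1e-6)
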