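"""The 45 radiomic features: frozen expected values, brute-force oracle
equivalence, and invariance properties."""

import warnings

import numpy as np
import pytest

from fieldfx.phantom import powerlaw_noise
from fieldfx.radiomics import (
    COARSENESS_CAP,
    FEATURE_NAMES,
    boxcounting_dimensions,
    edge_frequency_features,
    extract_all,
    fourier_features,
    glcm_compute,
    glcm_features,
    histogram_features,
    minkowski_dimension,
    ngtdm_features,
    powerlaw_betas,
)

from oracles import glcm_counts_bruteforce, haralick_bruteforce, ngtdm_bruteforce


def test_feature_names_frozen():
    """The canonical order (a)7 + (b)4 + (c)8 + (d)2 + (e)2 + (f)8 + (g)14
    is a package constant; any reorder is an API break."""
    assert len(FEATURE_NAMES) == 45
    assert FEATURE_NAMES[0] == "Boxcounting dimension"
    assert FEATURE_NAMES[6] == "Minkod global MD"
    assert FEATURE_NAMES[7] == "Edge frequency: mean gradient"
    assert FEATURE_NAMES[11] == "Histogram average"
    assert FEATURE_NAMES[19] == "Fourier root mean square (FRMS)"
    assert FEATURE_NAMES[21] == "Coarseness"
    assert FEATURE_NAMES[23] == "Powerlaw beta 1"
    assert FEATURE_NAMES[31] == "GLCM contrast"
    assert FEATURE_NAMES[44] == "GLCM variance"
    assert len(set(FEATURE_NAMES)) == 45


class TestHistogram:
    def test_uniform_gray_levels(self, rng):
        """Each value 0..4095 exactly 4 times: the empirical-CDF thresholds
        fall at ceil(q*4096)-1."""
        vals = np.repeat(np.arange(4096), 4)
        rng.shuffle(vals)
        avg, max_cdf, min_cdf, *_rest = histogram_features(vals.reshape(128, 128))
        assert max_cdf == 3891  # smallest g with CDF(g) >= 0.95
        assert min_cdf == 204
        assert avg == pytest.approx(2047.5)

    def test_constant_degenerate(self, constant_roi):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            h = histogram_features(constant_roi)
        avg, max_cdf, min_cdf, balance, seventy, thirty, quasi, skew = h
        assert avg == max_cdf == min_cdf == seventy == thirty == 7
        assert np.isnan(balance) and np.isnan(quasi) and np.isnan(skew)

    def test_symmetric_two_point(self):
        x = np.tile([1000, 3000], 8192).reshape(128, 128)
        h = histogram_features(x)
        assert h[0] == pytest.approx(2000.0)
        assert h[7] == pytest.approx(0.0, abs=1e-12)


class TestEdgeFrequency:
    def test_flat_field_all_zero(self, constant_roi):
        np.testing.assert_array_equal(edge_frequency_features(constant_roi), np.zeros(4))

    def test_vertical_step_max_gradient(self):
        """Sobel weights (1,2,1): a step of height h has max gradient 4h."""
        h = 10.0
        img = np.zeros((128, 128))
        img[:, 64:] = h
        assert edge_frequency_features(img)[1] == pytest.approx(4 * h)

    def test_transpose_invariance(self, random_roi):
        a = edge_frequency_features(random_roi.pixels)
        b = edge_frequency_features(random_roi.pixels.T)
        np.testing.assert_allclose(a, b, rtol=1e-12)


class TestFourier:
    def test_constant_frms_zero(self, constant_roi):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            frms, ffmp = fourier_features(constant_roi)
        assert frms == 0.0 and np.isnan(ffmp)

    def test_parseval_frms_equals_spatial_sd(self, rng):
        for _ in range(20):
            x = rng.integers(0, 4096, (128, 128)).astype(float)
            frms = fourier_features(x)[0]
            assert frms == pytest.approx(x.std(), rel=1e-6)

    def test_pure_cosine_first_moment(self):
        x = 2000 + 100 * np.cos(2 * np.pi * 0.25 * np.arange(128))[None, :] * np.ones((128, 1))
        assert fourier_features(x)[1] == pytest.approx(0.25, abs=1e-9)


class TestPowerlawBetas:
    def test_beta_recovery(self):
        for beta in (1.0, 2.0, 3.0):
            ests = [powerlaw_betas(powerlaw_noise((128, 128), beta, s))[0] for s in range(20)]
            assert np.mean(ests) == pytest.approx(beta, abs=0.3)

    def test_white_noise_flat_spectrum(self):
        ests = [powerlaw_betas(powerlaw_noise((128, 128), 0.0, s))[0] for s in range(20)]
        assert np.mean(ests) == pytest.approx(0.0, abs=0.3)

    def test_shift_invariance(self, random_roi):
        a = powerlaw_betas(random_roi.pixels)
        b = powerlaw_betas(random_roi.pixels + 500)
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_constant_all_nan(self, constant_roi):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert np.isnan(powerlaw_betas(constant_roi)).all()


class TestNGTDM:
    def test_constant_contrast_zero_coarseness_capped(self, constant_roi):
        coarseness, contrast = ngtdm_features(constant_roi)
        assert contrast == 0.0
        assert coarseness == COARSENESS_CAP

    def test_bruteforce_oracle_equivalence(self, rng):
        from fieldfx.radiomics import _requantize

        for _ in range(20):
            img = rng.integers(0, 256, (8, 8)).astype(float)
            q = _requantize(img, 8)
            expected = ngtdm_bruteforce(q, 8)
            got = ngtdm_features(img, levels=8)
            np.testing.assert_allclose(got, expected, rtol=1e-9)

    def test_checkerboard_less_coarse_than_flat(self):
        cb = (np.indices((128, 128)).sum(axis=0) % 2) * 4000
        assert ngtdm_features(cb)[0] < COARSENESS_CAP


class TestGLCM:
    def test_constant_point_mass(self, constant_roi):
        g = glcm_compute(constant_roi)
        assert g.matrix.sum() == pytest.approx(1.0)
        assert g.matrix[0, 0] == pytest.approx(1.0)

    def test_2x2_hand_count(self):
        """[[0,1],[2,3]] at levels=4, d=1 has 12 directed pairs over the
        four angles; compare with the brute-force enumeration."""
        img = np.array([[0.0, 1.0], [2.0, 3.0]])
        angles = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
        g = glcm_compute(img * 1000, levels=4, distance=1, angles=angles)
        counts = glcm_counts_bruteforce(np.array([[0, 1], [2, 3]]), 4, 1, angles)
        assert counts.sum() == 12  # 12 directed pairs after symmetrization
        np.testing.assert_allclose(g.matrix, counts / counts.sum(), rtol=1e-12)

    def test_symmetric_and_normalized(self, random_roi):
        g = glcm_compute(random_roi)
        assert g.matrix.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(g.matrix, g.matrix.T, rtol=1e-12)

    def test_checkerboard_closed_form(self):
        cb = (np.indices((128, 128)).sum(axis=0) % 2) * 1000
        g = glcm_compute(cb, levels=2, distance=1, angles=(0.0, np.pi / 2))
        f = glcm_features(g)
        assert f[0] == pytest.approx(1.0)  # contrast
        assert f[1] == pytest.approx(-1.0)  # correlation

    def test_constant_feature_values(self, constant_roi):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f = glcm_features(glcm_compute(constant_roi))
        assert f[0] == 0.0  # contrast
        assert f[4] == 1.0  # energy
        assert f[5] == 0.0  # entropy
        assert f[6] == 1.0  # homogeneity
        assert np.isnan(f[1])  # correlation

    def test_all_14_match_bruteforce(self, rng):
        for _ in range(20):
            img = rng.integers(0, 256, (8, 8)).astype(float)
            g = glcm_compute(img, levels=8, distance=1)
            got = glcm_features(g)
            exp = haralick_bruteforce(g.matrix)
            order = ["contrast", "correlation", "diff_entropy", "diff_var",
                     "energy", "entropy", "homogeneity", "imc1", "imc2", "mcc",
                     "sum_avg", "sum_entropy", "sum_var", "variance"]
            np.testing.assert_allclose(got, [exp[k] for k in order], rtol=1e-9, atol=1e-12)


class TestFractal:
    def test_solid_square_dimension_two(self):
        img = np.zeros((128, 128))
        img[32:96, 32:96] = 1000
        assert boxcounting_dimensions(img)[0] == pytest.approx(2.0, abs=0.1)

    def test_line_dimension_one(self):
        img = np.zeros((128, 128))
        img[64, :] = 1000
        assert boxcounting_dimensions(img)[0] == pytest.approx(1.0, abs=0.1)

    def test_affine_gray_rescale_invariance(self, random_roi):
        x = random_roi.pixels.astype(float)
        a = boxcounting_dimensions(x)
        b = boxcounting_dimensions(3.0 * x + 250.0)
        np.testing.assert_allclose(a, b, rtol=1e-12, equal_nan=True)

    def test_constant_mask_degenerate(self, constant_roi):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert np.isnan(boxcounting_dimensions(constant_roi)).all()

    def test_minkowski_flat_surface_is_two(self, constant_roi):
        assert minkowski_dimension(constant_roi) == pytest.approx(2.0, abs=1e-9)

    def test_minkowski_rough_surface_above_two(self, random_roi):
        d = minkowski_dimension(random_roi)
        assert 2.0 < d < 3.0


class TestExtractAll:
    def test_phantom_roi_full_finite_vector(self, phantom_roi):
        fv = extract_all(phantom_roi)
        assert len(fv.values) == 45
        assert fv.names == FEATURE_NAMES
        assert np.isfinite(fv.values).all()

    def test_constant_roi_nan_catalogue(self, constant_roi):
        """Degenerate flat patch: exactly the documented feature subset is
        NaN (balance ratios, skewness, FFMP, betas, the GLCM correlation
        family, and all box-counting thresholds), all others finite."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fv = extract_all(constant_roi)
        d = fv.as_dict()
        expected_nan = {
            *(f"Boxcounting dimension{s}" for s in ("", " 1", " 2", " 3", " 4", " 5")),
            "Histogram balance", "Histogram quasi balance", "Histogram skewness",
            "Fourier first moment of power spectrum (FFMP)",
            *(f"Powerlaw beta {k}" for k in range(1, 9)),
            "GLCM correlation",
            "GLCM information measure of correlation 1 (IMC1)",
            "GLCM information measure of correlation 2 (IMC2)",
            "GLCM maximum correlation coefficient",
        }
        got_nan = {k for k, v in d.items() if np.isnan(v)}
        assert got_nan == expected_nan

    def test_deterministic(self, phantom_roi):
        a = extract_all(phantom_roi).values
        b = extract_all(phantom_roi).values
        np.testing.assert_array_equal(a, b)
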