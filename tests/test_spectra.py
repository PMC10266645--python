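import numpy as np
import pytest

import somspec as ss
from somspec.exceptions import DomainError, ParameterError

from _oracles import sg_center_fit, upper_hull_chords


def make_set(wl, vals, tag="R"):
    vals = np.atleast_2d(vals)
    return ss.SpectrumSet([f"s{k}" for k in range(vals.shape[0])], wl, vals, tag)


class TestSpectrumSet:
    def test_grid_must_be_uniform_increasing(self):
        with pytest.raises(ParameterError):
            make_set(np.array([350, 351, 353]), np.zeros((1, 3)))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ParameterError):
            ss.SpectrumSet(["a", "a"], np.array([350, 351]), np.full((2, 2), 0.5), "R")

    def test_reflectance_range_enforced_for_r(self):
        with pytest.raises(ParameterError):
            make_set(np.array([350, 351]), np.array([[0.5, 1.2]]), "R")

    def test_lr_values_unbounded(self):
        s = make_set(np.array([350, 351]), np.array([[2.0, -3.0]]), "LR")
        assert s.transform_tag == "LR"


class TestSavitzkyGolay:
    def test_polynomial_reproduced_and_grid_trimmed(self):
        # degree <= poly_order is invariant under the smoother; the native
        # 2151-band grid must shrink to 2141 bands over 355-2495 nm
        wl = np.arange(350, 2501)
        t = (wl - 350) / 2150.0
        quad = 0.1 + 0.6 * t - 0.3 * t**2
        out = ss.savitzky_golay_smooth(make_set(wl, quad[None, :], "RAW"))
        assert out.n_bands == 2141
        assert out.wavelengths_nm[0] == 355 and out.wavelengths_nm[-1] == 2495
        expected = quad[5:-5]
        np.testing.assert_allclose(out.values[0], expected, atol=1e-12)
        assert out.transform_tag == "R"

    def test_matches_per_window_least_squares_oracle(self, toy_spectrum):
        out = ss.savitzky_golay_smooth(toy_spectrum, window_bands=11, poly_order=2)
        expected = sg_center_fit(toy_spectrum.values, 11, 2)
        np.testing.assert_allclose(out.values, expected, atol=1e-10)

    @pytest.mark.parametrize("window,order", [(10, 2), (3, 3), (41, 2)])
    def test_bad_window_parameters(self, toy_spectrum, window, order):
        with pytest.raises(ParameterError):
            ss.savitzky_golay_smooth(toy_spectrum, window, order)


class TestLogReflectance:
    def test_reference_values(self):
        s = make_set(np.array([400, 401]), np.array([[1.0, 0.1]]))
        out = ss.transform_lr(s)
        np.testing.assert_allclose(out.values, [[0.0, 1.0]], atol=1e-15)
        assert out.transform_tag == "LR"

    def test_monotone_inversion(self):
        vals = np.linspace(0.9, 0.3, 7)[None, :]
        out = ss.transform_lr(make_set(np.arange(400, 407), vals))
        assert np.all(np.diff(out.values[0]) > 0)

    def test_roundtrip(self, toy_spectrum):
        out = ss.transform_lr(toy_spectrum)
        np.testing.assert_allclose(10.0 ** (-out.values), toy_spectrum.values, rtol=1e-12)

    def test_nonpositive_value_names_sample_and_band(self):
        s = ss.SpectrumSet(["ok", "bad"], np.arange(400, 403),
                           np.array([[0.5, 0.5, 0.5], [0.5, 0.0, 0.5]]), "R")
        with pytest.raises(DomainError, match="bad.*401"):
            ss.transform_lr(s)

    def test_requires_smoothed_reflectance(self):
        s = make_set(np.arange(400, 403), np.full((1, 3), 0.5), "RAW")
        with pytest.raises(ParameterError):
            ss.transform_lr(s)


class TestContinuumRemoval:
    def test_affine_spectrum_is_its_own_hull(self):
        wl = np.arange(400, 420)
        vals = (0.2 + 0.01 * (wl - 400))[None, :]
        out = ss.transform_cr(make_set(wl, vals))
        np.testing.assert_allclose(out.values, 1.0, atol=1e-12)

    def test_three_band_dip(self):
        out = ss.transform_cr(make_set(np.arange(400, 403), np.array([[1.0, 0.5, 1.0]])))
        np.testing.assert_allclose(out.values, [[1.0, 0.5, 1.0]], atol=1e-12)

    def test_hull_matches_exhaustive_chord_oracle(self, rng):
        wl = np.arange(600, 612)
        for _ in range(10):
            v = rng.uniform(0.2, 0.9, size=12)
            hull = ss.upper_convex_hull(wl, v)
            np.testing.assert_allclose(hull, upper_hull_chords(wl, v), atol=1e-10)

    def test_endpoints_one_and_bounded(self, toy_spectrum):
        out = ss.transform_cr(toy_spectrum)
        assert np.all(out.values[:, 0] == 1.0) and np.all(out.values[:, -1] == 1.0)
        assert out.values.min() > 0 and out.values.max() <= 1.0

    def test_too_few_bands(self):
        with pytest.raises(ParameterError):
            ss.transform_cr(make_set(np.array([400]), np.array([[0.5]])))


class TestFirstDerivative:
    def test_constant_and_affine(self):
        wl = np.arange(400, 410)
        const = ss.transform_fdr(make_set(wl, np.full((1, 10), 0.4)))
        np.testing.assert_allclose(const.values, 0.0, atol=1e-15)
        affine = ss.transform_fdr(make_set(wl, (0.1 + 0.02 * (wl - 400))[None, :]))
        np.testing.assert_allclose(affine.values, 0.02, atol=1e-12)

    def test_sinusoid_matches_analytic_derivative(self):
        wl = np.arange(400, 1000)
        amp, period = 0.2, 200.0
        vals = (0.5 + amp * np.sin(2 * np.pi * wl / period))[None, :]
        out = ss.transform_fdr(make_set(wl, vals))
        analytic = amp * (2 * np.pi / period) * np.cos(2 * np.pi * wl / period)
        # central differences are second-order accurate; boundaries are first-order
        err = np.abs(out.values[0, 1:-1] - analytic[1:-1])
        assert err.max() <= 1e-3 * amp

    def test_derivative_of_cumulative_sum_recovers_spectrum(self, rng):
        wl = np.arange(500, 540)
        f = 0.001 * rng.uniform(0.2, 0.8, size=wl.size)
        cum = np.cumsum(f)[None, :]
        out = ss.transform_fdr(make_set(wl, cum))
        # interior central differences of a cumsum average adjacent increments
        mid = 0.5 * (f[1:-1] + f[2:])
        np.testing.assert_allclose(out.values[0, 1:-1], mid, atol=1e-12)

    def test_band_count_preserved(self, toy_spectrum):
        assert ss.transform_fdr(toy_spectrum).n_bands == toy_spectrum.n_bands

    def test_too_few_bands(self):
        with pytest.raises(ParameterError):
            ss.transform_fdr(make_set(np.array([400, 401]), np.full((1, 2), 0.5)))


def test_all_transforms_preserve_sample_order(small_soil_data):
    raw, _ = small_soil_data
    spectra = ss.all_transforms(raw)
    for tag, s in spectra.items():
        assert s.sample_ids == raw.sample_ids
        assert s.n_samples == raw.n_samples
        assert s.n_bands == 2141
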