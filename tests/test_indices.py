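import numpy as np
import pytest

import somspec as ss
from somspec.exceptions import DegenerateInputError, ParameterError
from somspec.indices import compute_index_column

from _oracles import correlation_map_loop, rank_cells_exhaustive


def make_set(wl, vals, tag="R"):
    vals = np.atleast_2d(vals)
    return ss.SpectrumSet([f"s{k}" for k in range(vals.shape[0])], np.asarray(wl), vals, tag)


def toy_map_data(rng, n=10, p=12, lo=0.1, hi=0.9):
    wl = np.arange(500, 500 + p)
    vals = rng.uniform(lo, hi, size=(n, p))
    s = make_set(wl, vals)
    som = ss.SoilSampleTable(s.sample_ids, rng.uniform(10, 50, n))
    return s, som


class TestDeviationOfArch:
    def test_flat_spectrum_zero(self):
        s = make_set(np.arange(500, 700), np.full((2, 200), 0.4))
        np.testing.assert_allclose(ss.deviation_of_arch(s), 0.0, atol=1e-15)

    def test_direct_arithmetic(self):
        wl = np.arange(550, 651, 50)  # 550, 600, 650
        s = make_set(wl, np.array([[0.10, 0.12, 0.15]]))
        np.testing.assert_allclose(ss.deviation_of_arch(s), [-0.005], atol=1e-15)

    def test_missing_band_error(self):
        s = make_set(np.arange(700, 800), np.full((1, 100), 0.4))
        with pytest.raises(ParameterError):
            ss.deviation_of_arch(s)

    def test_negative_correlation_on_synthetic_soil(self, small_transforms):
        spectra, som = small_transforms
        doa = ss.deviation_of_arch(spectra["R"])
        assert np.corrcoef(doa, som.som_g_per_kg)[0, 1] < 0


class TestPairIndexValues:
    def test_di_same_band_is_zero(self, rng):
        s, _ = toy_map_data(rng)
        np.testing.assert_allclose(ss.pair_index_values(s, 503, 503, "DI"), 0.0)

    def test_ndi_antisymmetric(self, rng):
        s, _ = toy_map_data(rng)
        a = ss.pair_index_values(s, 502, 508, "NDI")
        b = ss.pair_index_values(s, 508, 502, "NDI")
        np.testing.assert_allclose(a, -b, atol=1e-15)

    def test_ri_reciprocal_identity(self, rng):
        s, _ = toy_map_data(rng)
        a = ss.pair_index_values(s, 501, 507, "RI")
        b = ss.pair_index_values(s, 507, 501, "RI")
        np.testing.assert_allclose(a * b, 1.0, rtol=1e-12)

    def test_same_band_error_for_ratio_kinds(self, rng):
        s, _ = toy_map_data(rng)
        for kind in ("RI", "NDI"):
            with pytest.raises(ParameterError):
                ss.pair_index_values(s, 505, 505, kind)

    def test_near_zero_denominator_marked_invalid(self):
        wl = np.array([400, 401])
        s = make_set(wl, np.array([[0.5, 0.5], [0.3, -0.3]]), "FDR")
        out = ss.pair_index_values(s, 400, 401, "NDI")
        assert np.isfinite(out[0]) and np.isnan(out[1])


class TestCorrelationMap:
    def test_matches_scalar_loop_oracle(self, rng):
        s, som = toy_map_data(rng, n=10, p=12)
        for kind in ("DI", "RI", "NDI"):
            cmap = ss.index_correlation_map(s, som, kind)
            oracle = correlation_map_loop(s.values, som.som_g_per_kg, kind)
            both = cmap.valid & np.isfinite(oracle)
            assert np.array_equal(cmap.valid, np.isfinite(oracle))
            np.testing.assert_allclose(cmap.r_matrix[both], oracle[both], atol=1e-10)

    def test_di_map_antisymmetric_and_bounded(self, rng):
        s, som = toy_map_data(rng, n=15, p=10)
        cmap = ss.index_correlation_map(s, som, "DI")
        v = cmap.valid & cmap.valid.T
        np.testing.assert_allclose(
            cmap.r_matrix[v], -cmap.r_matrix.T[v], atol=1e-10
        )
        assert np.nanmax(np.abs(cmap.r_matrix)) <= 1.0

    def test_invariant_to_affine_som_rescaling(self, rng):
        s, som = toy_map_data(rng)
        m1 = ss.index_correlation_map(s, som, "NDI")
        som2 = ss.SoilSampleTable(som.sample_ids, 3.0 * som.som_g_per_kg + 7.0)
        m2 = ss.index_correlation_map(s, som2, "NDI")
        np.testing.assert_allclose(
            m1.r_matrix[m1.valid], m2.r_matrix[m2.valid], atol=1e-12
        )

    def test_constant_som_rejected(self, rng):
        s, _ = toy_map_data(rng)
        som = ss.SoilSampleTable(s.sample_ids, np.full(s.n_samples, 25.0))
        with pytest.raises(DegenerateInputError):
            ss.index_correlation_map(s, som, "DI")

    def test_planted_di_pair_is_argmax(self):
        cfg = ss.SyntheticConfig(
            n_samples=150, seed=5, noise_sd=0.005,
            planted_pair=ss.PlantedPair("DI", 1400, 1430, 0.99),
        )
        spectra, som, defn = ss.generate_planted_index_data(cfg)
        sub = spectra.crop(1300, 1530)
        top = ss.select_top_indexes(ss.index_correlation_map(sub, som, "DI"), 1)[0]
        assert abs(top.band_i_nm - 1400) <= 2 and abs(top.band_j_nm - 1430) <= 2


class TestSelectTopIndexes:
    def test_ranking_matches_exhaustive_sort(self, rng):
        s, som = toy_map_data(rng, n=12, p=6)
        for kind in ("DI", "RI", "NDI"):
            cmap = ss.index_correlation_map(s, som, kind)
            got = ss.select_top_indexes(cmap, 5)
            expected = rank_cells_exhaustive(cmap.bands, cmap.r_matrix, cmap.valid, kind, 5)
            assert [(d.band_i_nm, d.band_j_nm) for d in got] == [
                (i, j) for i, j, _ in expected
            ]
            np.testing.assert_allclose(
                [d.r_with_som for d in got], [r for _, _, r in expected], atol=1e-12
            )

    def test_no_mirrored_pairs_returned(self, rng):
        s, som = toy_map_data(rng, n=12, p=8)
        got = ss.select_top_indexes(ss.index_correlation_map(s, som, "DI"), 10)
        pairs = {(d.band_i_nm, d.band_j_nm) for d in got}
        assert all((j, i) not in pairs for i, j in pairs)

    def test_k_too_large(self, rng):
        s, som = toy_map_data(rng, n=10, p=4)
        cmap = ss.index_correlation_map(s, som, "DI")
        with pytest.raises(ParameterError):
            ss.select_top_indexes(cmap, 1000)


class TestAssembleFeatures:
    def test_column_counts_and_self_consistency(self, small_transforms):
        spectra, som = small_transforms
        frame, defs = ss.assemble_si_features(spectra, som, k=1, band_step=16)
        assert frame.shape == (som.n_samples, 13)
        for d in defs:
            np.testing.assert_allclose(
                frame[d.name].to_numpy(), compute_index_column(d, spectra), atol=1e-12
            )

    def test_missing_transform_error(self, small_transforms):
        spectra, som = small_transforms
        partial = {t: s for t, s in spectra.items() if t != "CR"}
        with pytest.raises(ParameterError):
            ss.assemble_si_features(partial, som, k=1, band_step=16)
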