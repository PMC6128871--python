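import numpy as np
import pandas as pd
import pytest

from peatspec.peaks import PeakMeasurement
from peatspec.spectra import Spectrum
from peatspec.synthetic import BandSpec, generate_spectrum
from peatspec.trends import (
    AreaNormalizedPCA, LoessSmoother, fit_external_vectors,
    humification_indices, latitudinal_regression, loess_profile, pca_spectra,
    pooled_t_test, surface_summary,
)


def pm(name, height, sid="s"):
    return PeakMeasurement(sid, name, 900.0, 1100.0, "local_minimum",
                           "local_minimum", 1000.0, height, height, height, 1.0)


class TestSurfaceSummary:
    def _table(self):
        return pd.DataFrame({
            "core_id": ["A", "A", "A", "B"],
            "depth_cm": [10.0, 30.0, 70.0, 5.0],
            "carbohydrates_est": [10.0, 20.0, 99.0, 33.0],
            "aromatics_est": [1.0, 3.0, 50.0, 2.0],
        })

    def test_mean_and_sample_sd_within_50cm(self):
        out = surface_summary(self._table()).set_index("core_id")
        assert out.loc["A", "n_sections"] == 2
        assert out.loc["A", "mean_carbohydrates_est"] == pytest.approx(15.0)
        assert out.loc["A", "sd_carbohydrates_est"] == pytest.approx(
            np.sqrt(50.0))  # sample SD of {10, 20}
        assert out.loc["B", "n_sections"] == 1
        assert np.isnan(out.loc["B", "sd_carbohydrates_est"])

    def test_core_without_surface_sections_omitted(self):
        t = self._table()
        t.loc[t.core_id == "B", "depth_cm"] = 80.0
        out = surface_summary(t)
        assert list(out["core_id"]) == ["A"]

    def test_row_order_invariance(self):
        t = self._table()
        shuffled = t.sample(frac=1.0, random_state=3).reset_index(drop=True)
        pd.testing.assert_frame_equal(surface_summary(t), surface_summary(shuffled))

    def test_excluded_rows_dropped(self):
        t = self._table()
        t["excluded"] = [False, True, False, False]
        out = surface_summary(t).set_index("core_id")
        assert out.loc["A", "n_sections"] == 1


class TestLatitudinalRegression:
    def test_exact_linear_relation(self):
        lats = np.array([5.0, 25.0, 45.0, 65.0])
        summ = pd.DataFrame({
            "core_id": list("abcd"), "latitude_deg": lats,
            "mean_carbohydrates_est": 0.5 * lats + 10.0,
        })
        r = latitudinal_regression(summ, "latitude_deg", "mean_carbohydrates_est")
        assert r.slope == pytest.approx(0.5)
        assert r.intercept == pytest.approx(10.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_permuted_covariate_p_values_are_null(self):
        rng = np.random.default_rng(0)
        lats = np.linspace(5, 65, 12)
        resp = 0.4 * lats + rng.normal(0, 2, 12)
        ps = []
        for seed in range(100):
            perm = np.random.default_rng(seed).permutation(lats)
            summ = pd.DataFrame({"core_id": range(12), "latitude_deg": perm,
                                 "mean_carbohydrates_est": resp})
            ps.append(latitudinal_regression(
                summ, "latitude_deg", "mean_carbohydrates_est").p_value)
        ps = np.array(ps)
        assert 0.35 < ps.mean() < 0.65   # roughly uniform null
        assert (ps < 0.05).mean() < 0.15

    def test_too_few_cores(self):
        summ = pd.DataFrame({"core_id": ["a", "b"], "latitude_deg": [5.0, 50.0],
                             "mean_carbohydrates_est": [1.0, 2.0]})
        with pytest.raises(ValueError):
            latitudinal_regression(summ, "latitude_deg", "mean_carbohydrates_est")


class TestPooledTTest:
    def test_hand_computed_example(self):
        """Pooled variance 1, t = -1/sqrt(2/3), df 4, p from the t(4) CDF."""
        t, df, p = pooled_t_test([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-np.sqrt(1.5), rel=1e-12)
        assert df == 4
        assert p == pytest.approx(0.28786, abs=5e-5)

    def test_identical_groups(self):
        t, df, p = pooled_t_test([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_swapping_groups_negates_t(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 12)
        t1, df1, p1 = pooled_t_test(a, b)
        t2, df2, p2 = pooled_t_test(b, a)
        assert t1 == -t2 and df1 == df2 and p1 == p2

    def test_singleton_group_is_not_determinable(self):
        with pytest.warns(UserWarning):
            t, df, p = pooled_t_test([1.0], [2.0, 3.0])
        assert np.isnan(t) and np.isnan(p)

    def test_zero_variance_unequal_means(self):
        with pytest.warns(UserWarning):
            t, df, p = pooled_t_test([1.0, 1.0], [2.0, 2.0])
        assert p == 0.0


def loess_oracle(x, y, x0, degree=2, span=0.75):
    """Independent local WLS: tricube weights on the span-nearest points,
    weighted polyfit, evaluate at x0."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    q = int(np.ceil(span * x.size))
    d = np.abs(x - x0)
    idx = np.argsort(d, kind="stable")[:q]
    dmax = d[idx].max()
    w = (1 - (d[idx] / dmax) ** 3) ** 3 if dmax > 0 else np.ones(q)
    keep = w > 0
    coeffs = np.polyfit(x[idx][keep] - x0, y[idx][keep], degree,
                        w=np.sqrt(w[keep]))
    return coeffs[-1]


class TestLoess:
    def test_quadratic_data_reproduced_exactly(self):
        x = np.linspace(0, 100, 25)
        y = 0.01 * x**2 - 0.5 * x + 3.0
        sm = LoessSmoother().fit(x, y)
        np.testing.assert_allclose(sm.predict(x), y, atol=1e-8)

    def test_constant_data_zero_band(self):
        x = np.linspace(0, 10, 15)
        sm = LoessSmoother().fit(x, np.full(15, 7.0))
        fit, lo, hi = sm.predict(x, return_band=True)
        np.testing.assert_allclose(fit, 7.0, atol=1e-10)
        np.testing.assert_allclose(hi - lo, 0.0, atol=1e-8)

    def test_agrees_with_direct_wls_oracle(self):
        rng = np.random.default_rng(13)
        x = np.sort(rng.uniform(0, 100, 20))
        y = 30 - 0.2 * x + rng.normal(0, 1.5, 20)
        sm = LoessSmoother().fit(x, y)
        for x0 in [5.0, 22.0, 47.5, 71.0, 95.0]:
            assert sm.predict([x0])[0] == pytest.approx(
                loess_oracle(x, y, x0), abs=1e-8)

    def test_grouped_profile_splits_at_45N(self):
        rng = np.random.default_rng(2)
        n = 40
        df = pd.DataFrame({
            "depth_cm": np.tile(np.linspace(0, 100, 10), 4),
            "latitude_deg": np.repeat([10.0, 20.0, 50.0, 60.0], 10),
            "carbohydrates_est": rng.uniform(20, 80, n),
        })
        out = loess_profile(df, "carbohydrates_est")
        assert set(out["group"]) == {"high_latitude", "low_latitude"}
        assert (out["upper"] >= out["fit"]).all() and (out["fit"] >= out["lower"]).all()


class TestPCA:
    def _toy_spectra(self, n=4, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            bands = [BandSpec(1030, rng.uniform(0.2, 0.6), 12),
                     BandSpec(1630, rng.uniform(0.1, 0.4), 12),
                     BandSpec(3400, 0.3, 250)]
            out.append(generate_spectrum(bands, seed=i, sample_id=f"s{i}"))
        return out

    def test_identical_spectra_have_zero_variance(self):
        s = self._toy_spectra(1)[0]
        spectra = [Spectrum(f"c{i}", s.wavenumbers, s.absorbance) for i in range(4)]
        pca = pca_spectra(spectra)
        np.testing.assert_allclose(pca.explained_variance_, 0.0, atol=1e-12)
        np.testing.assert_allclose(pca.scores_.to_numpy(), 0.0, atol=1e-9)

    def test_preprocessed_areas_are_exactly_100(self):
        spectra = self._toy_spectra(5)
        pca = AreaNormalizedPCA().fit(spectra)
        M, _ = pca._preprocess(spectra, pca.common_grid_)
        areas = np.trapezoid(M, pca.common_grid_, axis=1)
        np.testing.assert_allclose(areas, 100.0, rtol=1e-9)

    def test_scores_match_eigendecomposition_oracle(self):
        spectra = self._toy_spectra(4)
        pca = AreaNormalizedPCA(n_components=3).fit(spectra)
        M, _ = pca._preprocess(spectra, pca.common_grid_)
        C = M - M.mean(axis=0)
        # brute-force eigendecomposition of the Gram matrix (n << p)
        gram = C @ C.T
        evals, evecs = np.linalg.eigh(gram)
        order = np.argsort(evals)[::-1]
        for k in range(3):
            oracle = evecs[:, order[k]] * np.sqrt(max(evals[order[k]], 0.0))
            got = pca.scores_.iloc[:, k].to_numpy()
            err = min(np.abs(got - oracle).max(), np.abs(got + oracle).max())
            assert err < 1e-8

    def test_variance_conservation_and_reconstruction(self):
        spectra = self._toy_spectra(6, seed=5)
        pca = AreaNormalizedPCA().fit(spectra)
        M, _ = pca._preprocess(spectra, pca.common_grid_)
        C = M - M.mean(axis=0)
        total_var = np.sum(C**2) / (len(spectra) - 1)
        assert np.sum(pca.explained_variance_) == pytest.approx(total_var, rel=1e-9)
        recon = pca.scores_.to_numpy() @ pca.loadings_
        np.testing.assert_allclose(recon, C, atol=1e-8)

    def test_loading_sign_convention(self):
        pca = AreaNormalizedPCA().fit(self._toy_spectra(5, seed=9))
        for row in pca.loadings_:
            assert row[np.argmax(np.abs(row))] > 0


class TestVectorFitting:
    def _scores(self, n=30, seed=1):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.normal(0, 1, (n, 2)), columns=["PC1", "PC2"],
                            index=[f"s{i}" for i in range(n)])

    def test_variable_equal_to_pc1(self):
        scores = self._scores()
        variables = pd.DataFrame({"v": scores["PC1"]})
        out = fit_external_vectors(scores, variables, n_perm=99, seed=0)
        row = out.iloc[0]
        assert row["r_squared"] == pytest.approx(1.0)
        assert abs(row["dx"]) == pytest.approx(1.0, abs=1e-9)
        assert abs(row["dy"]) == pytest.approx(0.0, abs=1e-6)
        assert row["p_perm"] == pytest.approx(1 / 100)

    def test_noise_variable_is_rarely_significant(self):
        scores = self._scores(40, seed=2)
        n_sig = 0
        for seed in range(20):
            noise = pd.DataFrame(
                {"v": np.random.default_rng(100 + seed).normal(0, 1, 40)},
                index=scores.index)
            out = fit_external_vectors(scores, noise, n_perm=99, seed=seed)
            n_sig += int(out.iloc[0]["p_perm"] <= 0.05)
        assert n_sig <= 3

    def test_constant_variable_reported_undefined(self):
        scores = self._scores(10)
        with pytest.warns(UserWarning):
            out = fit_external_vectors(
                scores, pd.DataFrame({"v": np.ones(10)}, index=scores.index),
                n_perm=99, seed=0)
        assert out.iloc[0]["r_squared"] == 0.0
        assert out.iloc[0]["p_perm"] == 1.0


class TestHumificationIndices:
    def test_equal_heights_give_ratio_two(self):
        ms = [pm(n, 0.003) for n in ("carb", "arom15", "arom16", "aliph28", "aliph29")]
        arom, aliph = humification_indices(ms)
        assert arom == pytest.approx(2.0)
        assert aliph == pytest.approx(2.0)

    def test_zero_carb_is_undefined(self):
        ms = [pm("carb", 0.0), pm("arom15", 0.001), pm("arom16", 0.001)]
        with pytest.warns(UserWarning):
            arom, aliph = humification_indices(ms)
        assert np.isnan(arom) and np.isnan(aliph)

    def test_invariant_under_spectrum_scaling(self, triangle_spectrum):
        # normalized heights are scale-free, so the ratios are too
        ms1 = [pm("carb", 0.002), pm("arom15", 0.001), pm("arom16", 0.003)]
        ms2 = [pm("carb", 0.002), pm("arom15", 0.001), pm("arom16", 0.003)]
        assert humification_indices(ms1) == humification_indices(ms2)
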