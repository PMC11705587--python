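"""Least-squares unmixing: matrix assembly, OLS/WLS solvers, AF comparison."""

import numpy as np
import pytest

import lungspectra as ls
from lungspectra.simulate import cell_variant, CELL_SHIFTED_DEFAULT
from lungspectra.spectral import DetectorLayout, normalize_signature
from lungspectra.unmix import (
    CollinearityError,
    EndmemberMatrix,
    SpectralUnmixer,
    af_comparison_report,
    build_mixing_matrix,
    unmix_ols,
    unmix_wls,
)

TOY_LAYOUT = DetectorLayout(lasers=(("CH", 3),))


def _toy_matrix():
    sigs = [
        normalize_signature(v, mode="unit", name=n)
        for n, v in [("a", [1, 0, 0]), ("b", [0, 1, 0]), ("c", [0, 0, 1])]
    ]
    return build_mixing_matrix(sigs, layout=TOY_LAYOUT)


class TestBuildMixingMatrix:
    def test_full_panel_has_30_columns(self, fluor_sigs, af_truth):
        m = build_mixing_matrix(fluor_sigs, af_truth)
        assert m.n_endmembers == 30
        np.testing.assert_allclose(np.linalg.norm(m.matrix, axis=0), 1.0)

    def test_empty_af_set_keeps_fluorochromes_only(self, fluor_sigs):
        assert build_mixing_matrix(fluor_sigs).n_endmembers == 27

    def test_identical_columns_raise_collinearity_error(self):
        sig = normalize_signature(np.arange(64) + 1.0, mode="unit", name="x")
        twin = normalize_signature(2 * (np.arange(64) + 1.0), mode="unit", name="y")
        with pytest.raises(CollinearityError, match="'x' and 'y'"):
            build_mixing_matrix([sig, twin])

    def test_duplicate_names_are_a_structural_error(self):
        sig = normalize_signature(np.arange(64) + 1.0, mode="unit", name="x")
        other = normalize_signature(np.ones(64), mode="unit", name="x")
        with pytest.raises(ValueError, match="duplicate"):
            build_mixing_matrix([sig, other])


class TestUnmixOLS:
    def test_identity_matrix_returns_raw_values(self):
        result = unmix_ols(np.array([[2.0, 3.0, 5.0]]), _toy_matrix())
        np.testing.assert_allclose(result.abundances, [[2, 3, 5]], atol=1e-12)
        assert result.residual_rms[0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_noise_sample_recovers_truth_exactly(
        self, panel, profiles, endmembers
    ):
        zero = ls.NoiseModel(0.0, 0.0, 0.0)
        table = ls.simulate_sample(
            profiles, np.full(17, 1 / 17), panel, endmembers, zero, 500, seed=1,
            carrier="beads",
        )
        sigs = [endmembers[n] for n in table.truth_names]
        m = build_mixing_matrix(sigs)
        result = unmix_ols(table, m)
        assert np.max(np.abs(result.abundances - table.truth_abundances)) < 1e-8

    def test_matches_pseudo_inverse_oracle(self):
        rng = np.random.default_rng(2)
        A = rng.uniform(0, 1, (64, 30))
        A /= np.linalg.norm(A, axis=0)
        m = EndmemberMatrix(tuple(f"e{i}" for i in range(30)), A)
        X = rng.uniform(0, 100, (50, 64))
        result = unmix_ols(X, m)
        oracle = X @ np.linalg.pinv(A).T
        np.testing.assert_allclose(result.abundances, oracle, atol=1e-10)

    def test_residual_orthogonal_to_column_space(self, default_sample, true_matrix):
        result = unmix_ols(default_sample, true_matrix)
        resid = default_sample.raw - result.abundances @ true_matrix.matrix.T
        proj = resid @ true_matrix.matrix
        scale = np.abs(default_sample.raw).max()
        assert np.abs(proj).max() / scale < 1e-8

    def test_equivariant_under_column_rescaling(self):
        rng = np.random.default_rng(3)
        A = rng.uniform(0, 1, (16, 4))
        X = rng.uniform(0, 10, (20, 16))
        m1 = EndmemberMatrix(("a", "b", "c", "d"), A)
        scaled = A.copy()
        scaled[:, 2] *= 5.0
        m2 = EndmemberMatrix(("a", "b", "c", "d"), scaled)
        r1 = unmix_ols(X, m1)
        r2 = unmix_ols(X, m2)
        np.testing.assert_allclose(r2.abundances[:, 2] * 5.0, r1.abundances[:, 2], rtol=1e-9)

    def test_dimension_mismatch_is_a_structural_error(self):
        with pytest.raises(ValueError, match="detectors"):
            unmix_ols(np.ones((5, 10)), _toy_matrix())


class TestUnmixWLS:
    def test_equal_variances_reduce_to_ols(self):
        rng = np.random.default_rng(4)
        A = rng.uniform(0, 1, (16, 5))
        m = EndmemberMatrix(tuple("abcde"), A)
        X = rng.uniform(0, 10, (30, 16))
        ols = unmix_ols(X, m)
        wls = unmix_wls(X, m, np.full(16, 3.7))
        np.testing.assert_allclose(wls.abundances, ols.abundances, atol=1e-10)

    def test_nonpositive_variance_is_invalid(self):
        with pytest.raises(ValueError, match="positive"):
            unmix_wls(np.ones((2, 3)), _toy_matrix(), [1.0, 0.0, 1.0])

    def test_infinite_variance_ignores_that_detector(self):
        rng = np.random.default_rng(5)
        A = rng.uniform(0.1, 1, (8, 3))
        m = EndmemberMatrix(("a", "b", "c"), A)
        X = rng.uniform(0, 10, (20, 8))
        X_corrupt = X.copy()
        X_corrupt[:, 0] = 1e6  # garbage on the ignored detector
        var = np.ones(8)
        var[0] = np.inf
        wls = unmix_wls(X_corrupt, m, var)
        reduced = EndmemberMatrix(("a", "b", "c"), A[1:])
        ols_reduced = unmix_ols(X[:, 1:], reduced)
        np.testing.assert_allclose(wls.abundances, ols_reduced.abundances, atol=1e-8)

    def test_variance_weighting_beats_ols_under_heteroscedasticity(self):
        rng = np.random.default_rng(6)
        A = rng.uniform(0, 1, (16, 4))
        A /= np.linalg.norm(A, axis=0)
        m = EndmemberMatrix(("a", "b", "c", "d"), A)
        var = np.ones(16)
        var[:4] = 400.0  # four very noisy detectors
        rmse_ols, rmse_wls = [], []
        for seed in range(50):
            r = np.random.default_rng(seed)
            truth = r.uniform(10, 100, (40, 4))
            clean = truth @ A.T
            noisy = clean + r.normal(0, np.sqrt(var), size=clean.shape)
            rmse_ols.append(np.sqrt(np.mean((unmix_ols(noisy, m).abundances - truth) ** 2)))
            rmse_wls.append(
                np.sqrt(np.mean((unmix_wls(noisy, m, var).abundances - truth) ** 2))
            )
        assert np.mean(rmse_wls) < np.mean(rmse_ols)


class TestSpectralUnmixer:
    def test_sklearn_round_trip(self, fluor_sigs, af_truth, default_sample):
        est = SpectralUnmixer(endmembers=fluor_sigs + af_truth).fit()
        abund = est.transform(default_sample.raw)
        assert abund.shape == (default_sample.n_events, 30)
        assert list(est.get_feature_names_out()) == list(est.endmember_names_)
        params = est.get_params()
        assert params["method"] == "ols"

    def test_wls_requires_variances(self, fluor_sigs):
        with pytest.raises(ValueError, match="variances"):
            SpectralUnmixer(endmembers=fluor_sigs, method="wls").fit()


class TestAFComparisonReport:
    def test_multi_af_reduces_background_bias(
        self, panel, profiles, endmembers, af_truth, true_matrix, default_sample
    ):
        uns = ls.simulate_unstained(profiles, af_truth, ls.NoiseModel(), 4000, seed=30)
        single = normalize_signature(uns.raw.mean(axis=0), mode="unit", name="AF-whole")
        sigs = [
            cell_variant(endmembers[f]) if f in CELL_SHIFTED_DEFAULT else endmembers[f]
            for f in panel.fluorochromes
        ]
        m_single = build_mixing_matrix(sigs, [single])
        report = af_comparison_report(default_sample, true_matrix, m_single, panel)
        ratio = report.bias_multi.abs() / report.bias_single.abs()
        assert (ratio < 1).mean() >= 0.9
        assert set(report.laser) == {"UV", "V", "B", "YG", "R"}

    def test_single_true_af_source_makes_configs_agree(
        self, panel, profiles, endmembers, af_truth
    ):
        solo_af = af_truth[:1]
        from lungspectra.simulate import PopulationProfile

        solo = [
            PopulationProfile(
                p.name, p.marker_levels,
                {solo_af[0].name: sum(p.af_weights.values())},
                p.scatter, p.viability,
            )
            for p in profiles
        ]
        sample = ls.simulate_sample(
            solo, np.full(17, 1 / 17), panel,
            {**{f: endmembers[f] for f in panel.fluorochromes}, solo_af[0].name: solo_af[0]},
            ls.NoiseModel(), 4000, seed=31,
        )
        sigs = [
            cell_variant(endmembers[f]) if f in CELL_SHIFTED_DEFAULT else endmembers[f]
            for f in panel.fluorochromes
        ]
        m_multi = build_mixing_matrix(sigs, solo_af)
        m_single = build_mixing_matrix(sigs, solo_af)
        report = af_comparison_report(sample, m_multi, m_single, panel)
        np.testing.assert_allclose(report.bias_multi, report.bias_single, atol=1e-8)
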