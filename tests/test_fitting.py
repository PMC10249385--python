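"""Isothermal K-centric fitting, robust trimming, and range filtering."""

from dataclasses import replace

import numpy as np
import pytest

from gcretention import KCentricParams, fit_kcentric, filter_lnk_range, robust_fit
from gcretention.fitting import (
    InsufficientDataError,
    IsothermalRetentionModel,
    IsothermalSeries,
)
from gcretention.synth import SynthSpec, generate_isothermal


def make_series(params, grid_c, sigma=0.0, seed=0):
    return generate_isothermal(
        SynthSpec(params=params, T_grid_C=tuple(grid_c), sigma=sigma, seed=seed)
    )


class TestFitKcentric:
    def test_noiseless_recovery(self, true_kcentric):
        series = make_series(true_kcentric, range(60, 301, 10))
        res = fit_kcentric(series)
        assert res.converged
        assert res.params.Tchar == pytest.approx(true_kcentric.Tchar, rel=1e-6)
        assert res.params.thetachar == pytest.approx(true_kcentric.thetachar, rel=1e-6)
        assert res.params.dCp == pytest.approx(true_kcentric.dCp, rel=1e-6)
        assert res.params.beta0 == true_kcentric.beta0

    def test_three_points_interpolate_exactly(self, true_kcentric):
        series = make_series(true_kcentric, [110.0, 130.0, 150.0])
        res = fit_kcentric(series)
        assert res.N == 3
        assert np.max(np.abs(res.residuals)) < 1e-10
        assert all(se == pytest.approx(0.0, abs=1e-8) for se in res.std_errors.values())

    def test_too_few_points(self, true_kcentric):
        series = make_series(true_kcentric, [110.0, 150.0])
        with pytest.raises(InsufficientDataError):
            fit_kcentric(series)

    def test_monte_carlo_coverage(self, true_kcentric):
        """With sigma = 0.02 noise the 3-standard-error interval covers the
        true Tchar in at least 90% of replicates."""
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            series = make_series(true_kcentric, range(60, 301, 10), sigma=0.02, seed=seed)
            res = fit_kcentric(series)
            lo, hi = res.conf_int(nsigma=3.0)["Tchar"]
            hits += lo <= true_kcentric.Tchar <= hi
        assert hits >= 0.90 * n_rep

    def test_mean_recovery_unbiased(self, true_kcentric):
        estimates = []
        for seed in range(60):
            series = make_series(true_kcentric, range(60, 301, 10), sigma=0.02, seed=1000 + seed)
            estimates.append(fit_kcentric(series).params.Tchar)
        mean_se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates) - true_kcentric.Tchar) < 3 * mean_se

    def test_std_errors_scale_with_noise(self, true_kcentric):
        """Reported standard errors grow proportionally with the injected
        noise level."""
        med = {}
        for sigma in (0.005, 0.01, 0.02):
            ses = [
                fit_kcentric(
                    make_series(true_kcentric, range(100, 201, 10), sigma=sigma, seed=s)
                ).std_errors["Tchar"]
                for s in range(30)
            ]
            med[sigma] = np.median(ses)
        assert med[0.01] / med[0.005] == pytest.approx(2.0, rel=0.35)
        assert med[0.02] / med[0.01] == pytest.approx(2.0, rel=0.35)

    def test_abc_space_fit_equals_kcentric_fit(self, true_kcentric):
        """The two parameterizations span the same curve family, so fitting
        in either one gives the same fitted ln k curve."""
        from gcretention.fitting import _linear_abc_solve
        from gcretention import lnk_abc, lnk_kcentric

        series = make_series(true_kcentric, range(100, 241, 10), sigma=0.05, seed=7)
        abc = _linear_abc_solve(np.array(series.T), np.array(series.lnk), series.beta0)
        res = fit_kcentric(series, apply_range_filter=False)
        T = np.linspace(370.0, 500.0, 30)
        dev = np.abs(np.asarray(lnk_abc(T, abc)) - np.asarray(lnk_kcentric(T, res.params)))
        assert dev.max() < 1e-6


class TestRobustFit:
    def test_injected_outlier_recovered(self, true_kcentric):
        clean = make_series(true_kcentric, range(100, 200, 10))  # 10 points
        lnk = list(clean.lnk)
        lnk[4] += 1.0
        dirty = replace(clean, lnk=tuple(lnk))
        res = robust_fit(dirty, seed=0)
        ref = fit_kcentric(clean)
        assert res.outliers == [4]
        assert res.params.Tchar == pytest.approx(ref.params.Tchar, rel=1e-3)
        assert res.params.thetachar == pytest.approx(ref.params.thetachar, rel=1e-3)
        assert res.params.dCp == pytest.approx(ref.params.dCp, rel=1e-3)

    def test_no_outliers_matches_plain_fit(self, true_kcentric):
        series = make_series(true_kcentric, range(100, 200, 10))
        res = robust_fit(series, seed=0)
        ref = fit_kcentric(series)
        assert res.outliers == []
        assert res.params.Tchar == pytest.approx(ref.params.Tchar, rel=1e-9)
        assert res.params.thetachar == pytest.approx(ref.params.thetachar, rel=1e-9)

    def test_two_adjacent_outliers(self, true_kcentric):
        clean = make_series(true_kcentric, range(90, 210, 10))  # 12 points
        lnk = list(clean.lnk)
        lnk[5] += 1.0
        lnk[6] += 1.0
        dirty = replace(clean, lnk=tuple(lnk))
        res = robust_fit(dirty, seed=0)
        assert sorted(res.outliers) == [5, 6]

    def test_randomized_search_large_n(self, true_kcentric):
        """Above the exhaustive-enumeration size the seeded randomized search
        still isolates a gross outlier."""
        clean = make_series(true_kcentric, range(60, 301, 5), sigma=0.01, seed=3)
        model = IsothermalRetentionModel.from_series(clean)
        n = len(model.T)
        assert n > 12
        lnk = model.lnk.copy()
        lnk[n // 2] += 1.5
        dirty = IsothermalSeries(
            compound="dirty",
            T=tuple(model.T),
            lnk=tuple(lnk),
            beta0=true_kcentric.beta0,
        )
        res = robust_fit(dirty, seed=11, apply_range_filter=False)
        assert n // 2 in res.outliers

    def test_needs_redundancy(self, true_kcentric):
        series = make_series(true_kcentric, [110.0, 130.0, 150.0])
        with pytest.raises(InsufficientDataError):
            robust_fit(series)


class TestRangeFilter:
    def test_high_point_excluded(self):
        s = IsothermalSeries("x", (350.0, 400.0, 450.0), (3.6, 1.0, -1.0), beta0=1.0)
        filtered, excluded = filter_lnk_range(s)
        assert excluded == [0]
        assert filtered.lnk == (1.0, -1.0)

    def test_boundaries_inclusive(self):
        s = IsothermalSeries("x", (350.0, 400.0), (-2.0, 3.5), beta0=1.0)
        filtered, excluded = filter_lnk_range(s)
        assert excluded == []
        assert filtered is s

    def test_all_in_range_unchanged(self):
        s = IsothermalSeries("x", (350.0, 400.0, 450.0), (2.0, 0.0, -1.5), beta0=1.0)
        filtered, excluded = filter_lnk_range(s)
        assert excluded == []
        assert filtered.lnk == s.lnk


class TestModelObject:
    def test_from_dataframe_with_retention_times(self):
        import pandas as pd

        # tR/tM pairs encode k = 2 and k = 1 at two temperatures
        df = pd.DataFrame(
            {
                "T_C": [120.0, 140.0, 160.0],
                "tR_min": [3.0, 2.0, 1.5],
                "tM_min": [1.0, 1.0, 1.0],
                "beta0": [250.0] * 3,
            }
        )
        model = IsothermalRetentionModel.from_dataframe(df)
        assert model.lnk[0] == pytest.approx(np.log(2.0))
        res = model.fit()
        assert res.N == 3

    def test_summary_contains_estimates(self, true_kcentric):
        series = make_series(true_kcentric, range(100, 200, 10))
        res = fit_kcentric(series)
        text = res.summary()
        assert "Tchar" in text and "thetachar" in text and "400" in text

    def test_plot_smoke(self, true_kcentric):
        import matplotlib

        matplotlib.use("Agg")
        series = make_series(true_kcentric, range(100, 200, 10))
        ax = fit_kcentric(series).plot()
        assert ax.get_ylabel() == "ln k"
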