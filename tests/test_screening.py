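"""Gaussian GLM screening: AIC oracle, recovery, AR(1), correlations."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from erebia.screening import (
    ar1_check,
    biennial_test,
    build_analysis_dataset,
    climate_correlations,
    delta_aic_ledger,
    fit_gaussian_glm,
    pearson_ci,
    phenology_models,
    standardize,
    trend_test,
)
from erebia.climate import seasonal_table
from erebia.data import SeasonIndexRow
from erebia.simulate import SimulationConfig, simulate_dataset

from conftest import analysis_frame_from_truth


def brute_force_aic(y, X):
    """Independent AIC: explicit Gaussian log-likelihood at the ML estimate."""
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / len(y)
    ll = float(np.sum(stats.norm.logpdf(y, X @ beta, math.sqrt(sigma2))))
    return -2.0 * ll + 2.0 * (X.shape[1] + 1)


def _design_for(transects, *extra):
    dummies = pd.get_dummies(pd.Categorical(transects), drop_first=True, dtype=float)
    return np.column_stack([np.ones(len(transects)), dummies.to_numpy(), *extra])


class TestStandardize:
    def test_three_points(self):
        assert standardize([1, 2, 3]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            standardize([4.0, 4.0, 4.0])

    def test_idempotent(self, rng):
        x = rng.normal(size=50)
        once = standardize(x)
        assert standardize(once) == pytest.approx(once, abs=1e-12)

    def test_moments(self, rng):
        z = standardize(rng.uniform(0, 100, size=37))
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)


class TestGaussianGLM:
    def test_aic_matches_brute_force_on_random_designs(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 40))
            k = int(rng.integers(2, 4))
            transects = [f"T{i % k}" for i in range(n)]
            pred = rng.normal(size=n)
            y = rng.normal(size=n)
            result = fit_gaussian_glm(y, transects, pred)
            X = _design_for(transects, pred)
            assert result.aic == pytest.approx(brute_force_aic(y, X), abs=1e-8)
            assert result.df == n - X.shape[1]

    def test_zero_gain_predictor_costs_exactly_two(self, rng):
        n = 30
        transects = [f"T{i % 3}" for i in range(n)]
        X0 = _design_for(transects)
        y = rng.normal(size=n)
        resid = y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]
        # predictor orthogonal to both the null design and its residuals:
        # adding it cannot reduce RSS, so delta AIC is exactly +2
        raw = rng.normal(size=n)
        raw -= X0 @ np.linalg.lstsq(X0, raw, rcond=None)[0]
        raw -= (raw @ resid) / (resid @ resid) * resid
        null = fit_gaussian_glm(y, transects)
        full = fit_gaussian_glm(y, transects, raw, null_aic=null.aic)
        assert full.delta_aic == pytest.approx(2.0, abs=1e-8)
        assert full.slope == pytest.approx(0.0, abs=1e-10)

    def test_noiseless_slope_recovery(self, rng):
        n = 24
        transects = [f"T{i % 3}" for i in range(n)]
        effects = {"T0": 1.0, "T1": 2.0, "T2": 0.5}
        pred = rng.normal(size=n)
        y = np.array([effects[t] for t in transects]) + 0.5 * pred
        result = fit_gaussian_glm(y, transects, pred)
        assert result.slope == pytest.approx(0.5, abs=1e-9)

    def test_rank_deficient_design_rejected(self, rng):
        n = 20
        transects = [f"T{i % 2}" for i in range(n)]
        pred = rng.normal(size=n)
        with pytest.raises(ValueError, match="rank"):
            fit_gaussian_glm(y := rng.normal(size=n), transects, pred,
                             covariates={"dup": pred})

    def test_nonfinite_response_named(self, rng):
        y = rng.normal(size=10)
        y[4] = np.nan
        with pytest.raises(ValueError, match="row 4"):
            fit_gaussian_glm(y, ["A"] * 5 + ["B"] * 5)


class TestLedger:
    def _truth_dataset(self, seed, **cfg_kw):
        cfg = SimulationConfig(**cfg_kw)
        return analysis_frame_from_truth(simulate_dataset(cfg, seed=seed))

    def test_ledger_conservation_and_skipping(self, rng):
        frame = self._truth_dataset(1)
        frame["T_ground_Aut"] = np.nan  # pretend the sensor is absent
        log = []
        ledger = delta_aic_ledger(frame, "log_pai", log=log)
        fitted = [r for r in ledger if r.predictor_name is not None]
        assert len(fitted) == 20  # 21 predictors minus the missing one
        assert any("T_ground_Aut" in line for line in log)
        assert ledger[0].predictor_name is None and ledger[0].delta_aic == 0.0

    def test_planted_effect_flagged(self):
        frame = self._truth_dataset(
            3, climate_effects={"T_avg_Spr": 0.6}, year_process_sd=0.3
        )
        ledger = delta_aic_ledger(frame, "log_pai")
        by_name = {r.predictor_name: r for r in ledger}
        hit = by_name["T_avg_Spr"]
        assert hit.effect_class in ("moderate", "strong")
        assert hit.delta_aic < -2
        assert hit.slope == pytest.approx(0.6, abs=3 * hit.se)

    def test_delta_aic_invariant_to_predictor_rescaling(self):
        frame = self._truth_dataset(5)
        base = delta_aic_ledger(frame, "log_pai", ["T_avg_Spr"])[1]
        frame2 = frame.copy()
        frame2["T_avg_Spr"] = frame2["T_avg_Spr"] * 37.0 - 12.0
        rescaled = delta_aic_ledger(frame2, "log_pai", ["T_avg_Spr"])[1]
        assert rescaled.delta_aic == pytest.approx(base.delta_aic, abs=1e-10)
        assert rescaled.slope == pytest.approx(base.slope, abs=1e-10)


class TestAR1:
    @staticmethod
    def _frame(values, transects=3, years=12):
        rows = []
        i = 0
        for t in range(transects):
            for y in range(years):
                rows.append(
                    {"transect_id": f"T{t}", "year": 2000 + y, "log_pai": values[i]}
                )
                i += 1
        return pd.DataFrame(rows)

    def test_phi_recovered_from_long_ar1_series(self, rng):
        phi = 0.8
        n_years, n_tr = 30, 3
        values = []
        for _ in range(n_tr):
            e = np.zeros(n_years)
            e[0] = rng.normal(0, 1.0 / math.sqrt(1 - phi**2))
            for i in range(1, n_years):
                e[i] = phi * e[i - 1] + rng.normal()
            values.extend(e)
        check = ar1_check(self._frame(values, n_tr, n_years), "log_pai")
        assert check.phi == pytest.approx(phi, abs=0.1)
        assert check.use_ar1

    def test_loglik_matches_multivariate_normal(self, rng):
        # whitening-based profile likelihood vs direct MVN density
        from erebia.screening import _ar1_profile_loglik

        phi = 0.6
        n = 8
        y = rng.normal(size=n)
        X = np.ones((n, 1))
        gaps = np.array([0, 1, 1, 1, 1, 1, 1, 1], dtype=float)
        starts = np.array([True] + [False] * 7)
        ll = _ar1_profile_loglik(phi, y, X, gaps, starts)
        R = phi ** np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        Rinv = np.linalg.inv(R)
        XtRX = X.T @ Rinv @ X
        beta = np.linalg.solve(XtRX, X.T @ Rinv @ y)
        e = y - X @ beta
        sigma2 = float(e @ Rinv @ e) / n
        direct = stats.multivariate_normal.logpdf(y, (X @ beta).ravel(), sigma2 * R)
        assert ll == pytest.approx(direct, abs=1e-8)

    def test_too_few_years_rejected(self):
        frame = self._frame(list(range(4)), transects=2, years=2)
        with pytest.raises(ValueError, match="3 years"):
            ar1_check(frame, "log_pai")


class TestTrendAndBiennial:
    def test_deterministic_exponential_trend(self):
        years = np.arange(2008, 2020)
        rows = []
        for t, off in (("A", 1.0), ("B", 2.0)):
            for y in years:
                rows.append(
                    {"transect_id": t, "year": y, "log_pai": off + 0.06 * (y - 2008)}
                )
        frame = pd.DataFrame(rows)
        null, trend = trend_test(frame, "log_pai")
        assert trend.slope == pytest.approx(0.06, abs=1e-9)
        assert trend.delta_aic < -20

    def test_zero_trend_is_usually_not_flagged(self, rng):
        hits = 0
        for _ in range(50):
            frame = pd.DataFrame(
                {
                    "transect_id": [f"T{i % 3}" for i in range(36)],
                    "year": np.repeat(np.arange(2009, 2021), 3),
                    "log_pai": rng.normal(size=36),
                }
            )
            _, trend = trend_test(frame, "log_pai")
            if abs(trend.slope) > 2 * trend.se:
                hits += 1
        assert hits <= 10  # ~5% nominal

    def test_single_parity_rejected(self):
        frame = pd.DataFrame(
            {
                "transect_id": ["A"] * 4,
                "year": [2010, 2012, 2014, 2016],
                "log_pai": [1.0, 1.1, 0.9, 1.2],
            }
        )
        with pytest.raises(ValueError, match="parity|odd"):
            biennial_test(frame)

    def test_planted_parity_effect_recovered(self, rng):
        ratio = math.log(1.8)
        years = np.arange(2010, 2020)
        rows = []
        for t in range(4):
            for y in years:
                parity = 0.5 if y % 2 == 1 else -0.5
                rows.append(
                    {
                        "transect_id": f"T{t}",
                        "year": y,
                        "log_pai": 1.0 + parity * ratio + rng.normal(0, 0.3),
                    }
                )
        result = biennial_test(pd.DataFrame(rows))
        assert math.exp(result.slope) == pytest.approx(1.8, rel=0.25)
        assert result.delta_aic < -2


class TestPhenologyModels:
    def test_duration_model_wins_when_planted(self, rng):
        n = 36
        log_dur = rng.normal(math.log(14), 0.3, size=n)
        frame = pd.DataFrame(
            {
                "transect_id": [f"T{i % 3}" for i in range(n)],
                "year": np.repeat(np.arange(2009, 2021), 3),
                "log_onset": rng.normal(math.log(195), 0.01, size=n),
                "log_duration": log_dur,
                "log_pai": 0.8 * log_dur + rng.normal(0, 0.15, size=n),
            }
        )
        fits = phenology_models(frame)
        assert len(fits) == 4
        best = min(fits, key=lambda f: f.aic)
        assert best.predictor_name == "log_duration"
        assert best.delta_aic == 0.0
        assert best.slope == pytest.approx(0.8, abs=3 * best.se)


class TestCorrelations:
    def test_self_correlation(self, rng):
        x = rng.normal(size=20)
        res = pearson_ci(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.degenerate

    def test_anti_correlation(self, rng):
        x = rng.normal(size=20)
        assert pearson_ci(x, -x).r == pytest.approx(-1.0)

    def test_matches_direct_formula(self, rng):
        x = rng.normal(size=10)
        y = 0.4 * x + rng.normal(size=10)
        res = pearson_ci(x, y)
        r = float(np.corrcoef(x, y)[0, 1])
        z = math.atanh(r)
        half = 1.959963984540054 / math.sqrt(10 - 3)
        assert res.r == pytest.approx(r, abs=1e-10)
        assert res.ci_low == pytest.approx(math.tanh(z - half), abs=1e-10)
        assert res.ci_high == pytest.approx(math.tanh(z + half), abs=1e-10)

    def test_climate_matrix_properties(self):
        cfg = SimulationConfig()
        sim = simulate_dataset(cfg, seed=2)
        seasonal = seasonal_table(sim.climate, list(cfg.years), cfg.station_id)
        corr = climate_correlations(seasonal)
        mat = corr.to_numpy()
        assert np.allclose(mat, mat.T, atol=1e-12)
        assert np.allclose(np.diag(mat), 1.0, atol=1e-12)
        a, b = "T_avg_Spr", "T_min_Spr"
        direct = pearson_ci(
            seasonal[a].to_numpy(), seasonal[b].to_numpy()
        ).r
        assert corr.loc[a, b] == pytest.approx(direct, abs=1e-10)


class TestBuildAnalysisDataset:
    def test_join_and_logs(self):
        rows = [
            SeasonIndexRow("T1", "sp", 2015, 100.0, 195.0, 14.0, 0.9, 3.0, True),
            SeasonIndexRow("T1", "sp", 2016, math.nan, math.nan, math.nan,
                           math.nan, math.nan, False),
        ]
        seasonal = pd.DataFrame(
            {"station_id": ["S"], "flight_year": [2015], "T_avg_Spr": [7.5]}
        )
        frame = build_analysis_dataset(rows, seasonal, {"T1": "S"}, label="d")
        assert len(frame) == 1  # unusable row dropped
        assert frame.iloc[0]["log_pai"] == pytest.approx(math.log(100.0))
        assert frame.iloc[0]["T_avg_Spr"] == 7.5

    def test_nonpositive_index_is_an_error(self):
        rows = [SeasonIndexRow("T1", "sp", 2015, 0.0, 195.0, 14.0, 0.9, 3.0, True)]
        seasonal = pd.DataFrame(
            {"station_id": ["S"], "flight_year": [2015], "T_avg_Spr": [7.5]}
        )
        with pytest.raises(ValueError, match="T1/sp/2015"):
            build_analysis_dataset(rows, seasonal, {"T1": "S"})
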