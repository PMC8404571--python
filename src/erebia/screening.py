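"""Single-predictor delta-AIC screening of climate effects on the indices.

The response (log PAI, log Onset or log Duration, one value per
transect-year) is modelled with Gaussian GLMs — ordinary least squares —
always containing transect identity as a fixed factor. A null model
``response ~ transect`` anchors the comparison; each candidate predictor is
then added alone, standardized to zero mean and unit sample variance within
the analysis dataset, and judged by

    delta AIC = AIC(model) - AIC(null),

with delta AIC < -6 a strong and < -2 a moderate indication of an effect.
Multi-predictor models are deliberately not fitted: with ~35 transect-years
and ~20 intercorrelated climate variables they would overfit.

AIC uses the maximum-likelihood Gaussian convention

    AIC = n log(2 pi sigma2_ML) + n + 2 (p + 1),  sigma2_ML = RSS / n,

with p mean parameters plus one variance parameter — the lm/gaussian-glm
convention, so only differences within a dataset are meaningful.

Also here: a maximum-likelihood AR(1) check of year-to-year residual
autocorrelation within transects, year-trend tests, an odd/even-year
(biennial) contrast, abundance-vs-phenology models, and Pearson
correlations with Fisher-z confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .climate import PREDICTOR_NAMES, assign_station
from .data import (
    MODERATE_DELTA_AIC,
    STRONG_DELTA_AIC,
    ModelResult,
    SeasonIndexRow,
    classify_effect,
)

__all__ = [
    "standardize",
    "fit_gaussian_glm",
    "delta_aic_ledger",
    "ar1_check",
    "AR1Check",
    "trend_test",
    "biennial_test",
    "phenology_models",
    "pearson_ci",
    "PearsonCI",
    "climate_correlations",
    "build_analysis_dataset",
    "DeltaAICScreen",
    "ScreenResults",
]


def standardize(values) -> np.ndarray:
    """z-scores with the sample (n-1) standard deviation.

    Raises on constant input: a zero-variance predictor carries no signal
    and would divide by zero.
    """
    x = np.asarray(values, dtype=float)
    if len(np.unique(x[np.isfinite(x)])) < 2:
        raise ValueError("zero variance: cannot standardize a constant vector")
    return (x - x.mean()) / x.std(ddof=1)


def _gaussian_aic(rss: float, n: int, p: int) -> float:
    """ML-convention AIC; sigma2 counts as a parameter."""
    sigma2 = max(rss / n, 1e-300)
    return n * math.log(2.0 * math.pi * sigma2) + n + 2.0 * (p + 1)


def _design(
    transects: Sequence[str], extra: Sequence[np.ndarray] = ()
) -> np.ndarray:
    """Intercept + treatment-coded transect factor + extra columns."""
    labels = pd.Categorical(transects)
    dummies = pd.get_dummies(labels, drop_first=True, dtype=float).to_numpy()
    cols = [np.ones(len(labels)), *dummies.T, *extra]
    return np.column_stack(cols)


def _ols(y: np.ndarray, X: np.ndarray):
    """Least squares with rank check; returns (beta, rss, cov_unscaled)."""
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design matrix")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    xtx_inv = np.linalg.inv(X.T @ X)
    return beta, rss, xtx_inv


def fit_gaussian_glm(
    response,
    transects,
    predictor=None,
    covariates: Optional[Mapping[str, Sequence[float]]] = None,
    *,
    dataset_label: str = "",
    response_name: str = "",
    predictor_name: Optional[str] = None,
    null_aic: Optional[float] = None,
    strong: float = STRONG_DELTA_AIC,
    moderate: float = MODERATE_DELTA_AIC,
) -> ModelResult:
    """Fit ``response ~ transect (+ covariates) (+ predictor)`` by OLS.

    ``covariates`` enter unstandardized before the focal predictor (e.g. a
    linear year term in the biennial test). The reported slope and SE refer
    to the focal predictor only; SE uses the unbiased residual variance.
    ``delta_aic`` is computed against ``null_aic`` when given, else 0.
    """
    y = np.asarray(response, dtype=float)
    if not np.all(np.isfinite(y)):
        bad = int(np.flatnonzero(~np.isfinite(y))[0])
        raise ValueError(f"non-finite response at row {bad}")
    extra = []
    if covariates:
        extra.extend(np.asarray(v, dtype=float) for v in covariates.values())
    has_pred = predictor is not None
    if has_pred:
        extra.append(np.asarray(predictor, dtype=float))
    X = _design(transects, extra)
    n, p = X.shape
    if n - p < 1:
        raise ValueError("no residual degrees of freedom")
    beta, rss, xtx_inv = _ols(y, X)
    aic = _gaussian_aic(rss, n, p)
    slope = se = None
    if has_pred:
        sigma2 = rss / (n - p)
        slope = float(beta[-1])
        se = float(math.sqrt(sigma2 * xtx_inv[-1, -1]))
    delta = aic - null_aic if null_aic is not None else 0.0
    return ModelResult(
        dataset_label=dataset_label,
        response_name=response_name,
        predictor_name=predictor_name,
        slope=slope,
        se=se,
        df=n - p,
        aic=aic,
        delta_aic=delta,
        effect_class=classify_effect(delta, strong, moderate) if has_pred else "none",
    )


def delta_aic_ledger(
    dataset: pd.DataFrame,
    response_name: str,
    predictors: Optional[Sequence[str]] = None,
    *,
    dataset_label: str = "",
    strong: float = STRONG_DELTA_AIC,
    moderate: float = MODERATE_DELTA_AIC,
    log: Optional[list] = None,
) -> list[ModelResult]:
    """Null model plus one single-predictor model per available predictor.

    Predictors with any missing value in the dataset are skipped (and
    logged): a predictor not recorded for a station-period simply cannot be
    screened there. Each fitted predictor is standardized within the
    dataset's rows.
    """
    if predictors is None:
        predictors = [c for c in PREDICTOR_NAMES if c in dataset.columns]
    y = dataset[response_name].to_numpy(dtype=float)
    transects = dataset["transect_id"].tolist()
    null = fit_gaussian_glm(
        y,
        transects,
        dataset_label=dataset_label,
        response_name=response_name,
        predictor_name=None,
        strong=strong,
        moderate=moderate,
    )
    results = [null]
    for name in predictors:
        col = dataset[name].to_numpy(dtype=float)
        if np.any(~np.isfinite(col)):
            if log is not None:
                log.append(f"{dataset_label}/{response_name}: skipped {name} (missing)")
            continue
        try:
            z = standardize(col)
        except ValueError:
            if log is not None:
                log.append(
                    f"{dataset_label}/{response_name}: skipped {name} (constant)"
                )
            continue
        results.append(
            fit_gaussian_glm(
                y,
                transects,
                z,
                dataset_label=dataset_label,
                response_name=response_name,
                predictor_name=name,
                null_aic=null.aic,
                strong=strong,
                moderate=moderate,
            )
        )
    return results


# ---------------------------------------------------------------------------
# AR(1) residual check
# ---------------------------------------------------------------------------

@dataclass
class AR1Check:
    aic_iid: float
    aic_ar1: float
    phi: float
    use_ar1: bool


def _ar1_profile_loglik(
    phi: float, y: np.ndarray, X: np.ndarray, gaps: np.ndarray, starts: np.ndarray
) -> float:
    """Profile Gaussian log-likelihood of grouped AR(1) errors.

    ``gaps[i]`` is the year gap to the previous observation of the same
    transect (0 marks the first observation of a block, handled via
    ``starts``). beta and sigma2 are profiled out by whitening + OLS.
    """
    n = len(y)
    w_y = y.copy()
    w_X = X.copy()
    logdet_r = 0.0
    for i in range(n):
        if starts[i]:
            continue
        rho = phi ** gaps[i]
        denom = 1.0 - rho * rho
        logdet_r += math.log(denom)
        scale = 1.0 / math.sqrt(denom)
        w_y[i] = (y[i] - rho * y[i - 1]) * scale
        w_X[i] = (X[i] - rho * X[i - 1]) * scale
    beta, _, _, _ = np.linalg.lstsq(w_X, w_y, rcond=None)
    resid = w_y - w_X @ beta
    rss = float(resid @ resid)
    sigma2 = max(rss / n, 1e-300)
    return -0.5 * n * math.log(2.0 * math.pi * sigma2) - 0.5 * n - 0.5 * logdet_r


def ar1_check(dataset: pd.DataFrame, response_name: str) -> AR1Check:
    """Compare iid vs within-transect AR(1) errors by maximum likelihood.

    Both models share the transect-factor mean structure; the AR(1) model
    adds one correlation parameter (the year-to-year residual correlation
    phi, with gaps bridged as phi**gap). Both AICs use the ML convention so
    they are directly comparable; ``use_ar1`` is True when the AR(1) model
    has the smaller AIC.
    """
    frame = dataset.sort_values(["transect_id", "year"]).reset_index(drop=True)
    counts = frame.groupby("transect_id")["year"].nunique()
    if (counts < 3).any():
        raise ValueError("AR(1) check needs at least 3 years per transect")
    y = frame[response_name].to_numpy(dtype=float)
    X = _design(frame["transect_id"].tolist())
    n, p = X.shape

    same = frame["transect_id"].to_numpy()
    years = frame["year"].to_numpy()
    starts = np.ones(n, dtype=bool)
    gaps = np.zeros(n, dtype=float)
    for i in range(1, n):
        if same[i] == same[i - 1]:
            starts[i] = False
            gaps[i] = float(years[i] - years[i - 1])

    _, rss, _ = _ols(y, X)
    ll_iid = -0.5 * n * math.log(2.0 * math.pi * rss / n) - 0.5 * n
    aic_iid = -2.0 * ll_iid + 2.0 * (p + 1)

    res = optimize.minimize_scalar(
        lambda phi: -_ar1_profile_loglik(phi, y, X, gaps, starts),
        bounds=(-0.99, 0.99),
        method="bounded",
    )
    phi = float(res.x)
    aic_ar1 = 2.0 * float(res.fun) + 2.0 * (p + 2)
    return AR1Check(
        aic_iid=aic_iid, aic_ar1=aic_ar1, phi=phi, use_ar1=aic_ar1 < aic_iid
    )


# ---------------------------------------------------------------------------
# trend, biennial and phenology models
# ---------------------------------------------------------------------------

def trend_test(
    dataset: pd.DataFrame,
    response_name: str,
    *,
    dataset_label: str = "",
    strong: float = STRONG_DELTA_AIC,
    moderate: float = MODERATE_DELTA_AIC,
) -> tuple[ModelResult, ModelResult]:
    """``response ~ transect`` vs ``response ~ transect + year``.

    Year enters unstandardized, so the slope is per calendar year.
    """
    if dataset["year"].nunique() < 3:
        raise ValueError("trend test needs at least 3 years")
    y = dataset[response_name].to_numpy(dtype=float)
    transects = dataset["transect_id"].tolist()
    null = fit_gaussian_glm(
        y, transects, dataset_label=dataset_label, response_name=response_name
    )
    trend = fit_gaussian_glm(
        y,
        transects,
        dataset["year"].to_numpy(dtype=float),
        dataset_label=dataset_label,
        response_name=response_name,
        predictor_name="Year",
        null_aic=null.aic,
        strong=strong,
        moderate=moderate,
    )
    return null, trend


def biennial_test(
    dataset: pd.DataFrame,
    *,
    response_name: str = "log_pai",
    dataset_label: str = "",
    strong: float = STRONG_DELTA_AIC,
    moderate: float = MODERATE_DELTA_AIC,
) -> ModelResult:
    """Odd-vs-even-year contrast on abundance, over transect + year covariates.

    The returned slope is the parity coefficient on the log scale:
    ``exp(slope)`` is the multiplicative odd/even abundance ratio. Compared
    (delta AIC) against the matching model without the parity term.
    """
    parity = (dataset["year"].to_numpy() % 2 == 1).astype(float)
    if len(np.unique(parity)) < 2:
        raise ValueError("biennial test needs both odd and even years")
    y = dataset[response_name].to_numpy(dtype=float)
    transects = dataset["transect_id"].tolist()
    year = dataset["year"].to_numpy(dtype=float)
    null = fit_gaussian_glm(
        y,
        transects,
        covariates={"year": year},
        dataset_label=dataset_label,
        response_name=response_name,
    )
    return fit_gaussian_glm(
        y,
        transects,
        parity,
        covariates={"year": year},
        dataset_label=dataset_label,
        response_name=response_name,
        predictor_name="Parity",
        null_aic=null.aic,
        strong=strong,
        moderate=moderate,
    )


def phenology_models(
    dataset: pd.DataFrame,
    *,
    dataset_label: str = "",
    strong: float = STRONG_DELTA_AIC,
    moderate: float = MODERATE_DELTA_AIC,
) -> list[ModelResult]:
    """Does abundance depend on flight timing? The four-model comparison.

    Fits ``log PAI ~ transect``, ``+ log Onset``, ``+ log Duration`` and
    ``+ both``; delta AIC is reported against the best (smallest-AIC) model,
    so the best model has delta AIC = 0.
    """
    y = dataset["log_pai"].to_numpy(dtype=float)
    transects = dataset["transect_id"].tolist()
    onset = dataset["log_onset"].to_numpy(dtype=float)
    duration = dataset["log_duration"].to_numpy(dtype=float)
    fits = [
        fit_gaussian_glm(
            y, transects, dataset_label=dataset_label, response_name="log_pai"
        ),
        fit_gaussian_glm(
            y,
            transects,
            onset,
            dataset_label=dataset_label,
            response_name="log_pai",
            predictor_name="log_onset",
        ),
        fit_gaussian_glm(
            y,
            transects,
            duration,
            dataset_label=dataset_label,
            response_name="log_pai",
            predictor_name="log_duration",
        ),
    ]
    both = fit_gaussian_glm(
        y,
        transects,
        covariates={"log_onset": onset, "log_duration": duration},
        dataset_label=dataset_label,
        response_name="log_pai",
    )
    both.predictor_name = "log_onset+log_duration"
    fits.append(both)
    best = min(f.aic for f in fits)
    for f in fits:
        f.delta_aic = f.aic - best
    return fits


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

@dataclass
class PearsonCI:
    r: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


def pearson_ci(x, y, conf: float = 0.95) -> PearsonCI:
    """Pearson correlation with a Fisher-z confidence interval.

    ``z = atanh(r) +/- z_crit / sqrt(n - 3)``, back-transformed. With
    |r| = 1 the interval collapses to the point and is flagged degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 points for a correlation CI")
    r = float(stats.pearsonr(x, y).statistic)
    if abs(r) >= 1.0 - 1e-15:
        return PearsonCI(r=r, ci_low=r, ci_high=r, degenerate=True)
    zcrit = stats.norm.ppf(0.5 + conf / 2.0)
    z = math.atanh(r)
    half = zcrit / math.sqrt(len(x) - 3)
    return PearsonCI(r=r, ci_low=math.tanh(z - half), ci_high=math.tanh(z + half))


def climate_correlations(seasonal: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson matrix of the seasonal climate predictors."""
    cols = [c for c in seasonal.columns if c not in ("station_id", "flight_year")]
    return seasonal[cols].corr(method="pearson")


# ---------------------------------------------------------------------------
# analysis dataset assembly and the screening model object
# ---------------------------------------------------------------------------

def build_analysis_dataset(
    index_rows: Iterable[SeasonIndexRow],
    seasonal: pd.DataFrame,
    station_mapping: Mapping[str, str],
    *,
    label: str = "",
    species: Optional[str] = None,
    transects: Optional[Sequence[str]] = None,
    years: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Join usable season indices with their station's seasonal climate.

    One row per usable transect-year: log indices plus the predictor
    columns of the transect's assigned station for that flight year.
    Non-positive indices on usable rows are an error (they cannot be
    logged); unusable rows are silently dropped.
    """
    rows = []
    for r in index_rows:
        if not r.usable:
            continue
        if species is not None and r.species != species:
            continue
        if transects is not None and r.transect_id not in transects:
            continue
        if years is not None and r.year not in years:
            continue
        if not (r.pai > 0 and r.onset > 0 and r.duration > 0):
            raise ValueError(
                f"non-positive index for {r.transect_id}/{r.species}/{r.year}; "
                "cannot log-transform"
            )
        station = assign_station(r.transect_id, station_mapping)
        match = seasonal[
            (seasonal["station_id"] == station)
            & (seasonal["flight_year"] == r.year)
        ]
        predictors = (
            {c: np.nan for c in PREDICTOR_NAMES if c in seasonal.columns}
            if match.empty
            else {
                c: match.iloc[0][c]
                for c in PREDICTOR_NAMES
                if c in seasonal.columns
            }
        )
        rows.append(
            {
                "transect_id": r.transect_id,
                "species": r.species,
                "year": r.year,
                "log_pai": math.log(r.pai),
                "log_onset": math.log(r.onset),
                "log_duration": math.log(r.duration),
                **predictors,
            }
        )
    frame = pd.DataFrame(rows)
    frame.attrs["label"] = label
    return frame


@dataclass
class ScreenResults:
    """Everything the screening stage computes for one analysis dataset."""

    label: str
    ledgers: dict[str, list[ModelResult]]
    trends: dict[str, tuple[ModelResult, ModelResult]]
    biennial: Optional[ModelResult]
    phenology: list[ModelResult]
    ar1: Optional[AR1Check]
    onset_duration_corr: PearsonCI
    skipped: list[str]

    def all_results(self) -> list[ModelResult]:
        out: list[ModelResult] = []
        for ledger in self.ledgers.values():
            out.extend(ledger)
        for null, trend in self.trends.values():
            out.extend([null, trend])
        if self.biennial is not None:
            out.append(self.biennial)
        out.extend(self.phenology)
        return out

    def summary(self) -> pd.DataFrame:
        """Long-format table of every fitted model (screening-table layout)."""
        rows = []
        for r in self.all_results():
            rows.append(
                {
                    "dataset": r.dataset_label,
                    "response": r.response_name,
                    "predictor": r.predictor_name or "(null)",
                    "delta_aic": r.delta_aic,
                    "slope": r.slope,
                    "se": r.se,
                    "df": r.df,
                    "effect": r.effect_class,
                }
            )
        return pd.DataFrame(rows)


class DeltaAICScreen:
    """The screening analysis for one dataset (species x transect group).

    Parameters
    ----------
    dataset : DataFrame
        Output of :func:`build_analysis_dataset`: one row per usable
        transect-year with log indices and joined seasonal predictors.
    responses : sequence of str
        Which responses to screen against the climate predictors. By
        default abundance and both phenology indices.
    strong, moderate : float
        delta-AIC class thresholds (must satisfy strong < moderate < 0).
    """

    def __init__(
        self,
        dataset: pd.DataFrame,
        label: Optional[str] = None,
        predictors: Optional[Sequence[str]] = None,
        responses: Sequence[str] = ("log_pai", "log_onset", "log_duration"),
        strong: float = STRONG_DELTA_AIC,
        moderate: float = MODERATE_DELTA_AIC,
    ):
        if dataset.empty:
            raise ValueError("empty analysis dataset")
        self.dataset = dataset
        self.label = label if label is not None else dataset.attrs.get("label", "")
        self.predictors = predictors
        self.responses = list(responses)
        self.strong = strong
        self.moderate = moderate

    def fit(self) -> ScreenResults:
        skipped: list[str] = []
        ledgers = {}
        trends = {}
        for resp in self.responses:
            ledgers[resp] = delta_aic_ledger(
                self.dataset,
                resp,
                self.predictors,
                dataset_label=self.label,
                strong=self.strong,
                moderate=self.moderate,
                log=skipped,
            )
            trends[resp] = trend_test(
                self.dataset,
                resp,
                dataset_label=self.label,
                strong=self.strong,
                moderate=self.moderate,
            )
        try:
            biennial = biennial_test(
                self.dataset,
                dataset_label=self.label,
                strong=self.strong,
                moderate=self.moderate,
            )
        except ValueError as exc:
            biennial = None
            skipped.append(f"{self.label}: biennial test skipped ({exc})")
        try:
            ar1 = ar1_check(self.dataset, "log_pai")
        except ValueError as exc:
            ar1 = None
            skipped.append(f"{self.label}: AR(1) check skipped ({exc})")
        corr = pearson_ci(
            self.dataset["log_onset"].to_numpy(),
            self.dataset["log_duration"].to_numpy(),
        )
        return ScreenResults(
            label=self.label,
            ledgers=ledgers,
            trends=trends,
            biennial=biennial,
            phenology=phenology_models(
                self.dataset,
                dataset_label=self.label,
                strong=self.strong,
                moderate=self.moderate,
            ),
            ar1=ar1,
            onset_duration_corr=corr,
            skipped=skipped,
        )
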