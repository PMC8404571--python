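"""Flight-curve fitting and the PAI / Onset / Duration indices.

One transect-species-year of standardized counts (adults per km) is smoothed
over day-of-year with a penalized cubic-spline GAM (basis dimension 4, log
link, quasi-Poisson variance). The fitted curve — the population recruitment
curve — is evaluated on a 0.01-day grid and yields:

* **PAI**, the population abundance index: the area under the curve by the
  rectangle rule, a relative abundance measure robust to irregular walk
  effort;
* **Onset**, the day when 20% of the season's fitted abundance has accrued;
* **Duration**, the span between the 20% and 80% days.

Zero pseudo-counts are appended one week before the first walk and two weeks
after the last, which forces the log-link smooth toward zero outside the
flight period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam

from .data import SeasonIndexRow, WalkRecord

__all__ = [
    "PreparedSeries",
    "FlightCurveModel",
    "FlightCurveResults",
    "prepare_series",
    "fit_recruitment_curve",
    "integrate_pai",
    "quantile_day",
    "phenology_indices",
    "fit_flight_curves",
]

PAD_BEFORE_DAYS = 7.0
PAD_AFTER_DAYS = 14.0
GRID_STEP = 0.01

#: minimum-data rule: a season needs at least this many points (including
#: the two zero pads) and this many non-zero counts to be fitted at all
MIN_POINTS = 5
MIN_NONZERO = 3


@dataclass
class PreparedSeries:
    """Counts for one transect-species-year, standardized and zero-padded."""

    transect_id: str
    species: str
    year: int
    days: np.ndarray  # observed days plus the two pad days
    standardized_counts: np.ndarray  # raw counts / transect length, pads = 0
    pad_start_day: float
    pad_end_day: float

    @property
    def n_points(self) -> int:
        return len(self.days)

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(self.standardized_counts > 0))

    @property
    def usable(self) -> bool:
        return self.n_points >= MIN_POINTS and self.n_nonzero >= MIN_NONZERO


def prepare_series(walks: Sequence[WalkRecord]) -> PreparedSeries:
    """Standardize one season's walks and add the boundary zeros.

    All walks must belong to a single transect-species-year. Counts are
    divided by transect length; one zero pseudo-observation is placed 7 days
    before the first walk and one 14 days after the last.
    """
    walks = list(walks)
    if not walks:
        raise ValueError("no data: cannot prepare an empty season")
    keys = {(w.transect_id, w.species, w.year) for w in walks}
    if len(keys) > 1:
        raise ValueError(f"walks span multiple transect-species-years: {sorted(keys)}")
    lengths = {w.transect_length_km for w in walks}
    if len(lengths) > 1:
        raise ValueError("inconsistent transect length within one season")
    (transect_id, species, year), = keys
    length = lengths.pop()

    order = np.argsort([w.day for w in walks])
    days = np.array([walks[i].day for i in order], dtype=float)
    counts = np.array([walks[i].raw_count for i in order], dtype=float) / length
    pad_start = days[0] - PAD_BEFORE_DAYS
    pad_end = days[-1] + PAD_AFTER_DAYS
    return PreparedSeries(
        transect_id=transect_id,
        species=species,
        year=year,
        days=np.concatenate([[pad_start], days, [pad_end]]),
        standardized_counts=np.concatenate([[0.0], counts, [0.0]]),
        pad_start_day=pad_start,
        pad_end_day=pad_end,
    )


def _pearson_gcv(y: np.ndarray, mu: np.ndarray, edf: float) -> float:
    """GCV score with the Pearson statistic, as used for quasi-families."""
    n = len(y)
    pearson = float(np.sum((y - mu) ** 2 / np.maximum(mu, 1e-12)))
    return n * pearson / (n - edf) ** 2


class FlightCurveModel:
    """Penalized-spline smooth of one season's standardized counts.

    Parameters
    ----------
    series : PreparedSeries
        Standardized, zero-padded counts for one transect-species-year.
    k : int
        Spline basis dimension (number of mean parameters), default 4.
    alphas : array-like, optional
        Candidate penalty weights searched by generalized cross-validation
        (Pearson-based, appropriate for the quasi-Poisson variance
        assumption). Default: 21 log-spaced values in [1e-4, 1e6].
    grid_step : float
        Spacing of the prediction grid in days, default 0.01.
    """

    def __init__(
        self,
        series: PreparedSeries,
        k: int = 4,
        alphas: Optional[Sequence[float]] = None,
        grid_step: float = GRID_STEP,
    ):
        self.series = series
        self.k = int(k)
        self.alphas = (
            np.logspace(-4, 6, 21) if alphas is None else np.asarray(alphas, float)
        )
        self.grid_step = float(grid_step)

    def fit(self) -> "FlightCurveResults":
        """Fit the smooth, selecting the penalty by GCV.

        Raises
        ------
        ValueError
            If the series fails the minimum-data rule (fewer than 5 points
            or fewer than 3 non-zero counts).
        """
        s = self.series
        if not s.usable:
            raise ValueError(
                f"season {s.transect_id}/{s.species}/{s.year} fails the "
                f"minimum-data rule ({s.n_points} points, {s.n_nonzero} non-zero)"
            )
        y = s.standardized_counts
        n = len(y)
        basis = BSplines(s.days, df=self.k, degree=3, include_intercept=True)
        best = None
        with warnings.catch_warnings(), np.errstate(all="ignore"):
            warnings.simplefilter("ignore")
            for alpha in self.alphas:
                try:
                    res = GLMGam(
                        y, smoother=basis, family=sm.families.Poisson(), alpha=alpha
                    ).fit()
                except Exception:
                    continue
                if not np.all(np.isfinite(res.params)):
                    continue
                edf = float(np.sum(res.edf))
                score = _pearson_gcv(y, res.fittedvalues, edf)
                if not np.isfinite(score):
                    continue
                if best is None or score < best[0]:
                    best = (score, alpha, res, edf)
        if best is None:
            return FlightCurveResults(
                series=s,
                grid=np.array([]),
                density=np.array([]),
                grid_step=self.grid_step,
                dev_expl=np.nan,
                edf=np.nan,
                scale=np.nan,
                alpha=np.nan,
                converged=False,
            )
        _, alpha, res, edf = best
        grid = np.arange(s.pad_start_day, s.pad_end_day + 1e-9, self.grid_step)
        with np.errstate(all="ignore"):
            density = np.asarray(res.predict(exog_smooth=grid), dtype=float)
        pearson = float(np.sum((y - res.fittedvalues) ** 2 /
                               np.maximum(res.fittedvalues, 1e-12)))
        dev_expl = float(1.0 - res.deviance / res.null_deviance)
        return FlightCurveResults(
            series=s,
            grid=grid,
            density=density,
            grid_step=self.grid_step,
            dev_expl=dev_expl,
            edf=edf,
            scale=pearson / max(n - edf, 1e-8),
            alpha=float(alpha),
            converged=bool(getattr(res, "converged", True)),
        )


@dataclass
class FlightCurveResults:
    """A fitted (or analytically specified) recruitment curve on a fine grid.

    ``density`` holds the predicted standardized abundance at each grid day;
    it is non-negative by construction (log link). ``dev_expl`` is the
    fraction of quasi-Poisson deviance explained, ``edf`` the effective
    degrees of freedom of the smooth, and ``scale`` the Pearson dispersion
    estimate.
    """

    grid: np.ndarray
    density: np.ndarray
    grid_step: float = GRID_STEP
    dev_expl: float = np.nan
    edf: float = np.nan
    scale: float = np.nan
    alpha: float = np.nan
    converged: bool = True
    series: Optional[PreparedSeries] = field(default=None, repr=False)

    @classmethod
    def from_density(
        cls, grid: np.ndarray, density: np.ndarray, grid_step: Optional[float] = None
    ) -> "FlightCurveResults":
        """Wrap an analytically specified density (used for exact oracles)."""
        grid = np.asarray(grid, dtype=float)
        density = np.asarray(density, dtype=float)
        if grid.shape != density.shape:
            raise ValueError("grid and density must have the same shape")
        if np.any(density < 0):
            raise ValueError("density must be non-negative")
        if grid_step is None:
            grid_step = float(np.median(np.diff(grid)))
        return cls(grid=grid, density=density, grid_step=grid_step)

    @property
    def pai(self) -> float:
        """Population abundance index: rectangle-rule area under the curve."""
        if not self.converged:
            raise ValueError("curve did not converge; no PAI")
        return float(np.sum(self.density) * self.grid_step)

    def quantile_day(self, q: float) -> float:
        """Smallest grid day at which the cumulative area reaches fraction q."""
        if not 0.0 < q < 1.0:
            raise ValueError("q must be in (0, 1)")
        total = np.sum(self.density)
        if total <= 0:
            raise ValueError("curve has zero total area; quantiles undefined")
        cum = np.cumsum(self.density) / total
        idx = int(np.searchsorted(cum, q))
        return float(self.grid[min(idx, len(self.grid) - 1)])

    @property
    def onset(self) -> float:
        """Flight-period onset: the 20% day."""
        return self.quantile_day(0.20)

    @property
    def duration(self) -> float:
        """Flight-period duration: the span from the 20% to the 80% day."""
        return self.quantile_day(0.80) - self.quantile_day(0.20)

    def predict(self, days) -> np.ndarray:
        """Curve value at arbitrary days (linear interpolation on the grid)."""
        return np.interp(np.asarray(days, dtype=float), self.grid, self.density)

    def summary(self) -> pd.Series:
        s = self.series
        return pd.Series(
            {
                "transect_id": s.transect_id if s else None,
                "species": s.species if s else None,
                "year": s.year if s else None,
                "pai": self.pai if self.converged else np.nan,
                "onset": self.onset if self.converged else np.nan,
                "duration": self.duration if self.converged else np.nan,
                "dev_expl": self.dev_expl,
                "edf": self.edf,
                "scale": self.scale,
                "alpha": self.alpha,
                "converged": self.converged,
            }
        )

    def plot(self, ax=None):
        """Plot the fitted curve with the observed standardized counts."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.grid, self.density, label="fitted flight curve")
        if self.series is not None:
            ax.plot(
                self.series.days,
                self.series.standardized_counts,
                "o",
                label="standardized counts",
            )
            ax.set_title(
                f"{self.series.transect_id} / {self.series.species} / "
                f"{self.series.year}"
            )
        ax.set_xlabel("day of year")
        ax.set_ylabel("adults per km")
        ax.legend()
        return ax


def fit_recruitment_curve(series: PreparedSeries, **kwargs) -> FlightCurveResults:
    """Convenience wrapper: build and fit a :class:`FlightCurveModel`."""
    return FlightCurveModel(series, **kwargs).fit()


def integrate_pai(curve: FlightCurveResults) -> float:
    return curve.pai


def quantile_day(curve: FlightCurveResults, q: float) -> float:
    return curve.quantile_day(q)


def phenology_indices(curve: FlightCurveResults) -> SeasonIndexRow:
    """Collapse a fitted curve into a season-index row."""
    s = curve.series
    if s is None:
        raise ValueError("curve carries no series metadata")
    if not curve.converged:
        return SeasonIndexRow(
            transect_id=s.transect_id,
            species=s.species,
            year=s.year,
            pai=np.nan,
            onset=np.nan,
            duration=np.nan,
            fit_dev_expl=np.nan,
            fit_df=np.nan,
            usable=False,
        )
    onset = curve.quantile_day(0.20)
    return SeasonIndexRow(
        transect_id=s.transect_id,
        species=s.species,
        year=s.year,
        pai=curve.pai,
        onset=onset,
        duration=curve.quantile_day(0.80) - onset,
        fit_dev_expl=curve.dev_expl,
        fit_df=curve.edf,
        usable=True,
    )


def _unusable_row(series: PreparedSeries) -> SeasonIndexRow:
    return SeasonIndexRow(
        transect_id=series.transect_id,
        species=series.species,
        year=series.year,
        pai=np.nan,
        onset=np.nan,
        duration=np.nan,
        fit_dev_expl=np.nan,
        fit_df=np.nan,
        usable=False,
    )


def fit_flight_curves(
    walks: Iterable[WalkRecord],
    log: Optional[list] = None,
    **fit_kwargs,
) -> tuple[list[SeasonIndexRow], dict[tuple, FlightCurveResults]]:
    """Fit every transect-species-year in a walk table.

    Seasons failing the minimum-data rule, or whose smooth does not
    converge, yield rows with ``usable=False``; each such event is appended
    to ``log`` (a list of strings) when one is given.
    """
    groups: dict[tuple, list[WalkRecord]] = {}
    for w in walks:
        groups.setdefault((w.transect_id, w.species, w.year), []).append(w)

    rows: list[SeasonIndexRow] = []
    curves: dict[tuple, FlightCurveResults] = {}
    for key in sorted(groups):
        series = prepare_series(groups[key])
        if not series.usable:
            rows.append(_unusable_row(series))
            if log is not None:
                log.append(
                    f"dropped {key}: minimum-data rule "
                    f"({series.n_points} points, {series.n_nonzero} non-zero)"
                )
            continue
        curve = FlightCurveModel(series, **fit_kwargs).fit()
        curves[key] = curve
        rows.append(phenology_indices(curve))
        if not curve.converged and log is not None:
            log.append(f"dropped {key}: smoother did not converge")
    return rows, curves
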