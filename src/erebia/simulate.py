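"""Synthetic transect-walk counts and monthly climate with known truth.

The generator emulates the sampling design of a mountain butterfly
monitoring scheme: 2-4 walks per week inside a 1 July - 15 August window
(weather-limited, hence irregular walk days), overdispersed daily counts
under a unimodal flight-density curve per transect-year, and monthly
station climate whose seasonal aggregates vary between years with known
multiplicative effects on abundance and additive effects on flight timing.

Because every ground-truth quantity (seasonal abundance, peak day, onset,
duration, per-predictor z-scores) is retained, each downstream stage of the
pipeline can be checked by parameter recovery.

The within-season flight density is Gaussian by default (closed-form PAI /
Onset / Duration oracles); a two-piece Gaussian with unequal left/right
spreads is available to probe robustness to skewed emergence. Counts are
negative-binomial — the overdispersion that quasi-Poisson fitting assumes —
with Poisson as the ``dispersion = inf`` limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .climate import seasonal_table
from .data import MonthlyClimate, WalkRecord

__all__ = [
    "SimulationConfig",
    "TrueParameters",
    "SimulatedDataset",
    "flight_density",
    "flight_quantile",
    "simulate_climate",
    "simulate_flight_season",
    "simulate_dataset",
]

# monthly climatology of a ~1300 m central-European station:
# seasonal sine for temperature, flat precipitation, winter snow
BASE_P_TOT = 100.0  # mm / month
_SNOW_BASE = {11: 20.0, 12: 26.0, 1: 28.0, 2: 26.0, 3: 24.0, 4: 12.0}


def _base_t_avg(month: int) -> float:
    return 2.0 - 9.0 * math.cos(2.0 * math.pi * (month - 7) / 12.0)


@dataclass
class SimulationConfig:
    """Ground-truth parameters of a synthetic monitoring study.

    Defaults describe a three-transect, twelve-year scheme (36
    transect-years, the scale of the longer single-mountain datasets such
    schemes produce). ``climate_effects`` maps seasonal-predictor names to
    slopes on log-abundance per SD of the predictor; ``phenology_effects``
    maps them to shifts of the flight peak in days per SD.
    """

    n_transects: int = 3
    years: Sequence[int] = field(default_factory=lambda: list(range(2009, 2021)))
    season_window: tuple[int, int] = (182, 227)  # 1 July - 15 August
    walks_per_week: tuple[int, int] = (2, 4)
    transect_lengths_km: Optional[Sequence[float]] = None
    baseline_log_abundance: Optional[Sequence[float]] = None
    climate_effects: Mapping[str, float] = field(default_factory=dict)
    phenology_effects: Mapping[str, float] = field(default_factory=dict)
    peak_day_mean: float = 203.0
    peak_day_sd_between_years: float = 3.0
    flight_sd: float = 8.0
    flight_sd_right: Optional[float] = None  # two-piece Gaussian if set
    dispersion: float = 5.0  # negative-binomial size; inf -> Poisson
    year_process_sd: float = 0.5
    biennial_log_ratio: float = 0.0  # log of odd/even abundance ratio
    species: str = "sim_species"
    station_id: str = "SYN1"
    temp_anomaly_sd: float = 1.0  # deg C, per season-year, shared by all temps
    precip_anomaly_sd: float = 0.20  # log-scale, per season-year
    snow_anomaly_sd: float = 8.0  # days/month, per season-year
    monthly_temp_jitter_sd: float = 0.6
    monthly_precip_jitter_sd: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.flight_sd <= 0:
            raise ValueError("flight_sd must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        lo, hi = self.season_window
        if not (1 <= lo < hi <= 365):
            raise ValueError("season window must lie inside the calendar year")
        if self.transect_lengths_km is None:
            self.transect_lengths_km = [1.0 + 0.4 * i for i in range(self.n_transects)]
        if self.baseline_log_abundance is None:
            self.baseline_log_abundance = [
                5.0 - 0.3 * i for i in range(self.n_transects)
            ]
        if len(self.transect_lengths_km) != self.n_transects:
            raise ValueError("need one transect length per transect")
        if len(self.baseline_log_abundance) != self.n_transects:
            raise ValueError("need one baseline per transect")

    @property
    def transect_ids(self) -> list[str]:
        return [f"T{i + 1}" for i in range(self.n_transects)]

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        for key in ("season_window", "walks_per_week"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrueParameters:
    """Ground truth of one simulated dataset.

    ``per_season`` has one row per transect-year with the expected total
    abundance (individuals per km integrated over the season), the flight
    peak day, and the implied true onset (20% quantile day) and duration
    (20-80% span). ``z_scores`` holds the realized per-year standardized
    seasonal climate predictors shared by all transects.
    """

    per_season: pd.DataFrame
    z_scores: pd.DataFrame
    config: SimulationConfig


@dataclass
class SimulatedDataset:
    walks: list[WalkRecord]
    climate: list[MonthlyClimate]
    truth: TrueParameters


def flight_density(t, mu: float, sigma: float, sigma_right: Optional[float] = None):
    """Unit-area flight density at day(s) t.

    Gaussian when ``sigma_right`` is None, otherwise a two-piece Gaussian
    with spread ``sigma`` left of the peak and ``sigma_right`` right of it.
    """
    t = np.asarray(t, dtype=float)
    if sigma <= 0 or (sigma_right is not None and sigma_right <= 0):
        raise ValueError("flight spreads must be positive")
    if sigma_right is None:
        return stats.norm.pdf(t, loc=mu, scale=sigma)
    scale = np.where(t < mu, sigma, sigma_right)
    return (2.0 / (sigma + sigma_right)) * np.exp(
        -0.5 * ((t - mu) / scale) ** 2
    ) / math.sqrt(2.0 * math.pi)


def flight_quantile(
    q: float, mu: float, sigma: float, sigma_right: Optional[float] = None
) -> float:
    """Inverse CDF of the flight density (closed form for both shapes)."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    if sigma_right is None:
        return mu + sigma * stats.norm.ppf(q)
    w_left = sigma / (sigma + sigma_right)
    if q <= w_left:
        return mu + sigma * stats.norm.ppf(q / (2.0 * w_left))
    return mu + sigma_right * stats.norm.ppf(
        (q - w_left) / (2.0 * (1.0 - w_left)) + 0.5
    )


def true_onset_duration(
    mu: float, sigma: float, sigma_right: Optional[float] = None
) -> tuple[float, float]:
    """True 20% day and 20-80% span of the flight density."""
    q20 = flight_quantile(0.20, mu, sigma, sigma_right)
    q80 = flight_quantile(0.80, mu, sigma, sigma_right)
    return q20, q80 - q20


# ---------------------------------------------------------------------------
# climate generator
# ---------------------------------------------------------------------------

def _season_of_month(year: int, month: int) -> tuple[int, str]:
    """Map a calendar (year, month) to its (flight year, season)."""
    if month in (9, 10):
        return year + 1, "Aut"
    if month in (11, 12):
        return year + 1, "Win"
    if month <= 4:
        return year, "Win"
    if month in (5, 6):
        return year, "Spr"
    return year, "Sum"


def simulate_climate(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    n_years: Optional[int] = None,
) -> tuple[list[MonthlyClimate], pd.DataFrame]:
    """Generate monthly station records plus per-year seasonal z-scores.

    Temperature anomalies are drawn once per flight-year season and shared
    by all four temperature variables of that season (so the monthly
    ordering t_min <= t_avg <= t_max is preserved); precipitation gets a
    mean-one lognormal seasonal factor; snow days a per-season additive
    anomaly clipped to the month length. The returned z-score table
    standardizes each available seasonal aggregate across the configured
    flight years (sample SD).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    years = list(config.years)
    if len(years) < 2:
        raise ValueError("need at least 2 years of climate")
    if n_years is not None:
        years = list(range(years[0], years[0] + n_years))

    # one anomaly draw per (flight year, season), covering the margins
    anomalies: dict[tuple[int, str], dict[str, float]] = {}
    for fy in range(min(years) - 1, max(years) + 2):
        for season in ("Aut", "Win", "Spr", "Sum"):
            anomalies[(fy, season)] = {
                "temp": rng.normal(0.0, config.temp_anomaly_sd),
                # mean-one lognormal factor
                "precip": math.exp(
                    rng.normal(0.0, config.precip_anomaly_sd)
                    - 0.5 * config.precip_anomaly_sd**2
                ),
                "snow": rng.normal(0.0, config.snow_anomaly_sd),
            }

    import calendar as _cal

    records: list[MonthlyClimate] = []
    for year in range(min(years) - 1, max(years) + 1):
        for month in range(1, 13):
            anom = anomalies[_season_of_month(year, month)]
            t_jit = rng.normal(0.0, config.monthly_temp_jitter_sd)
            p_jit = math.exp(
                rng.normal(0.0, config.monthly_precip_jitter_sd)
                - 0.5 * config.monthly_precip_jitter_sd**2
            )
            t_avg = _base_t_avg(month) + anom["temp"] + t_jit
            dim = _cal.monthrange(year, month)[1]
            snow_base = _SNOW_BASE.get(month)
            snow = (
                None
                if snow_base is None or month not in _SNOW_BASE
                else int(np.clip(round(snow_base + anom["snow"]), 0, dim))
            )
            records.append(
                MonthlyClimate(
                    station_id=config.station_id,
                    year=year,
                    month=month,
                    t_avg=round(t_avg, 3),
                    t_max=round(t_avg + 4.5, 3),
                    t_min=round(t_avg - 4.5, 3),
                    t_ground=round(t_avg - 6.0, 3),
                    p_tot=round(BASE_P_TOT * anom["precip"] * p_jit, 2),
                    snow_days=snow if month in _SNOW_BASE else 0,
                )
            )

    seasonal = seasonal_table(records, years, config.station_id)
    z = pd.DataFrame(index=pd.Index(years, name="year"))
    for col in seasonal.columns:
        if col in ("station_id", "flight_year"):
            continue
        vals = seasonal[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            continue
        sd = vals.std(ddof=1)
        if sd > 0:
            z[col] = (vals - vals.mean()) / sd
    return records, z


# ---------------------------------------------------------------------------
# count generator
# ---------------------------------------------------------------------------

def simulate_flight_season(
    abundance: float,
    mu: float,
    sigma: float,
    walk_days: Sequence[int],
    length_km: float,
    dispersion: float,
    rng: np.random.Generator,
    sigma_right: Optional[float] = None,
) -> np.ndarray:
    """Negative-binomial daily counts under the flight-density curve.

    The count on day t has mean ``length_km * abundance * f(t)`` with f the
    unit-area flight density, and negative-binomial size ``dispersion``
    (variance mean * (1 + mean/dispersion)); counts are independent across
    days. ``dispersion = inf`` gives Poisson counts.
    """
    if abundance < 0:
        raise ValueError("abundance must be non-negative")
    mean = length_km * abundance * flight_density(
        np.asarray(walk_days, float), mu, sigma, sigma_right
    )
    if not math.isfinite(dispersion):
        return rng.poisson(mean)
    counts = np.zeros(len(mean), dtype=int)
    pos = mean > 0
    p = dispersion / (dispersion + mean[pos])
    counts[pos] = rng.negative_binomial(dispersion, p)
    return counts


def _draw_walk_days(
    window: tuple[int, int], walks_per_week: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    """Weather-limited effort: 2-4 walks on distinct days of each week."""
    lo, hi = window
    days = []
    start = lo
    while start <= hi:
        block = np.arange(start, min(start + 7, hi + 1))
        k = int(rng.integers(walks_per_week[0], walks_per_week[1] + 1))
        k = min(k, len(block))
        days.extend(rng.choice(block, size=k, replace=False))
        start += 7
    return np.sort(np.asarray(days, dtype=int))


def simulate_dataset(
    config: SimulationConfig, seed: Optional[int] = None
) -> SimulatedDataset:
    """Generate a full synthetic study: walks, monthly climate, and truth.

    Per transect t and year y,

    ``log A_ty = baseline_t + sum_c slope_c * z_c(y) + parity(y) *
    biennial_log_ratio / 2 + Normal(0, year_process_sd)``

    with parity +1 in odd and -1 in even calendar years, and

    ``mu_ty = peak_day_mean + sum_c phen_slope_c * z_c(y) +
    Normal(0, peak_day_sd_between_years)``.

    Fully reproducible given the seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    climate_records, z = simulate_climate(config, rng)

    for name in list(config.climate_effects) + list(config.phenology_effects):
        if name not in z.columns:
            raise ValueError(f"no simulated seasonal predictor named {name!r}")

    walks: list[WalkRecord] = []
    truth_rows = []
    for ti, transect in enumerate(config.transect_ids):
        length = float(config.transect_lengths_km[ti])
        base = float(config.baseline_log_abundance[ti])
        for year in config.years:
            log_a = base
            for name, slope in config.climate_effects.items():
                log_a += slope * float(z.loc[year, name])
            parity = 1.0 if year % 2 == 1 else -1.0
            log_a += parity * config.biennial_log_ratio / 2.0
            log_a += rng.normal(0.0, config.year_process_sd)
            abundance = math.exp(log_a)

            mu = config.peak_day_mean
            for name, slope in config.phenology_effects.items():
                mu += slope * float(z.loc[year, name])
            mu += rng.normal(0.0, config.peak_day_sd_between_years)

            walk_days = _draw_walk_days(config.season_window, config.walks_per_week, rng)
            counts = simulate_flight_season(
                abundance,
                mu,
                config.flight_sd,
                walk_days,
                length,
                config.dispersion,
                rng,
                config.flight_sd_right,
            )
            for day, count in zip(walk_days, counts):
                walks.append(
                    WalkRecord(
                        transect_id=transect,
                        species=config.species,
                        year=int(year),
                        day=int(day),
                        raw_count=int(count),
                        transect_length_km=length,
                    )
                )
            onset, duration = true_onset_duration(
                mu, config.flight_sd, config.flight_sd_right
            )
            truth_rows.append(
                {
                    "transect_id": transect,
                    "year": int(year),
                    "true_abundance": abundance,
                    "true_peak_day": mu,
                    "true_onset": onset,
                    "true_duration": duration,
                }
            )

    truth = TrueParameters(
        per_season=pd.DataFrame(truth_rows), z_scores=z, config=config
    )
    return SimulatedDataset(walks=walks, climate=climate_records, truth=truth)
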