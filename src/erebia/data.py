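"""Shared record types and delimited-text I/O for the monitoring pipeline.

All tables are plain CSV (UTF-8, header row). Four kinds of tables flow
through the pipeline:

* **walks** — one row per transect walk: a count of adults seen on one
  transect, for one species, on one day.
* **monthly climate** — one row per station-year-month of weather-station
  aggregates.
* **season indices** — one row per transect-species-year with the abundance
  index (PAI) and the phenology indices (Onset, Duration) extracted from the
  fitted flight curve.
* **model ledger** — one row per fitted screening model with its AIC,
  delta-AIC against the matching null, slope and standard error.
"""

from __future__ import annotations

import calendar
import datetime as _dt
import math
from dataclasses import dataclass, fields
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "WalkRecord",
    "MonthlyClimate",
    "SeasonIndexRow",
    "ModelResult",
    "ValidationError",
    "classify_effect",
    "day_of_year",
    "read_walks",
    "read_climate",
    "read_index_table",
    "read_ledger",
    "write_walks",
    "write_climate",
    "write_index_table",
    "write_ledger",
    "walks_to_frame",
    "climate_to_frame",
]

#: delta-AIC thresholds: below ``strong`` is strong support, below
#: ``moderate`` is moderate support, anything else is classed "none".
STRONG_DELTA_AIC = -6.0
MODERATE_DELTA_AIC = -2.0


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class WalkRecord:
    """One transect walk: adults of one species counted on one day.

    ``day`` is the integer day-of-year (Jan 1 = 1, leap-aware). Exactly one
    record may exist per (transect, species, year, day): the monitoring
    protocol is one walk per day.
    """

    transect_id: str
    species: str
    year: int
    day: int
    raw_count: int
    transect_length_km: float


@dataclass(frozen=True)
class MonthlyClimate:
    """Monthly weather-station aggregates.

    Temperatures in deg C, precipitation in mm. ``t_ground`` (minimum
    temperature 5 cm above ground, a ground-frost proxy) and ``snow_days``
    are optional; stations without those sensors leave them missing and
    missingness propagates downstream, it is never imputed.
    """

    station_id: str
    year: int
    month: int
    t_avg: float
    t_max: float
    t_min: float
    p_tot: float
    t_ground: Optional[float] = None
    snow_days: Optional[int] = None


@dataclass
class SeasonIndexRow:
    """Abundance and phenology indices for one transect-species-year.

    ``pai`` is the area under the fitted flight curve (individuals per km
    times days); ``onset`` the day-of-year when 20% of the season's fitted
    abundance has accrued; ``duration`` the 20%-80% day span. ``usable`` is
    False when the season had too little data to fit a curve, in which case
    the index fields are NaN.
    """

    transect_id: str
    species: str
    year: int
    pai: float
    onset: float
    duration: float
    fit_dev_expl: float
    fit_df: float
    usable: bool


@dataclass
class ModelResult:
    """One fitted screening model.

    ``delta_aic`` is relative to the matching null model of the same dataset
    and response (negative = the predictor improves on the null).
    ``slope``/``se`` refer to the focal predictor and are None for null
    models and for multi-predictor reference fits.
    """

    dataset_label: str
    response_name: str
    predictor_name: Optional[str]
    slope: Optional[float]
    se: Optional[float]
    df: int
    aic: float
    delta_aic: float
    effect_class: str


def classify_effect(
    delta_aic: float,
    strong: float = STRONG_DELTA_AIC,
    moderate: float = MODERATE_DELTA_AIC,
) -> str:
    """Map a delta-AIC value to {'strong', 'moderate', 'none'}."""
    if not strong < moderate < 0:
        raise ValueError("thresholds must satisfy strong < moderate < 0")
    if delta_aic < strong:
        return "strong"
    if delta_aic < moderate:
        return "moderate"
    return "none"


def day_of_year(date: _dt.date) -> int:
    """Integer day-of-year, Jan 1 = 1, leap-aware."""
    return date.timetuple().tm_yday


def _parse_day(value: str, year: int, line_no: int) -> int:
    """Parse a day field given either as day-of-year or ISO date."""
    text = str(value).strip()
    try:
        return int(text)
    except ValueError:
        pass
    try:
        date = _dt.date.fromisoformat(text)
    except ValueError:
        raise ValidationError(
            f"line {line_no}: day {value!r} is neither an integer "
            "day-of-year nor an ISO date"
        ) from None
    if date.year != year:
        raise ValidationError(
            f"line {line_no}: date {text} disagrees with year column {year}"
        )
    return day_of_year(date)


WALK_COLUMNS = [
    "transect_id",
    "species",
    "year",
    "day",
    "raw_count",
    "transect_length_km",
]

CLIMATE_COLUMNS = [
    "station_id",
    "year",
    "month",
    "t_avg",
    "t_max",
    "t_min",
    "t_ground",
    "p_tot",
    "snow_days",
]

INDEX_COLUMNS = [
    "transect_id",
    "species",
    "year",
    "pai",
    "onset",
    "duration",
    "fit_dev_expl",
    "fit_df",
    "usable",
]

LEDGER_COLUMNS = [
    "dataset_label",
    "response_name",
    "predictor_name",
    "slope",
    "se",
    "df",
    "aic",
    "delta_aic",
    "effect_class",
    "best",
]


def _require_columns(frame: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"{what} table is missing column(s): {', '.join(missing)}")


def read_walks(path) -> list[WalkRecord]:
    """Read and validate a transect-walk table.

    Counts must be non-negative integers, transect lengths positive, and
    (transect, species, year, day) unique — the protocol is one walk per
    day, so duplicates are a data error, not something to sum.
    """
    frame = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    _require_columns(frame, WALK_COLUMNS, "walks")
    records: list[WalkRecord] = []
    errors: list[str] = []
    seen: dict[tuple, int] = {}
    for idx, row in frame.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            year = int(row["year"])
            day = _parse_day(row["day"], year, line_no)
            count = int(row["raw_count"])
            length = float(row["transect_length_km"])
        except ValidationError as exc:
            errors.append(str(exc))
            continue
        except (TypeError, ValueError):
            errors.append(f"line {line_no}: malformed numeric field")
            continue
        if count < 0:
            errors.append(f"line {line_no}: negative count {count}")
            continue
        if length <= 0:
            errors.append(f"line {line_no}: non-positive transect length {length}")
            continue
        if not 1 <= day <= 366:
            errors.append(f"line {line_no}: day-of-year {day} outside 1..366")
            continue
        key = (str(row["transect_id"]), str(row["species"]), year, day)
        if key in seen:
            errors.append(
                f"line {line_no}: duplicate walk for {key} "
                f"(first seen on line {seen[key]})"
            )
            continue
        seen[key] = line_no
        records.append(
            WalkRecord(
                transect_id=str(row["transect_id"]),
                species=str(row["species"]),
                year=year,
                day=day,
                raw_count=count,
                transect_length_km=length,
            )
        )
    if errors:
        raise ValidationError("invalid walk rows:\n" + "\n".join(errors))
    return records


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    if text == "" or text.lower() in {"na", "nan"}:
        return None
    return float(text)


def read_climate(path) -> list[MonthlyClimate]:
    """Read and validate a monthly climate table.

    ``t_ground`` and ``snow_days`` may be empty; they are kept missing.
    """
    frame = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    _require_columns(frame, CLIMATE_COLUMNS, "climate")
    records: list[MonthlyClimate] = []
    errors: list[str] = []
    for idx, row in frame.iterrows():
        line_no = idx + 2
        try:
            year = int(row["year"])
            month = int(row["month"])
            t_avg = float(row["t_avg"])
            t_max = float(row["t_max"])
            t_min = float(row["t_min"])
            p_tot = float(row["p_tot"])
            t_ground = _opt_float(row["t_ground"])
            snow_raw = _opt_float(row["snow_days"])
        except (TypeError, ValueError):
            errors.append(f"line {line_no}: malformed numeric field")
            continue
        if not 1 <= month <= 12:
            errors.append(f"line {line_no}: month {month} outside 1..12")
            continue
        dim = calendar.monthrange(year, month)[1]
        snow_days: Optional[int] = None
        if snow_raw is not None:
            snow_days = int(round(snow_raw))
            if not 0 <= snow_days <= dim:
                errors.append(
                    f"line {line_no}: snow_days {snow_days} outside 0..{dim}"
                )
                continue
        if p_tot < 0:
            errors.append(f"line {line_no}: negative precipitation {p_tot}")
            continue
        if not t_min <= t_avg <= t_max:
            errors.append(
                f"line {line_no}: temperature ordering violated "
                f"(t_min={t_min}, t_avg={t_avg}, t_max={t_max})"
            )
            continue
        records.append(
            MonthlyClimate(
                station_id=str(row["station_id"]),
                year=year,
                month=month,
                t_avg=t_avg,
                t_max=t_max,
                t_min=t_min,
                p_tot=p_tot,
                t_ground=t_ground,
                snow_days=snow_days,
            )
        )
    if errors:
        raise ValidationError("invalid climate rows:\n" + "\n".join(errors))
    return records


def walks_to_frame(records: Iterable[WalkRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records], columns=WALK_COLUMNS)


def climate_to_frame(records: Iterable[MonthlyClimate]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = {f.name: getattr(r, f.name) for f in fields(MonthlyClimate)}
        rows.append(d)
    return pd.DataFrame(rows, columns=CLIMATE_COLUMNS)


def write_walks(records: Sequence[WalkRecord], path) -> None:
    if len(records) == 0:
        raise ValueError("refusing to write an empty walks table")
    walks_to_frame(records).to_csv(path, index=False)


def write_climate(records: Sequence[MonthlyClimate], path) -> None:
    if len(records) == 0:
        raise ValueError("refusing to write an empty climate table")
    climate_to_frame(records).to_csv(path, index=False)


def write_index_table(rows: Sequence[SeasonIndexRow], path) -> None:
    """Write season-index rows; full float precision so read-back is exact."""
    if len(rows) == 0:
        raise ValueError("refusing to write an empty index table")
    frame = pd.DataFrame([vars(r) for r in rows], columns=INDEX_COLUMNS)
    frame.to_csv(path, index=False)


def read_index_table(path) -> list[SeasonIndexRow]:
    frame = pd.read_csv(path)
    _require_columns(frame, INDEX_COLUMNS, "index")
    rows = []
    for _, row in frame.iterrows():
        rows.append(
            SeasonIndexRow(
                transect_id=str(row["transect_id"]),
                species=str(row["species"]),
                year=int(row["year"]),
                pai=float(row["pai"]),
                onset=float(row["onset"]),
                duration=float(row["duration"]),
                fit_dev_expl=float(row["fit_dev_expl"]),
                fit_df=float(row["fit_df"]),
                usable=bool(row["usable"]),
            )
        )
    return rows


def write_ledger(results: Sequence[ModelResult], path) -> None:
    """Write a model ledger sorted by dataset then predictor.

    Within each dataset-response group the model with the smallest AIC is
    flagged in the ``best`` column (the layout mirrors a delta-AIC
    screening table: predictor, delta-AIC, slope, SE).
    """
    if len(results) == 0:
        raise ValueError("refusing to write an empty ledger")
    frame = pd.DataFrame([vars(r) for r in results])
    frame["best"] = False
    for _, group in frame.groupby(["dataset_label", "response_name"]):
        frame.loc[group["aic"].idxmin(), "best"] = True
    frame = frame.sort_values(
        ["dataset_label", "response_name", "predictor_name"],
        na_position="first",
        kind="mergesort",
    )
    frame.to_csv(path, index=False, columns=LEDGER_COLUMNS)


def read_ledger(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _require_columns(frame, LEDGER_COLUMNS, "ledger")
    return frame
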