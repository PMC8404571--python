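"""Seasonal climate predictors aligned to the adult flight year.

The larvae hatch in late summer, feed through September-October (autumn),
overwinter November-April, resume feeding May-June (spring), and the adults
fly July-August (summer). Seasonal predictors for the flight year *y* are
therefore built from:

* autumn: Sep-Oct of year *y-1*
* winter: Nov-Dec of *y-1* plus Jan-Apr of *y*
* spring: May-Jun of *y*
* summer: Jul-Aug of *y* (concurrent with the adult flight)

Temperatures are averaged over a season's months, precipitation is summed,
and snow days are summed over the six winter months. A season field whose
source months are incomplete is left missing — missingness propagates,
downstream models simply skip that predictor.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .data import MonthlyClimate, climate_to_frame

__all__ = [
    "SEASON_MONTHS",
    "PREDICTOR_NAMES",
    "seasonal_aggregates",
    "seasonal_table",
    "assign_station",
]

#: season -> list of (year offset from flight year, month)
SEASON_MONTHS: dict[str, list[tuple[int, int]]] = {
    "Aut": [(-1, 9), (-1, 10)],
    "Win": [(-1, 11), (-1, 12), (0, 1), (0, 2), (0, 3), (0, 4)],
    "Spr": [(0, 5), (0, 6)],
    "Sum": [(0, 7), (0, 8)],
}

_TEMP_FIELDS = {"T_avg": "t_avg", "T_max": "t_max", "T_min": "t_min", "T_ground": "t_ground"}

#: the full predictor set: 5 variables x 4 seasons, plus winter snow days
PREDICTOR_NAMES: list[str] = [
    f"{var}_{season}"
    for season in ("Aut", "Win", "Spr", "Sum")
    for var in ("P_tot", "T_avg", "T_max", "T_min", "T_ground")
] + ["Snow_days"]


def _season_values(
    lookup: Mapping[tuple[int, int], MonthlyClimate],
    flight_year: int,
    season: str,
    field: str,
) -> Optional[list[float]]:
    """Collect one field over a season's months; None if any month missing."""
    values = []
    for offset, month in SEASON_MONTHS[season]:
        rec = lookup.get((flight_year + offset, month))
        if rec is None:
            return None
        value = getattr(rec, field)
        if value is None:
            return None
        values.append(float(value))
    return values


def seasonal_aggregates(
    monthly: Iterable[MonthlyClimate],
    flight_year: int,
    station_id: Optional[str] = None,
) -> dict:
    """Seasonal predictor values for one station and one flight year.

    Returns a dict with keys ``station_id``, ``flight_year`` and the 21
    predictor names; unavailable predictors are None.
    """
    records = [m for m in monthly if station_id is None or m.station_id == station_id]
    if station_id is None:
        stations = {m.station_id for m in records}
        if len(stations) > 1:
            raise ValueError(
                "multiple stations present; pass station_id to disambiguate"
            )
        station_id = next(iter(stations)) if stations else ""
    lookup = {(m.year, m.month): m for m in records}

    row: dict = {"station_id": station_id, "flight_year": flight_year}
    for season in SEASON_MONTHS:
        vals = _season_values(lookup, flight_year, season, "p_tot")
        row[f"P_tot_{season}"] = None if vals is None else sum(vals)
        for name, field in _TEMP_FIELDS.items():
            vals = _season_values(lookup, flight_year, season, field)
            row[f"{name}_{season}"] = None if vals is None else sum(vals) / len(vals)
    snow = _season_values(lookup, flight_year, "Win", "snow_days")
    row["Snow_days"] = None if snow is None else sum(snow)
    return row


def seasonal_table(
    monthly: Iterable[MonthlyClimate],
    flight_years: Sequence[int],
    station_id: Optional[str] = None,
) -> pd.DataFrame:
    """Seasonal predictor table over several flight years (one station).

    Missing predictors come back as NaN columns entries; a fully absent
    predictor yields an all-NaN column, which screening later skips.
    """
    monthly = list(monthly)
    rows = [seasonal_aggregates(monthly, y, station_id) for y in flight_years]
    frame = pd.DataFrame(rows)
    return frame


def assign_station(transect_id: str, mapping: Mapping[str, str]) -> str:
    """Look up the weather station serving a transect.

    Different transect groups on the same mountain may use different
    stations (e.g. a summit station for high transects, a valley station
    for low ones), so the same year can carry different climate rows for
    different transects.
    """
    try:
        return mapping[transect_id]
    except KeyError:
        raise ValueError(
            f"transect {transect_id!r} has no station assignment"
        ) from None


def monthly_frame(records: Iterable[MonthlyClimate]) -> pd.DataFrame:
    return climate_to_frame(records)
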