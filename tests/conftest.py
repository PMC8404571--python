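import numpy as np
import pandas as pd
import pytest

from erebia.climate import seasonal_table
from erebia.flightcurve import PAD_AFTER_DAYS, PAD_BEFORE_DAYS, PreparedSeries
from erebia.simulate import SimulatedDataset, flight_density


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def gaussian_series(
    mu: float,
    sigma: float,
    abundance: float,
    days=None,
    length_km: float = 1.0,
    year: int = 2015,
) -> PreparedSeries:
    """Noiseless season: standardized counts equal to expected values."""
    if days is None:
        lo = int(np.floor(mu - 2.5 * sigma))
        hi = int(np.ceil(mu + 2.5 * sigma))
        days = np.arange(lo, hi + 1, dtype=float)
    days = np.asarray(days, dtype=float)
    counts = abundance * flight_density(days, mu, sigma)
    pad_start = days[0] - PAD_BEFORE_DAYS
    pad_end = days[-1] + PAD_AFTER_DAYS
    return PreparedSeries(
        transect_id="T1",
        species="sim_species",
        year=year,
        days=np.concatenate([[pad_start], days, [pad_end]]),
        standardized_counts=np.concatenate([[0.0], counts / length_km, [0.0]]),
        pad_start_day=pad_start,
        pad_end_day=pad_end,
    )


def analysis_frame_from_truth(sim: SimulatedDataset) -> pd.DataFrame:
    """Screening-ready frame straight from simulated ground truth.

    Uses the true seasonal abundance / onset / duration as the indices, so
    screening-stage tests are not confounded by curve-fitting noise.
    """
    cfg = sim.truth.config
    seasonal = seasonal_table(sim.climate, list(cfg.years), cfg.station_id)
    frame = sim.truth.per_season.merge(
        seasonal.rename(columns={"flight_year": "year"}), on="year"
    )
    frame["log_pai"] = np.log(frame["true_abundance"])
    frame["log_onset"] = np.log(frame["true_onset"])
    frame["log_duration"] = np.log(frame["true_duration"])
    return frame
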