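import datetime as dt
import math
from typing import Dict, Optional

import numpy as np
import pandas as pd
import pytest

from climhealth import (
    DISTRICT_COUNTIES,
    DailyWeatherSeries,
    DetectionParams,
    load_high_vulnerability_matrix,
    load_registry,
    matrix_from_long,
)


@pytest.fixture(scope="session")
def params() -> DetectionParams:
    return DetectionParams()


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def district_matrix(registry):
    return matrix_from_long(
        load_high_vulnerability_matrix(), registry, DISTRICT_COUNTIES
    )


def make_series(
    county: str,
    observations: Dict[dt.date, Optional[float]],
    precip: Optional[Dict[dt.date, float]] = None,
) -> DailyWeatherSeries:
    """Build a weather series from a date->tmax mapping (None = missing
    value; absent dates are gaps)."""
    precip = precip or {}
    dates = sorted(set(observations) | set(precip))
    frame = pd.DataFrame(
        {
            "date": dates,
            "tmax_f": [
                math.nan if observations.get(d) is None else observations[d]
                for d in dates
            ],
            "precip_in": [precip.get(d, 0.0) for d in dates],
        }
    )
    return DailyWeatherSeries(county=county, frame=frame)


def random_summer_observations(
    rng: np.random.Generator,
    n_days: int = 200,
    start: dt.date = dt.date(2011, 4, 15),
    mean: float = 91.0,
    sd: float = 5.0,
    p_missing: float = 0.05,
    p_gap: float = 0.03,
) -> Dict[dt.date, Optional[float]]:
    """A random daily-maximum series that frequently crosses the 95 F
    threshold, includes missing values and date gaps, and straddles the
    season boundary."""
    obs: Dict[dt.date, Optional[float]] = {}
    for i in range(n_days):
        day = start + dt.timedelta(days=int(i))
        u = rng.random()
        if u < p_gap:
            continue
        if u < p_gap + p_missing:
            obs[day] = None
        else:
            obs[day] = float(np.round(mean + sd * rng.standard_normal(), 1))
    return obs
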