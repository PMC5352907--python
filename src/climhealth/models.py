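"""Core domain types: environmental series, exposure events, and detection
parameters.

Temperatures are degrees Fahrenheit and precipitation is inches throughout;
no implicit unit conversion is ever performed (``DetectionParams`` declares
the expected unit and a mismatch is an error).  Drought severity follows the
US Drought Monitor ordinal scale D0 (abnormally dry) through D4 (exceptional
drought); "exposure" downstream means severe drought (D2) or worse.
"""

from __future__ import annotations

import datetime as dt
import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import ConfigurationError, InputError

TMAX_BOUNDS_F = (-50.0, 130.0)


class Hazard(str, enum.Enum):
    """The three climate hazards tracked by the district."""

    HEAT = "heat"
    DROUGHT = "drought"
    FLOOD = "flood"


class DroughtCategory(enum.IntEnum):
    """US Drought Monitor category, ordered by severity."""

    NONE = -1
    D0 = 0
    D1 = 1
    D2 = 2
    D3 = 3
    D4 = 4

    @classmethod
    def parse(cls, label: str | "DroughtCategory") -> "DroughtCategory":
        if isinstance(label, DroughtCategory):
            return label
        key = str(label).strip().upper()
        if key in ("", "NONE", "NA", "-"):
            return cls.NONE
        try:
            return cls[key]
        except KeyError:
            raise ConfigurationError(
                f"unknown drought category {label!r}; expected NONE or D0..D4"
            ) from None

    @property
    def label(self) -> str:
        return "NONE" if self is DroughtCategory.NONE else self.name


class MonthDay(BaseModel):
    """A recurring calendar day (month, day), e.g. the season boundaries."""

    month: int = Field(ge=1, le=12)
    day: int = Field(ge=1, le=31)

    def as_tuple(self) -> Tuple[int, int]:
        return (self.month, self.day)

    @classmethod
    def parse(cls, value) -> "MonthDay":
        if isinstance(value, MonthDay):
            return value
        if isinstance(value, str):
            m, d = value.split("-")
            return cls(month=int(m), day=int(d))
        if isinstance(value, (tuple, list)) and len(value) == 2:
            return cls(month=int(value[0]), day=int(value[1]))
        if isinstance(value, dict):
            return cls(**value)
        raise ConfigurationError(f"cannot parse month-day from {value!r}")


class SeasonWindow(BaseModel):
    """An annually recurring window, inclusive at both ends.

    The default (May 1 - September 30) is the warm-season scope used both
    for extreme-heat event detection and for heat-outcome surveillance.
    """

    start: MonthDay = MonthDay(month=5, day=1)
    end: MonthDay = MonthDay(month=9, day=30)

    @model_validator(mode="after")
    def _ordered(self) -> "SeasonWindow":
        if self.start.as_tuple() > self.end.as_tuple():
            raise ConfigurationError("season start must not be after season end")
        return self

    def contains(self, day: dt.date) -> bool:
        return self.start.as_tuple() <= (day.month, day.day) <= self.end.as_tuple()


class DetectionParams(BaseModel):
    """Tunable exposure definitions.

    Defaults encode the district's operational definitions: an extreme heat
    event is >= 3 consecutive days with daily maximum temperature >= 95 F
    (inclusive) within the May-September season; a heavy-precipitation day
    has strictly more than 2 inches; drought exposure is a US Drought
    Monitor declaration of D2 (severe) or worse.
    """

    heat_threshold_f: float = 95.0
    min_run_days: int = Field(default=3, ge=1)
    season: SeasonWindow = SeasonWindow()
    precip_threshold_in: float = 2.0
    drought_min_severity: DroughtCategory = DroughtCategory.D2
    temperature_unit: str = "F"

    @field_validator("heat_threshold_f", "precip_threshold_in")
    @classmethod
    def _finite(cls, v: float) -> float:
        if not math.isfinite(v):
            raise ConfigurationError("thresholds must be finite")
        return v

    @field_validator("drought_min_severity", mode="before")
    @classmethod
    def _category(cls, v):
        return DroughtCategory.parse(v)

    @field_validator("temperature_unit")
    @classmethod
    def _unit(cls, v: str) -> str:
        if v.upper() != "F":
            raise ConfigurationError(
                f"temperature unit {v!r} not supported: series are Fahrenheit"
            )
        return "F"


@dataclass(frozen=True)
class DailyWeatherSeries:
    """Daily max-temperature / precipitation observations for one county.

    ``frame`` holds columns ``date`` (datetime.date), ``tmax_f`` and
    ``precip_in`` (floats, NaN = missing).  Dates must be unique and sorted;
    gaps are allowed and a missing date behaves like a missing value.
    """

    county: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"date", "tmax_f", "precip_in"}
        missing = required - set(self.frame.columns)
        if missing:
            raise InputError(f"weather frame missing columns {sorted(missing)}")
        dates = list(self.frame["date"])
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise InputError(f"weather dates for {self.county!r} must be sorted and unique")
        tmax = self.frame["tmax_f"]
        bad = tmax.dropna()
        if ((bad < TMAX_BOUNDS_F[0]) | (bad > TMAX_BOUNDS_F[1])).any():
            raise InputError(
                f"tmax for {self.county!r} outside plausible range {TMAX_BOUNDS_F} F"
            )
        precip = self.frame["precip_in"].dropna()
        if (precip < 0).any():
            raise InputError(f"negative precipitation for {self.county!r}")

    @classmethod
    def from_records(
        cls,
        county: str,
        records: Iterable[Tuple[dt.date, Optional[float], Optional[float]]],
    ) -> "DailyWeatherSeries":
        frame = pd.DataFrame(records, columns=["date", "tmax_f", "precip_in"])
        frame["tmax_f"] = frame["tmax_f"].astype(float)
        frame["precip_in"] = frame["precip_in"].astype(float)
        return cls(county=county, frame=frame)


@dataclass(frozen=True)
class DroughtCategorySeries:
    """Weekly US Drought Monitor categories for one county.

    ``weeks`` maps week-start dates (unique, sorted; 7 days apart within a
    contiguous block) to a :class:`DroughtCategory`.
    """

    county: str
    weeks: Tuple[Tuple[dt.date, DroughtCategory], ...]

    def __post_init__(self) -> None:
        starts = [w for w, _ in self.weeks]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise InputError(f"week starts for {self.county!r} must be sorted and unique")

    @classmethod
    def from_pairs(
        cls, county: str, pairs: Iterable[Tuple[dt.date, str | DroughtCategory]]
    ) -> "DroughtCategorySeries":
        weeks = tuple((w, DroughtCategory.parse(c)) for w, c in pairs)
        return cls(county=county, weeks=weeks)


@dataclass(frozen=True, order=True)
class HeatRun:
    """A maximal run of consecutive in-season days at/above the heat
    threshold, of any length (length < min_run is a near-miss, not an
    event)."""

    county: str
    start: dt.date
    end: dt.date
    peak_tmax_f: float

    @property
    def length(self) -> int:
        return (self.end - self.start).days + 1

    def overlaps(self, start: dt.date, end: dt.date) -> bool:
        return self.start <= end and start <= self.end


@dataclass(frozen=True, order=True)
class HeatEvent:
    """A qualifying extreme heat event: a maximal in-season run of
    >= min_run consecutive days with tmax >= threshold."""

    county: str
    start: dt.date
    end: dt.date
    peak_tmax_f: float

    @property
    def duration_days(self) -> int:
        return (self.end - self.start).days + 1

    def days(self) -> Sequence[dt.date]:
        return [self.start + dt.timedelta(days=i) for i in range(self.duration_days)]

    def overlaps(self, start: dt.date, end: dt.date) -> bool:
        return self.start <= end and start <= self.end


@dataclass(frozen=True)
class DistrictHeatEvent:
    """County heat events merged district-wide.

    ``counties_affected`` holds counties contributing a qualifying event to
    the merged window; ``near_threshold`` annotates counties whose longest
    overlapping run fell exactly one day short of qualifying (mirroring the
    footnote convention "all other counties reached threshold for 2 days").
    """

    start: dt.date
    end: dt.date
    counties_affected: frozenset[str]
    near_threshold: frozenset[Tuple[str, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.counties_affected:
            raise InputError("district event must affect at least one county")
        overlap = self.counties_affected & {c for c, _ in self.near_threshold}
        if overlap:
            raise InputError(
                f"counties {sorted(overlap)} cannot be both affected and near-threshold"
            )


@dataclass(frozen=True, order=True)
class DroughtSpell:
    """A maximal run of consecutive weeks at/above the severity floor."""

    county: str
    start_week: dt.date
    end_week: dt.date
    peak_category: DroughtCategory

    @property
    def n_weeks(self) -> int:
        return (self.end_week - self.start_week).days // 7 + 1

    def days(self) -> Sequence[dt.date]:
        """Expand the spell to daily dates: each week covers the 7 days
        starting at its week-start."""
        last = self.end_week + dt.timedelta(days=6)
        n = (last - self.start_week).days + 1
        return [self.start_week + dt.timedelta(days=i) for i in range(n)]
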