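"""Synthetic inputs with known embedded structure.

Every downstream stage (exposure detection, tier classification,
surveillance) is testable without external data: the generators here embed
heat runs, drought spells, indicator tiers, and coded-claim excesses at
known locations so tests can assert exact recovery.

What is emulated: Western-Kentucky-like summer weather (daily maxima around
the high 80s F with occasional convective rain), weekly US Drought Monitor
county trajectories, county/state/national indicator tables, and
claims-style ICD-coded records.  Background temperature noise is optional
(spread 0 is allowed) so that construction-exact tests exist alongside
statistical ones.  Weather across counties is generated independently; no
spatial correlation is modelled.
"""

from __future__ import annotations

import datetime as dt
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .classify import Direction, IndicatorObservation, Tier
from .errors import ConfigurationError
from .models import (
    DailyWeatherSeries,
    DroughtCategory,
    DroughtCategorySeries,
    Hazard,
)
from .surveillance import HealthRecord, RecordType

ONE_DAY = dt.timedelta(days=1)


# --------------------------------------------------------------------------
# weather


class HeatRunSpec(BaseModel):
    """An embedded run of hot days: ``length_days`` consecutive days whose
    maximum temperature is set to threshold + ``offset_f``."""

    county: str
    start: dt.date
    length_days: int = Field(ge=1)
    offset_f: float = Field(default=1.0, ge=0.0)

    @property
    def end(self) -> dt.date:
        return self.start + dt.timedelta(days=self.length_days - 1)


class PrecipDaySpec(BaseModel):
    county: str
    date: dt.date
    inches: float = Field(ge=0.0)


class WeatherSimConfig(BaseModel):
    """Daily-weather simulation settings.

    Defaults emulate a rural Western-Kentucky summer: mean daily maximum
    86 F with 6 F day-to-day spread, rain on about one day in four with a
    mean of 0.4 inches when it falls.
    """

    counties: List[str] = Field(min_length=1)
    start: dt.date
    end: dt.date
    baseline_tmax_mean_f: float = 86.0
    baseline_tmax_sd_f: float = Field(default=6.0, ge=0.0)
    precip_probability: float = Field(default=0.25, ge=0.0, le=1.0)
    precip_mean_in: float = Field(default=0.4, gt=0.0)
    heat_threshold_f: float = 95.0
    embedded_heat_runs: List[HeatRunSpec] = []
    embedded_precip_days: List[PrecipDaySpec] = []
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "WeatherSimConfig":
        if self.end < self.start:
            raise ConfigurationError("date range start must not be after end")
        for run in self.embedded_heat_runs:
            if run.county not in self.counties:
                raise ConfigurationError(f"embedded run county {run.county!r} unknown")
            if run.start < self.start or run.end > self.end:
                raise ConfigurationError(
                    f"embedded heat run {run.start}..{run.end} outside date range"
                )
        for day in self.embedded_precip_days:
            if day.county not in self.counties:
                raise ConfigurationError(f"embedded precip county {day.county!r} unknown")
            if not (self.start <= day.date <= self.end):
                raise ConfigurationError(f"embedded precip day {day.date} outside range")
        return self


def gen_weather(config: WeatherSimConfig) -> List[DailyWeatherSeries]:
    """One series per county covering every date in range.

    Embedded heat runs force tmax to ``heat_threshold_f + offset`` on
    exactly their days (background noise can independently exceed the
    threshold elsewhere unless the spread is 0).  Identical config and seed
    give identical output.
    """
    rng = np.random.default_rng(config.seed)
    n_days = (config.end - config.start).days + 1
    dates = [config.start + dt.timedelta(days=i) for i in range(n_days)]
    index = {d: i for i, d in enumerate(dates)}
    out: List[DailyWeatherSeries] = []
    for county in config.counties:
        tmax = config.baseline_tmax_mean_f + config.baseline_tmax_sd_f * rng.standard_normal(
            n_days
        )
        wet = rng.random(n_days) < config.precip_probability
        amounts = rng.exponential(config.precip_mean_in, n_days)
        precip = np.where(wet, amounts, 0.0)
        for run in config.embedded_heat_runs:
            if run.county == county:
                for day_offset in range(run.length_days):
                    i = index[run.start + dt.timedelta(days=day_offset)]
                    tmax[i] = max(tmax[i], config.heat_threshold_f + run.offset_f)
        for spec in config.embedded_precip_days:
            if spec.county == county:
                precip[index[spec.date]] = spec.inches
        frame = pd.DataFrame(
            {"date": dates, "tmax_f": np.round(tmax, 2), "precip_in": np.round(precip, 3)}
        )
        out.append(DailyWeatherSeries(county=county, frame=frame))
    return out


# --------------------------------------------------------------------------
# drought


class DroughtSpellSpec(BaseModel):
    """An embedded drought spell: ``length_weeks`` consecutive weeks at or
    above D2, peaking at ``peak``."""

    county: str
    start_week: dt.date
    length_weeks: int = Field(ge=1)
    peak: DroughtCategory = DroughtCategory.D2

    @field_validator("peak", mode="before")
    @classmethod
    def _cat(cls, v):
        cat = DroughtCategory.parse(v)
        if cat < DroughtCategory.D2:
            raise ConfigurationError("embedded spell peak must be D2 or worse")
        return cat

    @property
    def end_week(self) -> dt.date:
        return self.start_week + dt.timedelta(weeks=self.length_weeks - 1)


def gen_drought(
    counties: Sequence[str],
    start: dt.date,
    end: dt.date,
    embedded_spells: Sequence[DroughtSpellSpec] = (),
    seed: int = 0,
) -> List[DroughtCategorySeries]:
    """Weekly drought-category series (week starts every 7 days from
    ``start``).  Weeks outside embedded spells stay below D2; spell weeks
    ramp from D2 up to the stated peak and back, so the peak is reached."""
    if end < start:
        raise ConfigurationError("date range start must not be after end")
    rng = np.random.default_rng(seed)
    weeks: List[dt.date] = []
    w = start
    while w <= end:
        weeks.append(w)
        w += dt.timedelta(weeks=1)
    week_index = {w: i for i, w in enumerate(weeks)}
    for spell in embedded_spells:
        if spell.county not in counties:
            raise ConfigurationError(f"embedded spell county {spell.county!r} unknown")
        if spell.start_week not in week_index or spell.end_week not in week_index:
            raise ConfigurationError(
                f"embedded spell {spell.start_week}..{spell.end_week} not on the week grid"
            )
    background = [DroughtCategory.NONE, DroughtCategory.D0, DroughtCategory.D1]
    out: List[DroughtCategorySeries] = []
    for county in counties:
        cats = [background[i] for i in rng.integers(0, len(background), len(weeks))]
        for spell in embedded_spells:
            if spell.county != county:
                continue
            n = spell.length_weeks
            # symmetric ramp D2 -> peak -> D2 touching the peak mid-spell
            for k in range(n):
                depth = min(k, n - 1 - k)
                cat = DroughtCategory(
                    min(int(DroughtCategory.D2) + depth, int(spell.peak))
                )
                cats[week_index[spell.start_week] + k] = cat
            cats[week_index[spell.start_week] + (n - 1) // 2] = spell.peak
        out.append(
            DroughtCategorySeries(county=county, weeks=tuple(zip(weeks, cats)))
        )
    return out


# --------------------------------------------------------------------------
# indicator tables


class EmbeddedIndicator(BaseModel):
    """One indicator observation to synthesize with a known true tier."""

    indicator_id: str
    tier: Tier
    direction: Direction = Direction.HIGHER_IS_WORSE
    state_value: float
    national_value: Optional[float] = None
    offset: float = Field(default=2.0, gt=0.0)

    @field_validator("tier")
    @classmethod
    def _tier(cls, v: Tier) -> Tier:
        if v is Tier.UNKNOWN:
            raise ConfigurationError("embedded tier must be high, moderate, or low")
        return v


class IndicatorSimConfig(BaseModel):
    county: str = "SimCounty"
    indicators: List[EmbeddedIndicator] = Field(min_length=1)
    seed: int = 0


def gen_indicator_table(config: IndicatorSimConfig) -> List[IndicatorObservation]:
    """County values displaced from their references in the direction the
    embedded tier implies, so classification recovers the tier exactly.

    high: worse than the worst reference by ``offset``; low: better than
    the best by ``offset``; moderate: strictly between distinct references,
    or tied with a single/equal reference.
    """
    out: List[IndicatorObservation] = []
    for spec in config.indicators:
        refs = [spec.state_value] + (
            [spec.national_value] if spec.national_value is not None else []
        )
        lo, hi = min(refs), max(refs)
        worse_ref = hi if spec.direction is Direction.HIGHER_IS_WORSE else lo
        better_ref = lo if spec.direction is Direction.HIGHER_IS_WORSE else hi
        sign = 1.0 if spec.direction is Direction.HIGHER_IS_WORSE else -1.0
        if spec.tier is Tier.HIGH:
            value = worse_ref + sign * spec.offset
        elif spec.tier is Tier.LOW:
            value = better_ref - sign * spec.offset
        else:
            value = (lo + hi) / 2.0  # ties with the reference when refs coincide
        out.append(
            IndicatorObservation(
                indicator_id=spec.indicator_id,
                county=config.county,
                county_value=value,
                state_value=spec.state_value,
                national_value=spec.national_value,
            )
        )
    return out


# --------------------------------------------------------------------------
# claims


class ClaimsSimConfig(BaseModel):
    """Claims-style record simulation.

    Independent per-county-day Poisson counts: a background process drawing
    from ``background_codes`` (distractors, never reportable) plus, on
    hazard-exposed days, an excess process drawing from that hazard's code
    pool.  Code pool entries are ``(icd_version, code)`` pairs; the default
    pools are the shipped reportable sets.
    """

    counties: List[str] = Field(min_length=1)
    start: dt.date
    end: dt.date
    background_daily_rate: float = Field(default=0.2, ge=0.0)
    excess_rate: Dict[Hazard, float] = {}
    code_pools: Optional[Dict[Hazard, List[Tuple[int, str]]]] = None
    background_codes: List[Tuple[int, str]] = [
        (10, "J18"),   # pneumonia
        (10, "I10"),   # essential hypertension
        (9, "4659"),   # acute URI
        (9, "78060"),  # fever
    ]
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "ClaimsSimConfig":
        if self.end < self.start:
            raise ConfigurationError("date range start must not be after end")
        for rate in self.excess_rate.values():
            if rate < 0:
                raise ConfigurationError("rates must be >= 0")
        if not self.background_codes:
            raise ConfigurationError("background code pool must be non-empty")
        return self

    def resolved_pools(self) -> Dict[Hazard, List[Tuple[int, str]]]:
        if self.code_pools is not None:
            pools = self.code_pools
        else:
            from .fixtures import load_code_sets

            pools = {}
            for hazard, cs in load_code_sets().items():
                pools[hazard] = [(10, c) for c in cs.icd10] + [(9, c) for c in cs.icd9]
        for hazard, rate in self.excess_rate.items():
            if rate > 0 and not pools.get(hazard):
                raise ConfigurationError(f"empty code pool for hazard {hazard.value!r}")
        return pools


def _record_type(rng: np.random.Generator, icd_version: int) -> RecordType:
    if icd_version == 10:
        return RecordType.DEATH
    return RecordType.HOSPITALIZATION if rng.random() < 0.5 else RecordType.ED_VISIT


def gen_claims(
    config: ClaimsSimConfig,
    exposure_days: Mapping[Hazard, Mapping[str, Set[dt.date]]] | None = None,
) -> List[HealthRecord]:
    """Generate coded records; reproducible under seed.

    ``exposure_days`` maps hazard -> county -> hazard-exposed dates; excess
    records are only ever generated on those days and always draw from the
    hazard's pool.
    """
    exposure_days = exposure_days or {}
    pools = config.resolved_pools()
    rng = np.random.default_rng(config.seed)
    n_days = (config.end - config.start).days + 1
    records: List[HealthRecord] = []
    counter = 0
    for county in config.counties:
        for i in range(n_days):
            day = config.start + dt.timedelta(days=i)
            n_bg = rng.poisson(config.background_daily_rate)
            draws: List[Tuple[int, str]] = [
                config.background_codes[j]
                for j in rng.integers(0, len(config.background_codes), n_bg)
            ]
            for hazard, rate in sorted(config.excess_rate.items(), key=lambda kv: kv[0].value):
                if rate <= 0:
                    continue
                if day not in exposure_days.get(hazard, {}).get(county, set()):
                    continue
                pool = pools[hazard]
                n_excess = rng.poisson(rate)
                draws.extend(pool[j] for j in rng.integers(0, len(pool), n_excess))
            for version, code in draws:
                counter += 1
                records.append(
                    HealthRecord(
                        record_id=f"R{counter:06d}",
                        county=county,
                        date=day,
                        icd_version=version,
                        code=code,
                        record_type=_record_type(rng, version),
                    )
                )
    return records
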