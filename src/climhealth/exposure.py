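"""Hazard exposure detection from environmental series.

Implements the district's three operational exposure definitions:

* extreme heat — >= ``min_run_days`` consecutive in-season days with daily
  maximum temperature at or above ``heat_threshold_f`` (the comparison is
  inclusive: exactly 95.0 F qualifies);
* heavy precipitation — a calendar day with precipitation strictly over
  ``precip_threshold_in`` inches;
* drought — a week at or above ``drought_min_severity`` (default D2,
  "severe") on the US Drought Monitor scale.

Runs are built from consecutive *calendar* days: a date gap or a missing
temperature value breaks a run (a missing day is never assumed hot), and
only days inside the May-September season can qualify, so detected events
are automatically clipped to the season.
"""

from __future__ import annotations

import datetime as dt
from typing import Iterable, List, Mapping, Sequence, Tuple, Union

import pandas as pd

from .errors import InputError
from .models import (
    DailyWeatherSeries,
    DetectionParams,
    DistrictHeatEvent,
    DroughtCategorySeries,
    DroughtSpell,
    HeatEvent,
    HeatRun,
)

ONE_DAY = dt.timedelta(days=1)
WEEK = dt.timedelta(days=7)

DroughtPeriod = Union[
    Tuple[dt.date, dt.date],
    Sequence[DroughtSpell],
]


def _qualifying_days(
    series: DailyWeatherSeries, params: DetectionParams
) -> List[Tuple[dt.date, float]]:
    frame = series.frame
    out: List[Tuple[dt.date, float]] = []
    for day, tmax in zip(frame["date"], frame["tmax_f"]):
        if pd.isna(tmax):
            continue
        if tmax >= params.heat_threshold_f and params.season.contains(day):
            out.append((day, float(tmax)))
    return out


def detect_heat_runs(
    series: DailyWeatherSeries, params: DetectionParams | None = None
) -> List[HeatRun]:
    """All maximal runs of consecutive qualifying days, of any length.

    Sub-threshold-length runs are kept so that district consolidation can
    annotate near-misses (counties one day short of an event).
    """
    params = params or DetectionParams()
    runs: List[HeatRun] = []
    current: List[Tuple[dt.date, float]] = []
    for day, tmax in _qualifying_days(series, params):
        if current and day != current[-1][0] + ONE_DAY:
            runs.append(_close_run(series.county, current))
            current = []
        current.append((day, tmax))
    if current:
        runs.append(_close_run(series.county, current))
    return runs


def _close_run(county: str, days: List[Tuple[dt.date, float]]) -> HeatRun:
    return HeatRun(
        county=county,
        start=days[0][0],
        end=days[-1][0],
        peak_tmax_f=max(t for _, t in days),
    )


def detect_heat_events(
    series: DailyWeatherSeries, params: DetectionParams | None = None
) -> List[HeatEvent]:
    """Maximal qualifying runs of length >= ``min_run_days``, sorted by
    start date.  An empty series yields an empty list."""
    params = params or DetectionParams()
    return [
        HeatEvent(r.county, r.start, r.end, r.peak_tmax_f)
        for r in detect_heat_runs(series, params)
        if r.length >= params.min_run_days
    ]


def consolidate_district_events(
    per_county_events: Mapping[str, Sequence[HeatEvent]],
    per_county_runs: Mapping[str, Sequence[HeatRun]],
    params: DetectionParams | None = None,
) -> List[DistrictHeatEvent]:
    """Merge county-level events into district events.

    County events whose date ranges overlap or abut (0-day gap, i.e. one
    ends the day before the other starts) are merged into a district event
    spanning the union of their ranges.  Counties with a run of exactly
    ``min_run_days - 1`` days overlapping the merged window — and no
    qualifying event of their own there — are annotated near-threshold.
    """
    params = params or DetectionParams()
    events = sorted(e for evs in per_county_events.values() for e in evs)
    if not events:
        return []

    windows: List[List] = []  # [start, end, {counties}]
    for ev in events:
        if windows and ev.start <= windows[-1][1] + ONE_DAY:
            windows[-1][1] = max(windows[-1][1], ev.end)
            windows[-1][2].add(ev.county)
        else:
            windows.append([ev.start, ev.end, {ev.county}])

    near_len = params.min_run_days - 1
    district: List[DistrictHeatEvent] = []
    for start, end, affected in windows:
        near = {
            (run.county, run.length)
            for runs in per_county_runs.values()
            for run in runs
            if run.length == near_len
            and run.overlaps(start, end)
            and run.county not in affected
        }
        district.append(
            DistrictHeatEvent(
                start=start,
                end=end,
                counties_affected=frozenset(affected),
                near_threshold=frozenset(near),
            )
        )
    return district


def count_heavy_precip_days(
    series: DailyWeatherSeries, params: DetectionParams | None = None, year: int | None = None
) -> int:
    """Days in ``year`` with precipitation strictly over the threshold
    ("over 2 inches" — exactly 2.0 does not count).  Missing days count 0.
    With ``year=None`` all days in the series are counted."""
    params = params or DetectionParams()
    n = 0
    for day, precip in zip(series.frame["date"], series.frame["precip_in"]):
        if pd.isna(precip):
            continue
        if year is not None and day.year != year:
            continue
        if precip > params.precip_threshold_in:
            n += 1
    return n


def extract_drought_spells(
    series: DroughtCategorySeries, params: DetectionParams | None = None
) -> List[DroughtSpell]:
    """Maximal runs of consecutive weeks at/above the severity floor.

    Weeks are consecutive when their start dates are exactly 7 days apart;
    a gap in the weekly record breaks a spell.
    """
    params = params or DetectionParams()
    floor = params.drought_min_severity
    spells: List[DroughtSpell] = []
    current: List[Tuple[dt.date, int]] = []
    for week, cat in series.weeks:
        if cat >= floor:
            if current and week != current[-1][0] + WEEK:
                spells.append(_close_spell(series.county, current))
                current = []
            current.append((week, cat))
        elif current:
            spells.append(_close_spell(series.county, current))
            current = []
    if current:
        spells.append(_close_spell(series.county, current))
    return spells


def _close_spell(county: str, weeks: List[Tuple[dt.date, int]]) -> DroughtSpell:
    from .models import DroughtCategory

    return DroughtSpell(
        county=county,
        start_week=weeks[0][0],
        end_week=weeks[-1][0],
        peak_category=DroughtCategory(max(c for _, c in weeks)),
    )


def _period_days(period: DroughtPeriod) -> frozenset[dt.date]:
    if (
        isinstance(period, tuple)
        and len(period) == 2
        and isinstance(period[0], dt.date)
    ):
        start, end = period
        if end < start:
            raise InputError("period end before start")
        n = (end - start).days + 1
        return frozenset(start + dt.timedelta(days=i) for i in range(n))
    days: set[dt.date] = set()
    for spell in period:  # type: ignore[union-attr]
        days.update(spell.days())
    return frozenset(days)


def overlap_days(
    heat_events: Iterable[HeatEvent],
    drought_period: DroughtPeriod,
    policy: str = "full_containment",
) -> int:
    """Distinct calendar days covered by heat events inside a drought period.

    ``drought_period`` is either an explicit ``(start, end)`` date window or
    a sequence of :class:`DroughtSpell` (expanded to daily dates, 7 days per
    week).  Under ``"full_containment"`` an event contributes its days only
    when every one of them lies inside the period; under ``"per_day"`` each
    event contributes exactly the days it shares with the period.
    """
    if policy not in ("full_containment", "per_day"):
        raise InputError(f"unknown overlap policy {policy!r}")
    period = _period_days(drought_period)
    covered: set[dt.date] = set()
    for ev in heat_events:
        days = set(ev.days())
        if policy == "full_containment":
            if days <= period:
                covered.update(days)
        else:
            covered.update(days & period)
    return len(covered)
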