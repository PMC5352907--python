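"""CSV / YAML / JSON readers and writers for the pipeline's external
formats.

Weather CSV: ``date,county,tmax_f,precip_in`` (empty cell = missing).
Drought CSV: ``week_start,county,category`` with category NONE or D0-D4.
Records CSV: ``record_id,county,date,icd_version,code,record_type``.
Observations CSV: ``indicator_id,county,county_value,state_value,
national_value`` (empty = absent).
"""

from __future__ import annotations

import datetime as dt
import json
import math
from typing import Dict, Iterable, List, Sequence

import pandas as pd
import yaml

from .classify import IndicatorObservation, TierAssignment
from .errors import InputError
from .models import (
    DailyWeatherSeries,
    DetectionParams,
    DistrictHeatEvent,
    DroughtCategory,
    DroughtCategorySeries,
    DroughtSpell,
    HeatEvent,
)
from .surveillance import Alert, HealthRecord


def _parse_date(value) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise InputError(f"bad ISO date {value!r}") from exc


# --- weather ---------------------------------------------------------------


def read_weather_csv(path) -> List[DailyWeatherSeries]:
    frame = pd.read_csv(path)
    required = {"date", "county", "tmax_f", "precip_in"}
    if not required <= set(frame.columns):
        raise InputError(f"weather CSV needs columns {sorted(required)}")
    frame["date"] = [_parse_date(d) for d in frame["date"]]
    out = []
    for county, group in frame.groupby("county", sort=True):
        sub = group.sort_values("date")[["date", "tmax_f", "precip_in"]].reset_index(drop=True)
        out.append(DailyWeatherSeries(county=str(county), frame=sub))
    return out


def write_weather_csv(series: Sequence[DailyWeatherSeries], path) -> None:
    frames = []
    for s in series:
        sub = s.frame.copy()
        sub.insert(1, "county", s.county)
        frames.append(sub)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# --- drought ---------------------------------------------------------------


def read_drought_csv(path) -> List[DroughtCategorySeries]:
    frame = pd.read_csv(path, keep_default_na=False)
    required = {"week_start", "county", "category"}
    if not required <= set(frame.columns):
        raise InputError(f"drought CSV needs columns {sorted(required)}")
    out = []
    for county, group in frame.groupby("county", sort=True):
        group = group.sort_values("week_start")
        pairs = [
            (_parse_date(w), DroughtCategory.parse(c))
            for w, c in zip(group["week_start"], group["category"])
        ]
        out.append(DroughtCategorySeries(county=str(county), weeks=tuple(pairs)))
    return out


def write_drought_csv(series: Sequence[DroughtCategorySeries], path) -> None:
    rows = [
        {"week_start": w.isoformat(), "county": s.county, "category": c.label}
        for s in series
        for w, c in s.weeks
    ]
    pd.DataFrame(rows, columns=["week_start", "county", "category"]).to_csv(path, index=False)


# --- events / spells -------------------------------------------------------


def write_events_csv(events: Sequence[HeatEvent], path) -> None:
    rows = [
        {
            "county": e.county,
            "start": e.start.isoformat(),
            "end": e.end.isoformat(),
            "duration_days": e.duration_days,
            "peak_tmax_f": e.peak_tmax_f,
        }
        for e in sorted(events)
    ]
    pd.DataFrame(
        rows, columns=["county", "start", "end", "duration_days", "peak_tmax_f"]
    ).to_csv(path, index=False)


def write_district_events_json(events: Sequence[DistrictHeatEvent], path) -> None:
    payload = [
        {
            "start": e.start.isoformat(),
            "end": e.end.isoformat(),
            "counties_affected": sorted(e.counties_affected),
            "near_threshold": [
                {"county": c, "run_days": n} for c, n in sorted(e.near_threshold)
            ],
        }
        for e in sorted(events, key=lambda e: e.start)
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def write_spells_csv(spells: Sequence[DroughtSpell], path) -> None:
    rows = [
        {
            "county": s.county,
            "start_week": s.start_week.isoformat(),
            "end_week": s.end_week.isoformat(),
            "n_weeks": s.n_weeks,
            "peak_category": s.peak_category.label,
        }
        for s in sorted(spells)
    ]
    pd.DataFrame(
        rows, columns=["county", "start_week", "end_week", "n_weeks", "peak_category"]
    ).to_csv(path, index=False)


# --- indicators ------------------------------------------------------------


def read_observations_csv(path) -> List[IndicatorObservation]:
    frame = pd.read_csv(path)
    required = {"indicator_id", "county", "county_value"}
    if not required <= set(frame.columns):
        raise InputError(f"observations CSV needs columns {sorted(required)}")
    out = []
    for row in frame.itertuples(index=False):
        state = getattr(row, "state_value", math.nan)
        national = getattr(row, "national_value", math.nan)
        out.append(
            IndicatorObservation(
                indicator_id=row.indicator_id,
                county=str(row.county),
                county_value=float(row.county_value),
                state_value=None if pd.isna(state) else float(state),
                national_value=None if pd.isna(national) else float(national),
            )
        )
    return out


def write_observations_csv(observations: Sequence[IndicatorObservation], path) -> None:
    rows = [
        {
            "indicator_id": o.indicator_id,
            "county": o.county,
            "county_value": o.county_value,
            "state_value": o.state_value,
            "national_value": o.national_value,
        }
        for o in observations
    ]
    pd.DataFrame(
        rows,
        columns=["indicator_id", "county", "county_value", "state_value", "national_value"],
    ).to_csv(path, index=False)


def write_tiers_csv(tiers: Sequence[TierAssignment], path) -> None:
    rows = [
        {
            "indicator_id": t.indicator_id,
            "county": t.county,
            "tier": t.tier.value,
            "standard_result": t.standard_result.value,
        }
        for t in tiers
    ]
    pd.DataFrame(
        rows, columns=["indicator_id", "county", "tier", "standard_result"]
    ).to_csv(path, index=False)


# --- health records --------------------------------------------------------


def read_records_csv(path) -> List[HealthRecord]:
    frame = pd.read_csv(path, dtype={"code": str})
    required = {"record_id", "county", "date", "icd_version", "code", "record_type"}
    if not required <= set(frame.columns):
        raise InputError(f"records CSV needs columns {sorted(required)}")
    return [
        HealthRecord(
            record_id=str(row.record_id),
            county=str(row.county),
            date=_parse_date(row.date),
            icd_version=int(row.icd_version),
            code=str(row.code),
            record_type=row.record_type,
        )
        for row in frame.itertuples(index=False)
    ]


def write_records_csv(records: Sequence[HealthRecord], path) -> None:
    rows = [
        {
            "record_id": r.record_id,
            "county": r.county,
            "date": r.date.isoformat(),
            "icd_version": r.icd_version,
            "code": r.code,
            "record_type": r.record_type.value,
        }
        for r in records
    ]
    pd.DataFrame(
        rows, columns=["record_id", "county", "date", "icd_version", "code", "record_type"]
    ).to_csv(path, index=False)


def write_alerts_jsonl(alerts: Sequence[Alert], path) -> None:
    with open(path, "w") as fh:
        for a in alerts:
            fh.write(
                json.dumps(
                    {
                        "date": a.date.isoformat(),
                        "county": a.county,
                        "hazard": a.hazard.value,
                        "condition": a.condition,
                    }
                )
            )
            fh.write("\n")


# --- params ----------------------------------------------------------------


def read_params_yaml(path) -> DetectionParams:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return DetectionParams(**raw)
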