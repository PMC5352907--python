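"""Proposed climate-and-health surveillance: exposure triggers and
reportable-outcome matching over ICD-coded records.

The shipped defaults are the district's proposed system: heat outcomes are
heat-related deaths (ICD-10 X30) and heat-stress hospitalizations / ED
visits (ICD-9 992, E900.0, E900.9) restricted to May-September; flood
outcomes are unintentional drownings (ICD-10 W69, W70, X38) and
flooding-related hospitalizations / ED visits (ICD-9 E908.2, E908.9,
E910.8, E910.9) year-round.  The drought trigger (a county week at D2 or
worse) ships with an empty outcome code set — its reportable outcome list
is still in development and is configurable.

Codes are matched case- and dot-insensitively at the category level: a
listed code matches itself and its subdivisions ("X30", "x30", "X30.0" and
"X300" all match an X30 entry; "X3" does not).
"""

from __future__ import annotations

import datetime as dt
import enum
import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from pydantic import BaseModel, field_validator

from .errors import ConfigurationError, InputError
from .models import (
    DailyWeatherSeries,
    DetectionParams,
    DroughtCategorySeries,
    Hazard,
    SeasonWindow,
)

logger = logging.getLogger(__name__)

_ICD10_RE = re.compile(r"^[A-Z][0-9][0-9A-Z][0-9A-Z]{0,4}$")
_ICD9_RE = re.compile(r"^(?:[0-9]{3}[0-9]{0,2}|E[0-9]{3}[0-9]?|V[0-9]{2}[0-9]{0,2})$")


class RecordType(str, enum.Enum):
    DEATH = "death"
    HOSPITALIZATION = "hospitalization"
    ED_VISIT = "ed_visit"


def normalize_code(code: str) -> str:
    """Uppercase and strip the decimal point: 'e900.0' -> 'E9000'."""
    return code.strip().upper().replace(".", "")


def validate_code(code: str, icd_version: int) -> str:
    """Normalize and syntax-check a code for its ICD revision."""
    norm = normalize_code(code)
    pattern = _ICD10_RE if icd_version == 10 else _ICD9_RE
    if icd_version not in (9, 10):
        raise InputError(f"unsupported ICD version {icd_version!r}")
    if not pattern.match(norm):
        raise InputError(f"malformed ICD-{icd_version} code {code!r}")
    return norm


class HealthRecord(BaseModel):
    record_id: str
    county: str
    date: dt.date
    icd_version: int
    code: str
    record_type: RecordType

    @field_validator("icd_version")
    @classmethod
    def _version(cls, v: int) -> int:
        if v not in (9, 10):
            raise InputError(f"unsupported ICD version {v!r}")
        return v


class CodeSet(BaseModel):
    """Reportable-outcome codes for one hazard, with an optional seasonal
    restriction on matching (heat outcomes are May-September)."""

    hazard: Hazard
    icd10: List[str] = []
    icd9: List[str] = []
    season: Optional[SeasonWindow] = None

    def normalized(self, icd_version: int) -> List[str]:
        codes = self.icd10 if icd_version == 10 else self.icd9
        return [normalize_code(c) for c in codes]

    def matches(self, record: HealthRecord) -> bool:
        norm = validate_code(record.code, record.icd_version)
        listed = self.normalized(record.icd_version)
        hit = any(norm == c or norm.startswith(c) for c in listed)
        if hit and self.season is not None and not self.season.contains(record.date):
            return False
        return hit


def default_code_sets() -> Dict[Hazard, CodeSet]:
    """The shipped surveillance configuration (see module docstring)."""
    from .fixtures import load_code_sets

    return load_code_sets()


@dataclass
class MatchResult:
    """Outcome of reportable matching: matched records per hazard, plus
    records rejected for malformed codes (never silently dropped)."""

    matched: Dict[Hazard, List[HealthRecord]]
    rejected: List[Tuple[HealthRecord, str]] = field(default_factory=list)

    def __getitem__(self, hazard: Hazard) -> List[HealthRecord]:
        return self.matched.get(hazard, [])


def match_reportable(
    records: Iterable[HealthRecord],
    code_sets: Optional[Mapping[Hazard, CodeSet]] = None,
) -> MatchResult:
    """Assign records to hazards by reportable-code matching.

    A record matches a hazard when its normalized code equals a listed code
    or extends it as a subdivision, and (for seasonal sets) its date falls
    inside the season.  Under the default disjoint code sets a record
    matches at most one hazard; if overlapping custom sets are supplied the
    first matching hazard in mapping order wins.
    """
    sets = code_sets if code_sets is not None else default_code_sets()
    matched: Dict[Hazard, List[HealthRecord]] = {hz: [] for hz in sets}
    rejected: List[Tuple[HealthRecord, str]] = []
    for record in records:
        try:
            validate_code(record.code, record.icd_version)
        except InputError as exc:
            logger.warning("rejected record %s: %s", record.record_id, exc)
            rejected.append((record, str(exc)))
            continue
        for hazard, code_set in sets.items():
            if code_set.matches(record):
                matched[hazard].append(record)
                break
    return MatchResult(matched=matched, rejected=rejected)


@dataclass(frozen=True, order=True)
class Alert:
    date: dt.date
    county: str
    hazard: Hazard
    condition: str


def evaluate_triggers(
    weather: Sequence[DailyWeatherSeries] = (),
    drought: Sequence[DroughtCategorySeries] = (),
    params: DetectionParams | None = None,
) -> List[Alert]:
    """Emit surveillance alerts from environmental series.

    Heat: an alert on the day a run reaches ``min_run_days`` qualifying
    days and on each subsequent day of the run (the first alert of an event
    fires on its third day under the defaults).
    Drought: one alert per county-week at/above the severity floor.
    Flood: one alert per day with precipitation over the threshold.
    Deterministic and idempotent; output sorted by (date, county, hazard).
    """
    from .exposure import detect_heat_events

    params = params or DetectionParams()
    alerts: List[Alert] = []
    for series in weather:
        for ev in detect_heat_events(series, params):
            for i, day in enumerate(ev.days()):
                if i + 1 >= params.min_run_days:
                    alerts.append(
                        Alert(
                            date=day,
                            county=series.county,
                            hazard=Hazard.HEAT,
                            condition=(
                                f"day {i + 1} of run >= {params.heat_threshold_f:g} F "
                                f"since {ev.start.isoformat()}"
                            ),
                        )
                    )
        for day, precip in zip(series.frame["date"], series.frame["precip_in"]):
            if precip == precip and precip > params.precip_threshold_in:  # NaN-safe
                alerts.append(
                    Alert(
                        date=day,
                        county=series.county,
                        hazard=Hazard.FLOOD,
                        condition=f"precipitation {precip:.2f} in > {params.precip_threshold_in:g} in",
                    )
                )
    for series in drought:
        for week, cat in series.weeks:
            if cat >= params.drought_min_severity:
                alerts.append(
                    Alert(
                        date=week,
                        county=series.county,
                        hazard=Hazard.DROUGHT,
                        condition=f"county declared {cat.label}",
                    )
                )
    return sorted(alerts)


def surveillance_report(
    alerts: Sequence[Alert],
    match_result: MatchResult,
    period: Tuple[dt.date, dt.date],
) -> dict:
    """Tabulate alerts and matched records within a reporting period.

    Returns a deterministic nested structure: alert counts per
    (hazard, county) and matched-record counts per
    (hazard, county, record type).  Record order never matters.
    """
    start, end = period
    if end < start:
        raise InputError("report period end before start")
    alert_counts: Dict[str, Dict[str, int]] = {}
    for alert in alerts:
        if start <= alert.date <= end:
            by_county = alert_counts.setdefault(alert.hazard.value, {})
            by_county[alert.county] = by_county.get(alert.county, 0) + 1
    record_counts: Dict[str, Dict[str, Dict[str, int]]] = {}
    for hazard, records in match_result.matched.items():
        for rec in records:
            if start <= rec.date <= end:
                by_county = record_counts.setdefault(hazard.value, {}).setdefault(
                    rec.county, {}
                )
                by_county[rec.record_type.value] = by_county.get(rec.record_type.value, 0) + 1
    return {
        "period": [start.isoformat(), end.isoformat()],
        "alerts": {h: dict(sorted(c.items())) for h, c in sorted(alert_counts.items())},
        "matched_records": {
            h: {c: dict(sorted(t.items())) for c, t in sorted(by.items())}
            for h, by in sorted(record_counts.items())
        },
        "rejected_records": len(match_result.rejected),
    }
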