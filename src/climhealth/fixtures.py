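"""Loaders for the packaged reference data.

Three small datasets ship with the package:

* the district's 2000-2012 extreme-heat event table (date windows with the
  counties affected and near-threshold footnotes), transcribed from the
  published district assessment;
* the district's high-vulnerability matrix (county, indicator, hazard
  checkmarks), likewise transcribed, used as a regression fixture
  independent of the classification pipeline;
* the default indicator registry and reportable-code configuration.
"""

from __future__ import annotations

import datetime as dt
from importlib import resources
from typing import Dict, List

import pandas as pd
import yaml

from .classify import IndicatorDefinition, IndicatorRegistry
from .models import DistrictHeatEvent, Hazard, HeatEvent, MonthDay, SeasonWindow
from .surveillance import CodeSet

#: The seven district counties, in the published presentation order.
DISTRICT_COUNTIES: List[str] = [
    "Daviess",
    "Hancock",
    "Henderson",
    "McLean",
    "Ohio",
    "Union",
    "Webster",
]


def _data_path(name: str):
    return resources.files("climhealth.data").joinpath(name)


def load_registry(path=None) -> IndicatorRegistry:
    """The indicator registry (default: the packaged one)."""
    source = path if path is not None else _data_path("indicator_registry.yaml")
    with open(source) if isinstance(source, str) else source.open() as fh:
        raw = yaml.safe_load(fh)
    return IndicatorRegistry(IndicatorDefinition(**item) for item in raw["indicators"])


def load_code_sets(path=None) -> Dict[Hazard, CodeSet]:
    """The reportable-outcome code sets (default: the packaged ones)."""
    source = path if path is not None else _data_path("reportable_codes.yaml")
    with open(source) if isinstance(source, str) else source.open() as fh:
        raw = yaml.safe_load(fh)
    sets: Dict[Hazard, CodeSet] = {}
    for name, body in raw.items():
        hazard = Hazard(name)
        season = None
        if body.get("season"):
            season = SeasonWindow(
                start=MonthDay.parse(body["season"]["start"]),
                end=MonthDay.parse(body["season"]["end"]),
            )
        sets[hazard] = CodeSet(
            hazard=hazard,
            icd10=[str(c) for c in body.get("icd10", [])],
            icd9=[str(c) for c in body.get("icd9", [])],
            season=season,
        )
    return sets


def load_heat_event_table() -> pd.DataFrame:
    """The 2000-2012 district heat-event table.

    Columns: ``start``/``end`` (datetime.date), ``counties`` (list of
    county names), ``near_threshold_note`` (footnote tag or empty).
    """
    with _data_path("district_heat_events.csv").open() as fh:
        frame = pd.read_csv(fh, keep_default_na=False)
    frame["start"] = [dt.date.fromisoformat(s) for s in frame["start"]]
    frame["end"] = [dt.date.fromisoformat(s) for s in frame["end"]]
    frame["counties"] = [c.split(";") for c in frame["counties"]]
    return frame


def heat_events_from_table(frame: pd.DataFrame | None = None) -> List[HeatEvent]:
    """Expand the event table to per-county :class:`HeatEvent` objects.

    Peak temperatures are not published, so ``peak_tmax_f`` is recorded as
    NaN-free 95.0 (the qualifying threshold, a lower bound).
    """
    if frame is None:
        frame = load_heat_event_table()
    events: List[HeatEvent] = []
    for row in frame.itertuples(index=False):
        for county in row.counties:
            events.append(
                HeatEvent(county=county, start=row.start, end=row.end, peak_tmax_f=95.0)
            )
    return events


def district_events_from_table(frame: pd.DataFrame | None = None) -> List[DistrictHeatEvent]:
    """The event table as district-level events (one per printed window)."""
    if frame is None:
        frame = load_heat_event_table()
    out: List[DistrictHeatEvent] = []
    for row in frame.itertuples(index=False):
        affected = frozenset(row.counties)
        near = frozenset()
        if row.near_threshold_note == "all_others_two_days":
            near = frozenset(
                (c, 2) for c in DISTRICT_COUNTIES if c not in affected
            )
        out.append(
            DistrictHeatEvent(
                start=row.start,
                end=row.end,
                counties_affected=affected,
                near_threshold=near,
            )
        )
    return out


def load_high_vulnerability_matrix() -> pd.DataFrame:
    """Long-form (county, indicator_id, hazard) checkmarks of the
    district's published high-vulnerability matrix."""
    with _data_path("district_high_vulnerability.csv").open() as fh:
        return pd.read_csv(fh)
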