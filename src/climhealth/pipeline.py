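"""End-to-end pipeline: detect -> classify -> matrix -> surveil -> report.

``run_pipeline`` executes every stage for which an input is configured,
writes each stage's artifacts to the output directory, and records them in
a manifest.  Rerunning with identical inputs reproduces identical outputs.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional

from pydantic import BaseModel

from . import exposure, io, matrix as matrix_mod, surveillance
from .classify import classify_table
from .errors import ClimHealthError, ConfigurationError
from .fixtures import load_code_sets, load_registry
from .models import DetectionParams

logger = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """Paths and parameters for one pipeline run.

    Any of the stage inputs may be omitted; the corresponding stage is
    skipped.  ``registry`` and ``codes`` default to the packaged
    configuration.
    """

    weather_csv: Optional[str] = None
    drought_csv: Optional[str] = None
    observations_csv: Optional[str] = None
    records_csv: Optional[str] = None
    registry: Optional[str] = None
    codes: Optional[str] = None
    params: DetectionParams = DetectionParams()
    out_dir: str = "climhealth_out"
    seed: int = 0
    log_level: str = "INFO"

    def check_paths(self) -> None:
        for label, path in [
            ("weather_csv", self.weather_csv),
            ("drought_csv", self.drought_csv),
            ("observations_csv", self.observations_csv),
            ("records_csv", self.records_csv),
            ("registry", self.registry),
            ("codes", self.codes),
        ]:
            if path is not None and not Path(path).exists():
                raise ConfigurationError(f"{label} path does not exist: {path}")


def run_pipeline(config: RunConfig) -> Dict:
    """Execute configured stages and return the artifact manifest."""
    logging.basicConfig(level=config.log_level)
    config.check_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {
        "params": json.loads(config.params.model_dump_json()),
        "seed": config.seed,
        "artifacts": {},
    }

    def _register(name: str, path: Path) -> None:
        manifest["artifacts"][name] = str(path)

    weather = drought = None
    all_events = []
    all_runs: Dict[str, list] = {}
    per_county_events: Dict[str, list] = {}

    if config.weather_csv:
        weather = io.read_weather_csv(config.weather_csv)
        logger.info("stage detect: %d weather series read", len(weather))
        for series in weather:
            runs = exposure.detect_heat_runs(series, config.params)
            events = [e for e in exposure.detect_heat_events(series, config.params)]
            all_runs[series.county] = runs
            per_county_events[series.county] = events
            all_events.extend(events)
        path = out_dir / "heat_events.csv"
        io.write_events_csv(all_events, path)
        _register("heat_events", path)
        district = exposure.consolidate_district_events(
            per_county_events, all_runs, config.params
        )
        path = out_dir / "district_events.json"
        io.write_district_events_json(district, path)
        _register("district_events", path)
        years = sorted({d.year for s in weather for d in s.frame["date"]})
        precip_rows = {
            s.county: {str(y): exposure.count_heavy_precip_days(s, config.params, y) for y in years}
            for s in weather
        }
        path = out_dir / "heavy_precip_days.json"
        path.write_text(json.dumps(precip_rows, indent=2, sort_keys=True) + "\n")
        _register("heavy_precip_days", path)
        logger.info(
            "stage detect: %d county events, %d district events", len(all_events), len(district)
        )

    spells = []
    if config.drought_csv:
        drought = io.read_drought_csv(config.drought_csv)
        for series in drought:
            spells.extend(exposure.extract_drought_spells(series, config.params))
        path = out_dir / "drought_spells.csv"
        io.write_spells_csv(spells, path)
        _register("drought_spells", path)
        logger.info("stage detect: %d drought spells", len(spells))

    registry = load_registry(config.registry)
    summary = None
    if config.observations_csv:
        observations = io.read_observations_csv(config.observations_csv)
        tiers = classify_table(observations, registry)
        path = out_dir / "tiers.csv"
        io.write_tiers_csv(tiers, path)
        _register("tiers", path)
        mat = matrix_mod.build_matrix(tiers, registry)
        path = out_dir / "matrix.csv"
        mat.to_long().to_csv(path, index=False)
        _register("matrix", path)
        summary = matrix_mod.summarize(mat)
        path = out_dir / "summary.json"
        path.write_text(json.dumps(summary, indent=2) + "\n")
        _register("summary", path)
        logger.info(
            "stage classify/matrix: %d observations -> %d tier rows", len(observations), len(tiers)
        )

    if config.weather_csv or config.drought_csv:
        alerts = surveillance.evaluate_triggers(weather or [], drought or [], config.params)
        path = out_dir / "alerts.jsonl"
        io.write_alerts_jsonl(alerts, path)
        _register("alerts", path)
        logger.info("stage surveil: %d alerts", len(alerts))

    if config.records_csv:
        records = io.read_records_csv(config.records_csv)
        code_sets = load_code_sets(config.codes)
        result = surveillance.match_reportable(records, code_sets)
        matched_rows = [
            {"hazard": hz.value, "record_id": r.record_id}
            for hz, recs in sorted(result.matched.items(), key=lambda kv: kv[0].value)
            for r in sorted(recs, key=lambda r: (r.date, r.record_id))
        ]
        path = out_dir / "matched_records.json"
        path.write_text(json.dumps(matched_rows, indent=2) + "\n")
        _register("matched_records", path)
        if records:
            period = (min(r.date for r in records), max(r.date for r in records))
            alerts_list = (
                surveillance.evaluate_triggers(weather or [], drought or [], config.params)
                if (weather or drought)
                else []
            )
            report = surveillance.surveillance_report(alerts_list, result, period)
            path = out_dir / "surveillance_report.json"
            path.write_text(json.dumps(report, indent=2) + "\n")
            _register("surveillance_report", path)
        logger.info("stage surveil: %d records matched", len(matched_rows))

    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    report_md = render_report(manifest)
    report_path = out_dir / "report.md"
    report_path.write_text(report_md)
    manifest["artifacts"]["report"] = str(report_path)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def render_report(manifest: Dict) -> str:
    """Render a district summary in markdown from a run manifest.

    All numbers are read back from the stage artifacts (single source of
    truth); nothing is recomputed here.
    """
    artifacts = manifest.get("artifacts", {})
    lines: List[str] = ["# District climate-and-health summary", ""]

    lines.append("## Extreme heat")
    if "heat_events" in artifacts:
        import pandas as pd

        events = pd.read_csv(artifacts["heat_events"])
        lines.append(f"- qualifying heat events detected: {len(events)}")
        if len(events):
            lines.append(
                f"- event windows span {events['start'].min()} to {events['end'].max()}"
            )
    else:
        lines.append("- no weather input configured")
    lines.append("")

    lines.append("## Drought")
    if "drought_spells" in artifacts:
        import pandas as pd

        spells = pd.read_csv(artifacts["drought_spells"])
        lines.append(f"- drought spells at/above the severity floor: {len(spells)}")
    else:
        lines.append("- no drought input configured")
    lines.append("")

    lines.append("## Flooding")
    if "heavy_precip_days" in artifacts:
        precip = json.loads(Path(artifacts["heavy_precip_days"]).read_text())
        total = sum(sum(v.values()) for v in precip.values())
        lines.append(f"- heavy-precipitation days (all counties, all years): {total}")
    else:
        lines.append("- no weather input configured")
    lines.append("")

    lines.append("## Vulnerability tiers")
    if "summary" in artifacts:
        summary = json.loads(Path(artifacts["summary"]).read_text())
        lines.append(
            f"- high-vulnerability indicators per county: "
            f"min {summary['min_county_high']}, max {summary['max_county_high']}"
        )
        for county, n in summary["per_county_high"].items():
            lines.append(f"  - {county}: {n}")
    else:
        lines.append("- no observations input configured")
    lines.append("")

    lines.append("## Surveillance")
    if "alerts" in artifacts:
        n_alerts = sum(1 for _ in Path(artifacts["alerts"]).read_text().splitlines())
        lines.append(f"- alerts emitted: {n_alerts}")
    if "matched_records" in artifacts:
        matched = json.loads(Path(artifacts["matched_records"]).read_text())
        lines.append(f"- reportable records matched: {len(matched)}")
    if "alerts" not in artifacts and "matched_records" not in artifacts:
        lines.append("- no surveillance inputs configured")
    lines.append("")
    return "\n".join(lines)


def load_run_config(path) -> RunConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)
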