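# climhealth

Local climate-and-health environmental public health indicators for a
rural multi-county health district.

Rural health departments face growing climate hazards — extreme heat,
drought, and flooding — with thin data and thinner analytic capacity. This
package implements, as reusable and testable code, the indicator workflow
such a department can actually run: detect hazard exposure from routinely
available environmental series, benchmark county indicators against state,
national, and federal-standard references, assemble the county ×
indicator × hazard vulnerability matrix, and evaluate syndromic
surveillance triggers over ICD-coded health records. It ships with the
seven-county Western Kentucky district's published reference tables
(2000–2012 heat event windows, the high-vulnerability matrix, and the
proposed surveillance code sets) as regression fixtures, plus synthetic
generators so every stage is testable without restricted data.

## The definitions at the core

**Exposure.** An *extreme heat event* is a maximal run of ≥ 3 consecutive
days with daily maximum temperature T_max ≥ 95 °F inside the May 1 –
September 30 season (inclusive threshold; a missing day breaks a run). A
*heavy-precipitation day* has precipitation strictly over 2 in. *Drought
exposure* is a US Drought Monitor declaration at category D2 (severe) or
worse; spells are maximal runs of consecutive qualifying weeks.

**Vulnerability tier.** For a county value x with reference values r₁
(state) and r₂ (national), under the indicator's worse-direction ≻:

- high if x ≻ r for every available r,
- low if r ≻ x for every available r,
- moderate otherwise (between, or tied with either),
- unknown if no reference is available.

Five indicators are additionally benchmarked against a federal
standard/goal (ties meet the standard); the standard comparison
supplements, never replaces, the tier.

**Surveillance.** Heat alerts fire on the third qualifying day of a run
and each day thereafter; drought alerts per county-week at ≥ D2; flood
alerts per heavy-precipitation day. Reportable outcomes are matched case-
and dot-insensitively at the ICD category level (heat: ICD-10 X30, ICD-9
992 / E900.0 / E900.9, May–September only; flood: ICD-10 W69 / W70 / X38,
ICD-9 E908.2 / E908.9 / E910.8 / E910.9, year-round).

## Worked example

```python
import datetime as dt
import climhealth as ch

# 1. shipped district event table: 2012 heat/drought coincidence
table = ch.load_heat_event_table()
events_2012 = [ch.HeatEvent("district", r.start, r.end, 95.0)
               for r in table.itertuples(index=False) if r.start.year == 2012]
days = ch.overlap_days(events_2012, (dt.date(2012, 7, 1), dt.date(2012, 8, 31)))
print(f"2012 heat event days inside the Jul-Aug drought window: {days}")

# 2. shipped high-vulnerability matrix
registry = ch.load_registry()
matrix = ch.matrix_from_long(ch.load_high_vulnerability_matrix(),
                             registry, ch.DISTRICT_COUNTIES)
summary = ch.summarize(matrix)
print("high-vulnerability indicators per county:", summary["per_county_high"])
print("elderly flagged for extreme heat in",
      ch.count_counties_flagged(matrix, "elderly", ch.Hazard.HEAT), "of 7 counties")

# 3. detection on synthetic weather with an embedded 4-day run
config = ch.WeatherSimConfig(
    counties=["Union"], start=dt.date(2012, 6, 1), end=dt.date(2012, 8, 31),
    baseline_tmax_sd_f=0.0, baseline_tmax_mean_f=82.0, precip_probability=0.0,
    embedded_heat_runs=[dict(county="Union", start=dt.date(2012, 7, 15),
                             length_days=4, offset_f=2.0)],
    seed=1)
series = ch.gen_weather(config)[0]
for ev in ch.detect_heat_events(series):
    print(f"event: {ev.county} {ev.start} .. {ev.end} "
          f"({ev.duration_days} days, peak {ev.peak_tmax_f} F)")

# 4. classification of the published fine-particulate comparison
obs = ch.IndicatorObservation(indicator_id="air_pollution_pm25", county="District",
                              county_value=14.1, state_value=13.5, national_value=11.1)
print("PM2.5 14.1 vs state 13.5 / national 11.1 ->",
      ch.classify_tier(obs, registry["air_pollution_pm25"]).value)
```

prints

```
2012 heat event days inside the Jul-Aug drought window: 33
high-vulnerability indicators per county: {'Daviess': 6, 'Hancock': 8, 'Henderson': 8, 'McLean': 8, 'Ohio': 8, 'Union': 6, 'Webster': 8}
elderly flagged for extreme heat in 7 of 7 counties
event: Union 2012-07-15 .. 2012-07-18 (4 days, peak 97.0 F)
PM2.5 14.1 vs state 13.5 / national 11.1 -> high
```

The 33 overlap days are the three 2012 event windows fully contained in
July–August (26 + 3 + 4 days); the per-county counts are distinct
indicators flagged high under at least one hazard, spanning the district's
six-to-eight range; and the fine-particulate comparison is "high" because
the district mean is strictly worse than both the state and national means.

## Command line

A thin CLI wraps the library:

```sh
climhealth simulate weather --config weather.yaml --seed 1 --out weather.csv
climhealth detect heat --in weather.csv --out events.csv --district-out district.json
climhealth detect overlap --events events.csv --window 2012-07-01..2012-08-31
climhealth classify --observations obs.csv --out tiers.csv
climhealth matrix build --tiers tiers.csv --out matrix.csv
climhealth surveil triggers --weather weather.csv --drought drought.csv --out alerts.jsonl
climhealth run --config run.yaml     # all stages, writes a manifest
climhealth report --manifest out/manifest.json
```

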