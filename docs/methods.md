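# Methods

`climhealth` implements the indicator-and-surveillance workflow a rural
multi-county health district can run with routinely available data: daily
weather observations, weekly US Drought Monitor declarations, indicator
tables compared across spatial scales, and ICD-coded claims records. This
note documents the operational definitions, the numerical and design
choices, what the synthetic generators do and do not emulate, and the known
limitations.

## Hazard exposure definitions

Three climate hazards are tracked; each has a fixed operational exposure
definition, held in `DetectionParams`:

| Parameter | Default | Meaning |
|---|---|---|
| `heat_threshold_f` | 95.0 °F | daily maximum temperature floor, **inclusive** (exactly 95.0 qualifies) |
| `min_run_days` | 3 | minimum consecutive qualifying days for an extreme heat event |
| `season` | May 1 – Sep 30 | warm-season window for heat qualification and heat-outcome matching |
| `precip_threshold_in` | 2.0 in | heavy-precipitation day floor, **strict** ("over 2 inches"; exactly 2.0 does not count) |
| `drought_min_severity` | D2 | minimum US Drought Monitor category counting as drought exposure |

Temperatures are Fahrenheit and precipitation inches throughout; the
parameter object declares the unit and anything else is rejected rather
than converted.

### Heat events

A qualifying day is an in-season calendar day with a recorded maximum
temperature at or above threshold. Events are maximal runs of consecutive
qualifying days of length ≥ `min_run_days`. Two conservatism rules:

- **Missing days break runs.** A day with no temperature record is never
  assumed hot; inventing exposure is worse than splitting a run.
- **Season clipping.** Only in-season days can qualify, so a hot spell
  straddling September 30 is automatically truncated at the boundary and
  qualifies only if its in-season part is long enough.

Runs of *any* length (including 1–2 days) are retained separately so that
district consolidation can annotate near-misses: when county events are
merged into district events (windows that overlap or exactly abut — a
one-day gap keeps them separate, matching how the district's historical
event table prints disjoint windows), any county whose longest overlapping
run is exactly one day short of qualifying is recorded as `near_threshold`,
mirroring the table's "reached threshold for 2 days" footnotes.

### Heat–drought overlap

`overlap_days` counts distinct calendar days covered by at least one heat
event inside a drought period (an explicit date window, or drought spells
expanded to 7 daily dates per week). Two policies are provided:

- `full_containment` (default): an event contributes only if *every* one of
  its days lies inside the period;
- `per_day`: each event contributes exactly the days it shares with the
  period.

The source assessment does not state which rule it used for its July–August
2012 worked figure; full containment of the printed 2012 windows in the
July 1 – August 31 window reproduces the published 33 days (26 + 3 + 4),
whereas per-day intersection does not, so full containment is the default
and the per-day variant is kept as an explicit option.

### Drought spells and flooding

Drought spells are maximal runs of consecutive weeks (week starts exactly
7 days apart; a gap in the weekly record splits a spell) at or above the
severity floor, with the peak category recorded. Flooding exposure is the
annual count of days with precipitation strictly over the threshold.
Streamflow-based flood detection and heat-index/humidity-adjusted heat
definitions are out of scope.

## Vulnerability tiers

Each indicator observation (county value plus optional state and national
reference values, all pre-normalized to comparable units) is classified:

- **high** — strictly worse than every available reference;
- **low** — strictly better than every available reference;
- **moderate** — otherwise (between the references, or tied with any);
- **unknown** — no reference available.

"Worse" follows the indicator's declared direction (`higher_is_worse` for
rates and concentrations; `lower_is_worse` for protective measures such as
air-conditioning access). Design choices:

- **Ties are moderate.** The tier wording ("fell short of both" /
  "improvement over both") reads as strict comparison; ties in continuous
  rates are rare, and moderate is the neutral assignment.
- **Single reference.** Worse than the sole reference → high. The district's
  own floodplain indicator is classified high from a state-only comparison,
  so a single-reference high must be possible.
- **Standards supplement, never replace.** Five indicators (fine-particulate
  exposure, obesity, heart-disease mortality, asthma hospitalizations,
  cerebrovascular deaths) also carry a federal standard/goal comparison
  (ties meet the standard). The shipped registry records the standard
  *sources* but leaves their numeric values as required configuration:
  goal values are revised over time and should be pinned by the operator,
  and comparing against an unset standard is a hard configuration error.
- The registry maps poverty to all three hazards. The source tables are
  internally inconsistent on this point (the indicator inventory lists
  heat/flood; the per-county results check poverty under drought as well);
  the drought mapping is retained because economic drought vulnerability of
  low-income populations is well supported and it keeps the published
  per-county matrix ingestible under the registry fan-out invariant.

## Hazard × indicator matrix

`build_matrix` fans each (indicator, county) tier out to exactly the
hazards the registry associates with the indicator. The headline
"high-vulnerability indicators per county" counts **distinct indicators**
flagged high under at least one hazard, not indicator–hazard checkmarks —
the only reading under which the published seven-county matrix yields its
stated six-to-eight range. The published matrix itself ships as a
transcribed long-form fixture (county, indicator, hazard triples) and is
used as a regression dataset independent of the classification code.

## Surveillance

Triggers: a heat alert on each day a run has accumulated ≥ `min_run_days`
qualifying days (so the first alert of an event fires on its third day);
a drought alert per county-week at ≥ D2; a flood alert per day over the
precipitation threshold. Alert days therefore coincide exactly with
detected heat-event days from the qualifying day onward — asserted as an
invariant.

Reportable-outcome matching normalizes codes (uppercase, decimal point
removed) and matches at the category level: a listed code matches itself
and any subdivision extending it ("X30.0"/"X300" match an X30 entry; "X3"
does not), since the shipped lists are category-level codes and category
listings conventionally include their subcodes. The heat set is matched
only inside the May–September window; flood codes match year-round. The
drought code set ships empty (outcomes in development) but remains
configurable. Malformed codes are rejected with a logged reason, never
silently dropped. ICD-10-CM morbidity equivalents for the ICD-9 lists are
left to configuration.

## Synthetic data

The generators emulate the study inputs with known embedded structure:

- **Weather** (`gen_weather`): per-county daily series; defaults emulate a
  rural Western-Kentucky summer (mean daily maximum 86 °F, day-to-day SD
  6 °F; rain on ~25 % of days, exponential magnitude with mean 0.4 in).
  Embedded heat runs set their days to threshold + offset; embedded heavy
  days set exact precipitation values. A spread of 0 is allowed so that
  construction-exact recovery tests exist; statistical tests are used when
  noise is on.
- **Drought** (`gen_drought`): weekly series on a 7-day grid; background
  weeks stay below D2; embedded spells ramp D2 → peak → D2 so the stated
  peak is always reached. Daily expansion happens downstream, not here.
- **Indicators** (`gen_indicator_table`): county values displaced from
  their references by a positive offset in the direction the embedded tier
  implies, so classification recovers the tier exactly (moderate uses the
  reference midpoint, which degenerates to a tie when references coincide —
  still moderate).
- **Claims** (`gen_claims`): independent per-county-day Poisson counts — a
  background process drawing distractor codes (never reportable) plus, on
  exposure days only, per-hazard excesses drawing from that hazard's
  reportable pool. No within-person correlation is modelled; surveillance
  matching only needs codes and dates.

What the generators do **not** emulate — and what passing tests therefore
do not show about real data: spatial correlation between counties or
stations, seasonality and autocorrelation of real temperature series,
station-to-county aggregation, coding error and miscoded claims,
reporting delays, and population denominators. Recovery results validate
the algorithms, not the measurement chain.

## Numerical and degenerate-input choices

- Date arithmetic is exact (`datetime.date`); no floating-point time.
- Threshold comparisons are `>=` for heat, `>` for precipitation, `>=` on
  the ordinal category scale for drought — all stated above and asserted
  by boundary tests.
- Empty series, empty tier sets, and empty matrices are valid inputs that
  yield empty outputs, not errors; unsorted or duplicate dates, unknown
  indicator ids, non-finite values, and malformed codes are errors.
- Simulation sizes used by the test suite and the acceptance script (200–
  400-day series, 300–1,000 random trials, 20-seed Poisson checks) were
  chosen to give exhaustive-oracle coverage and tight Monte-Carlo error at
  interactive runtimes.

## Limitations

- The published per-county matrix is ingested as outcomes; the raw
  prevalence values behind it are not published, so the package cannot
  re-derive (for example) why obesity is flagged only in two counties.
- No statistical validation, spatial analysis, composite indices, or
  mapping: classification is a deterministic comparison rule by design.
- "Outdoor workers", "homeless", and "stressed housing" are treated as
  opaque pre-computed rates; their upstream definitions live with their
  data sources.
- Multi-station-to-county consolidation of weather observations is not
  modelled; one series per county is assumed.
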