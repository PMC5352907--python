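"""The per-county hazard x indicator vulnerability matrix.

Each classified (indicator, county) tier is fanned out to exactly the
hazards the registry associates with that indicator, producing the
district's "high vulnerability by climate hazard" table.  Per-county
headline counts are *distinct indicators* flagged high under at least one
hazard, not indicator-hazard checkmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .classify import IndicatorRegistry, Tier, TierAssignment
from .errors import InputError
from .models import Hazard


@dataclass
class HazardIndicatorMatrix:
    counties: List[str]
    registry: IndicatorRegistry
    entries: Dict[Tuple[str, str, Hazard], Tier] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (county, indicator, hazard), tier in self.entries.items():
            if hazard not in self.registry.hazards_for(indicator):
                raise InputError(
                    f"entry ({county}, {indicator}, {hazard.value}) not permitted: "
                    f"registry does not map {indicator!r} to {hazard.value}"
                )
            if not isinstance(tier, Tier):
                raise InputError(f"invalid tier {tier!r}")

    def tier(self, county: str, indicator: str, hazard: Hazard) -> Optional[Tier]:
        return self.entries.get((county, indicator, hazard))

    def high_indicators(self, county: str) -> List[str]:
        """Distinct indicators high under at least one hazard, in registry
        order."""
        if county not in self.counties:
            raise InputError(f"unknown county {county!r}")
        flagged = {
            ind
            for (cty, ind, _), tier in self.entries.items()
            if cty == county and tier is Tier.HIGH
        }
        return [i for i in self.registry.ids if i in flagged]

    def to_long(self) -> pd.DataFrame:
        rows = [
            {"county": c, "indicator_id": i, "hazard": h.value, "tier": t.value}
            for (c, i, h), t in sorted(
                self.entries.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2].value)
            )
        ]
        return pd.DataFrame(rows, columns=["county", "indicator_id", "hazard", "tier"])


def build_matrix(
    tiers: Sequence[TierAssignment],
    registry: IndicatorRegistry,
    counties: Optional[Sequence[str]] = None,
) -> HazardIndicatorMatrix:
    """Fan classified tiers out to their registry hazards.

    ``counties`` fixes the matrix's county list (and ordering) so counties
    without any high entry still appear; by default the observed counties
    are used in first-seen order.
    """
    unknown = sorted({t.indicator_id for t in tiers if t.indicator_id not in registry})
    if unknown:
        raise InputError(f"tiers reference unknown indicator ids: {unknown}")
    if counties is None:
        seen: List[str] = []
        for t in tiers:
            if t.county not in seen:
                seen.append(t.county)
        counties = seen
    entries: Dict[Tuple[str, str, Hazard], Tier] = {}
    for t in tiers:
        for hazard in registry.hazards_for(t.indicator_id):
            entries[(t.county, t.indicator_id, hazard)] = t.tier
    return HazardIndicatorMatrix(counties=list(counties), registry=registry, entries=entries)


def matrix_from_long(
    frame: pd.DataFrame,
    registry: IndicatorRegistry,
    counties: Optional[Sequence[str]] = None,
) -> HazardIndicatorMatrix:
    """Ingest a long-form table ``county,indicator_id,hazard[,tier]``
    (tier defaults to high — the checkmark convention)."""
    entries: Dict[Tuple[str, str, Hazard], Tier] = {}
    for row in frame.itertuples(index=False):
        tier = Tier(getattr(row, "tier", "high")) if hasattr(row, "tier") else Tier.HIGH
        entries[(row.county, row.indicator_id, Hazard(row.hazard))] = tier
    if counties is None:
        counties = list(dict.fromkeys(frame["county"]))
    return HazardIndicatorMatrix(counties=list(counties), registry=registry, entries=entries)


def count_high(matrix: HazardIndicatorMatrix, county: str) -> int:
    """Distinct indicators flagged high for this county under >= 1 hazard."""
    return len(matrix.high_indicators(county))


def count_counties_flagged(
    matrix: HazardIndicatorMatrix, indicator: str, hazard: Hazard
) -> int:
    """Counties where (indicator, hazard) is flagged high."""
    if hazard not in matrix.registry.hazards_for(indicator):
        raise InputError(
            f"hazard {hazard.value!r} is not mapped to indicator {indicator!r}"
        )
    return sum(
        1
        for county in matrix.counties
        if matrix.entries.get((county, indicator, hazard)) is Tier.HIGH
    )


def summarize(matrix: HazardIndicatorMatrix) -> dict:
    """Deterministic summary: per-county distinct-high counts, per-indicator
    county counts per hazard, and the min/max county count."""
    per_county = {c: count_high(matrix, c) for c in matrix.counties}
    per_indicator: Dict[str, Dict[str, int]] = {}
    for ind in matrix.registry.ids:
        counts = {
            h.value: count_counties_flagged(matrix, ind, h)
            for h in matrix.registry.hazards_for(ind)
        }
        if any(counts.values()):
            per_indicator[ind] = counts
    counts = list(per_county.values())
    return {
        "per_county_high": per_county,
        "per_indicator_county_counts": per_indicator,
        "min_county_high": min(counts) if counts else 0,
        "max_county_high": max(counts) if counts else 0,
        "total_high_pairs": sum(counts),
    }
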