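"""Vulnerability tier classification of environmental public health
indicators.

A county's indicator value is compared against the parallel state and
national values.  The tier rule:

* **high** — strictly worse than every available reference,
* **low** — strictly better than every available reference,
* **moderate** — otherwise (between the references, or tied with one),
* **unknown** — no reference value available at all.

"Worse" follows each indicator's declared direction: for most rates and
concentrations higher is worse; for protective measures (e.g. air
conditioning access) lower is worse.  Values are assumed pre-normalized to
comparable units (percentage, rate per 10,000, ug/m3); no standardization is
performed here.

A handful of indicators are *additionally* compared with a federal standard
or goal value (EPA annual fine-particulate standard, Healthy People 2020
goals); the standard comparison supplements the state/national tier rather
than replacing it and both results are reported side by side.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

from pydantic import BaseModel, Field, field_validator

from .errors import ConfigurationError, InputError
from .models import Hazard


class Tier(str, enum.Enum):
    HIGH = "high"
    MODERATE = "moderate"
    LOW = "low"
    UNKNOWN = "unknown"


class Direction(str, enum.Enum):
    HIGHER_IS_WORSE = "higher_is_worse"
    LOWER_IS_WORSE = "lower_is_worse"


class StandardResult(str, enum.Enum):
    MEETS = "meets"
    FAILS = "fails"
    NOT_APPLICABLE = "not_applicable"


class IndicatorCategory(str, enum.Enum):
    ENVIRONMENTAL_EXPOSURE = "environmental_exposure"
    HEALTH_OUTCOME = "health_outcome"
    POPULATION_VULNERABILITY = "population_vulnerability"
    ENVIRONMENTAL_VULNERABILITY = "environmental_vulnerability"


class FederalStandard(BaseModel):
    """A federal standard/goal an indicator is benchmarked against.

    ``value`` is deliberately optional in the shipped registry: the standard
    source is fixed but the numeric value is a required configuration entry,
    and comparing against a standard whose value is unset is an error.
    """

    source: str
    value: Optional[float] = None


class IndicatorDefinition(BaseModel):
    id: str
    name: str
    category: IndicatorCategory
    hazards: List[Hazard] = Field(min_length=1)
    direction: Direction = Direction.HIGHER_IS_WORSE
    standard: Optional[FederalStandard] = None

    @field_validator("hazards")
    @classmethod
    def _unique(cls, v: List[Hazard]) -> List[Hazard]:
        if len(set(v)) != len(v):
            raise ConfigurationError("duplicate hazards in indicator definition")
        return v


class IndicatorObservation(BaseModel):
    indicator_id: str
    county: str
    county_value: float
    state_value: Optional[float] = None
    national_value: Optional[float] = None


@dataclass(frozen=True)
class TierAssignment:
    indicator_id: str
    county: str
    tier: Tier
    standard_result: StandardResult = StandardResult.NOT_APPLICABLE


class IndicatorRegistry:
    """Lookup of indicator definitions, preserving declaration order."""

    def __init__(self, definitions: Iterable[IndicatorDefinition]):
        self._defs: Dict[str, IndicatorDefinition] = {}
        for d in definitions:
            if d.id in self._defs:
                raise ConfigurationError(f"duplicate indicator id {d.id!r}")
            self._defs[d.id] = d

    def __contains__(self, indicator_id: str) -> bool:
        return indicator_id in self._defs

    def __getitem__(self, indicator_id: str) -> IndicatorDefinition:
        try:
            return self._defs[indicator_id]
        except KeyError:
            raise InputError(f"unknown indicator id {indicator_id!r}") from None

    def __iter__(self):
        return iter(self._defs.values())

    def __len__(self) -> int:
        return len(self._defs)

    @property
    def ids(self) -> List[str]:
        return list(self._defs)

    def hazards_for(self, indicator_id: str) -> List[Hazard]:
        return list(self[indicator_id].hazards)


def _is_worse(a: float, b: float, direction: Direction) -> bool:
    """Is value ``a`` strictly worse than ``b`` under ``direction``?"""
    if direction is Direction.HIGHER_IS_WORSE:
        return a > b
    return a < b


def classify_tier(obs: IndicatorObservation, defn: IndicatorDefinition) -> Tier:
    """Classify one county observation against its references.

    With two references: strictly worse than both -> high, strictly better
    than both -> low, anything else (in between, or tied with either) ->
    moderate.  With a single reference the same rule degenerates to
    worse -> high, better -> low, tie -> moderate.  No references -> unknown.
    """
    if obs.indicator_id != defn.id:
        raise InputError(
            f"observation for {obs.indicator_id!r} classified against {defn.id!r}"
        )
    if not math.isfinite(obs.county_value):
        raise InputError(f"non-finite county value for {obs.indicator_id!r}")
    refs = [v for v in (obs.state_value, obs.national_value) if v is not None]
    for v in refs:
        if not math.isfinite(v):
            raise InputError(f"non-finite reference value for {obs.indicator_id!r}")
    if not refs:
        return Tier.UNKNOWN
    if all(_is_worse(obs.county_value, r, defn.direction) for r in refs):
        return Tier.HIGH
    if all(_is_worse(r, obs.county_value, defn.direction) for r in refs):
        return Tier.LOW
    return Tier.MODERATE


def compare_to_standard(
    obs: IndicatorObservation, defn: IndicatorDefinition
) -> StandardResult:
    """Benchmark a county value against the indicator's federal standard.

    Ties meet the standard; an indicator without a configured standard is
    not applicable; a standard configured without a numeric value is a
    configuration error.
    """
    if defn.standard is None:
        return StandardResult.NOT_APPLICABLE
    if defn.standard.value is None:
        raise ConfigurationError(
            f"standard {defn.standard.source!r} for {defn.id!r} has no value configured"
        )
    if not math.isfinite(obs.county_value):
        raise InputError(f"non-finite county value for {obs.indicator_id!r}")
    if _is_worse(obs.county_value, defn.standard.value, defn.direction):
        return StandardResult.FAILS
    return StandardResult.MEETS


def classify_table(
    observations: Sequence[IndicatorObservation], registry: IndicatorRegistry
) -> List[TierAssignment]:
    """Classify a whole observation table; deterministic and
    order-independent (output sorted by county then indicator)."""
    unknown = sorted({o.indicator_id for o in observations if o.indicator_id not in registry})
    if unknown:
        raise InputError(f"observations reference unknown indicator ids: {unknown}")
    out: List[TierAssignment] = []
    for obs in observations:
        defn = registry[obs.indicator_id]
        tier = classify_tier(obs, defn)
        if defn.standard is not None and defn.standard.value is not None:
            std = compare_to_standard(obs, defn)
        else:
            std = StandardResult.NOT_APPLICABLE
        out.append(TierAssignment(obs.indicator_id, obs.county, tier, std))
    return sorted(out, key=lambda t: (t.county, t.indicator_id))
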