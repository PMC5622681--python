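"""Bundled, provenance-tagged reference data.

Ships as versioned JSON under ``proteinclaims/data/v1``:

* jurisdiction parameter sets (``jurisdictions/*.json``) — claim tiers,
  DV/NRV constants, energy units, each constant carrying a citation;
* reference amino acid scoring patterns (``patterns/*.json``) — the
  FAO/WHO 1991 preschool-child pattern is bundled, with its provenance
  marked (the values are transcribed reference data and swappable);
* a serving-basis registry for common food categories (RDI / RA / RACC
  with citations);
* the JSON Schema of the food-definition file format.

The registry is data, not code: adding a jurisdiction or food category is a
matter of adding a file or an entry, with no engine change.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field

from .claims import JurisdictionRules
from .composition import ScoringPattern
from .errors import UnknownFoodCategoryError, UnknownJurisdictionError

__all__ = [
    "DATA_VERSION",
    "Amount",
    "ServingRegistryEntry",
    "available_jurisdictions",
    "load_jurisdiction",
    "available_patterns",
    "load_scoring_pattern",
    "load_serving_registry",
    "lookup_serving",
]

DATA_VERSION = "v1"

_DEFAULT_PATTERN = "fao-who-1991-preschool"


def _data_root():
    return resources.files("proteinclaims") / "data" / DATA_VERSION


def _read_json(relative: str) -> dict:
    return json.loads((_data_root() / relative).read_text(encoding="utf-8"))


class Amount(BaseModel):
    model_config = ConfigDict(frozen=True)

    amount: float = Field(gt=0.0)
    unit: str
    note: str = ""
    companion: str = ""


class ServingRegistryEntry(BaseModel):
    """Regulated serving bases for one food category, with citations."""

    model_config = ConfigDict(frozen=True)

    food_category: str
    description: str = ""
    rdi: Optional[Amount] = None
    rdi_with_companion: Optional[Amount] = None
    ra: Optional[Amount] = None
    racc: Optional[Amount] = None
    source: str = Field(min_length=1)


def available_jurisdictions() -> list[str]:
    root = _data_root() / "jurisdictions"
    return sorted(p.name.removesuffix(".json")
                  for p in root.iterdir() if p.name.endswith(".json"))


def load_jurisdiction(jurisdiction_id: str) -> JurisdictionRules:
    """Load a bundled jurisdiction parameter set by id."""
    available = available_jurisdictions()
    if jurisdiction_id not in available:
        raise UnknownJurisdictionError(
            f"unknown jurisdiction {jurisdiction_id!r}; available: {available}")
    return JurisdictionRules.model_validate(
        _read_json(f"jurisdictions/{jurisdiction_id}.json"))


def available_patterns() -> list[str]:
    root = _data_root() / "patterns"
    return sorted(p.name.removesuffix(".json")
                  for p in root.iterdir() if p.name.endswith(".json"))


def load_scoring_pattern(name: str = _DEFAULT_PATTERN) -> ScoringPattern:
    """Load a bundled amino acid scoring pattern (default: FAO/WHO 1991,
    preschool children 2-5 y — the pattern regulatory PDCAAS prescribes)."""
    if name not in available_patterns():
        raise UnknownFoodCategoryError(
            f"unknown scoring pattern {name!r}; available: {available_patterns()}")
    return ScoringPattern.model_validate(_read_json(f"patterns/{name}.json"))


def load_serving_registry() -> list[ServingRegistryEntry]:
    """All bundled serving-basis entries."""
    payload = _read_json("serving_registry.json")
    return [ServingRegistryEntry.model_validate(e) for e in payload["entries"]]


def lookup_serving(food_category: str) -> ServingRegistryEntry:
    """Serving bases for one food category; raises on unknown categories."""
    for entry in load_serving_registry():
        if entry.food_category == food_category:
            return entry
    raise UnknownFoodCategoryError(
        f"unknown food category {food_category!r}; available: "
        f"{[e.food_category for e in load_serving_registry()]}")
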