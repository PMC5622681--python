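"""Domain model for foods, protein ingredients and serving bases.

A :class:`Food` is described by the protein density of the product
(``protein_per_100`` — g protein per 100 g for solids, per 100 mL for
liquids), the protein-contributing ingredients (each with an indispensable
amino acid profile in mg/g protein, a true fecal nitrogen digestibility and
its share of the food's protein), the regulated serving bases the various
claim frameworks reference (RDI, reference amount, RACC, label serving) and,
optionally, measured quality scores (PER, PDCAAS) that override computed
ones. Protein mass at any basis is always derived from ``protein_per_100``;
no per-basis protein is stored independently.

Food-definition files are versioned JSON (schema shipped in-package) with a
CSV flattening (one row per ingredient, food-level columns repeated).
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError,
    field_validator,
    model_validator,
)

from .errors import DefinitionParseError, FoodValidationError, MissingBasisError

__all__ = [
    "CANONICAL_AA",
    "AminoAcidProfile",
    "ScoringPattern",
    "IngredientProtein",
    "ServingBases",
    "CombinationDeclaration",
    "Food",
    "QualityResult",
    "BasisName",
    "SCHEMA_VERSION",
    "protein_at_basis",
    "read_food_definitions",
    "write_food_definitions",
    "food_definition_json_schema",
]

#: The nine scored indispensable amino acid classes, in canonical
#: (alphabetical) order. Methionine+cysteine and phenylalanine+tyrosine are
#: scored as pairs.
CANONICAL_AA: tuple[str, ...] = (
    "His",
    "Ile",
    "Leu",
    "Lys",
    "Met+Cys",
    "Phe+Tyr",
    "Thr",
    "Trp",
    "Val",
)

SCHEMA_VERSION = "1"

BasisName = Literal["rdi", "ra", "racc", "serving"]


def _check_aa_keys(content: dict, *, what: str) -> None:
    keys = set(content)
    canonical = set(CANONICAL_AA)
    if keys != canonical:
        missing = sorted(canonical - keys)
        extra = sorted(keys - canonical)
        parts = []
        if missing:
            parts.append(f"missing {missing}")
        if extra:
            parts.append(f"unexpected {extra}")
        raise ValueError(f"{what} must cover exactly the canonical amino acid "
                         f"classes {list(CANONICAL_AA)}: " + "; ".join(parts))


class AminoAcidProfile(BaseModel):
    """Indispensable amino acid content of a protein source, mg per g protein."""

    model_config = ConfigDict(frozen=True)

    content: dict[str, float]

    @field_validator("content")
    @classmethod
    def _validate_content(cls, v: dict[str, float]) -> dict[str, float]:
        _check_aa_keys(v, what="amino acid profile")
        for k, x in v.items():
            if not math.isfinite(x) or x < 0:
                raise ValueError(f"amino acid content for {k} must be finite and >= 0, got {x}")
        return {k: float(v[k]) for k in CANONICAL_AA}


class ScoringPattern(BaseModel):
    """Reference amino acid requirements of a scoring population, mg/g protein."""

    model_config = ConfigDict(frozen=True)

    population_label: str
    requirement: dict[str, float]
    provenance: str = ""

    @field_validator("requirement")
    @classmethod
    def _validate_requirement(cls, v: dict[str, float]) -> dict[str, float]:
        _check_aa_keys(v, what="scoring pattern")
        for k, x in v.items():
            if not math.isfinite(x) or x <= 0:
                raise ValueError(f"requirement for {k} must be finite and > 0, got {x}")
        return {k: float(v[k]) for k in CANONICAL_AA}


class IngredientProtein(BaseModel):
    """One protein source within a food.

    ``digestibility`` is true fecal nitrogen digestibility as a fraction in
    (0, 1]; ``protein_share`` is this ingredient's fraction of the food's
    total protein (shares across a food must sum to 1).
    """

    model_config = ConfigDict(frozen=True)

    name: str
    profile: AminoAcidProfile
    digestibility: float = Field(gt=0.0, le=1.0)
    protein_share: float = Field(ge=0.0, le=1.0)


class ServingBases(BaseModel):
    """Regulated serving bases, in g (solids) or mL (liquids).

    ``rdi``: Canadian Reasonable Daily Intake; ``ra``: Canadian reference
    amount; ``racc``: USA reference amount customarily consumed; ``serving``:
    label serving. At least one basis must be present.
    """

    model_config = ConfigDict(frozen=True)

    rdi: Optional[float] = Field(default=None, gt=0.0)
    ra: Optional[float] = Field(default=None, gt=0.0)
    racc: Optional[float] = Field(default=None, gt=0.0)
    serving: Optional[float] = Field(default=None, gt=0.0)
    unit_kind: Literal["mass-g", "volume-mL"] = "mass-g"

    @model_validator(mode="after")
    def _at_least_one(self) -> "ServingBases":
        if all(getattr(self, b) is None for b in ("rdi", "ra", "racc", "serving")):
            raise ValueError("at least one serving basis (rdi/ra/racc/serving) must be present")
        return self


class CombinationDeclaration(BaseModel):
    """Declares that this food is traditionally consumed with a companion.

    The only combination rule in Canadian regulation is breakfast cereal with
    125 mL milk, under which the cereal's RDI switches (28 g -> 30 g); that
    switched RDI is declared here as ``rdi_combined``.
    """

    model_config = ConfigDict(frozen=True)

    companion_name: str
    rdi_combined: Optional[float] = Field(default=None, gt=0.0)


class Food(BaseModel):
    """A food product, its protein composition and serving bases."""

    model_config = ConfigDict(frozen=True)

    name: str
    ingredients: tuple[IngredientProtein, ...] = ()
    protein_per_100: float = Field(ge=0.0)
    energy_per_serving: Optional[float] = Field(default=None, ge=0.0)
    state: Literal["solid", "liquid"] = "solid"
    bases: ServingBases
    measured_per: Optional[float] = Field(default=None, ge=0.0)
    measured_pdcaas: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    combination: Optional[CombinationDeclaration] = None

    @model_validator(mode="after")
    def _shares_sum_to_one(self) -> "Food":
        if self.ingredients:
            total = sum(i.protein_share for i in self.ingredients)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"ingredient protein shares must sum to 1 (got {total!r})")
        return self

    @model_validator(mode="after")
    def _unit_matches_state(self) -> "Food":
        expected = "volume-mL" if self.state == "liquid" else "mass-g"
        if self.bases.unit_kind != expected:
            raise ValueError(
                f"{self.state} food must use {expected} serving bases, "
                f"got {self.bases.unit_kind}")
        return self


class QualityResult(BaseModel):
    """Outcome of a PDCAAS computation.

    ``raw_score`` is the untruncated digestibility-corrected amino acid
    score; ``pdcaas`` is the score truncated at 1. ``tied`` lists every
    amino acid attaining the minimum ratio when there is a tie (the reported
    ``limiting_aa`` is the first in canonical order).
    """

    model_config = ConfigDict(frozen=True)

    method_variant: Literal["single", "multi-1991", "multi-2007"]
    raw_score: float = Field(ge=0.0)
    pdcaas: float = Field(ge=0.0, le=1.0)
    limiting_aa: str
    digestibility_used: float = Field(gt=0.0, le=1.0)
    tied: tuple[str, ...] = ()

    @model_validator(mode="after")
    def _truncation(self) -> "QualityResult":
        if abs(self.pdcaas - min(self.raw_score, 1.0)) > 1e-12:
            raise ValueError("pdcaas must equal min(raw_score, 1)")
        return self


# ---------------------------------------------------------------------------
# basis arithmetic

def protein_at_basis(food: Food, basis: BasisName) -> float:
    """Grams of protein in the requested serving basis of ``food``.

    Computed as ``protein_per_100 * basis_amount / 100`` — the food's stored
    protein density is the single source of truth. Raises
    :class:`MissingBasisError` if the basis is absent (no silent fallback).
    """
    if basis not in ("rdi", "ra", "racc", "serving"):
        raise ValueError(f"unknown basis {basis!r}")
    amount = getattr(food.bases, basis)
    if amount is None:
        raise MissingBasisError(
            f"food {food.name!r} has no {basis.upper()} basis declared")
    return food.protein_per_100 * amount / 100.0


# ---------------------------------------------------------------------------
# food definition files

class FoodDefinitionFile(BaseModel):
    """Top-level structure of a JSON food-definition file."""

    model_config = ConfigDict(frozen=True)

    schema_version: str = SCHEMA_VERSION
    foods: tuple[Food, ...] = ()


def food_definition_json_schema() -> dict:
    """JSON Schema for the food-definition file format (machine-generated)."""
    return FoodDefinitionFile.model_json_schema()


_CSV_FOOD_COLUMNS = [
    "food_name", "state", "protein_per_100", "energy_per_serving",
    "rdi", "ra", "racc", "serving", "unit_kind",
    "measured_per", "measured_pdcaas", "companion_name", "rdi_combined",
]
_CSV_ING_COLUMNS = ["ingredient_name", "digestibility", "protein_share"]
_CSV_AA_COLUMNS = [f"aa_{k}" for k in CANONICAL_AA]
CSV_COLUMNS = _CSV_FOOD_COLUMNS + _CSV_ING_COLUMNS + _CSV_AA_COLUMNS


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    return "csv" if path.suffix.lower() == ".csv" else "json"


def read_food_definitions(path, format: Optional[str] = None) -> list[Food]:
    """Read and validate a food-definition file (JSON or CSV).

    Raises :class:`DefinitionParseError` for malformed files and
    :class:`FoodValidationError` (naming the food and the violated rule)
    for invariant violations.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        return _read_json(path)
    if fmt == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown format {fmt!r}")


def _validate_food(raw: dict, *, where: str) -> Food:
    try:
        return Food.model_validate(raw)
    except ValidationError as exc:
        name = raw.get("name", "<unnamed>") if isinstance(raw, dict) else "<unnamed>"
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise FoodValidationError(
            f"{where}: food {name!r} failed validation at {loc or '<root>'}: "
            f"{first['msg']}") from exc


def _read_json(path: Path) -> list[Food]:
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise DefinitionParseError(
            f"{path}: invalid JSON at line {exc.lineno}, column {exc.colno}: "
            f"{exc.msg}") from exc
    if not isinstance(payload, dict) or "foods" not in payload:
        raise DefinitionParseError(
            f"{path}: expected an object with a 'foods' array")
    version = str(payload.get("schema_version", ""))
    if version != SCHEMA_VERSION:
        raise DefinitionParseError(
            f"{path}: unsupported schema_version {version!r} "
            f"(expected {SCHEMA_VERSION!r})")
    return [_validate_food(raw, where=str(path)) for raw in payload["foods"]]


def write_food_definitions(foods: Sequence[Food], path, format: Optional[str] = None) -> None:
    """Write foods to a JSON or CSV definition file (UTF-8, RFC 4180 CSV)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        doc = FoodDefinitionFile(schema_version=SCHEMA_VERSION, foods=tuple(foods))
        path.write_text(
            json.dumps(doc.model_dump(mode="json"), indent=2, sort_keys=False) + "\n",
            encoding="utf-8")
    elif fmt == "csv":
        _write_csv(foods, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _num(x) -> str:
    return "" if x is None else repr(float(x))


def _write_csv(foods: Iterable[Food], path: Path) -> None:
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for food in foods:
            combo = food.combination
            food_cells = [
                food.name, food.state, _num(food.protein_per_100),
                _num(food.energy_per_serving),
                _num(food.bases.rdi), _num(food.bases.ra),
                _num(food.bases.racc), _num(food.bases.serving),
                food.bases.unit_kind,
                _num(food.measured_per), _num(food.measured_pdcaas),
                combo.companion_name if combo else "",
                _num(combo.rdi_combined) if combo else "",
            ]
            if not food.ingredients:
                writer.writerow(food_cells + [""] * (len(_CSV_ING_COLUMNS) + len(_CSV_AA_COLUMNS)))
                continue
            for ing in food.ingredients:
                writer.writerow(
                    food_cells
                    + [ing.name, _num(ing.digestibility), _num(ing.protein_share)]
                    + [_num(ing.profile.content[k]) for k in CANONICAL_AA])


def _opt_float(cell: str, *, where: str, column: str):
    cell = cell.strip()
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError as exc:
        raise DefinitionParseError(
            f"{where}: column {column!r}: not a number: {cell!r}") from exc


def _read_csv(path: Path) -> list[Food]:
    with path.open("r", newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DefinitionParseError(f"{path}: empty CSV file") from None
        if header != CSV_COLUMNS:
            raise DefinitionParseError(
                f"{path}: unexpected CSV header; expected columns {CSV_COLUMNS}")
        rows = [(lineno, row) for lineno, row in enumerate(reader, start=2) if any(row)]

    grouped: dict[str, list[tuple[int, list[str]]]] = {}
    order: list[str] = []
    for lineno, row in rows:
        if len(row) != len(CSV_COLUMNS):
            raise DefinitionParseError(
                f"{path}: line {lineno}: expected {len(CSV_COLUMNS)} cells, got {len(row)}")
        name = row[0]
        if name not in grouped:
            grouped[name] = []
            order.append(name)
        grouped[name].append((lineno, row))

    foods = []
    for name in order:
        food_rows = grouped[name]
        lineno, first = food_rows[0]
        where = f"{path}: line {lineno}"
        cell = dict(zip(CSV_COLUMNS, first))
        for ln, row in food_rows[1:]:
            if row[: len(_CSV_FOOD_COLUMNS)] != first[: len(_CSV_FOOD_COLUMNS)]:
                raise DefinitionParseError(
                    f"{path}: line {ln}: food-level columns differ across the "
                    f"ingredient rows of food {name!r}")
        ingredients = []
        for ln, row in food_rows:
            rcell = dict(zip(CSV_COLUMNS, row))
            if rcell["ingredient_name"].strip() == "":
                continue
            profile = {
                k: _opt_float(rcell[f"aa_{k}"], where=f"{path}: line {ln}", column=f"aa_{k}")
                for k in CANONICAL_AA
            }
            if any(v is None for v in profile.values()):
                missing = [k for k, v in profile.items() if v is None]
                raise DefinitionParseError(
                    f"{path}: line {ln}: ingredient {rcell['ingredient_name']!r} "
                    f"is missing amino acid columns {missing}")
            ingredients.append({
                "name": rcell["ingredient_name"],
                "profile": {"content": profile},
                "digestibility": _opt_float(rcell["digestibility"], where=where,
                                            column="digestibility"),
                "protein_share": _opt_float(rcell["protein_share"], where=where,
                                            column="protein_share"),
            })
        combo = None
        if cell["companion_name"].strip():
            combo = {
                "companion_name": cell["companion_name"],
                "rdi_combined": _opt_float(cell["rdi_combined"], where=where,
                                           column="rdi_combined"),
            }
        raw = {
            "name": name,
            "state": cell["state"],
            "protein_per_100": _opt_float(cell["protein_per_100"], where=where,
                                          column="protein_per_100"),
            "energy_per_serving": _opt_float(cell["energy_per_serving"], where=where,
                                             column="energy_per_serving"),
            "bases": {
                "rdi": _opt_float(cell["rdi"], where=where, column="rdi"),
                "ra": _opt_float(cell["ra"], where=where, column="ra"),
                "racc": _opt_float(cell["racc"], where=where, column="racc"),
                "serving": _opt_float(cell["serving"], where=where, column="serving"),
                "unit_kind": cell["unit_kind"],
            },
            "measured_per": _opt_float(cell["measured_per"], where=where,
                                       column="measured_per"),
            "measured_pdcaas": _opt_float(cell["measured_pdcaas"], where=where,
                                          column="measured_pdcaas"),
            "ingredients": ingredients,
            "combination": combo,
        }
        foods.append(_validate_food(raw, where=str(path)))
    return foods
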