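"""Protein content claim evaluation across regulatory jurisdictions.

Each jurisdiction is described by a :class:`JurisdictionRules` parameter set
(bundled as JSON, user-overridable) naming the metric it compares
(protein rating, grams of protein, %DV of PDCAAS-corrected protein, percent
of energy from protein, or percent-of-NRV routes), the serving basis it uses,
and its ordered claim tiers with inclusive (>=) thresholds. Evaluation
returns a :class:`ClaimResult` carrying the awarded tier, the metric value,
and a replayable calculation trace.

Two display conventions are supported: by default all comparisons are made
on unrounded values; with ``paper_rounding=True`` grams-at-basis and each
food's metric component are rounded half-up to one decimal before use, which
reproduces how regulatory worked examples compare printed 1-decimal numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .composition import BasisName, Food, protein_at_basis
from .errors import (
    MissingBasisError,
    MissingDataError,
    UnsupportedPopulationError,
)
from .rounding import round_half_up
from .scoring import (
    CASEIN_PER,
    KCAL_PER_G_PROTEIN,
    pdcaas_multi,
    per_from_pdcaas,
)

__all__ = [
    "TierRule",
    "Constant",
    "JurisdictionRules",
    "TraceStep",
    "ClaimResult",
    "TIER_RANK",
    "replay_trace",
    "evaluate",
    "evaluate_canada_current",
    "evaluate_canada_option1",
    "evaluate_canada_option2",
    "evaluate_usa",
    "evaluate_eu",
    "evaluate_anz",
    "evaluate_nrv_family",
    "evaluate_all",
]

KJ_PER_KCAL = 4.184

#: Ordering of claim tiers for monotonicity comparisons. "source" and
#: "general" are entry tiers; "high-source" and "excellent-source" are the
#: top tier under different naming traditions.
TIER_RANK = {
    "none": 0,
    "source": 1,
    "general": 1,
    "good-source": 2,
    "excellent-source": 3,
    "high-source": 3,
}


class TierRule(BaseModel):
    model_config = ConfigDict(frozen=True)

    tier: str
    threshold: float = Field(gt=0.0)
    citation: str = ""


class Constant(BaseModel):
    model_config = ConfigDict(frozen=True)

    value: float | str
    citation: str


class JurisdictionRules(BaseModel):
    """Parameter set for one jurisdiction's protein claim rules."""

    model_config = ConfigDict(frozen=True)

    jurisdiction_id: str
    name: str
    metric: Literal[
        "protein-rating", "grams-per-basis", "percent-dv",
        "percent-energy", "nrv-routes",
    ]
    basis: Optional[BasisName] = None
    basis_fallback: Optional[BasisName] = None
    tiers: tuple[TierRule, ...]
    constants: dict[str, Constant] = {}
    notes: str = ""
    citation: str = ""

    @model_validator(mode="after")
    def _tiers_ascending(self) -> "JurisdictionRules":
        if not self.tiers:
            raise ValueError("at least one claim tier is required")
        thresholds = [t.threshold for t in self.tiers]
        if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
            raise ValueError("tiers must be ordered by strictly ascending threshold")
        return self

    def constant(self, name: str) -> float | str:
        return self.constants[name].value


@dataclass(frozen=True)
class TraceStep:
    """One step of a claim calculation.

    ``op`` is one of ``value`` (a given quantity), ``mul``/``add``/``div``
    (arithmetic on ``operands``) or ``note`` (non-numeric commentary).
    Numeric steps can be replayed to re-derive ``value``.
    """

    label: str
    op: str = "note"
    operands: tuple[float, ...] = ()
    value: Optional[float] = None

    def replay(self) -> Optional[float]:
        if self.op == "note":
            return None
        if self.op == "value":
            return self.value
        if self.op == "mul":
            return math.prod(self.operands)
        if self.op == "add":
            return sum(self.operands)
        if self.op == "div":
            a, b = self.operands
            return a / b
        raise ValueError(f"unknown trace op {self.op!r}")

    def __str__(self) -> str:
        if self.op == "note":
            return self.label
        sym = {"mul": " x ", "add": " + ", "div": " / "}.get(self.op)
        if sym is None:
            return f"{self.label} = {self.value:g}"
        expr = sym.join(f"{x:g}" for x in self.operands)
        return f"{self.label} = {expr} = {self.value:g}"


@dataclass(frozen=True)
class ClaimResult:
    """Outcome of evaluating one food (or combination) in one jurisdiction."""

    jurisdiction_id: str
    tier: str
    metric_value: Optional[float]
    basis_used: str
    threshold_applied: Optional[float]
    trace: tuple[TraceStep, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "jurisdiction_id": self.jurisdiction_id,
            "tier": self.tier,
            "metric_value": self.metric_value,
            "basis_used": self.basis_used,
            "threshold_applied": self.threshold_applied,
            "trace": [
                {"label": s.label, "op": s.op, "operands": list(s.operands),
                 "value": s.value, "text": str(s)}
                for s in self.trace
            ],
        }


def replay_trace(trace: Sequence[TraceStep], rtol: float = 1e-9) -> Optional[float]:
    """Recompute every numeric step of a trace and return the final value.

    Raises ``ValueError`` if any step's recorded value disagrees with its
    recomputation — used to audit that traces are complete and faithful.
    """
    last = None
    for step in trace:
        got = step.replay()
        if got is None:
            continue
        if step.value is None or abs(got - step.value) > rtol * max(1.0, abs(step.value)):
            raise ValueError(f"trace step {step.label!r} does not replay: "
                             f"recorded {step.value!r}, recomputed {got!r}")
        last = got
    return last


# ---------------------------------------------------------------------------
# shared helpers

def _maybe_round(x: float, paper_rounding: bool, ndigits: int = 1) -> float:
    return round_half_up(x, ndigits) if paper_rounding else x


def _grams_at(food: Food, basis: BasisName, paper_rounding: bool,
              trace: list[TraceStep]) -> float:
    amount = getattr(food.bases, basis)
    grams = protein_at_basis(food, basis)
    grams = _maybe_round(grams, paper_rounding)
    trace.append(TraceStep(
        label=f"protein of {food.name!r} per {basis.upper()} "
              f"({amount:g} {'mL' if food.state == 'liquid' else 'g'})",
        op="mul", operands=(food.protein_per_100, amount / 100.0), value=grams
        if not paper_rounding else None))
    if paper_rounding:
        # the mul step above cannot carry the rounded value; restate it
        trace[-1] = TraceStep(
            label=f"protein of {food.name!r} per {basis.upper()} ({amount:g} "
                  f"{'mL' if food.state == 'liquid' else 'g'}, displayed to 1 decimal)",
            op="value", value=grams)
    return grams


def _pdcaas_of(food: Food, pattern, variant: str, trace: list[TraceStep]) -> float:
    if food.measured_pdcaas is not None:
        trace.append(TraceStep(label=f"PDCAAS of {food.name!r} (measured)",
                               op="value", value=food.measured_pdcaas))
        return food.measured_pdcaas
    if food.ingredients:
        if pattern is None:
            from .registry import load_scoring_pattern
            pattern = load_scoring_pattern()
        result = pdcaas_multi(food.ingredients, pattern, variant=variant)
        trace.append(TraceStep(
            label=f"PDCAAS of {food.name!r} (computed, {result.method_variant}, "
                  f"limiting {result.limiting_aa})",
            op="value", value=result.pdcaas))
        return result.pdcaas
    raise MissingDataError(
        f"food {food.name!r} needs a quality score: no measured PDCAAS and "
        f"no ingredient profiles to compute one")


def _per_of(food: Food, pattern, variant: str, trace: list[TraceStep]) -> float:
    if food.measured_per is not None:
        trace.append(TraceStep(label=f"PER of {food.name!r} (measured)",
                               op="value", value=food.measured_per))
        return food.measured_per
    pdcaas = _pdcaas_of(food, pattern, variant, trace)
    per = per_from_pdcaas(pdcaas)
    trace.append(TraceStep(label=f"PER of {food.name!r} = PDCAAS x {CASEIN_PER}",
                           op="mul", operands=(pdcaas, CASEIN_PER), value=per))
    return per


def _award(rules: JurisdictionRules, metric: float, basis_used: str,
           trace: list[TraceStep], paper_rounding: bool,
           threshold_scale: float = 1.0) -> ClaimResult:
    compared = _maybe_round(metric, paper_rounding)
    tier_name = "none"
    threshold = rules.tiers[0].threshold * threshold_scale
    for rule in reversed(rules.tiers):
        if compared >= rule.threshold * threshold_scale:
            tier_name = rule.tier
            threshold = rule.threshold * threshold_scale
            break
    trace.append(TraceStep(
        label=f"compare {compared:g} against {rules.jurisdiction_id} thresholds "
              f"({', '.join(f'{t.tier} >= {t.threshold * threshold_scale:g}' for t in rules.tiers)})"
              f" -> {tier_name}"))
    return ClaimResult(
        jurisdiction_id=rules.jurisdiction_id,
        tier=tier_name,
        metric_value=compared,
        basis_used=basis_used,
        threshold_applied=threshold,
        trace=tuple(trace),
    )


def _load(jurisdiction_id: str, rules: Optional[JurisdictionRules]) -> JurisdictionRules:
    if rules is not None:
        return rules
    from .registry import load_jurisdiction
    return load_jurisdiction(jurisdiction_id)


def _rating_basis(food: Food, trace: list[TraceStep],
                  rdi_override: Optional[float] = None) -> tuple[Food, BasisName]:
    """RDI basis for a protein rating, falling back to the RA when absent."""
    if rdi_override is not None:
        food = food.model_copy(
            update={"bases": food.bases.model_copy(update={"rdi": rdi_override})})
        trace.append(TraceStep(
            label=f"RDI of {food.name!r} switched to {rdi_override:g} "
                  f"(combined-consumption RDI)"))
        return food, "rdi"
    if food.bases.rdi is not None:
        return food, "rdi"
    if food.bases.ra is not None:
        trace.append(TraceStep(
            label=f"no RDI exists for {food.name!r}; using the reference amount "
                  f"({food.bases.ra:g}) in its place"))
        return food, "ra"
    raise MissingBasisError(
        f"food {food.name!r} has neither an RDI nor a reference amount")


# ---------------------------------------------------------------------------
# jurisdiction evaluators

def evaluate_canada_current(food: Food, companion: Optional[Food] = None, *,
                            pattern=None, variant: str = "1991",
                            paper_rounding: bool = False,
                            rules: Optional[JurisdictionRules] = None) -> ClaimResult:
    """Current Canadian framework: protein rating (PER x g protein per RDI).

    A declared companion (breakfast cereal + 125 mL milk) contributes its own
    rating; the food's RDI switches to its declared combined-consumption RDI.
    """
    rules = _load("canada-current", rules)
    trace: list[TraceStep] = []

    def one_rating(f: Food, rdi_override: Optional[float]) -> float:
        f, basis = _rating_basis(f, trace, rdi_override)
        grams = _grams_at(f, basis, paper_rounding, trace)
        per = _per_of(f, pattern, variant, trace)
        rating = _maybe_round(per * grams, paper_rounding)
        trace.append(TraceStep(label=f"protein rating of {f.name!r}",
                               op="mul", operands=(per, grams),
                               value=per * grams))
        if paper_rounding:
            trace.append(TraceStep(label=f"protein rating of {f.name!r} (1 decimal)",
                                   op="value", value=rating))
        return rating

    rdi_override = None
    if companion is not None and food.combination is not None \
            and food.combination.companion_name == companion.name:
        rdi_override = food.combination.rdi_combined

    total = one_rating(food, rdi_override)
    basis_used = "rdi"
    if companion is not None:
        companion_rating = one_rating(companion, None)
        combined = total + companion_rating
        trace.append(TraceStep(label="total protein rating (food + companion)",
                               op="add", operands=(total, companion_rating),
                               value=combined))
        total = combined
        basis_used = "rdi (combined)"
    return _award(rules, total, basis_used, trace, paper_rounding)


def evaluate_canada_option1(food: Food, companion: Optional[Food] = None, *,
                            paper_rounding: bool = False,
                            rules: Optional[JurisdictionRules] = None) -> ClaimResult:
    """Proposed Option 1: absolute grams of protein per reference amount."""
    rules = _load("canada-option1", rules)
    trace: list[TraceStep] = []
    if food.bases.ra is None:
        raise MissingBasisError(f"food {food.name!r} has no reference amount")
    total = _grams_at(food, "ra", paper_rounding, trace)
    if companion is not None:
        if companion.bases.ra is None:
            raise MissingBasisError(f"food {companion.name!r} has no reference amount")
        companion_grams = _grams_at(companion, "ra", paper_rounding, trace)
        combined = total + companion_grams
        trace.append(TraceStep(label="total protein per RA (food + companion)",
                               op="add", operands=(total, companion_grams),
                               value=combined))
        total = combined
    return _award(rules, total, "ra", trace, paper_rounding)


def evaluate_canada_option2(food: Food, companion: Optional[Food] = None,
                            dv_g: Optional[float] = None, *,
                            pattern=None, variant: str = "1991",
                            paper_rounding: bool = False,
                            rules: Optional[JurisdictionRules] = None) -> ClaimResult:
    """Proposed Option 2: %DV of PDCAAS-corrected protein per reference amount."""
    rules = _load("canada-option2", rules)
    if dv_g is None:
        dv_g = float(rules.constant("dv_g"))
    trace: list[TraceStep] = []

    def corrected(f: Food) -> float:
        if f.bases.ra is None:
            raise MissingBasisError(f"food {f.name!r} has no reference amount")
        grams = _grams_at(f, "ra", paper_rounding, trace)
        pdcaas = _pdcaas_of(f, pattern, variant, trace)
        value = pdcaas * grams
        trace.append(TraceStep(label=f"corrected protein of {f.name!r} per RA",
                               op="mul", operands=(pdcaas, grams), value=value))
        return value

    total = corrected(food)
    if companion is not None:
        companion_corrected = corrected(companion)
        combined = total + companion_corrected
        trace.append(TraceStep(label="total corrected protein (food + companion)",
                               op="add", operands=(total, companion_corrected),
                               value=combined))
        total = combined
    percent_dv = total / dv_g * 100.0
    trace.append(TraceStep(label=f"%DV of corrected protein (DV {dv_g:g} g)",
                           op="mul", operands=(total / dv_g, 100.0),
                           value=percent_dv))
    return _award(rules, percent_dv, "ra", trace, paper_rounding)


def evaluate_usa(food: Food, age_group: str = "4y-adult", *,
                 pattern=None, variant: str = "1991",
                 paper_rounding: bool = False,
                 rules: Optional[JurisdictionRules] = None) -> ClaimResult:
    """USA framework: %DV of PDCAAS-corrected protein per RACC."""
    rules = _load("usa", rules)
    if age_group == "infant":
        raise UnsupportedPopulationError(
            "infant foods (<= 12 months) require the in vivo PER bioassay and "
            "are not evaluated by this engine")
    if age_group not in ("1-3y", "4y-adult"):
        raise ValueError(f"age_group must be '1-3y' or '4y-adult', got {age_group!r}")
    dv_g = float(rules.constant("dv_g_children_1_3" if age_group == "1-3y" else "dv_g"))
    trace: list[TraceStep] = []
    if food.bases.racc is None:
        raise MissingBasisError(f"food {food.name!r} has no RACC")
    grams = _grams_at(food, "racc", paper_rounding, trace)
    pdcaas = _pdcaas_of(food, pattern, variant, trace)
    corrected = pdcaas * grams
    trace.append(TraceStep(label=f"corrected protein of {food.name!r} per RACC",
                           op="mul", operands=(pdcaas, grams), value=corrected))
    percent_dv = corrected / dv_g * 100.0
    trace.append(TraceStep(label=f"%DV of corrected protein (DV {dv_g:g} g, {age_group})",
                           op="mul", operands=(corrected / dv_g, 100.0),
                           value=percent_dv))
    return _award(rules, percent_dv, "racc", trace, paper_rounding)


def evaluate_eu(food: Food, *, paper_rounding: bool = False,
                rules: Optional[JurisdictionRules] = None) -> ClaimResult:
    """EU framework: percent of the serving's energy provided by protein."""
    rules = _load("eu", rules)
    trace: list[TraceStep] = []
    if food.bases.serving is None:
        raise MissingBasisError(f"food {food.name!r} has no label serving declared")
    if food.energy_per_serving is None or food.energy_per_serving <= 0:
        raise MissingDataError(
            f"food {food.name!r} has no (positive) energy per serving; the EU "
            f"rule compares percent of energy from protein")
    kcal_per_g = float(rules.constant("kcal_per_g_protein"))
    grams = _grams_at(food, "serving", paper_rounding, trace)
    protein_kcal = grams * kcal_per_g
    trace.append(TraceStep(label=f"energy from protein ({kcal_per_g:g} kcal/g)",
                           op="mul", operands=(grams, kcal_per_g), value=protein_kcal))
    percent = protein_kcal / food.energy_per_serving * 100.0
    trace.append(TraceStep(
        label=f"percent of serving energy ({food.energy_per_serving:g} kcal) from protein",
        op="mul", operands=(protein_kcal / food.energy_per_serving, 100.0),
        value=percent))
    return _award(rules, percent, "serving", trace, paper_rounding)


def evaluate_anz(food: Food, *, paper_rounding: bool = False,
                 rules: Optional[JurisdictionRules] = None) -> ClaimResult:
    """Australia/New Zealand framework: grams of protein per serving."""
    rules = _load("anz", rules)
    trace: list[TraceStep] = []
    if food.bases.serving is None:
        raise MissingBasisError(f"food {food.name!r} has no label serving declared")
    grams = _grams_at(food, "serving", paper_rounding, trace)
    return _award(rules, grams, "serving", trace, paper_rounding)


def evaluate_nrv_family(food: Food, region: str = "codex", *,
                        paper_rounding: bool = False,
                        rules: Optional[JurisdictionRules] = None) -> ClaimResult:
    """Codex/China/South-Korea framework: percent of the protein NRV by route.

    Every applicable route is evaluated (per 100 g for solids, per 100 mL for
    liquids, per 100 kcal or 420 kJ, per serving where the region allows); a
    food is a source if ANY route meets its threshold and a high source if
    any route meets twice its threshold. All routes appear in the trace.
    """
    rules = _load(region, rules)
    nrv = float(rules.constant("nrv_g"))
    trace: list[TraceStep] = [TraceStep(label=f"protein NRV: {nrv:g} g/day")]
    routes: list[tuple[str, float, float]] = []  # (route, pct of NRV, source threshold)

    if food.state == "solid":
        pct = food.protein_per_100 / nrv * 100.0
        trace.append(TraceStep(label="route per-100g: %NRV per 100 g",
                               op="mul", operands=(food.protein_per_100 / nrv, 100.0),
                               value=pct))
        routes.append(("per-100g", pct, float(rules.constant("per_100g_pct"))))
    else:
        pct = food.protein_per_100 / nrv * 100.0
        trace.append(TraceStep(label="route per-100mL: %NRV per 100 mL",
                               op="mul", operands=(food.protein_per_100 / nrv, 100.0),
                               value=pct))
        routes.append(("per-100mL", pct, float(rules.constant("per_100ml_pct"))))

    if food.energy_per_serving and food.bases.serving:
        energy_per_100 = food.energy_per_serving / food.bases.serving * 100.0
        unit = str(rules.constant("energy_unit"))
        if unit == "kJ-420":
            protein_per_unit = food.protein_per_100 / (energy_per_100 * KJ_PER_KCAL) * 420.0
            route_label = "per-420kJ"
        else:
            protein_per_unit = food.protein_per_100 / energy_per_100 * 100.0
            route_label = "per-100kcal"
        pct = protein_per_unit / nrv * 100.0
        trace.append(TraceStep(label=f"route {route_label}: %NRV per energy unit",
                               op="mul", operands=(protein_per_unit / nrv, 100.0),
                               value=pct))
        routes.append((route_label, pct, float(rules.constant("per_energy_pct"))))

    if "per_serving_pct" in rules.constants and food.bases.serving:
        grams = protein_at_basis(food, "serving")
        pct = grams / nrv * 100.0
        trace.append(TraceStep(label="route per-serving: %NRV per serving",
                               op="mul", operands=(grams / nrv, 100.0), value=pct))
        routes.append(("per-serving", pct, float(rules.constant("per_serving_pct"))))

    if not routes:
        raise MissingDataError(
            f"no NRV route is evaluable for {food.name!r} (need per-100 protein, "
            f"energy density, or a serving)")

    best_route, best_pct, best_threshold = max(
        routes, key=lambda r: _maybe_round(r[1], paper_rounding) / r[2])
    trace.append(TraceStep(
        label=f"best route: {best_route} at {best_pct:g}% of NRV "
              f"(source threshold {best_threshold:g}%, high at {2 * best_threshold:g}%)"))
    trace.append(TraceStep(label=f"%NRV by route {best_route}", op="value",
                           value=_maybe_round(best_pct, paper_rounding)))
    # tiers hold multipliers of the route threshold (source 1x, high 2x)
    return _award(rules, best_pct, best_route, trace, paper_rounding,
                  threshold_scale=best_threshold)


_EVALUATORS = {
    "canada-current": lambda food, companion, kw: evaluate_canada_current(
        food, companion, **kw),
    "canada-option1": lambda food, companion, kw: evaluate_canada_option1(
        food, companion, paper_rounding=kw.get("paper_rounding", False)),
    "canada-option2": lambda food, companion, kw: evaluate_canada_option2(
        food, companion, **kw),
    "usa": lambda food, companion, kw: evaluate_usa(food, **kw),
    "eu": lambda food, companion, kw: evaluate_eu(
        food, paper_rounding=kw.get("paper_rounding", False)),
    "anz": lambda food, companion, kw: evaluate_anz(
        food, paper_rounding=kw.get("paper_rounding", False)),
    "codex": lambda food, companion, kw: evaluate_nrv_family(
        food, "codex", paper_rounding=kw.get("paper_rounding", False)),
    "china": lambda food, companion, kw: evaluate_nrv_family(
        food, "china", paper_rounding=kw.get("paper_rounding", False)),
    "south-korea": lambda food, companion, kw: evaluate_nrv_family(
        food, "south-korea", paper_rounding=kw.get("paper_rounding", False)),
}


def evaluate(food: Food, jurisdiction_id: str, companion: Optional[Food] = None,
             **kwargs) -> ClaimResult:
    """Evaluate one food in one jurisdiction by id."""
    try:
        fn = _EVALUATORS[jurisdiction_id]
    except KeyError:
        from .errors import UnknownJurisdictionError
        raise UnknownJurisdictionError(
            f"unknown jurisdiction {jurisdiction_id!r}; available: "
            f"{sorted(_EVALUATORS)}") from None
    return fn(food, companion, kwargs)


def evaluate_all(food: Food, companion: Optional[Food] = None, *,
                 jurisdictions: Optional[Sequence[str]] = None,
                 pattern=None, variant: str = "1991",
                 paper_rounding: bool = False) -> list[ClaimResult]:
    """Evaluate a food against every configured jurisdiction.

    Jurisdictions lacking required data return a ``tier="none"`` result with
    the reason recorded in the trace rather than failing the batch.
    """
    if jurisdictions is None:
        jurisdictions = list(_EVALUATORS)
    results = []
    kwargs = {"pattern": pattern, "variant": variant,
              "paper_rounding": paper_rounding}
    for jid in jurisdictions:
        try:
            results.append(evaluate(food, jid, companion, **{
                k: v for k, v in kwargs.items()
                if jid in ("canada-current", "canada-option2", "usa") or k == "paper_rounding"
            }))
        except (MissingBasisError, MissingDataError, UnsupportedPopulationError) as exc:
            results.append(ClaimResult(
                jurisdiction_id=jid, tier="none", metric_value=None,
                basis_used="", threshold_applied=None,
                trace=(TraceStep(label=f"not evaluable: {exc}"),)))
    return results
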