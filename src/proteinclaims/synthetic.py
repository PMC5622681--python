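"""Seeded synthetic food generator for property testing.

Foods are drawn around a reference scoring pattern: each ingredient's amino
acid profile is the pattern scaled by independent per-amino-acid multipliers,
so generated amino acid scores straddle 1 and exercise both sides of the
PDCAAS truncation rule. Default ranges reflect common food values: true
fecal nitrogen digestibilities between 0.5 and 1.0 (plant through animal
proteins), protein densities between 1 and 30 g/100 g, energy densities
between 50 and 500 kcal/100 g, and one to four protein-contributing
ingredients with Dirichlet-distributed protein shares.

Generation is fully deterministic under the spec's seed: the same
:class:`SyntheticFoodSpec` always yields byte-identical foods.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .composition import (
    AminoAcidProfile,
    CANONICAL_AA,
    Food,
    IngredientProtein,
    ScoringPattern,
    ServingBases,
)

__all__ = ["SyntheticFoodSpec", "generate_synthetic_foods"]


def _check_interval(name: str, lo: float, hi: float, *, domain_lo: float,
                    domain_hi: float, open_lo: bool = False) -> None:
    if lo > hi:
        raise ValueError(f"{name}: empty range ({lo!r} > {hi!r})")
    lo_ok = lo > domain_lo if open_lo else lo >= domain_lo
    if not (lo_ok and hi <= domain_hi):
        raise ValueError(f"{name}: range ({lo}, {hi}) outside domain "
                         f"({domain_lo}, {domain_hi}]")


class SyntheticFoodSpec(BaseModel):
    """Parameters of the synthetic food generator."""

    model_config = ConfigDict(frozen=True)

    seed: int
    n_foods: int = Field(ge=0)
    n_ingredients_range: tuple[int, int] = (1, 4)
    digestibility_range: tuple[float, float] = (0.5, 1.0)
    aa_multiplier_range: tuple[float, float] = (0.3, 2.0)
    protein_per_100_range: tuple[float, float] = (1.0, 30.0)
    energy_density_range: tuple[float, float] = (50.0, 500.0)

    @model_validator(mode="after")
    def _validate_ranges(self) -> "SyntheticFoodSpec":
        lo, hi = self.n_ingredients_range
        if lo < 1 or lo > hi:
            raise ValueError(f"n_ingredients_range must be a non-empty range of "
                             f"counts >= 1, got {self.n_ingredients_range}")
        _check_interval("digestibility_range", *self.digestibility_range,
                        domain_lo=0.0, domain_hi=1.0, open_lo=True)
        _check_interval("aa_multiplier_range", *self.aa_multiplier_range,
                        domain_lo=0.0, domain_hi=float("inf"))
        _check_interval("protein_per_100_range", *self.protein_per_100_range,
                        domain_lo=0.0, domain_hi=float("inf"))
        _check_interval("energy_density_range", *self.energy_density_range,
                        domain_lo=0.0, domain_hi=float("inf"), open_lo=True)
        return self


def generate_synthetic_foods(spec: SyntheticFoodSpec,
                             pattern: ScoringPattern | None = None) -> list[Food]:
    """Generate ``spec.n_foods`` valid foods, deterministically under the seed."""
    if pattern is None:
        from .registry import load_scoring_pattern
        pattern = load_scoring_pattern()
    rng = np.random.default_rng(spec.seed)
    foods: list[Food] = []
    for idx in range(spec.n_foods):
        n_ing = int(rng.integers(spec.n_ingredients_range[0],
                                 spec.n_ingredients_range[1] + 1))
        shares = rng.dirichlet(np.ones(n_ing))
        shares = shares / shares.sum()  # guard the sum-to-1 invariant exactly
        ingredients = []
        for j in range(n_ing):
            multipliers = rng.uniform(*spec.aa_multiplier_range, size=len(CANONICAL_AA))
            profile = AminoAcidProfile(content={
                k: pattern.requirement[k] * float(m)
                for k, m in zip(CANONICAL_AA, multipliers)})
            ingredients.append(IngredientProtein(
                name=f"ingredient-{j + 1}",
                profile=profile,
                digestibility=float(rng.uniform(*spec.digestibility_range)),
                protein_share=float(shares[j]),
            ))
        state = "liquid" if rng.random() < 0.2 else "solid"
        serving = float(rng.uniform(20.0, 250.0))
        energy_density = float(rng.uniform(*spec.energy_density_range))
        foods.append(Food(
            name=f"synthetic-food-{idx + 1:04d}",
            ingredients=tuple(ingredients),
            protein_per_100=float(rng.uniform(*spec.protein_per_100_range)),
            energy_per_serving=energy_density * serving / 100.0,
            state=state,
            bases=ServingBases(
                rdi=float(rng.uniform(20.0, 300.0)),
                ra=float(rng.uniform(20.0, 150.0)),
                racc=float(rng.uniform(20.0, 150.0)),
                serving=serving,
                unit_kind="volume-mL" if state == "liquid" else "mass-g",
            ),
        ))
    return foods
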