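"""Protein quality arithmetic.

Implements amino acid scoring against a reference pattern, PDCAAS for single
protein sources and for multi-ingredient mixtures (two weighting variants),
the regulatory PDCAAS -> PER conversion, the Canadian protein rating, and
PDCAAS-corrected protein with its %DV.

PDCAAS for a single source is the lowest ratio of the food's indispensable
amino acid content (mg/g protein) to the reference population's requirement,
multiplied by the source's true fecal nitrogen digestibility, truncated at 1.

For mixtures of ingredients with protein shares w_i, amino acid profiles
aa_{i,a} and digestibilities d_i, two weighting conventions exist:

* 1991 convention: score the share-weighted mixture profile, then multiply by
  the share-weighted digestibility::

      raw = min_a( (sum_i w_i aa_{i,a}) / ref_a ) * (sum_i w_i d_i)

* 2007 convention: weight each ingredient's amino acids by its own
  digestibility first (digestible amino acid content), then apply the
  weighted-average digestibility coefficient::

      g_a  = sum_i w_i aa_{i,a} d_i           (digestible content)
      D    = sum_i w_i d_i
      raw  = min_a( g_a / (ref_a * D) ) * D   (simplifies to min_a g_a/ref_a)

  The normalisation by D inside the ratio and the final multiplication by D
  cancel; the simplified form is what is computed. The two conventions agree
  exactly whenever all ingredient digestibilities are equal.

Truncation at 1 is applied to the mixture score only, never per ingredient,
and before any downstream use (PER conversion, corrected protein); the
untruncated ``raw_score`` is kept for audit.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

from .composition import (
    CANONICAL_AA,
    AminoAcidProfile,
    IngredientProtein,
    QualityResult,
    ScoringPattern,
)
from .errors import DomainError, FoodValidationError

__all__ = [
    "AminoAcidScore",
    "CorrectedProtein",
    "amino_acid_score",
    "pdcaas_single",
    "pdcaas_multi",
    "per_from_pdcaas",
    "protein_rating",
    "corrected_protein",
    "CASEIN_PER",
    "KCAL_PER_G_PROTEIN",
]

#: Standardized PER of the casein control in the rat bioassay.
CASEIN_PER = 2.5

#: Atwater energy conversion factor for protein (kcal per g).
KCAL_PER_G_PROTEIN = 4.0

class AminoAcidScore(NamedTuple):
    """Minimum content/requirement ratio and the amino acid attaining it."""

    score: float
    limiting_aa: str
    tied: tuple[str, ...]


class CorrectedProtein(NamedTuple):
    """PDCAAS-corrected protein at a serving basis and its percent of the DV."""

    grams: float
    basis: str
    percent_dv: float


def _score_ratios(content: dict[str, float], pattern: ScoringPattern) -> AminoAcidScore:
    ratios = {a: content[a] / pattern.requirement[a] for a in CANONICAL_AA}
    lowest = min(ratios.values())
    tied = tuple(a for a in CANONICAL_AA if ratios[a] == lowest)
    return AminoAcidScore(score=lowest, limiting_aa=tied[0],
                          tied=tied if len(tied) > 1 else ())


def amino_acid_score(profile: AminoAcidProfile, pattern: ScoringPattern) -> AminoAcidScore:
    """Lowest content/requirement ratio over the nine scored amino acids.

    Ties are broken by canonical (alphabetical) key order and reported in
    ``tied``.
    """
    return _score_ratios(profile.content, pattern)


def pdcaas_single(profile: AminoAcidProfile, pattern: ScoringPattern,
                  digestibility: float) -> QualityResult:
    """PDCAAS of a single protein source."""
    if not (0.0 < digestibility <= 1.0):
        raise DomainError(
            f"digestibility must be in (0, 1], got {digestibility!r}")
    aas = amino_acid_score(profile, pattern)
    raw = aas.score * digestibility
    return QualityResult(
        method_variant="single",
        raw_score=raw,
        pdcaas=min(raw, 1.0),
        limiting_aa=aas.limiting_aa,
        digestibility_used=digestibility,
        tied=aas.tied,
    )


def pdcaas_multi(ingredients: Sequence[IngredientProtein], pattern: ScoringPattern,
                 variant: str = "1991") -> QualityResult:
    """PDCAAS of a multi-ingredient mixture under the 1991 or 2007 weighting."""
    if variant not in ("1991", "2007"):
        raise DomainError(f"variant must be '1991' or '2007', got {variant!r}")
    if not ingredients:
        raise DomainError("ingredient list must be non-empty")
    total_share = sum(i.protein_share for i in ingredients)
    if abs(total_share - 1.0) > 1e-9:
        raise FoodValidationError(
            f"ingredient protein shares must sum to 1 (got {total_share!r})")

    weighted_digestibility = sum(i.protein_share * i.digestibility for i in ingredients)

    if variant == "1991":
        mixture = {a: sum(i.protein_share * i.profile.content[a] for i in ingredients)
                   for a in CANONICAL_AA}
        aas = _score_ratios(mixture, pattern)
        raw = aas.score * weighted_digestibility
    else:
        digestible = {a: sum(i.protein_share * i.profile.content[a] * i.digestibility
                             for i in ingredients)
                      for a in CANONICAL_AA}
        # min_a(g_a / (ref_a * D)) * D == min_a(g_a / ref_a)
        aas = _score_ratios(digestible, pattern)
        raw = aas.score

    return QualityResult(
        method_variant=f"multi-{variant}",
        raw_score=raw,
        pdcaas=min(raw, 1.0),
        limiting_aa=aas.limiting_aa,
        digestibility_used=weighted_digestibility,
        tied=aas.tied,
    )


def per_from_pdcaas(pdcaas: float) -> float:
    """Regulatory PER derived from a (truncated) PDCAAS: ``PDCAAS * 2.5``.

    2.5 is the standardized PER of the casein control; the input must already
    be truncated to [0, 1], so the output lies in [0, 2.5].
    """
    if not (0.0 <= pdcaas <= 1.0):
        raise DomainError(
            f"pdcaas must be in [0, 1] (truncate first), got {pdcaas!r}")
    return pdcaas * CASEIN_PER


def protein_rating(per: float, protein_g: float) -> float:
    """Canadian protein rating: PER times grams of protein in the RDI."""
    if per < 0:
        raise DomainError(f"per must be >= 0, got {per!r}")
    if protein_g < 0:
        raise DomainError(f"protein_g must be >= 0, got {protein_g!r}")
    return per * protein_g


def corrected_protein(pdcaas: float, protein_g: float, dv_g: float,
                      basis: str = "ra") -> CorrectedProtein:
    """PDCAAS-corrected protein grams at a basis and the corresponding %DV."""
    if not (0.0 <= pdcaas <= 1.0):
        raise DomainError(f"pdcaas must be in [0, 1], got {pdcaas!r}")
    if protein_g < 0:
        raise DomainError(f"protein_g must be >= 0, got {protein_g!r}")
    if dv_g <= 0:
        raise DomainError(f"dv_g must be > 0, got {dv_g!r}")
    grams = pdcaas * protein_g
    return CorrectedProtein(grams=grams, basis=basis,
                            percent_dv=grams / dv_g * 100.0)
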