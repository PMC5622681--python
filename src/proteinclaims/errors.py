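"""Exception hierarchy for food definitions, scoring and claim evaluation."""


class ProteinClaimsError(Exception):
    """Base class for all package-specific errors."""


class DefinitionParseError(ProteinClaimsError, ValueError):
    """A food-definition file could not be parsed (malformed JSON/CSV)."""


class FoodValidationError(ProteinClaimsError, ValueError):
    """A parsed food record violates a model invariant.

    The message names the offending food and the rule that failed.
    """


class DomainError(ProteinClaimsError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class MissingBasisError(ProteinClaimsError, LookupError):
    """A serving basis (RDI/RA/RACC/serving) required by a rule is absent."""


class MissingDataError(ProteinClaimsError, LookupError):
    """A quantity required by a rule (energy, quality score) is unavailable."""


class UnknownJurisdictionError(ProteinClaimsError, KeyError):
    """Requested jurisdiction id is not in the registry."""


class UnknownFoodCategoryError(ProteinClaimsError, KeyError):
    """Requested serving-registry category is not bundled."""


class UnsupportedPopulationError(ProteinClaimsError, ValueError):
    """Claim evaluation requested for a population the engine does not cover
    (infant foods require the in vivo PER bioassay)."""
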