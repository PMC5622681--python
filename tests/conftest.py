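import numpy as np
import pytest

from proteinclaims import (
    AminoAcidProfile,
    CANONICAL_AA,
    IngredientProtein,
    build_paper_fixtures,
    load_scoring_pattern,
)


@pytest.fixture(scope="session")
def pattern():
    """The bundled FAO/WHO 1991 preschool scoring pattern."""
    return load_scoring_pattern()


@pytest.fixture(scope="session")
def paper():
    """Worked-example foods and their expected printed outcomes."""
    return build_paper_fixtures()


def make_profile(pattern, multipliers):
    """Profile equal to the pattern scaled amino-acid-wise by `multipliers`."""
    if np.isscalar(multipliers):
        multipliers = [multipliers] * len(CANONICAL_AA)
    return AminoAcidProfile(content={
        k: pattern.requirement[k] * m for k, m in zip(CANONICAL_AA, multipliers)})


def random_ingredients(rng, pattern, n, digestibility=None):
    """Random ingredient list with Dirichlet shares; optional common digestibility."""
    shares = rng.dirichlet(np.ones(n))
    shares = shares / shares.sum()
    out = []
    for j in range(n):
        d = digestibility if digestibility is not None else float(rng.uniform(0.3, 1.0))
        out.append(IngredientProtein(
            name=f"ing-{j}",
            profile=make_profile(pattern, rng.uniform(0.2, 2.5, size=len(CANONICAL_AA))),
            digestibility=d,
            protein_share=float(shares[j]),
        ))
    return out
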