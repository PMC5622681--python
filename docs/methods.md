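# Methods

## Scope and model

The package evaluates protein content claims from four inputs: a food's
protein density (g per 100 g for solids, per 100 mL for liquids), its
regulated serving bases (RDI, reference amount, RACC, label serving), its
protein quality (a measured PER or PDCAAS, or ingredient data from which
PDCAAS is computed), and optionally its energy per serving. Protein mass at
any basis is always `protein_per_100 × basis / 100`; no per-basis protein
is stored independently, so a food cannot silently carry inconsistent
protein declarations.

### Amino acid scoring and PDCAAS

The amino acid score is the minimum over the nine scored indispensable
amino acid classes (His, Ile, Leu, Lys, Met+Cys, Phe+Tyr, Thr, Trp, Val) of
content (mg/g protein) over the reference pattern's requirement. Ties for
the minimum are resolved to the first amino acid in canonical
(alphabetical) order and all tied keys are reported; ties are exact-equality
events, which in practice arise only for constructed inputs. A missing
amino acid entry is a validation error, never imputed as zero — a silent
zero would manufacture a spurious limiting amino acid.

PDCAAS multiplies the score by true fecal nitrogen digestibility and
truncates at 1. Truncation applies once, to the food-level (mixture) score,
never per ingredient, and happens before any downstream use — the PER
conversion and corrected-protein arithmetic take the truncated value, while
the untruncated `raw_score` is retained for audit. Digestibility is always
an input; the package does not estimate it.

### Mixture weighting: 1991 vs 2007

For a mixture with protein shares `w_i`, profiles `aa_{i,a}` and
digestibilities `d_i`:

* **1991** (default): `raw = min_a(Σ_i w_i·aa_{i,a} / ref_a) × D` with
  `D = Σ_i w_i·d_i`. This is the convention the USA regulations cite, and
  it is what the worked examples assume, hence the default.
* **2007**: the digestible amino acid content is formed first,
  `g_a = Σ_i w_i·aa_{i,a}·d_i`, and the weighted digestibility coefficient
  is then applied: `raw = min_a(g_a / (ref_a·D)) × D`. The description of
  this two-step procedure in the literature is ambiguous about the
  normalisation; the formula implemented is the one in which the second
  step's multiplication by `D` cancels the normalisation, so it simplifies
  to `min_a(g_a / ref_a)`. No published worked number distinguishes the two
  variants; the algebraic identity that they coincide whenever all `d_i`
  are equal is verified to 1e-12 over 10⁴ random mixtures in the test
  suite, which pins the implementation to the intended relationship.

### PER, protein rating, corrected protein

`PER = PDCAAS × 2.5` converts a PDCAAS into a casein-standardized PER
(casein = 2.5); the input must already be truncated, so PER ∈ [0, 2.5].
The Canadian protein rating is PER × grams of protein in the RDI; where no
RDI exists the reference amount is used and the substitution is flagged in
the trace. Corrected protein is PDCAAS × grams at the stated basis, with
`%DV = corrected / DV × 100`.

## Claim frameworks

Each jurisdiction is a JSON parameter file (tiers with inclusive ≥
thresholds in ascending stringency, constants with citations); the engine
dispatches on the declared metric, so adding a jurisdiction that uses an
existing metric requires no code change. Bundled parameter sets:

| id | metric | basis | tiers |
|---|---|---|---|
| canada-current | protein rating | RDI (RA fallback) | ≥20 good, ≥40 excellent |
| canada-option1 | g protein | RA | ≥5 good, ≥10 excellent |
| canada-option2 | %DV corrected (DV 50 g) | RA | ≥5% source, ≥10% good, ≥20% excellent |
| usa | %DV corrected (DV 50 g; 13 g ages 1–3) | RACC | ≥10% good, ≥20% excellent |
| eu | % energy from protein | serving | ≥12% source, ≥20% high |
| anz | g protein | serving | ≥5 general, ≥10 good |
| codex / south-korea / china | % NRV (50 / 55 / 60 g) | routes | source ×1, high ×2 |

The current Canadian framework is two-tier ("source" and "good source" are
equivalent). The NRV family evaluates every applicable route — ≥10% NRV per
100 g (solids), ≥5% per 100 mL (liquids), ≥5% per 100 kcal (Codex, South
Korea) or per 420 kJ (China), and ≥10% per serving (Codex and South Korea
only) — with OR semantics: any route qualifying awards the tier, a route at
twice its threshold awards "high source", and every evaluated route is
recorded in the trace.

Combination of foods traditionally consumed together (the sanctioned case
is breakfast cereal with 125 mL milk) is restricted to explicitly declared
pairs on the food record. Under the current framework the two ratings are
summed with the cereal's RDI switched to its declared with-milk RDI; under
Options 1 and 2 the grams (respectively corrected grams) are summed before
the threshold (or the %DV) is taken. Whether milk's 125 mL with-cereal
amount acts as its reference amount in these combinations is a
fixture-level declaration, not a general rule.

Protein energy uses the Atwater factor of 4 kcal/g (17 kJ/g); the claim
regulations state no factor, so it is a cited, configurable constant.
Infant foods (≤ 12 months) are refused: they require the in vivo PER
bioassay, which is outside this package's scope.

## Rounding and the paper-rounding mode

All computation is unrounded; `round_half_up` (ties away from zero, on the
shortest decimal representation) is the single display-rounding function.
Regulatory worked tables print grams and metrics to one decimal and compare
thresholds on the printed numbers, so the engines accept
`paper_rounding=True`, which (a) rounds grams-at-basis to one decimal
before use, (b) rounds each food's metric component to one decimal before
summing combinations, and (c) compares thresholds on the 1-decimal metric.
PER values derived from PDCAAS are deliberately never pre-rounded: the
bread worked example (rating 20.3) follows from the unrounded 1.145, not
the printed 1.15.

## Worked-example fixtures and known inconsistent cells

The bundled fixtures encode the published example foods with their measured
PER/PDCAAS values. Three rows of the reformulated-foods table are not
internally consistent — the same food implies different protein densities
at different bases — so each fixture anchors its density to one printed
cell (bread to its 17.7 g/125 g RDI, which reproduces all three of its
bases; pasta to its 8.1 g/55 g RA; the low-density cereal to its
5.5 g/30 g RA; the pancake mix to its 30.4 g/110 g RACC). The cells that do
not follow from their own row's printed inputs are enumerated in
`fixtures.EXCLUDED_CELLS` with the computed value; every claim *verdict*
still reproduces, with one exception: the low-density-cereal-plus-milk
current-framework verdict rests entirely on a milk rating printed as 6.8
where the row's own inputs give 2.5 × 4.3 = 10.75, and is therefore not
asserted. The narrative "highest achievable rating 5.9" for the example
cereals is likewise superseded by the table's own 2.32 × 2.5 = 5.8.

## Synthetic foods

The generator draws ingredient profiles as the reference pattern scaled by
independent per-amino-acid multipliers in [0.3, 2.0], so amino acid scores
straddle 1 and exercise truncation from both sides; digestibilities are
uniform in [0.5, 1.0] (plant through animal proteins), protein densities in
[1, 30] g/100 g, energy densities in [50, 500] kcal/100 g, 1–4 ingredients
with Dirichlet protein shares, and a 20% chance of being a liquid. All
randomness flows from one `numpy` generator seeded by the spec, so equal
specs produce byte-identical serialized foods. Synthetic foods emulate the
*structure* of real composition data, not its covariances (amino acid
levels in real foods are correlated across classes, digestibility
correlates with the food matrix); passing property tests on them
demonstrates the engine's invariants (score bounds, variant identities,
tier monotonicity), not nutritional realism.

## Numerical choices and limitations

* Share sums are validated to 1 within 1e-9; digestibility domain is (0, 1].
* Claim traces are structured steps (operation, operands, value) that can
  be replayed; a test audits that every trace recomputes its reported
  metric to 1e-9.
* kJ are converted at 4.184 kJ/kcal where the energy route is stated in kJ.
* The acceptance script's cross-check sweep uses 200 synthetic foods and
  the test suite's variant-identity check uses 10⁴ random mixtures — sizes
  chosen so the full arithmetic is exercised while the suites stay
  desk-scale.
* The package models protein, amino acids, digestibility and energy only —
  it is not a Nutrition Facts engine, generates no label wording, and
  performs no legal interpretation beyond the numeric rules.
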