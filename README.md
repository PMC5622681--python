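# proteinclaims

Protein quality scoring and protein content claim evaluation for food
regulatory work.

Whether a food may carry a "source of protein" claim depends on where it is
sold. Canada currently requires a **protein rating**: the food's protein
efficiency ratio (PER, a rat-bioassay growth measure standardized so casein
scores 2.5) multiplied by the grams of protein in its Reasonable Daily
Intake (RDI), with claims at rating ≥ 20 ("good source") and ≥ 40
("excellent source"). The USA instead corrects protein by **PDCAAS** — the
protein digestibility corrected amino acid score — and compares the
corrected protein per reference amount customarily consumed (RACC) against
a 50 g Daily Value. Europe uses percent of energy from protein,
Australia/New Zealand use absolute grams per serving, and the
Codex/China/South-Korea family uses percent of a Nutrient Reference Value
by several alternative routes. This package implements all of these — plus
two proposed modernization options for Canada — as one typed library with a
data-driven rules registry, and reproduces the published worked examples
for these frameworks to the printed decimal.

The core quantities, for a food with indispensable amino acid content
$aa_a$ (mg/g protein), reference pattern requirement $ref_a$, and true
fecal nitrogen digestibility $d$:

```
amino acid score = min_a ( aa_a / ref_a )          (limiting amino acid = argmin)
PDCAAS           = min( score × d , 1 )            (truncated at 1)
PER_PDCAAS       = PDCAAS × 2.5                    (casein-standardized PER)
protein rating   = PER × g protein per RDI
corrected g      = PDCAAS × g protein per basis;   %DV = corrected / DV × 100
```

For mixtures of ingredients with protein shares $w_i$, two weighting
conventions are provided: the 1991 convention scores the share-weighted
profile and multiplies by the share-weighted digestibility
$D=\sum_i w_i d_i$; the 2007 convention weights each ingredient's amino
acids by its own digestibility first. They agree exactly whenever all
ingredient digestibilities are equal.

## Worked example

The bundled fixtures include a hypothetical chickpea-based breakfast cereal
(5 g protein per 55 g reference amount, measured PER 2.32, PDCAAS 0.52)
traditionally consumed with 125 mL of 2% milk (4.3 g protein, PER 2.5,
PDCAAS 1.0):

```bash
protein-claims fixtures --out foods.json
protein-claims evaluate --foods foods.json \
    --jurisdictions canada-current,canada-option1,canada-option2 --paper-rounding
```

```text
food                       companion  jurisdiction    metric_value  basis           tier         threshold
chickpea breakfast cereal             canada-current  5.8           rdi             none         20.0
chickpea breakfast cereal             canada-option1  5.0           ra              good-source  5.0
chickpea breakfast cereal             canada-option2  5.2           ra              source       5.0
chickpea breakfast cereal  2% milk    canada-current  17.1          rdi (combined)  none         20.0
chickpea breakfast cereal  2% milk    canada-option1  9.3           ra              good-source  5.0
chickpea breakfast cereal  2% milk    canada-option2  13.8          ra              good-source  10.0
```

Alone, the cereal rates 2.32 × 2.5 g = 5.8 at its 28 g RDI; even combined
with milk (6.3 + 10.8 = 17.1 at the 30 g with-milk RDI) it stays below the
current Canadian threshold of 20 and gets no claim. Under proposed Option 1
the combination's 5 + 4.3 = 9.3 g of protein per reference amount is a good
source, and under proposed Option 2 its PDCAAS-corrected protein
(0.52 × 5 + 1.0 × 4.3 = 6.9 g, i.e. 13.8% of the 50 g DV) is likewise a
good source. `--format json` exposes the full replayable calculation trace
behind each row.

The same works from Python:

```python
from proteinclaims import build_paper_fixtures, evaluate_canada_option2

fx = build_paper_fixtures().foods
result = evaluate_canada_option2(fx["chickpea breakfast cereal"], fx["2% milk"],
                                 paper_rounding=True)
print(result.metric_value, result.tier)   # 13.8 good-source
```

`--paper-rounding` compares thresholds on 1-decimal displayed values, as
regulatory worked tables do; without it all comparisons are unrounded.

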