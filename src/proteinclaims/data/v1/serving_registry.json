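{
  "schema_version": "1",
  "entries": [
    {
      "food_category": "high-density breakfast cereal",
      "description": ">=43 g per 250 mL",
      "rdi": {"amount": 28, "unit": "g"},
      "rdi_with_companion": {"amount": 30, "unit": "g", "companion": "125 mL milk"},
      "ra": {"amount": 55, "unit": "g"},
      "source": "Canada Food and Drug Regulations Schedule K (RDI 28 g); FDR protein rating provisions (RDI 30 g with 125 mL milk); Canada Table of Reference Amounts for Food (RA 55 g)"
    },
    {
      "food_category": "low-density breakfast cereal",
      "description": "20 g to 42 g per 250 mL",
      "rdi_with_companion": {"amount": 30, "unit": "g", "companion": "125 mL milk"},
      "ra": {"amount": 30, "unit": "g"},
      "racc": {"amount": 40, "unit": "g"},
      "source": "Canada Table of Reference Amounts for Food (RA 30 g); US 21 CFR 101.12 (RACC 40 g for 20 to <43 g/240 mL cereals)"
    },
    {
      "food_category": "milk",
      "rdi": {"amount": 852, "unit": "mL"},
      "rdi_with_companion": {"amount": 125, "unit": "mL", "companion": "breakfast cereal"},
      "ra": {"amount": 250, "unit": "mL"},
      "source": "Canada Food and Drug Regulations Schedule K (RDI 852 mL); FDR protein rating provisions (125 mL with breakfast cereal); Canada Table of Reference Amounts for Food (RA 250 mL)"
    },
    {
      "food_category": "bread",
      "rdi": {"amount": 125, "unit": "g", "note": "5 slices"},
      "ra": {"amount": 75, "unit": "g"},
      "racc": {"amount": 50, "unit": "g"},
      "source": "Canada Food and Drug Regulations Schedule K (RDI, 5 slices = 125 g); Canada Table of Reference Amounts for Food (RA 75 g); US 21 CFR 101.12 (RACC 50 g)"
    },
    {
      "food_category": "pancakes",
      "ra": {"amount": 75, "unit": "g"},
      "racc": {"amount": 110, "unit": "g"},
      "source": "Canada Table of Reference Amounts for Food (RA 75 g); US 21 CFR 101.12 (RACC 110 g); no RDI exists, the reference amount is used for protein ratings"
    },
    {
      "food_category": "pasta",
      "rdi": {"amount": 85, "unit": "g", "note": "dry"},
      "ra": {"amount": 55, "unit": "g", "note": "dry"},
      "racc": {"amount": 55, "unit": "g", "note": "dry"},
      "source": "Canada Food and Drug Regulations Schedule K (RDI 85 g dry); Canada Table of Reference Amounts for Food (RA 55 g dry); US 21 CFR 101.12 (RACC 55 g dry)"
    }
  ]
}
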