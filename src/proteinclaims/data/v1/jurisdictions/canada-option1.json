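{
  "jurisdiction_id": "canada-option1",
  "name": "Canada (proposed Option 1): absolute protein per reference amount",
  "metric": "grams-per-basis",
  "basis": "ra",
  "tiers": [
    {"tier": "good-source", "threshold": 5.0,
     "citation": "Proposed Canadian Option 1: >= 5 g protein per reference amount for 'good source'"},
    {"tier": "excellent-source", "threshold": 10.0,
     "citation": "Proposed Canadian Option 1: >= 10 g protein per reference amount for 'excellent source'"}
  ],
  "constants": {},
  "notes": "Protein quality is not considered; foods traditionally consumed together sum their grams of protein per reference amount.",
  "citation": "Proposed modernization option aligning with FSANZ absolute-content thresholds"
}
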