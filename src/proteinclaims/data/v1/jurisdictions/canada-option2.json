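{
  "jurisdiction_id": "canada-option2",
  "name": "Canada (proposed Option 2): PDCAAS-corrected protein vs a 50 g DV",
  "metric": "percent-dv",
  "basis": "ra",
  "tiers": [
    {"tier": "source", "threshold": 5.0,
     "citation": "Proposed Canadian Option 2: >= 5% DV (2.5 g) corrected protein per reference amount for 'source'"},
    {"tier": "good-source", "threshold": 10.0,
     "citation": "Proposed Canadian Option 2: >= 10% DV (5 g) corrected protein per reference amount for 'good source'"},
    {"tier": "excellent-source", "threshold": 20.0,
     "citation": "Proposed Canadian Option 2: >= 20% DV (10 g) corrected protein per reference amount for 'excellent source'"}
  ],
  "constants": {
    "dv_g": {"value": 50.0,
             "citation": "Proposed adoption of the 50 g protein DV (same as the USA DV for ages >= 4 y)"}
  },
  "notes": "Three-tier framework on PDCAAS-corrected protein per reference amount relative to a 50 g DV; foods traditionally consumed together sum their corrected protein before the %DV is taken.",
  "citation": "Proposed PDCAAS-based framework harmonizing with the USA"
}
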