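{
  "jurisdiction_id": "usa",
  "name": "USA: PDCAAS-corrected protein vs the DV per RACC",
  "metric": "percent-dv",
  "basis": "racc",
  "tiers": [
    {"tier": "good-source", "threshold": 10.0,
     "citation": "US 21 CFR 101.54(c): >= 10% DV (5 g) corrected protein per RACC for 'good source'"},
    {"tier": "excellent-source", "threshold": 20.0,
     "citation": "US 21 CFR 101.54(b): >= 20% DV (10 g) corrected protein per RACC for 'high'/'excellent source'"}
  ],
  "constants": {
    "dv_g": {"value": 50.0,
             "citation": "US protein DV for >= 4 y through adults: 50 g"},
    "dv_g_children_1_3": {"value": 13.0,
                          "citation": "US protein DV for children 1 through 3 y: 13 g"}
  },
  "notes": "Applies to foods marketed to ages >= 1 y; infant foods (<= 12 months) require the PER bioassay and are out of scope.",
  "citation": "US 21 CFR 101.54; FDA nutrition labeling regulations"
}
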