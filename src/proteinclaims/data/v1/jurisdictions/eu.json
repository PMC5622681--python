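{
  "jurisdiction_id": "eu",
  "name": "European Union: percent of energy from protein per serving",
  "metric": "percent-energy",
  "basis": "serving",
  "tiers": [
    {"tier": "source", "threshold": 12.0,
     "citation": "EC Regulation 1924/2006 Annex: 'source of protein' where >= 12% of energy is provided by protein"},
    {"tier": "high-source", "threshold": 20.0,
     "citation": "EC Regulation 1924/2006 Annex: 'high in protein' where >= 20% of energy is provided by protein"}
  ],
  "constants": {
    "kcal_per_g_protein": {"value": 4.0,
                           "citation": "Atwater general factor for protein (4 kcal/g, 17 kJ/g); the claim regulation itself states no factor"}
  },
  "notes": "Requires the label serving's energy content.",
  "citation": "EC Regulation 1924/2006 on nutrition and health claims"
}
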