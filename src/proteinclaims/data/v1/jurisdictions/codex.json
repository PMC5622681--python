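{
  "jurisdiction_id": "codex",
  "name": "Codex Alimentarius: percent of the protein NRV by route",
  "metric": "nrv-routes",
  "tiers": [
    {"tier": "source", "threshold": 1.0,
     "citation": "Codex CAC/GL 23-1997: 'source' where any route meets its threshold"},
    {"tier": "high-source", "threshold": 2.0,
     "citation": "Codex CAC/GL 23-1997: 'high' reserved for 2x the level qualifying for a 'source' claim"}
  ],
  "constants": {
    "nrv_g": {"value": 50.0, "citation": "Codex protein NRV: 50 g/day"},
    "per_100g_pct": {"value": 10.0, "citation": "Codex CAC/GL 23-1997: >= 10% NRV per 100 g (solids)"},
    "per_100ml_pct": {"value": 5.0, "citation": "Codex CAC/GL 23-1997: >= 5% NRV per 100 mL (liquids)"},
    "per_energy_pct": {"value": 5.0, "citation": "Codex CAC/GL 23-1997: >= 5% NRV per 100 kcal"},
    "energy_unit": {"value": "kcal-100", "citation": "Codex energy route is per 100 kcal"},
    "per_serving_pct": {"value": 10.0, "citation": "Codex CAC/GL 23-1997: >= 10% NRV per serving"}
  },
  "notes": "A food is a source if ANY applicable route meets its threshold; 'high source' needs any route at twice its threshold. All evaluated routes are recorded in the trace.",
  "citation": "Codex Alimentarius CAC/GL 23-1997 Guidelines for Use of Nutrition and Health Claims"
}
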