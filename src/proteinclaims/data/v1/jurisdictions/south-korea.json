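{
  "jurisdiction_id": "south-korea",
  "name": "South Korea: percent of the protein NRV by route",
  "metric": "nrv-routes",
  "tiers": [
    {"tier": "source", "threshold": 1.0,
     "citation": "South Korea MFDS labelling standard: 'source' where any route meets its threshold"},
    {"tier": "high-source", "threshold": 2.0,
     "citation": "South Korea MFDS labelling standard: 'high' at 2x the 'source' level"}
  ],
  "constants": {
    "nrv_g": {"value": 55.0, "citation": "South Korea protein NRV: 55 g/day"},
    "per_100g_pct": {"value": 10.0, "citation": "South Korea: >= 10% NRV per 100 g (solids)"},
    "per_100ml_pct": {"value": 5.0, "citation": "South Korea: >= 5% NRV per 100 mL (liquids)"},
    "per_energy_pct": {"value": 5.0, "citation": "South Korea: >= 5% NRV per 100 kcal"},
    "energy_unit": {"value": "kcal-100", "citation": "South Korea's energy route is per 100 kcal"},
    "per_serving_pct": {"value": 10.0, "citation": "South Korea: >= 10% NRV per serving"}
  },
  "notes": "",
  "citation": "South Korea Ministry of Food and Drug Safety food labelling standard"
}
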