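{
  "jurisdiction_id": "china",
  "name": "China: percent of the protein NRV by route",
  "metric": "nrv-routes",
  "tiers": [
    {"tier": "source", "threshold": 1.0,
     "citation": "China GB 28050: 'source' where any route meets its threshold"},
    {"tier": "high-source", "threshold": 2.0,
     "citation": "China GB 28050: 'high' at 2x the 'source' level"}
  ],
  "constants": {
    "nrv_g": {"value": 60.0, "citation": "China protein NRV: 60 g/day"},
    "per_100g_pct": {"value": 10.0, "citation": "China GB 28050: >= 10% NRV per 100 g (solids)"},
    "per_100ml_pct": {"value": 5.0, "citation": "China GB 28050: >= 5% NRV per 100 mL (liquids)"},
    "per_energy_pct": {"value": 5.0, "citation": "China GB 28050: >= 5% NRV per 420 kJ"},
    "energy_unit": {"value": "kJ-420", "citation": "China's energy route is per 420 kJ"}
  },
  "notes": "China has no per-serving route.",
  "citation": "China National Food Safety Standard GB 28050"
}
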