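{
  "jurisdiction_id": "anz",
  "name": "Australia & New Zealand: absolute protein per serving",
  "metric": "grams-per-basis",
  "basis": "serving",
  "tiers": [
    {"tier": "general", "threshold": 5.0,
     "citation": "FSANZ Standard 1.2.7 Schedule 4: general protein claim at >= 5 g protein per serving"},
    {"tier": "good-source", "threshold": 10.0,
     "citation": "FSANZ Standard 1.2.7 Schedule 4: 'good source' at >= 10 g protein per serving"}
  ],
  "constants": {},
  "notes": "",
  "citation": "Food Standards Australia New Zealand, Standard 1.2.7"
}
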