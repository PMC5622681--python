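{
  "population_label": "Preschool children 2-5 y (FAO/WHO 1991)",
  "provenance": "Transcribed from the 1991 Report of the Joint FAO/WHO Expert Consultation on Protein Quality Evaluation (external reference data; values are not re-derived in this package). This is the scoring pattern the US FDA prescribes for PDCAAS-based protein claims.",
  "requirement": {
    "His": 19.0,
    "Ile": 28.0,
    "Leu": 66.0,
    "Lys": 58.0,
    "Met+Cys": 25.0,
    "Phe+Tyr": 63.0,
    "Thr": 34.0,
    "Trp": 11.0,
    "Val": 35.0
  }
}
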