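{
  "jurisdiction_id": "canada-current",
  "name": "Canada (current): PER / protein rating framework",
  "metric": "protein-rating",
  "basis": "rdi",
  "basis_fallback": "ra",
  "tiers": [
    {"tier": "good-source", "threshold": 20.0,
     "citation": "Canada FDR / CFIA Industry Labelling Tool: protein rating >= 20 qualifies a 'source'/'good source' of protein claim"},
    {"tier": "excellent-source", "threshold": 40.0,
     "citation": "Canada FDR / CFIA Industry Labelling Tool: protein rating >= 40 qualifies an 'excellent source' of protein claim"}
  ],
  "constants": {},
  "notes": "Two-tier framework: 'source of' and 'good source of' protein claims are equivalent. Rating = PER x g protein in the RDI; where no RDI exists the reference amount is used (flagged in the trace). Breakfast cereal may be combined with 125 mL milk, the cereal RDI switching to its declared with-milk RDI.",
  "citation": "Canadian Food and Drug Regulations; Health Canada Method FO-1; CFIA Industry Labelling Tool"
}
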