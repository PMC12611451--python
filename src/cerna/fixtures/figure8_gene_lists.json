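{
  "_comment": "Risk-gene overlap (Venn) between the ASD-group and placenta-group relevant genes after the risk-catalog search. Lists are stored as printed; note SRSF11 appears both in asd_only and shared in the source figure legend (a discrepancy that is surfaced, not resolved).",
  "asd_only": ["EP300", "CCNK", "ZC3H11A", "CPSF7", "U2AF2", "SRSF11"],
  "placenta_only": ["HLA-A", "HLA-B", "NUP155", "NSD2"],
  "shared": ["PSMD11", "CREBBP", "TBL1X", "SRSF11", "NOTCH1"]
}
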