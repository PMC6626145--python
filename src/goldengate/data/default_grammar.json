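{
  "level2": {
    "A": "GGAG",
    "B": "TACT",
    "C": "AATG",
    "D": "GCTT",
    "E": "GGTA",
    "F": "CGCT",
    "G": "CCAT"
  },
  "level3": {
    "1": "TGCC",
    "2": "GCAA",
    "3": "ACTA",
    "4": "TTAC",
    "5": "CAGA",
    "6": "AGGC"
  },
  "entry": ["CTAT", "TGAG"],
  "enzymes": {"entry": "BpiI", "level2": "BsaI", "level3": "BpiI"}
}
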