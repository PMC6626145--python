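[
  {"name": "BsaI",    "recognition": "GGTCTC",   "cut_top": 1,  "cut_bottom": 5},
  {"name": "BpiI",    "recognition": "GAAGAC",   "cut_top": 2,  "cut_bottom": 6},
  {"name": "Esp3I",   "recognition": "CGTCTC",   "cut_top": 1,  "cut_bottom": 5},
  {"name": "SapI",    "recognition": "GCTCTTC",  "cut_top": 1,  "cut_bottom": 4},
  {"name": "AarI",    "recognition": "CACCTGC",  "cut_top": 4,  "cut_bottom": 8},
  {"name": "MlyI",    "recognition": "GAGTC",    "cut_top": 5,  "cut_bottom": 5},
  {"name": "EcoRI",   "recognition": "GAATTC",   "cut_top": -5, "cut_bottom": -1},
  {"name": "HindIII", "recognition": "AAGCTT",   "cut_top": -5, "cut_bottom": -1},
  {"name": "XbaI",    "recognition": "TCTAGA",   "cut_top": -5, "cut_bottom": -1},
  {"name": "PstI",    "recognition": "CTGCAG",   "cut_top": -1, "cut_bottom": -5},
  {"name": "SphI",    "recognition": "GCATGC",   "cut_top": -1, "cut_bottom": -5},
  {"name": "NotI",    "recognition": "GCGGCCGC", "cut_top": -6, "cut_bottom": -2}
]
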