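[
  {
    "matrix": "BLOSUM62",
    "gap_open": 11,
    "gap_extend": 1,
    "lambda": 0.2400855373844469,
    "K": 0.04245990983398098,
    "method": "moment-matched Gumbel over Smith-Waterman scores of 400 random length-200 uniform-background pairs",
    "seed": 271828
  }
]
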