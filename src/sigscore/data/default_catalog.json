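{
 "sig1": [
  {"name": "Veillonella parvula"},
  {"name": "Veillonella atypica"},
  {"name": "Veillonella dispar"},
  {"name": "Streptococcus salivarius"},
  {"name": "Streptococcus parasanguinis"},
  {"name": "Streptococcus anginosus"},
  {"name": "Streptococcus mitis"},
  {"name": "Streptococcus vestibularis"},
  {"name": "Bifidobacterium dentium"},
  {"name": "SIG1 oral placeholder 01", "placeholder": true},
  {"name": "SIG1 oral placeholder 02", "placeholder": true},
  {"name": "SIG1 oral placeholder 03", "placeholder": true},
  {"name": "SIG1 oral placeholder 04", "placeholder": true},
  {"name": "SIG1 oral placeholder 05", "placeholder": true},
  {"name": "SIG1 oral placeholder 06", "placeholder": true},
  {"name": "Hungatella hathewayi"},
  {"name": "Clostridium innocuum"},
  {"name": "Clostridium symbiosum"},
  {"name": "Enterocloster clostridioformis"},
  {"name": "Enterocloster bolteae"},
  {"name": "Enterocloster aldenensis"},
  {"name": "Enterocloster asparagiformis"},
  {"name": "Erysipelatoclostridium ramosum"},
  {"name": "SIG1 gut placeholder 01", "placeholder": true},
  {"name": "SIG1 gut placeholder 02", "placeholder": true},
  {"name": "SIG1 gut placeholder 03", "placeholder": true},
  {"name": "SIG1 gut placeholder 04", "placeholder": true},
  {"name": "SIG1 gut placeholder 05", "placeholder": true},
  {"name": "SIG1 gut placeholder 06", "placeholder": true},
  {"name": "SIG1 gut placeholder 07", "placeholder": true},
  {"name": "SIG1 gut placeholder 08", "placeholder": true},
  {"name": "SIG1 gut placeholder 09", "placeholder": true},
  {"name": "SIG1 gut placeholder 10", "placeholder": true},
  {"name": "SIG1 gut placeholder 11", "placeholder": true},
  {"name": "SIG1 gut placeholder 12", "placeholder": true},
  {"name": "SIG1 gut placeholder 13", "placeholder": true},
  {"name": "SIG1 gut placeholder 14", "placeholder": true}
 ],
 "sig2": [
  {"name": "Faecalibacterium prausnitzii"},
  {"name": "Faecalibacterium duncaniae"},
  {"name": "Eubacterium rectale"},
  {"name": "Coprococcus comes"},
  {"name": "Roseburia inulinivorans"},
  {"name": "Oscillibacter sp. ER4"},
  {"name": "SIG2 placeholder 01", "placeholder": true},
  {"name": "SIG2 placeholder 02", "placeholder": true},
  {"name": "SIG2 placeholder 03", "placeholder": true},
  {"name": "SIG2 placeholder 04", "placeholder": true},
  {"name": "SIG2 placeholder 05", "placeholder": true},
  {"name": "SIG2 placeholder 06", "placeholder": true},
  {"name": "SIG2 placeholder 07", "placeholder": true},
  {"name": "SIG2 placeholder 08", "placeholder": true},
  {"name": "SIG2 placeholder 09", "placeholder": true},
  {"name": "SIG2 placeholder 10", "placeholder": true},
  {"name": "SIG2 placeholder 11", "placeholder": true},
  {"name": "SIG2 placeholder 12", "placeholder": true},
  {"name": "SIG2 placeholder 13", "placeholder": true},
  {"name": "SIG2 placeholder 14", "placeholder": true},
  {"name": "SIG2 placeholder 15", "placeholder": true},
  {"name": "SIG2 placeholder 16", "placeholder": true},
  {"name": "SIG2 placeholder 17", "placeholder": true},
  {"name": "SIG2 placeholder 18", "placeholder": true},
  {"name": "SIG2 placeholder 19", "placeholder": true},
  {"name": "SIG2 placeholder 20", "placeholder": true},
  {"name": "SIG2 placeholder 21", "placeholder": true},
  {"name": "SIG2 placeholder 22", "placeholder": true},
  {"name": "SIG2 placeholder 23", "placeholder": true},
  {"name": "SIG2 placeholder 24", "placeholder": true},
  {"name": "SIG2 placeholder 25", "placeholder": true},
  {"name": "SIG2 placeholder 26", "placeholder": true},
  {"name": "SIG2 placeholder 27", "placeholder": true},
  {"name": "SIG2 placeholder 28", "placeholder": true},
  {"name": "SIG2 placeholder 29", "placeholder": true},
  {"name": "SIG2 placeholder 30", "placeholder": true},
  {"name": "SIG2 placeholder 31", "placeholder": true},
  {"name": "SIG2 placeholder 32", "placeholder": true},
  {"name": "SIG2 placeholder 33", "placeholder": true},
  {"name": "SIG2 placeholder 34", "placeholder": true},
  {"name": "SIG2 placeholder 35", "placeholder": true},
  {"name": "SIG2 placeholder 36", "placeholder": true},
  {"name": "SIG2 placeholder 37", "placeholder": true},
  {"name": "SIG2 placeholder 38", "placeholder": true},
  {"name": "SIG2 placeholder 39", "placeholder": true}
 ],
 "sig1_oral": [
  "Veillonella parvula",
  "Veillonella atypica",
  "Veillonella dispar",
  "Streptococcus salivarius",
  "Streptococcus parasanguinis",
  "Streptococcus anginosus",
  "Streptococcus mitis",
  "Streptococcus vestibularis",
  "Bifidobacterium dentium",
  "SIG1 oral placeholder 01",
  "SIG1 oral placeholder 02",
  "SIG1 oral placeholder 03",
  "SIG1 oral placeholder 04",
  "SIG1 oral placeholder 05",
  "SIG1 oral placeholder 06"
 ],
 "akkermansia": {"name": "Akkermansia muciniphila", "sgb": "SGB9226"},
 "thresholds": {"t_low": 0.535, "t_high": 0.791, "akk_over_cutoff": 4.799}
}
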