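{
  "comment": "Background amino-acid composition (percent) of the complete UniProtKB/Swiss-Prot database, release 55.0 (Feb 2008), from the public release-notes statistics.",
  "percent": {
    "ALA": 7.86,
    "ARG": 5.35,
    "ASN": 4.17,
    "ASP": 5.30,
    "CYS": 1.53,
    "GLN": 3.93,
    "GLU": 6.59,
    "GLY": 6.93,
    "HIS": 2.28,
    "ILE": 5.91,
    "LEU": 9.64,
    "LYS": 5.89,
    "MET": 2.37,
    "PHE": 3.97,
    "PRO": 4.85,
    "SER": 6.84,
    "THR": 5.41,
    "TRP": 1.13,
    "TYR": 3.08,
    "VAL": 6.69
  }
}
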