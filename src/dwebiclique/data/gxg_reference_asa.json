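{
  "comment": "Total accessible surface area (Angstrom^2) of residue X in an extended Gly-X-Gly tripeptide; NACCESS standard reference values used to convert absolute residue ASA to relative (percent) accessibility.",
  "total": {
    "ALA": 107.95,
    "ARG": 238.76,
    "ASN": 143.94,
    "ASP": 140.39,
    "CYS": 134.28,
    "GLN": 178.50,
    "GLU": 172.25,
    "GLY": 80.10,
    "HIS": 182.88,
    "ILE": 175.12,
    "LEU": 178.63,
    "LYS": 200.78,
    "MET": 194.15,
    "PHE": 199.48,
    "PRO": 136.13,
    "SER": 116.50,
    "THR": 139.27,
    "TRP": 249.36,
    "TYR": 212.76,
    "VAL": 151.44
  }
}
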