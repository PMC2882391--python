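{
  "comment": "Heavy-atom van der Waals radii (Angstrom), Chothia-style set as used by NACCESS. Assignment: backbone carbonyl carbon (atom name C) 1.76; all other carbons 1.87; nitrogens 1.65; oxygens 1.40; sulfurs 1.85; fallback per element below.",
  "by_atom_name": {
    "C": 1.76
  },
  "by_element": {
    "C": 1.87,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.90,
    "SE": 1.90
  },
  "default": 1.80
}
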