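"""Accessibility and sequence-redundancy building blocks.

First part: solvent accessible surface area of a lone atom matches the
closed form 4*pi*(r+1.4)^2, and burying it under a second atom reduces it.
Second part: percent-identity-based redundancy removal keeps one of two
near-identical chain pairs (both-chain similarity above 90%).
"""

import math

import numpy as np

from dwebiclique import compute_sasa
from dwebiclique.model import Atom
from dwebiclique.redundancy import ChainPairSeqs, remove_redundant_pairs

atom = Atom("CA", "C", np.zeros(3), 1.87)
area = compute_sasa([atom])[0]
print(f"isolated atom SASA: {area:.2f} A^2 "
      f"(closed form {4 * math.pi * (1.87 + 1.4) ** 2:.2f})")

neighbour = Atom("CB", "C", np.array([2.0, 0.0, 0.0]), 1.87)
pair = compute_sasa([atom, neighbour])
print(f"with a touching neighbour: {pair[0]:.2f} A^2 (burial)")

seq_a = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQ"
seq_b = seq_a[:30] + "W" + seq_a[31:]  # one substitution: ~98% identical
pairs = [
    ChainPairSeqs("pair-1", seq_a, seq_a[::-1]),
    ChainPairSeqs("pair-2", seq_b, seq_a[::-1]),  # redundant with pair-1
    ChainPairSeqs("pair-3", seq_a, "GSHMGSGSGLEVLFQGPLGSPEFKGSSGSSG"),
]
retained, removed = remove_redundant_pairs(pairs, s=90.0)
print("retained:", [p.pair_id for p in retained])
print("removed: ", [f"{a} (matches {b})" for a, b in removed])
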