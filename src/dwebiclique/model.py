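"""Core data model: heavy-atom structures and interaction records.

The model is deliberately minimal: parsed chains of standard amino-acid
residues, each residue holding its heavy atoms with coordinates and van der
Waals radii. Hydrogens, waters and ligands never enter the model; selenomethionine
is mapped to methionine at parse time (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Tuple

import numpy as np

#: The 20 standard amino acids, 3-letter code -> 1-letter code.
THREE_TO_ONE: Dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
STANDARD_RESIDUES = frozenset(THREE_TO_ONE)
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Residue identity within a structure: (chain_id, seq_num, icode).
ResidueId = Tuple[str, int, str]


class EmptyStructureError(ValueError):
    """Raised when a parsed file contains no standard amino-acid residues."""


class UnknownChainError(KeyError):
    """Raised when a requested chain identifier is absent from a structure."""


@dataclass(frozen=True)
class Atom:
    """A heavy atom with coordinates (Å) and a van der Waals radius (Å)."""

    name: str
    element: str
    coords: np.ndarray  # shape (3,)
    vdw_radius: float
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        if self.element.upper() in ("H", "D"):
            raise ValueError("hydrogens are excluded from the model")
        if not self.vdw_radius > 0:
            raise ValueError(f"non-positive vdW radius for atom {self.name!r}")


@dataclass
class Residue:
    """One standard amino-acid residue and its heavy atoms."""

    chain_id: str
    seq_num: int
    icode: str
    res_type: str
    atoms: List[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.res_type not in STANDARD_RESIDUES:
            raise ValueError(f"nonstandard residue type {self.res_type!r}")

    @property
    def rid(self) -> ResidueId:
        return (self.chain_id, self.seq_num, self.icode)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE[self.res_type]

    def atom_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def atom_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def __repr__(self) -> str:  # compact, for logs and asserts
        return f"<{self.res_type} {self.chain_id}:{self.seq_num}{self.icode}>"


@dataclass
class Structure:
    """Parsed structure: ordered residues per chain (first model only)."""

    pdb_id: str
    chains: Dict[str, List[Residue]] = field(default_factory=dict)

    def chain(self, chain_id: str) -> List[Residue]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise UnknownChainError(
                f"chain {chain_id!r} not in structure {self.pdb_id!r} "
                f"(has {sorted(self.chains)})"
            ) from None

    def residues(self) -> Iterator[Residue]:
        for chain in self.chains.values():
            yield from chain

    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())


#: Interaction class labels used throughout.
CLASS_LABELS = ("obligate", "non_obligate", "crystal_packing")


@dataclass
class InteractionRecord:
    """A pair of interacting chains from one structure, with a class label."""

    interaction_id: str
    structure: Structure
    chain_a: str
    chain_b: str
    class_label: str

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(
                f"class_label must be one of {CLASS_LABELS}, got {self.class_label!r}"
            )
        if self.chain_a == self.chain_b:
            raise ValueError("chain_a and chain_b must be distinct identifiers")

    def chain_residues(self) -> Tuple[List[Residue], List[Residue]]:
        return self.structure.chain(self.chain_a), self.structure.chain(self.chain_b)


def merge_structures(a: Structure, b: Structure, rename_b: Dict[str, str]) -> Structure:
    """Combine two structures (e.g. crystal-packing copies from distinct files)
    into one, renaming chains of ``b`` to avoid identifier clashes."""
    merged = Structure(pdb_id=f"{a.pdb_id}+{b.pdb_id}", chains=dict(a.chains))
    for cid, residues in b.chains.items():
        new_id = rename_b.get(cid, cid)
        if new_id in merged.chains:
            raise ValueError(f"chain id clash after rename: {new_id!r}")
        renamed = [
            Residue(new_id, r.seq_num, r.icode, r.res_type, list(r.atoms))
            for r in residues
        ]
        merged.chains[new_id] = renamed
    return merged
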