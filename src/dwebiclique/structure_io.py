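"""Read and write PDB-format structures into the heavy-atom model.

Parsing policy (all standard for interface work):

* first model only;
* hydrogens/deuteriums, waters and HETATM ligands are discarded;
* MSE (selenomethionine) is mapped to MET by default; other nonstandard
  residues are dropped with a logged warning;
* for alternate locations only the highest-occupancy conformer is kept,
  ties broken by altloc letter order;
* every retained atom is assigned a van der Waals radius from the packaged
  Chothia/NACCESS-style radius table.

Biopython's ``Bio.PDB`` does the low-level record parsing; this module owns
the filtering policy and the conversion into :mod:`dwebiclique.model` types.
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from importlib import resources
from pathlib import Path
from typing import Dict, Union

from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from .model import (
    Atom,
    EmptyStructureError,
    Residue,
    Structure,
    THREE_TO_ONE,
    STANDARD_RESIDUES,
)

logger = logging.getLogger(__name__)

_MSE_TO_MET_ATOM = {"SE": "SD"}  # selenium takes sulfur's place


class RadiusTable:
    """Van der Waals radius lookup: atom-name override, then element."""

    def __init__(self, by_atom_name: Dict[str, float], by_element: Dict[str, float],
                 default: float):
        self.by_atom_name = dict(by_atom_name)
        self.by_element = {k.upper(): v for k, v in by_element.items()}
        self.default = default

    @classmethod
    def packaged(cls) -> "RadiusTable":
        with resources.files("dwebiclique.data").joinpath("vdw_radii.json").open() as fh:
            raw = json.load(fh)
        return cls(raw["by_atom_name"], raw["by_element"], raw["default"])

    def radius(self, atom_name: str, element: str) -> float:
        if atom_name in self.by_atom_name:
            return self.by_atom_name[atom_name]
        return self.by_element.get(element.upper(), self.default)


def _guess_element(atom_name: str, element_field: str) -> str:
    el = element_field.strip().upper()
    if el:
        return el
    # Fall back to PDB atom-name conventions: strip digits, take first letter(s).
    name = atom_name.strip()
    if name[:2].upper() in ("SE",):
        return "SE"
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def read_structure(
    path: Union[str, Path],
    radius_table: RadiusTable | None = None,
    map_mse: bool = True,
    pdb_id: str | None = None,
) -> Structure:
    """Parse a PDB-format file into a :class:`Structure`.

    Raises :class:`EmptyStructureError` if no standard residues survive
    filtering, and ``OSError`` for unreadable files.
    """
    path = Path(path)
    radius_table = radius_table or RadiusTable.packaged()
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        bio_struct = parser.get_structure(path.stem, str(path))
    try:
        model = next(iter(bio_struct))  # first model only
    except StopIteration:
        raise EmptyStructureError(f"{path}: no models found") from None

    out = Structure(pdb_id=pdb_id or path.stem)
    for bio_chain in model:
        residues = []
        for bio_res in bio_chain:
            hetflag, seq_num, icode = bio_res.id
            resname = bio_res.get_resname().strip()
            if hetflag == "W":
                continue
            if resname == "MSE" and map_mse:
                res_type = "MET"
            elif resname in STANDARD_RESIDUES and hetflag == " ":
                res_type = resname
            else:
                if hetflag == " " and resname not in STANDARD_RESIDUES:
                    logger.warning(
                        "%s: dropping nonstandard residue %s %s%s%s",
                        path.name, resname, bio_chain.id, seq_num, icode.strip(),
                    )
                continue
            atoms = []
            for bio_atom in bio_res:
                # DisorderedAtom: keep highest occupancy, ties by altloc letter.
                if bio_atom.is_disordered():
                    conformers = bio_atom.disordered_get_list()
                    conformers.sort(key=lambda a: (-(a.get_occupancy() or 0.0),
                                                   a.get_altloc()))
                    bio_atom = conformers[0]
                element = _guess_element(bio_atom.get_name(), bio_atom.element or "")
                if element in ("H", "D"):
                    continue
                name = bio_atom.get_name().strip()
                if resname == "MSE" and map_mse:
                    name = _MSE_TO_MET_ATOM.get(name, name)
                    if element == "SE":
                        element = "S"
                atoms.append(
                    Atom(
                        name=name,
                        element=element,
                        coords=bio_atom.get_coord(),
                        vdw_radius=radius_table.radius(name, element),
                        occupancy=bio_atom.get_occupancy() or 1.0,
                        altloc=(bio_atom.get_altloc() or "").strip(),
                    )
                )
            if atoms:
                residues.append(
                    Residue(bio_chain.id, seq_num, icode.strip(), res_type, atoms)
                )
        if residues:
            out.chains[bio_chain.id] = residues

    if not out.chains:
        raise EmptyStructureError(f"{path}: no standard amino-acid residues")
    return out


def chain_sequence(structure: Structure, chain_id: str) -> str:
    """One-letter sequence of a chain, in residue order."""
    chain = structure.chain(chain_id)
    if not chain:
        raise EmptyStructureError(
            f"chain {chain_id!r} of {structure.pdb_id!r} is empty after filtering"
        )
    return "".join(THREE_TO_ONE[r.res_type] for r in chain)


def write_pdb(structure: Structure) -> str:
    """Serialize the model back to minimal PDB-format ATOM records.

    Round-trips through :func:`read_structure`: parsing the output yields an
    identical model (used by tests and the synthetic generator).
    """
    buf = io.StringIO()
    serial = 0
    for chain_id, residues in structure.chains.items():
        for res in residues:
            for atom in res.atoms:
                serial += 1
                name = atom.name
                # PDB atom-name column alignment: 1-letter elements start col 14.
                if len(name) < 4 and len(atom.element) == 1:
                    name_field = f" {name:<3s}"
                else:
                    name_field = f"{name:<4s}"
                x, y, z = atom.coords
                buf.write(
                    f"ATOM  {serial:5d} {name_field}{'':1s}{res.res_type:>3s} "
                    f"{chain_id:1s}{res.seq_num:4d}{res.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}\n"
                )
        buf.write("TER\n")
    buf.write("END\n")
    return buf.getvalue()


def dump_json(structure: Structure) -> str:
    """Debug dump of the parsed model as JSON."""
    payload = {
        "pdb_id": structure.pdb_id,
        "chains": {
            cid: [
                {
                    "seq_num": r.seq_num,
                    "icode": r.icode,
                    "res_type": r.res_type,
                    "atoms": [
                        {
                            "name": a.name,
                            "element": a.element,
                            "coords": [round(float(c), 3) for c in a.coords],
                            "vdw_radius": a.vdw_radius,
                        }
                        for a in r.atoms
                    ],
                }
                for r in residues
            ]
            for cid, residues in structure.chains.items()
        },
    }
    return json.dumps(payload, indent=2)
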