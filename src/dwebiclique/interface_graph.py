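"""Residue contacts and the accessibility-filtered contact bipartite graph.

Two residues from opposite chains are in contact when the minimum over all
heavy-atom pairs of the surface gap

    gap = d(a, a') - r(a) - r(a')

is strictly below the water van der Waals diameter ``d_water`` = 2.75 Å:
no water molecule fits between them. The double-water-exclusion bipartite
keeps only contact residues that are themselves dry in the bound complex —
relative accessibility strictly below ``t_ra`` = 36 % — and prunes vertices
left without partners. Maximal bicliques of this graph are the hot-spot
candidates mined downstream.

Interface coverage statistics use the coarser interface definition:
contact residues plus their same-chain neighbours within 6 Å CA–CA.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Sequence, Set, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .model import Atom, InteractionRecord, Residue, ResidueId
from .sasa import residues_sasa

logger = logging.getLogger(__name__)

D_WATER = 2.75  # van der Waals diameter of water, Å
T_RA = 36.0     # relative-accessibility burial threshold, percent
CA_CUTOFF = 6.0  # CA-CA nearby-residue cutoff, Å


def atom_gap(a1: Atom, a2: Atom) -> float:
    """Surface-to-surface gap between two atoms (may be negative)."""
    d = float(np.linalg.norm(a1.coords - a2.coords))
    return d - a1.vdw_radius - a2.vdw_radius


def min_residue_gap(r1: Residue, r2: Residue) -> float:
    """Minimum atom-pair surface gap between two residues."""
    c1, c2 = r1.atom_coords(), r2.atom_coords()
    d = np.linalg.norm(c1[:, None, :] - c2[None, :, :], axis=-1)
    gaps = d - r1.atom_radii()[:, None] - r2.atom_radii()[None, :]
    return float(gaps.min())


def count_contact_atom_pairs(r1: Residue, r2: Residue, d_water: float = D_WATER) -> int:
    """Number of atom pairs with gap strictly below ``d_water``."""
    c1, c2 = r1.atom_coords(), r2.atom_coords()
    d = np.linalg.norm(c1[:, None, :] - c2[None, :, :], axis=-1)
    gaps = d - r1.atom_radii()[:, None] - r2.atom_radii()[None, :]
    return int((gaps < d_water).sum())


def residues_contact(r1: Residue, r2: Residue, d_water: float = D_WATER) -> bool:
    """True iff the closest heavy-atom pair has gap strictly below ``d_water``."""
    return min_residue_gap(r1, r2) < d_water


def _contact_pairs(
    chain_a: Sequence[Residue],
    chain_b: Sequence[Residue],
    d_water: float,
    min_atom_pairs: int = 1,
) -> Set[Tuple[int, int]]:
    """Indices (i, j) of contacting cross-chain residue pairs.

    A KD-tree over atoms prunes the quadratic pair scan: two atoms can only
    contact if their centers are within r1 + r2 + d_water, bounded by
    2 * r_max + d_water.
    """
    if not chain_a or not chain_b:
        return set()
    atoms_a = [(i, a) for i, r in enumerate(chain_a) for a in r.atoms]
    atoms_b = [(j, a) for j, r in enumerate(chain_b) for a in r.atoms]
    coords_a = np.array([a.coords for _, a in atoms_a])
    coords_b = np.array([a.coords for _, a in atoms_b])
    r_max = max(
        max(a.vdw_radius for _, a in atoms_a),
        max(a.vdw_radius for _, a in atoms_b),
    )
    reach = 2.0 * r_max + d_water
    tree_b = cKDTree(coords_b)
    candidates: Set[Tuple[int, int]] = set()
    for (i, _), hits in zip(atoms_a, cKDTree(coords_a).query_ball_tree(tree_b, reach)):
        for h in hits:
            candidates.add((i, atoms_b[h][0]))
    pairs = set()
    for i, j in candidates:
        if count_contact_atom_pairs(chain_a[i], chain_b[j], d_water) >= min_atom_pairs:
            pairs.add((i, j))
    return pairs


@dataclass
class DWEBipartite:
    """Accessibility-filtered residue-contact bipartite graph of one interaction.

    ``v1``/``v2`` hold the retained residues of each chain; ``edges`` are
    (v1-index, v2-index) pairs. Every vertex is buried (relative ASA < t_ra)
    and has degree >= 1.
    """

    interaction_id: str
    v1: List[Residue] = field(default_factory=list)
    v2: List[Residue] = field(default_factory=list)
    edges: Set[Tuple[int, int]] = field(default_factory=set)

    @property
    def types1(self) -> List[str]:
        return [r.res_type for r in self.v1]

    @property
    def types2(self) -> List[str]:
        return [r.res_type for r in self.v2]

    def is_empty(self) -> bool:
        return not self.edges

    def degree_ok(self) -> bool:
        d1 = {i for i, _ in self.edges}
        d2 = {j for _, j in self.edges}
        return d1 == set(range(len(self.v1))) and d2 == set(range(len(self.v2)))


def from_type_lists(
    interaction_id: str,
    types1: Sequence[str],
    types2: Sequence[str],
    edges: Iterable[Tuple[int, int]],
) -> DWEBipartite:
    """Build a bipartite from residue-type labels only (no geometry).

    Vertices get synthetic residue identities; used by the graph-level
    generator and anywhere mining is exercised without structures.
    """
    v1 = [Residue("A", i + 1, "", t) for i, t in enumerate(types1)]
    v2 = [Residue("B", j + 1, "", t) for j, t in enumerate(types2)]
    # synthetic vertices carry a single dummy CA atom so downstream code
    # that only reads types/ids still works; geometry is meaningless here
    for k, r in enumerate(v1 + v2):
        r.atoms.append(
            Atom("CA", "C", np.array([float(k), 0.0, 0.0]), 1.87)
        )
    return DWEBipartite(interaction_id, v1, v2, set(edges))


def build_dwe_bipartite(
    rec: InteractionRecord,
    d_water: float = D_WATER,
    t_ra: float = T_RA,
    min_atom_pairs: int = 1,
    asa_context: str = "complex",
    n_sphere_points: int = 960,
) -> DWEBipartite:
    """Construct the filtered contact bipartite for one interaction.

    Steps: (1) all cross-chain contact edges; (2) drop vertices whose
    relative ASA (computed in the bound complex by default, or per isolated
    chain with ``asa_context='isolated'``) is >= ``t_ra``; (3) iteratively
    drop vertices left with degree 0. No contacts at all yields an empty
    bipartite, which simply contributes no bicliques.
    """
    if asa_context not in ("complex", "isolated"):
        raise ValueError("asa_context must be 'complex' or 'isolated'")
    chain_a, chain_b = rec.chain_residues()
    pairs = _contact_pairs(chain_a, chain_b, d_water, min_atom_pairs)
    if not pairs:
        return DWEBipartite(rec.interaction_id)

    ia = sorted({i for i, _ in pairs})
    jb = sorted({j for _, j in pairs})

    if asa_context == "complex":
        sasa = residues_sasa(chain_a + chain_b, n_sphere_points=n_sphere_points)
        rel = sasa.per_residue_relative
    else:
        rel = {}
        for chain in (chain_a, chain_b):
            rel.update(
                residues_sasa(chain, n_sphere_points=n_sphere_points)
                .per_residue_relative
            )

    keep_a = {i for i in ia if rel[chain_a[i].rid] < t_ra}
    keep_b = {j for j in jb if rel[chain_b[j].rid] < t_ra}
    kept = {(i, j) for i, j in pairs if i in keep_a and j in keep_b}

    # degree-0 pruning to a fixed point (one pass suffices for a bipartite
    # edge-subset, but iterate for safety)
    while True:
        da = {i for i, _ in kept}
        db = {j for _, j in kept}
        if da == keep_a and db == keep_b:
            break
        keep_a, keep_b = da, db
        kept = {(i, j) for i, j in kept if i in keep_a and j in keep_b}

    v1 = [chain_a[i] for i in sorted(keep_a)]
    v2 = [chain_b[j] for j in sorted(keep_b)]
    remap_a = {i: k for k, i in enumerate(sorted(keep_a))}
    remap_b = {j: k for k, j in enumerate(sorted(keep_b))}
    edges = {(remap_a[i], remap_b[j]) for i, j in kept}
    return DWEBipartite(rec.interaction_id, v1, v2, edges)


@dataclass
class InterfaceClasses:
    """Contact and nearby residues per side; interface = union per side."""

    contact_a: Set[ResidueId] = field(default_factory=set)
    contact_b: Set[ResidueId] = field(default_factory=set)
    nearby_a: Set[ResidueId] = field(default_factory=set)
    nearby_b: Set[ResidueId] = field(default_factory=set)

    @property
    def interface_a(self) -> Set[ResidueId]:
        return self.contact_a | self.nearby_a

    @property
    def interface_b(self) -> Set[ResidueId]:
        return self.contact_b | self.nearby_b


def _nearby(
    chain: Sequence[Residue],
    contact_ids: Set[ResidueId],
    ca_cutoff: float,
) -> Set[ResidueId]:
    with_ca = [(r, r.get_atom("CA")) for r in chain]
    missing = [r for r, ca in with_ca if ca is None]
    for r in missing:
        logger.warning("residue %r has no CA atom; excluded from nearby computation", r)
    coords = np.array([ca.coords for _, ca in with_ca if ca is not None])
    residues = [r for r, ca in with_ca if ca is not None]
    contact_idx = [k for k, r in enumerate(residues) if r.rid in contact_ids]
    if not contact_idx or len(residues) == 0:
        return set()
    tree = cKDTree(coords)
    nearby: Set[ResidueId] = set()
    for k in contact_idx:
        for h in tree.query_ball_point(coords[k], ca_cutoff):
            rid = residues[h].rid
            if rid not in contact_ids:
                # strict < cutoff: query_ball_point includes the boundary
                if float(np.linalg.norm(coords[h] - coords[k])) < ca_cutoff:
                    nearby.add(rid)
    return nearby


def interface_classes(
    rec: InteractionRecord,
    d_water: float = D_WATER,
    ca_cutoff: float = CA_CUTOFF,
    min_atom_pairs: int = 1,
) -> InterfaceClasses:
    """Contact residues (heavy-atom gap < d_water) and nearby residues
    (same-chain CA within < ca_cutoff of a contact residue's CA)."""
    chain_a, chain_b = rec.chain_residues()
    pairs = _contact_pairs(chain_a, chain_b, d_water, min_atom_pairs)
    out = InterfaceClasses()
    out.contact_a = {chain_a[i].rid for i, _ in pairs}
    out.contact_b = {chain_b[j].rid for _, j in pairs}
    out.nearby_a = _nearby(chain_a, out.contact_a, ca_cutoff)
    out.nearby_b = _nearby(chain_b, out.contact_b, ca_cutoff)
    return out


class UndefinedFractionError(ZeroDivisionError):
    """Coverage fraction requested over an empty residue set."""


def biclique_coverage(
    biclique_members: Iterable[FrozenSet[ResidueId]],
    classes: Iterable[InterfaceClasses],
) -> Tuple[float, float]:
    """Pooled coverage of biclique residues over contact and interface residues.

    ``biclique_members``: per interaction, the set of residue ids appearing
    in any qualifying biclique. Returns percentages (over all contact
    residues, over all interface residues) pooled across interactions.
    """
    member_total = 0
    contact_total = 0
    interface_total = 0
    for members, cls in zip(biclique_members, classes):
        contact = cls.contact_a | cls.contact_b
        interface = cls.interface_a | cls.interface_b
        member_total += len(members & interface)
        contact_total += len(contact)
        interface_total += len(interface)
    if contact_total == 0 or interface_total == 0:
        raise UndefinedFractionError("no contact residues in the pooled dataset")
    return (
        100.0 * member_total / contact_total,
        100.0 * member_total / interface_total,
    )


def serialize_bipartite(g: DWEBipartite, params: Dict | None = None) -> str:
    """TSV edge list with a JSON parameter header line (miner input format)."""
    lines = [f"#params\t{json.dumps(params or {}, sort_keys=True)}"]
    for i, j in sorted(g.edges):
        a, b = g.v1[i], g.v2[j]
        lines.append(
            f"{g.interaction_id}\t"
            f"{a.chain_id}:{a.seq_num}:{a.icode}:{a.res_type}\t"
            f"{b.chain_id}:{b.seq_num}:{b.icode}:{b.res_type}"
        )
    return "\n".join(lines) + "\n"


def parse_bipartite_tsv(text: str) -> List[DWEBipartite]:
    """Inverse of :func:`serialize_bipartite` (possibly many interactions)."""
    graphs: Dict[str, Dict] = {}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        interaction_id, a_spec, b_spec = line.split("\t")
        g = graphs.setdefault(interaction_id, {"v1": {}, "v2": {}, "edges": []})

        def _vertex(side: Dict, spec: str) -> int:
            if spec not in side:
                side[spec] = len(side)
            return side[spec]

        g["edges"].append((_vertex(g["v1"], a_spec), _vertex(g["v2"], b_spec)))

    out = []
    for interaction_id, g in graphs.items():
        def _mk(side: Dict) -> List[Residue]:
            residues = [None] * len(side)
            for spec, idx in side.items():
                chain_id, seq_num, icode, res_type = spec.split(":")
                r = Residue(chain_id, int(seq_num), icode, res_type)
                r.atoms.append(Atom("CA", "C", np.zeros(3), 1.87))
                residues[idx] = r
            return residues

        out.append(
            DWEBipartite(interaction_id, _mk(g["v1"]), _mk(g["v2"]), set(g["edges"]))
        )
    return out
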