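"""Ground-truthed synthetic inputs for every pipeline stage.

Two generators:

* :func:`make_interface_structure` emits a PDB-format two-chain structure
  with a planted, geometrically realized contact biclique: a compact core
  on each chain whose cross-chain residue pairs all contact (closest
  heavy-atom gap < 2.75 Å), exposed rim residues that touch the opposite
  core but stay above the 36 % relative-accessibility threshold, and
  backing shells that bury the cores without ever contacting the other
  chain. The generator verifies its own claims (brute-force gap scan plus
  an SASA evaluation) and raises :class:`GenerationError` if the requested
  geometry cannot be realized.

* :func:`random_bipartite_db` emits databases of vertex-labelled bipartite
  graphs with planted complete-biclique patterns of known class and copy
  number, for exercising the miner without any geometry.

Residues are minimal stubs (N, CA, C, O and a CB apex; shells use
numbered carbon atoms) — enough for gap and SASA computations, with no
pretence of rotamer-level realism. Everything is deterministic per seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

from .biclique import BicliquePattern, make_pattern
from .interface_graph import DWEBipartite, D_WATER, T_RA, from_type_lists
from .model import Atom, InteractionRecord, Residue, ResidueId, Structure
from .sasa import residues_sasa
from .structure_io import RadiusTable, write_pdb


class GenerationError(RuntimeError):
    """The requested synthetic geometry could not be realized."""


@dataclass
class FixtureTruth:
    """What was planted, for verification by tests and the pipeline."""

    seed: int
    buried: bool = True  # False: rim-less layout, everything exposed,
    #                      the filtered bipartite is expected to be empty
    core_a: List[ResidueId] = field(default_factory=list)
    core_b: List[ResidueId] = field(default_factory=list)
    rim: List[ResidueId] = field(default_factory=list)
    shell: List[ResidueId] = field(default_factory=list)
    edges: Set[Tuple[ResidueId, ResidueId]] = field(default_factory=set)
    planted_patterns: List[Tuple[BicliquePattern, str, int]] = field(
        default_factory=list
    )  # (pattern, class_label, copies planted)


# Layout constants (Å). Chosen so that, with NACCESS-style radii, every
# core cross pair contacts through the CB apexes, rim residues contact the
# opposite core while keeping more than a third of their reference area,
# and shell atoms stay beyond contact reach of the other chain.
_CORE_RADIUS_STEP = 1.45   # ring radius grows with core size
_CHAIN_GAP = 5.0           # z offset between the two core planes
_RIM_RADIUS = 5.4
_RIM_Z = 1.1
_SHELL_PLATE_Z = -3.6
_SHELL_PLATE_RADIUS = 5.2
_SHELL_PLATE_SPACING = 1.7
_SHELL_RING_RADIUS = 3.3
_SHELL_RING_Z = -2.9
_JITTER = 0.04

_DEFAULT_CORE_TYPES = ("LEU", "VAL", "ILE", "PHE", "MET", "TRP", "TYR", "ALA")


def _ring(n: int, radius: float, phase: float = 0.0) -> List[Tuple[float, float]]:
    if n == 1:
        return [(0.0, 0.0)]
    return [
        (radius * math.cos(phase + 2 * math.pi * k / n),
         radius * math.sin(phase + 2 * math.pi * k / n))
        for k in range(n)
    ]


def _stub_residue(
    chain_id: str,
    seq_num: int,
    res_type: str,
    center: Tuple[float, float],
    z0: float,
    flip: bool,
    radii: RadiusTable,
    rng: np.random.Generator,
    with_apex: bool = True,
) -> Residue:
    """Five-atom residue stub. ``flip`` mirrors it for the upper chain so
    the CB apex points at the partner chain."""
    x, y = center
    s = -1.0 if flip else 1.0

    def _at(name: str, element: str, dx: float, dy: float, dz: float) -> Atom:
        jit = rng.uniform(-_JITTER, _JITTER, size=3)
        coords = np.array([x + dx + jit[0], y + dy + jit[1], z0 + s * dz + jit[2]])
        return Atom(name, element, coords, radii.radius(name, element))

    atoms = [
        _at("CA", "C", 0.0, 0.0, -0.8),
        _at("N", "N", -0.9, 0.0, -1.2),
        _at("C", "C", 0.9, 0.0, -1.2),
        _at("O", "O", 0.0, -0.9, -1.4),
    ]
    if with_apex:
        atoms.append(_at("CB", "C", 0.0, 0.0, 1.2))
    return Residue(chain_id, seq_num, "", res_type, atoms)


def _shell_residues(
    chain_id: str,
    start_seq: int,
    z_sign: float,
    z_offset: float,
    radii: RadiusTable,
) -> List[Residue]:
    """Backing plate plus a lateral ring, grouped into GLY 'shell' residues.

    Shell atoms are placed exactly (no jitter): their clearance from the
    other chain is the tightest constraint in the layout.
    """
    points: List[Tuple[float, float, float]] = []
    # hexagonal-ish plate below (above) the core
    n_r = int(_SHELL_PLATE_RADIUS / _SHELL_PLATE_SPACING)
    for ix in range(-n_r, n_r + 1):
        for iy in range(-n_r, n_r + 1):
            px = ix * _SHELL_PLATE_SPACING
            py = iy * _SHELL_PLATE_SPACING + (0.5 * _SHELL_PLATE_SPACING if ix % 2 else 0)
            if math.hypot(px, py) <= _SHELL_PLATE_RADIUS:
                points.append((px, py, _SHELL_PLATE_Z))
    # lateral ring around the core body
    for px, py in _ring(12, _SHELL_RING_RADIUS):
        points.append((px, py, _SHELL_RING_Z))

    residues: List[Residue] = []
    chunk = 12  # atoms per shell residue
    for r_idx, chunk_start in enumerate(range(0, len(points), chunk)):
        atoms = []
        for a_idx, (px, py, pz) in enumerate(points[chunk_start:chunk_start + chunk]):
            coords = np.array([px, py, z_offset + z_sign * pz])
            atoms.append(Atom(f"C{a_idx + 1}", "C", coords, radii.radius("CX", "C")))
        residues.append(Residue(chain_id, start_seq + r_idx, "", "GLY", atoms))
    return residues


def make_interface_structure(
    n_core_a: int,
    n_core_b: int,
    n_rim: int,
    seed: int,
    core_types_a: Sequence[str] | None = None,
    core_types_b: Sequence[str] | None = None,
    verify: bool = True,
) -> Tuple[str, FixtureTruth]:
    """PDB text of a planted two-chain interface plus its ground truth.

    The planted contact bipartite is the complete biclique between the
    ``n_core_a`` chain-A and ``n_core_b`` chain-B core residues. ``n_rim``
    exposed rim residues (alternating between the chains) each contact the
    opposite core but fail the burial filter. Same seed, same bytes.

    With ``n_rim = 0`` no rim or shell is emitted: every residue stays
    solvent-exposed (verified; feasible only for small cores, larger
    requests raise :class:`GenerationError`), so the accessibility filter
    empties the bipartite even though the contact edges exist.
    """
    if n_core_a < 1 or n_core_b < 1 or n_rim < 0:
        raise GenerationError("core sizes must be >= 1 and n_rim >= 0")
    rng = np.random.default_rng(seed)
    radii = RadiusTable.packaged()
    types_a = list(core_types_a or itertools.islice(
        itertools.cycle(_DEFAULT_CORE_TYPES), n_core_a))
    types_b = list(core_types_b or itertools.islice(
        itertools.cycle(_DEFAULT_CORE_TYPES[::-1]), n_core_b))
    if len(types_a) != n_core_a or len(types_b) != n_core_b:
        raise GenerationError("core type lists must match the core sizes")

    truth = FixtureTruth(seed=seed, buried=n_rim > 0)
    struct = Structure(pdb_id=f"synthetic-{seed}")

    # chain A: core at z=0 pointing up; chain B: core at z=_CHAIN_GAP pointing down
    ra = _CORE_RADIUS_STEP * max(0, n_core_a - 1) ** 0.5
    rb = _CORE_RADIUS_STEP * max(0, n_core_b - 1) ** 0.5
    chain_a: List[Residue] = []
    chain_b: List[Residue] = []
    for k, ((x, y), t) in enumerate(zip(_ring(n_core_a, ra), types_a)):
        chain_a.append(_stub_residue("A", k + 1, t, (x, y), 0.0, False, radii, rng))
    for k, ((x, y), t) in enumerate(zip(_ring(n_core_b, rb, phase=0.3), types_b)):
        chain_b.append(_stub_residue("B", k + 1, t, (x, y), _CHAIN_GAP, True, radii, rng))
    truth.core_a = [r.rid for r in chain_a]
    truth.core_b = [r.rid for r in chain_b]
    truth.edges = {(a.rid, b.rid) for a in chain_a for b in chain_b}

    # rim: alternate chains around the interface perimeter, apex-less GLY
    n_rim_a = (n_rim + 1) // 2
    seq_a, seq_b = n_core_a, n_core_b
    rim_positions = _ring(max(n_rim, 1), _RIM_RADIUS, phase=0.15)
    for k in range(n_rim):
        x, y = rim_positions[k]
        if k % 2 == 0:
            seq_a += 1
            res = _stub_residue("A", seq_a, "GLY", (x, y), _RIM_Z, False,
                                radii, rng, with_apex=False)
            chain_a.append(res)
        else:
            seq_b += 1
            res = _stub_residue("B", seq_b, "GLY", (x, y), _CHAIN_GAP - _RIM_Z,
                                True, radii, rng, with_apex=False)
            chain_b.append(res)
        truth.rim.append(res.rid)

    # shells bury the cores from behind; they never touch the other chain
    if n_rim > 0:
        shell_a = _shell_residues("A", seq_a + 1, 1.0, 0.0, radii)
        shell_b = _shell_residues("B", seq_b + 1, -1.0, _CHAIN_GAP, radii)
        chain_a.extend(shell_a)
        chain_b.extend(shell_b)
        truth.shell = [r.rid for r in shell_a + shell_b]

    struct.chains["A"] = chain_a
    struct.chains["B"] = chain_b
    if verify:
        _verify_interface(struct, truth)
    return write_pdb(struct), truth


def _min_gap(r1: Residue, r2: Residue) -> float:
    c1, c2 = r1.atom_coords(), r2.atom_coords()
    d = np.linalg.norm(c1[:, None, :] - c2[None, :, :], axis=-1)
    return float((d - r1.atom_radii()[:, None] - r2.atom_radii()[None, :]).min())


def _verify_interface(struct: Structure, truth: FixtureTruth) -> None:
    """Generator self-check of the planted facts; GenerationError on failure."""
    chain_a, chain_b = struct.chains["A"], struct.chains["B"]
    by_rid = {r.rid: r for r in chain_a + chain_b}
    core_a = [by_rid[rid] for rid in truth.core_a]
    core_b = [by_rid[rid] for rid in truth.core_b]
    rim = [by_rid[rid] for rid in truth.rim]
    shell = [by_rid[rid] for rid in truth.shell]

    for a in core_a:
        for b in core_b:
            if not _min_gap(a, b) < D_WATER:
                raise GenerationError(
                    f"planted edge {a!r}-{b!r} does not contact; "
                    "core too large for the layout"
                )
    for r in rim:
        opposite = core_b if r.chain_id == "A" else core_a
        if not any(_min_gap(r, c) < D_WATER for c in opposite):
            raise GenerationError(f"rim residue {r!r} fails to contact the opposite core")
    for s in shell:
        opposite = chain_b if s.chain_id == "A" else chain_a
        for o in opposite:
            if _min_gap(s, o) < D_WATER:
                raise GenerationError(f"shell residue {s!r} contacts the other chain")

    rel = residues_sasa(chain_a + chain_b).per_residue_relative
    if truth.buried:
        for r in core_a + core_b:
            if not rel[r.rid] < T_RA:
                raise GenerationError(
                    f"core residue {r!r} is too exposed ({rel[r.rid]:.1f}% rASA)"
                )
        for r in rim:
            if not rel[r.rid] > T_RA:
                raise GenerationError(
                    f"rim residue {r!r} is too buried ({rel[r.rid]:.1f}% rASA)"
                )
    else:
        for r in core_a + core_b:
            if not rel[r.rid] > T_RA:
                raise GenerationError(
                    f"rim-less layout infeasible: {r!r} is buried "
                    f"({rel[r.rid]:.1f}% rASA); use smaller cores"
                )


def planted_interaction(
    n_core_a: int,
    n_core_b: int,
    n_rim: int,
    seed: int,
    class_label: str = "obligate",
    **kwargs,
) -> Tuple[InteractionRecord, FixtureTruth, str]:
    """Convenience wrapper: generate, parse-free record plus truth and text."""
    from .structure_io import read_structure  # cycle-free local import
    import io as _io
    import tempfile
    import os

    pdb_text, truth = make_interface_structure(n_core_a, n_core_b, n_rim, seed, **kwargs)
    with tempfile.NamedTemporaryFile("w", suffix=".pdb", delete=False) as fh:
        fh.write(pdb_text)
        path = fh.name
    try:
        struct = read_structure(path, pdb_id=f"synthetic-{seed}")
    finally:
        os.unlink(path)
    rec = InteractionRecord(
        interaction_id=f"synthetic-{seed}-A:B",
        structure=struct,
        chain_a="A",
        chain_b="B",
        class_label=class_label,
    )
    return rec, truth, pdb_text


def random_bipartite_db(
    n_graphs: int,
    side_sizes: Tuple[int, int],
    density: float,
    planted: Sequence[Tuple[BicliquePattern, str, int]] = (),
    class_mix: Dict[str, int] | None = None,
    seed: int = 0,
) -> Tuple[List[DWEBipartite], Dict[str, str], FixtureTruth]:
    """Random vertex-typed bipartite graphs with planted biclique patterns.

    ``side_sizes`` is an inclusive (lo, hi) range for each side's vertex
    count; edges are Bernoulli(density); vertex types are uniform over the
    20 codes. ``class_mix`` maps class label -> number of graphs (defaults
    to all 'obligate'); planted entries (pattern, class, n_copies) are
    inserted as complete bicliques into the first ``n_copies`` graphs of
    their class. Planted support is a lower bound on mined support except
    at density 0, where it is exact.
    """
    from .composition import AA3

    if not 0.0 <= density <= 1.0:
        raise ValueError("density must be in [0, 1]")
    lo, hi = side_sizes
    if lo < 1 or hi < lo:
        raise ValueError("invalid side size range")
    class_mix = dict(class_mix or {"obligate": n_graphs})
    if sum(class_mix.values()) != n_graphs:
        raise ValueError("class_mix must sum to n_graphs")
    for pat, _, _ in planted:
        if len(pat.large_side) > hi:
            raise GenerationError(
                f"planted pattern {pat} larger than the maximum side size {hi}"
            )

    rng = np.random.default_rng(seed)
    labels_seq = [c for c, n in sorted(class_mix.items()) for _ in range(n)]
    graphs: List[DWEBipartite] = []
    class_labels: Dict[str, str] = {}
    for g_idx, label in enumerate(labels_seq):
        n1 = int(rng.integers(lo, hi + 1))
        n2 = int(rng.integers(lo, hi + 1))
        types1 = [AA3[t] for t in rng.integers(0, 20, size=n1)]
        types2 = [AA3[t] for t in rng.integers(0, 20, size=n2)]
        edges = {
            (i, j)
            for i in range(n1)
            for j in range(n2)
            if rng.random() < density
        }
        gid = f"syn-{g_idx:04d}"
        graphs.append(from_type_lists(gid, types1, types2, edges))
        class_labels[gid] = label

    truth = FixtureTruth(seed=seed, planted_patterns=list(planted))
    by_class: Dict[str, List[DWEBipartite]] = {}
    for g in graphs:
        by_class.setdefault(class_labels[g.interaction_id], []).append(g)
    # each pattern claims a fresh vertex range in its host graphs, so
    # several patterns can share a host without clobbering each other
    watermarks: Dict[str, Tuple[int, int]] = {}
    for pat, label, n_copies in planted:
        hosts = by_class.get(label, [])
        if len(hosts) < n_copies:
            raise GenerationError(
                f"cannot plant {n_copies} copies in {len(hosts)} graphs of class {label!r}"
            )
        for g in hosts[:n_copies]:
            watermarks[g.interaction_id] = _embed_pattern(
                g, pat, watermarks.get(g.interaction_id, (0, 0)))
    return graphs, class_labels, truth


def _embed_pattern(
    g: DWEBipartite, pat: BicliquePattern, start: Tuple[int, int] = (0, 0)
) -> Tuple[int, int]:
    """Write the pattern into ``g`` at the vertex ranges beginning at
    ``start`` (smaller side into v1), extending the sides if needed;
    returns the new watermark past the embedded vertices."""
    need1, need2 = list(pat.small_side), list(pat.large_side)
    s1, s2 = start
    while len(g.v1) < s1 + len(need1):
        g.v1.append(_synthetic_vertex("A", len(g.v1) + 1))
    while len(g.v2) < s2 + len(need2):
        g.v2.append(_synthetic_vertex("B", len(g.v2) + 1))
    idx1 = range(s1, s1 + len(need1))
    idx2 = range(s2, s2 + len(need2))
    for i, t in zip(idx1, need1):
        g.v1[i] = _synthetic_vertex("A", g.v1[i].seq_num, t)
    for j, t in zip(idx2, need2):
        g.v2[j] = _synthetic_vertex("B", g.v2[j].seq_num, t)
    g.edges.update((i, j) for i in idx1 for j in idx2)
    return (s1 + len(need1), s2 + len(need2))


def _synthetic_vertex(chain_id: str, seq_num: int, res_type: str = "GLY") -> Residue:
    r = Residue(chain_id, seq_num, "", res_type)
    r.atoms.append(Atom("CA", "C", np.array([float(seq_num), 0.0, 0.0]), 1.87))
    return r
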