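"""Maximal biclique enumeration, pattern canonicalization and support counting.

A biclique is a complete bipartite subgraph: every residue on one side
contacts every residue on the other. Maximal bicliques (no vertex can be
added to either side) with smaller side >= p and larger side >= q are the
hot-spot candidates; each is abstracted to a residue-type *pattern* — an
unordered pair of sorted type multisets — and a pattern's *support* is the
number of interactions whose bipartite graph contains an occurrence of it
(not necessarily maximal, full cross-contacts required). Patterns with
support >= sup (default 2) are the frequent hot-spot patterns.

Enumeration uses the standard reduction to maximal cliques: completing each
partite side into a clique makes the maximal cliques of the auxiliary graph
correspond one-to-one with the maximal bicliques of the bipartite graph.
``networkx.find_cliques`` does the enumeration; tests pin correctness
against an independent brute-force oracle on small graphs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Set, Tuple

import networkx as nx

from .interface_graph import DWEBipartite
from .model import Residue

P_MIN = 2    # minimum size of the smaller biclique side
Q_MIN = 3    # minimum size of the larger biclique side
SUP_MIN = 2  # minimum support (interactions containing the pattern)


@dataclass
class BicliqueInstance:
    """A concrete biclique: residues of one chain vs residues of the other."""

    interaction_id: str
    side1: FrozenSet[int]  # v1 indices in the source bipartite
    side2: FrozenSet[int]  # v2 indices
    residues1: Tuple[Residue, ...]
    residues2: Tuple[Residue, ...]
    is_maximal: bool = True


@dataclass(frozen=True)
class BicliquePattern:
    """Residue-type-level pattern: unordered pair of sorted type multisets.

    ``small_side`` is the shorter multiset (lexicographic order breaks size
    ties), making the pattern orientation-free: swapping the chains of an
    instance canonicalizes to the identical pattern.
    """

    small_side: Tuple[str, ...]
    large_side: Tuple[str, ...]

    def __post_init__(self):
        if len(self.small_side) > len(self.large_side) or (
            len(self.small_side) == len(self.large_side)
            and self.small_side > self.large_side
        ):
            raise ValueError("sides are not in canonical order")

    @property
    def canonical_key(self) -> str:
        return "+".join(self.small_side) + "|" + "+".join(self.large_side)

    def __str__(self) -> str:
        return (
            "<{" + ",".join(self.small_side) + "},{" + ",".join(self.large_side) + "}>"
        )


def make_pattern(types_a: Iterable[str], types_b: Iterable[str]) -> BicliquePattern:
    """Canonical pattern from two residue-type multisets (either orientation)."""
    a = tuple(sorted(types_a))
    b = tuple(sorted(types_b))
    if (len(a), a) > (len(b), b):
        a, b = b, a
    return BicliquePattern(a, b)


def canonical_pattern(inst: BicliqueInstance) -> BicliquePattern:
    if not inst.residues1 or not inst.residues2:
        raise ValueError("biclique sides must be non-empty")
    return make_pattern(
        (r.res_type for r in inst.residues1),
        (r.res_type for r in inst.residues2),
    )


def maximal_bicliques(
    g: DWEBipartite, p: int = P_MIN, q: int = Q_MIN
) -> List[BicliqueInstance]:
    """All maximal bicliques with min side >= p and max side >= q.

    Reduction: in the auxiliary graph H with all within-side pairs joined
    plus the cross edges of ``g``, a vertex set is a clique iff it is a
    biclique of ``g``; maximality transfers both ways. Bicliques with an
    empty side never satisfy p >= 1 and are discarded.
    """
    if p > q:
        raise ValueError("require p <= q")
    if p < 1:
        raise ValueError("require p >= 1 (both sides non-empty)")
    n1, n2 = len(g.v1), len(g.v2)
    if not g.edges or n1 == 0 or n2 == 0:
        return []
    H = nx.Graph()
    H.add_nodes_from(("a", i) for i in range(n1))
    H.add_nodes_from(("b", j) for j in range(n2))
    H.add_edges_from((("a", i), ("a", k)) for i, k in combinations(range(n1), 2))
    H.add_edges_from((("b", j), ("b", k)) for j, k in combinations(range(n2), 2))
    H.add_edges_from((("a", i), ("b", j)) for i, j in g.edges)

    out: List[BicliqueInstance] = []
    for clique in nx.find_cliques(H):
        side1 = frozenset(i for tag, i in clique if tag == "a")
        side2 = frozenset(j for tag, j in clique if tag == "b")
        lo, hi = sorted((len(side1), len(side2)))
        if lo >= p and hi >= q:
            out.append(
                BicliqueInstance(
                    interaction_id=g.interaction_id,
                    side1=side1,
                    side2=side2,
                    residues1=tuple(g.v1[i] for i in sorted(side1)),
                    residues2=tuple(g.v2[j] for j in sorted(side2)),
                )
            )
    out.sort(key=lambda b: (sorted(b.side1), sorted(b.side2)))
    return out


def _occurs_oriented(
    pat_side1: Sequence[str],
    pat_side2: Sequence[str],
    types1: Sequence[str],
    types2: Sequence[str],
    adj1: Sequence[Set[int]],
) -> bool:
    """Backtracking check: can ``pat_side1`` map injectively into partite 1
    and ``pat_side2`` into partite 2 with full cross-adjacency?

    Side-1 vertices are chosen per type (combinations, not permutations);
    side 2 then only needs, among the common neighbours of the chosen
    side-1 vertices, enough vertices of each required type.
    """
    need1 = Counter(pat_side1)
    need2 = Counter(pat_side2)
    by_type1: Dict[str, List[int]] = {}
    for i, t in enumerate(types1):
        by_type1.setdefault(t, []).append(i)
    for t, m in need1.items():
        if len(by_type1.get(t, ())) < m:
            return False
    k2 = len(pat_side2)
    types_needed = list(need1.items())

    def extend(level: int, chosen_common: Set[int] | None) -> bool:
        if chosen_common is not None and len(chosen_common) < k2:
            return False
        if level == len(types_needed):
            counts = Counter(types2[j] for j in (chosen_common or ()))
            return all(counts[t] >= m for t, m in need2.items())
        t, m = types_needed[level]
        candidates = [
            i for i in by_type1[t]
            if len(adj1[i]) >= k2
            and (chosen_common is None or len(chosen_common & adj1[i]) >= k2)
        ]
        for combo in combinations(candidates, m):
            common = chosen_common
            for i in combo:
                common = adj1[i] if common is None else (common & adj1[i])
            if len(common) >= k2 and extend(level + 1, common):
                return True
        return False

    return extend(0, None)


def pattern_occurs(g: DWEBipartite, pat: BicliquePattern) -> bool:
    """True iff the pattern occurs in ``g``: an injective type-respecting
    assignment of one side to one partite and the other side to the other
    (either orientation) with all cross pairs being edges. Occurrence does
    not require maximality."""
    if not g.edges:
        return False
    types1, types2 = g.types1, g.types2
    adj1 = [set() for _ in types1]
    for i, j in g.edges:
        adj1[i].add(j)
    adj2 = [set() for _ in types2]
    for i, j in g.edges:
        adj2[j].add(i)
    return _occurs_oriented(pat.small_side, pat.large_side, types1, types2, adj1) or \
        _occurs_oriented(pat.small_side, pat.large_side, types2, types1, adj2)


@dataclass
class SupportRecord:
    """A frequent pattern with per-class interaction support."""

    pattern: BicliquePattern
    support_by_class: Dict[str, int] = field(default_factory=dict)
    supporting_ids: Dict[str, List[str]] = field(default_factory=dict)

    @property
    def total_support(self) -> int:
        return sum(self.support_by_class.values())


def mine_frequent_patterns(
    db: Sequence[DWEBipartite],
    class_labels: Mapping[str, str],
    p: int = P_MIN,
    q: int = Q_MIN,
    sup: int = SUP_MIN,
) -> List[SupportRecord]:
    """Mine frequent hot-spot patterns from a database of bipartite graphs.

    Candidates are the canonical patterns of all maximal bicliques across
    the database; each candidate's support counts the interactions where it
    occurs (at most once per interaction). Records with total support < sup
    are discarded. Output is sorted by canonical key, so mining is
    deterministic and independent of database order.

    ``class_labels`` maps interaction_id -> class label.
    """
    if not db:
        raise ValueError("empty graph database")
    candidates: Set[BicliquePattern] = set()
    for g in db:
        for inst in maximal_bicliques(g, p, q):
            candidates.add(canonical_pattern(inst))

    records: List[SupportRecord] = []
    for pat in sorted(candidates, key=lambda c: c.canonical_key):
        rec = SupportRecord(pattern=pat)
        for g in db:
            if pattern_occurs(g, pat):
                label = class_labels[g.interaction_id]
                rec.support_by_class[label] = rec.support_by_class.get(label, 0) + 1
                rec.supporting_ids.setdefault(label, []).append(g.interaction_id)
        if rec.total_support >= sup:
            records.append(rec)
    return records


def instances_of_pattern(
    db: Sequence[DWEBipartite], pat: BicliquePattern, p: int = P_MIN, q: int = Q_MIN
) -> List[BicliqueInstance]:
    """Maximal instances across the database whose canonical pattern matches."""
    out = []
    for g in db:
        for inst in maximal_bicliques(g, p, q):
            if canonical_pattern(inst) == pat:
                out.append(inst)
    return out


def support_records_tsv(records: Sequence[SupportRecord],
                        classes: Sequence[str]) -> str:
    """TSV rendering: pattern, sides, per-class supports, supporting ids."""
    header = ["canonical_key", "small_side", "large_side"]
    header += [f"sup_{c}" for c in classes] + ["supporting_ids"]
    lines = ["\t".join(header)]
    for rec in records:
        ids = ";".join(
            f"{c}:{','.join(rec.supporting_ids.get(c, []))}"
            for c in classes
            if rec.supporting_ids.get(c)
        )
        row = [
            rec.pattern.canonical_key,
            ",".join(rec.pattern.small_side),
            ",".join(rec.pattern.large_side),
            *[str(rec.support_by_class.get(c, 0)) for c in classes],
            ids,
        ]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
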