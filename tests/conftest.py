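"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use different algorithms from the package:
maximal bicliques via exhaustive subset closure (Galois connection),
pattern occurrence via exhaustive combination search, and two-sphere SASA
via the analytic spherical-cap formula. They define correctness; the
package implementations are checked against them.
"""

from __future__ import annotations

import math
from collections import Counter
from itertools import combinations
from typing import FrozenSet, Iterable, List, Sequence, Set, Tuple

import numpy as np
import pytest

from dwebiclique.interface_graph import DWEBipartite, from_type_lists
from dwebiclique.model import Atom, Residue, Structure
from dwebiclique.synthetic import planted_interaction


# ---------------------------------------------------------------- oracles

def brute_force_maximal_bicliques(
    n1: int, n2: int, edges: Iterable[Tuple[int, int]], p: int = 1, q: int = 1
) -> Set[Tuple[FrozenSet[int], FrozenSet[int]]]:
    """Exhaustive enumeration: for every subset S1 of side 1, close it
    through common neighbours; (S1, N(S1)) is a maximal biclique iff S1 is
    itself closed. Both sides non-empty; size filter (p, q) applied to
    (min side, max side)."""
    edge_set = set(edges)
    adj1 = [set(j for j in range(n2) if (i, j) in edge_set) for i in range(n1)]
    adj2 = [set(i for i in range(n1) if (i, j) in edge_set) for j in range(n2)]

    def common(indices: Iterable[int], adj: List[Set[int]], universe: int) -> Set[int]:
        out = set(range(universe))
        for i in indices:
            out &= adj[i]
        return out

    found = set()
    for r in range(1, n1 + 1):
        for s1 in combinations(range(n1), r):
            s2 = common(s1, adj1, n2)
            if not s2:
                continue
            closure = common(s2, adj2, n1)
            if closure == set(s1):
                lo, hi = sorted((len(s1), len(s2)))
                if lo >= p and hi >= q:
                    found.add((frozenset(s1), frozenset(s2)))
    return found


def brute_force_pattern_occurs(
    g: DWEBipartite, small: Sequence[str], large: Sequence[str]
) -> bool:
    """Exhaustive search over vertex combinations in both orientations."""
    edge_set = set(g.edges)
    types1, types2 = g.types1, g.types2

    def oriented(side_a, side_b, t1, t2, flip: bool) -> bool:
        k1, k2 = len(side_a), len(side_b)
        need_a, need_b = Counter(side_a), Counter(side_b)
        for s1 in combinations(range(len(t1)), k1):
            if Counter(t1[i] for i in s1) != need_a:
                continue
            for s2 in combinations(range(len(t2)), k2):
                if Counter(t2[j] for j in s2) != need_b:
                    continue
                pairs = (
                    ((j, i) for i in s1 for j in s2) if flip
                    else ((i, j) for i in s1 for j in s2)
                )
                if all(pr in edge_set for pr in pairs):
                    return True
        return False

    return oriented(small, large, types1, types2, False) or \
        oriented(small, large, types2, types1, True)


def two_sphere_exposed_areas(
    r1: float, r2: float, d: float, probe: float = 1.4
) -> Tuple[float, float]:
    """Analytic accessible areas of two intersecting probe-inflated spheres.

    For center distance d with |R1 - R2| < d < R1 + R2, each sphere loses a
    spherical cap 2 pi R h with h = R - (d^2 + R^2 - R'^2) / (2 d).
    """
    R1, R2 = r1 + probe, r2 + probe
    assert abs(R1 - R2) < d < R1 + R2, "spheres must properly intersect"
    h1 = R1 - (d * d + R1 * R1 - R2 * R2) / (2 * d)
    h2 = R2 - (d * d + R2 * R2 - R1 * R1) / (2 * d)
    a1 = 4 * math.pi * R1 * R1 - 2 * math.pi * R1 * h1
    a2 = 4 * math.pi * R2 * R2 - 2 * math.pi * R2 * h2
    return a1, a2


def random_bipartite(
    rng: np.random.Generator, max_side: int = 12, density: float = 0.3
) -> DWEBipartite:
    """A random type-labelled bipartite graph for oracle-equivalence suites."""
    from dwebiclique.composition import AA3

    n1 = int(rng.integers(1, max_side + 1))
    n2 = int(rng.integers(1, max_side + 1))
    types1 = [AA3[t] for t in rng.integers(0, 20, size=n1)]
    types2 = [AA3[t] for t in rng.integers(0, 20, size=n2)]
    edges = {(i, j) for i in range(n1) for j in range(n2) if rng.random() < density}
    return from_type_lists("random", types1, types2, edges)


# ---------------------------------------------------------------- builders

def make_atom(x: float, y: float, z: float, radius: float = 1.87,
              name: str = "CA", element: str = "C") -> Atom:
    return Atom(name, element, np.array([x, y, z]), radius)


def make_residue(chain_id: str, seq_num: int, res_type: str,
                 atoms: List[Atom]) -> Residue:
    return Residue(chain_id, seq_num, "", res_type, atoms)


def single_atom_residue(chain_id: str, seq_num: int, res_type: str,
                        x: float, y: float = 0.0, z: float = 0.0,
                        radius: float = 1.87) -> Residue:
    return make_residue(chain_id, seq_num, res_type, [make_atom(x, y, z, radius)])


def two_chain_structure(chain_a: List[Residue], chain_b: List[Residue]) -> Structure:
    return Structure(pdb_id="test", chains={"A": chain_a, "B": chain_b})


# ---------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def planted_346():
    """The reference planted interface: 3x4 buried core, 6 exposed rim."""
    rec, truth, pdb_text = planted_interaction(3, 4, 6, seed=7)
    return rec, truth, pdb_text
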