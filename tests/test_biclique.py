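"""Maximal biclique enumeration, canonical patterns, occurrence, mining.

Correctness is defined by the independent brute-force oracles in conftest
(subset-closure enumeration and exhaustive assignment search).
"""

import numpy as np
import pytest

from dwebiclique.biclique import (
    BicliquePattern,
    canonical_pattern,
    instances_of_pattern,
    make_pattern,
    maximal_bicliques,
    mine_frequent_patterns,
    pattern_occurs,
    support_records_tsv,
)
from dwebiclique.interface_graph import from_type_lists
from dwebiclique.synthetic import random_bipartite_db

from conftest import (
    brute_force_maximal_bicliques,
    brute_force_pattern_occurs,
    random_bipartite,
)


def _graph(types1, types2, edges):
    return from_type_lists("g", types1, types2, edges)


def _complete(n1, n2):
    return {(i, j) for i in range(n1) for j in range(n2)}


class TestMaximalBicliques:
    def test_complete_k34_single_maximal(self):
        g = _graph(["ALA"] * 3, ["GLY"] * 4, _complete(3, 4))
        out = maximal_bicliques(g, p=2, q=3)
        assert len(out) == 1
        assert out[0].side1 == frozenset(range(3))
        assert out[0].side2 == frozenset(range(4))

    def test_three_edge_example(self):
        # edges {(a1,b1),(a2,b1),(a2,b2)} -> <{a1,a2},{b1}> and <{a2},{b1,b2}>
        g = _graph(["ALA", "GLY"], ["LEU", "VAL"], {(0, 0), (1, 0), (1, 1)})
        out = maximal_bicliques(g, p=1, q=1)
        found = {(b.side1, b.side2) for b in out}
        assert found == {
            (frozenset({0, 1}), frozenset({0})),
            (frozenset({1}), frozenset({0, 1})),
        }

    def test_empty_graph(self):
        g = _graph(["ALA"], ["GLY"], set())
        assert maximal_bicliques(g, p=1, q=1) == []

    def test_size_filter_monotonicity(self):
        rng = np.random.default_rng(3)
        g = random_bipartite(rng, max_side=10, density=0.4)
        base = {(b.side1, b.side2) for b in maximal_bicliques(g, p=1, q=1)}
        for p, q in [(1, 2), (2, 2), (2, 3), (3, 3)]:
            sub = {(b.side1, b.side2) for b in maximal_bicliques(g, p=p, q=q)}
            assert sub <= base

    def test_invalid_sizes(self):
        g = _graph(["ALA"], ["GLY"], {(0, 0)})
        with pytest.raises(ValueError):
            maximal_bicliques(g, p=3, q=2)
        with pytest.raises(ValueError):
            maximal_bicliques(g, p=0, q=1)

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence_sampled(self, seed):
        rng = np.random.default_rng(seed)
        g = random_bipartite(rng, max_side=12, density=0.3)
        ours = {(b.side1, b.side2) for b in maximal_bicliques(g, p=1, q=1)}
        oracle = brute_force_maximal_bicliques(
            len(g.v1), len(g.v2), g.edges, p=1, q=1)
        assert ours == oracle


class TestCanonicalPattern:
    def test_table_style_instance(self):
        # {VAL,THR,LEU} vs {VAL,LEU}: smaller side first, each side sorted
        g = _graph(["VAL", "THR", "LEU"], ["VAL", "LEU"], _complete(3, 2))
        (inst,) = maximal_bicliques(g, p=2, q=3)
        pat = canonical_pattern(inst)
        assert pat.small_side == ("LEU", "VAL")
        assert pat.large_side == ("LEU", "THR", "VAL")
        assert pat.canonical_key == "LEU+VAL|LEU+THR+VAL"

    def test_orientation_invariance(self):
        a, b = ["GLN", "GLY", "SER"], ["CYS", "LYS"]
        assert make_pattern(a, b) == make_pattern(b, a)

    def test_same_types_different_positions_same_key(self):
        g1 = _graph(["ALA", "GLY"], ["LEU"] * 3, _complete(2, 3))
        g2 = _graph(["GLY", "ALA"], ["LEU"] * 3, _complete(2, 3))
        (i1,) = maximal_bicliques(g1, p=2, q=3)
        (i2,) = maximal_bicliques(g2, p=2, q=3)
        assert canonical_pattern(i1).canonical_key == canonical_pattern(i2).canonical_key

    def test_equal_sizes_lexicographic(self):
        pat = make_pattern(["VAL", "ALA"], ["GLY", "LEU"])
        assert pat.small_side == ("ALA", "VAL")
        assert pat.large_side == ("GLY", "LEU")
        with pytest.raises(ValueError):
            BicliquePattern(("VAL",), ("ALA",))  # non-canonical order rejected


class TestPatternOccurs:
    def test_self_occurrence(self):
        g = _graph(["ALA", "GLY", "VAL"], ["LEU", "THR"],
                   _complete(3, 2) - {(2, 1)})
        for inst in maximal_bicliques(g, p=1, q=1):
            assert pattern_occurs(g, canonical_pattern(inst))

    def test_absent_type_fails(self):
        g = _graph(["ALA"], ["GLY"], {(0, 0)})
        assert not pattern_occurs(g, make_pattern(["TRP"], ["GLY"]))

    def test_non_maximal_sub_biclique_occurs(self):
        # planted K_{3,3}; a 2x2 sub-pattern occurs though never maximal
        g = _graph(["ALA", "ALA", "GLY"], ["LEU", "LEU", "VAL"], _complete(3, 3))
        assert pattern_occurs(g, make_pattern(["ALA", "ALA"], ["LEU", "LEU"]))

    def test_orientation_both_ways(self):
        g = _graph(["CYS", "LYS"], ["GLN", "GLY", "SER"], _complete(2, 3))
        pat = make_pattern(["GLN", "GLY", "SER"], ["CYS", "LYS"])
        assert pattern_occurs(g, pat)

    def test_multiplicity_respected(self):
        # pattern needs two ALA on one side; graph has only one
        g = _graph(["ALA", "GLY"], ["LEU", "LEU"], _complete(2, 2))
        assert not pattern_occurs(g, make_pattern(["ALA", "ALA"], ["LEU", "LEU"]))

    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_equivalence_sampled(self, seed):
        rng = np.random.default_rng(100 + seed)
        g = random_bipartite(rng, max_side=8, density=0.4)
        # probe with patterns canonicalized from another random graph's
        # maximal bicliques plus this graph's own
        probes = []
        for src in (g, random_bipartite(rng, max_side=6, density=0.5)):
            probes += [canonical_pattern(b) for b in maximal_bicliques(src, 1, 1)]
        for pat in probes[:12]:
            assert pattern_occurs(g, pat) == brute_force_pattern_occurs(
                g, pat.small_side, pat.large_side)


class TestMining:
    def test_two_identical_graphs_support_two(self):
        mk = lambda gid: from_type_lists(
            gid, ["ALA", "GLY"], ["LEU", "VAL", "THR"], _complete(2, 3))
        db = [mk("i1"), mk("i2")]
        labels = {"i1": "obligate", "i2": "obligate"}
        (rec,) = mine_frequent_patterns(db, labels)
        assert rec.pattern == make_pattern(["ALA", "GLY"], ["LEU", "VAL", "THR"])
        assert rec.support_by_class == {"obligate": 2}
        assert rec.supporting_ids["obligate"] == ["i1", "i2"]

    def test_support_one_filtered_at_sup_two(self):
        db = [
            from_type_lists("i1", ["ALA", "GLY"], ["LEU", "VAL", "THR"],
                            _complete(2, 3)),
            from_type_lists("i2", ["TRP", "TRP"], ["CYS", "CYS", "CYS"],
                            _complete(2, 3)),
        ]
        labels = {"i1": "obligate", "i2": "obligate"}
        assert mine_frequent_patterns(db, labels) == []
        assert len(mine_frequent_patterns(db, labels, sup=1)) == 2

    def test_planted_pattern_support_counted(self):
        pat = make_pattern(["TRP", "GLY"], ["CYS", "LYS", "SER"])
        db, labels, _ = random_bipartite_db(
            20, (4, 8), density=0.0, planted=[(pat, "obligate", 5)],
            class_mix={"obligate": 12, "crystal_packing": 8}, seed=11)
        records = mine_frequent_patterns(db, labels)
        by_key = {r.pattern.canonical_key: r for r in records}
        assert pat.canonical_key in by_key
        assert by_key[pat.canonical_key].support_by_class == {"obligate": 5}

    def test_mining_deterministic_and_order_independent(self):
        pat = make_pattern(["ALA", "VAL"], ["GLY", "LEU", "SER"])
        db, labels, _ = random_bipartite_db(
            12, (3, 7), density=0.25, planted=[(pat, "obligate", 3)], seed=5)
        r1 = mine_frequent_patterns(db, labels)
        r2 = mine_frequent_patterns(list(reversed(db)), labels)
        key = lambda rs: [(r.pattern.canonical_key, r.support_by_class) for r in rs]
        assert key(r1) == key(r2)

    def test_support_at_least_maximal_instance_count(self):
        pat = make_pattern(["ALA", "VAL"], ["GLY", "LEU", "SER"])
        db, labels, _ = random_bipartite_db(
            15, (4, 8), density=0.2, planted=[(pat, "obligate", 4)], seed=9)
        records = mine_frequent_patterns(db, labels)
        for rec in records:
            n_maximal_hosts = len(
                {i.interaction_id for i in instances_of_pattern(db, rec.pattern)}
            )
            assert rec.total_support >= n_maximal_hosts

    def test_raising_sup_never_adds_patterns(self):
        db, labels, _ = random_bipartite_db(10, (3, 8), density=0.35, seed=2)
        keys = {}
        for sup in (1, 2, 3):
            recs = mine_frequent_patterns(db, labels, sup=sup)
            keys[sup] = {r.pattern.canonical_key for r in recs}
        assert keys[3] <= keys[2] <= keys[1]

    def test_empty_db_errors(self):
        with pytest.raises(ValueError):
            mine_frequent_patterns([], {})

    def test_tsv_output_shape(self):
        db, labels, _ = random_bipartite_db(
            6, (3, 6), density=0.0,
            planted=[(make_pattern(["ALA", "VAL"], ["GLY", "LEU", "SER"]),
                      "obligate", 3)],
            seed=4)
        recs = mine_frequent_patterns(db, labels)
        text = support_records_tsv(recs, ["obligate"])
        lines = text.strip().splitlines()
        assert lines[0].startswith("canonical_key\t")
        assert len(lines) == 1 + len(recs)
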