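"""Mine frequent hot-spot patterns from a synthetic graph database.

Plants the pattern <{TRP,GLY},{CYS,LYS,SER}> into 5 of 20 random bipartite
graphs, mines maximal bicliques (smaller side >= 2, larger >= 3), and
counts per-interaction support. The planted pattern must come back with
support at least 5 (exactly 5 here, since the random background has
density 0.1 and rarely completes a competing biclique).
"""

from dwebiclique import make_pattern, mine_frequent_patterns, random_bipartite_db

pattern = make_pattern(["TRP", "GLY"], ["CYS", "LYS", "SER"])
db, labels, truth = random_bipartite_db(
    n_graphs=20, side_sizes=(4, 8), density=0.1,
    planted=[(pattern, "obligate", 5)],
    class_mix={"obligate": 12, "non_obligate": 8},
    seed=11,
)

records = mine_frequent_patterns(db, labels, p=2, q=3, sup=2)
print(f"{len(records)} frequent pattern(s) with support >= 2:")
for rec in records:
    print(f"  {rec.pattern}  support={rec.support_by_class}")
    for cls, ids in rec.supporting_ids.items():
        print(f"    {cls}: {', '.join(ids)}")
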