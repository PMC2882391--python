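# Methods

This note documents the model, the numerical choices, and what the
synthetic data does and does not establish.

## Contact model

Two residues from opposite chains are in contact when the minimum over
all heavy-atom pairs of the surface gap d(a, a′) − r(a) − r(a′) is
**strictly** below d_water = 2.75 Å, the van der Waals diameter of a
water molecule: no water fits between the atomic surfaces. All published
thresholds in the method are worded as "less than", so every comparison
in this package is strict (contact gap, the 36 % accessibility cut, the
6 Å CA–CA cutoff for nearby residues, the 1.05/0.8 preference ratios and
the ipRP log-threshold). Hydrogens are never modelled; heavy atoms carry
Chothia-style radii as used by NACCESS (carbonyl C 1.76 Å, other C
1.87 Å, N 1.65 Å, O 1.40 Å, S 1.85 Å), shipped as package data.

"At least two atoms contacting" in the interface-residue definition is
read as one contacting atom *pair* (one atom from each residue); a
`min_atom_pairs` knob raises this for anyone preferring the ≥ 2-pairs
reading.

## Accessibility

SASA is Shrake–Rupley numerical integration with a water probe of 1.4 Å
and a deterministic golden-spiral lattice (default 960 points/atom), so
results are exactly reproducible; doubling the lattice moves per-atom
areas by well under 1 % of the sphere scale. Agreement with
slicing-based programs (NACCESS, which the method family uses) is at the
few-percent level on absolute areas — ample for a 36 % threshold.
Relative accessibility divides a residue's absolute area by the NACCESS
reference for its type in an extended Gly-X-Gly tripeptide (packaged
table).

The burial filter is evaluated **in the bound complex** by default: the
water-exclusion hypothesis concerns the interface after complex
formation, and published per-residue tables report in-complex areas of
biclique members near zero. `asa_context="isolated"` switches to
per-chain evaluation, since the original description does not state the
context explicitly.

## Bipartite construction

Three steps, in order: all cross-chain contact edges; removal of
vertices with relative accessibility ≥ t_ra = 36 %; removal of vertices
left with degree 0 (iterated to a fixed point, although one pass
suffices for a bipartite edge subset). An interaction without contacts
yields an empty graph and simply contributes nothing downstream.

## Biclique enumeration and patterns

Maximal bicliques are enumerated through the standard clique transform:
completing each partite side into a clique makes maximal cliques of the
auxiliary graph correspond one-to-one to maximal bicliques of the
bipartite graph; `networkx.find_cliques` does the search. The choice of
algorithm is immaterial to the results — correctness is pinned by an
independent brute-force oracle (subset closure over one side) that the
test suite runs on hundreds of random graphs. Size filters: smaller side
≥ p = 2, larger side ≥ q = 3.

Patterns are residue-type level and orientation-free: an unordered pair
of sorted type multisets (smaller side first; lexicographic order breaks
size ties). This follows how recurring bicliques are reported across
unrelated chain pairs, identified purely by their type composition.

A pattern *occurs* in an interaction when its types can be injectively
assigned to bipartite vertices (either orientation) with all cross pairs
present as edges — maximality is *not* required for occurrence. Support
counts supporting interactions, not instances: several instances inside
one interaction count once, which matches comparing support against
interaction counts. Candidates are the canonical patterns of maximal
instances; with sup = 2 the expected support of any fixed 2×3 instance
under uniform independent types is 10·868/20⁵ ≈ 0.0027 at the original
dataset scale, so support ≥ 2 is far above chance. (Some prose sources
print 0.027 for this quantity; the formula itself gives 0.0027125, and
the package implements the formula.)

## Contrast statistics

For a positive and a negative class set, the signed ratio is +S_h/S_l
when the higher support is positive, −S_h/S_l otherwise, ±INF when the
lower support is 0 (a *unique* pattern); records with S_pos + S_neg < 2
are dropped as noise. The binned contrast matrices replicate the
published bin layouts — (−1.5,1.5) common, [1.5,2.5), [2.5,3.5),
[3.5,7.5) and ±INF for the biological-vs-crystal table; a (−3.5,−2.5]
and [2.5,5.5) variant for obligate-vs-non-obligate — with rows by the
higher support (2, 3, 4, ≥5). Bins are configurable; a ratio outside all
configured bins is a configuration error, never silently dropped.

## Composition

Residue (20-vector) and cross-side pair (210-vector) frequencies are
percent-normalized. The default weighting counts each pattern once per
supporting interaction of the class, matching the support semantics; a
`per_pattern` mode is provided because the original description is
ambiguous on this point. Background: amino-acid percentages of
UniProtKB/Swiss-Prot release 55.0 (packaged); pair expectations use the
multinomial independence form 2·P_iP_j off-diagonal and P_i² on the
diagonal. Selections: idR = top 7 residues by frequency (ties broken
alphabetically), ipR ratio > 1.05, anti-ipR ratio < 0.8, idRP = top 10
pairs (the source does not fix this cardinality; 10 is the package
default, configurable), ipRP ln(ratio+1) > 1.05, i.e. ratio >
e^1.05 − 1 ≈ 1.8577.

Δf is the root-sum-of-squares distance over the 20 percent components
(the rendering of the defining equation is lost in the source text; the
cited prior works use plain Euclidean distance, so that is the default,
with an RMS variant selectable). CC is the Pearson correlation of two
ratio vectors; zero-variance input is an error, not a NaN.

The published single-value consistency checks that are computable from
shipped data hold: an obligate Gly frequency of 6.78 % over the packaged
background gives a ratio of 0.98, within 0.02 of the quoted 0.96.
Checks requiring the original (unpublished) class profiles, such as the
Tyr ratio of 1.87, cannot be recomputed here.

## Redundancy removal

Two chain pairs are redundant when both chains match directly or
crosswise above s = 90 % similarity. Similarity is percent identity over
the best local alignment (BLOSUM62, gap open 11 / extend 1, no
low-complexity masking, identities divided by aligned columns); "score"
is not fully specified in the original description, and published
similarity tables are treated as approximate references (±5) rather than
exact targets. Removal is a greedy scan keeping the first member of each
redundant group — which member the original study kept is unstated.

## Synthetic data: what it emulates and what it does not

`make_interface_structure` plants a geometrically realized hot spot: two
facing residue clusters whose cross pairs all contact through apex
atoms, exposed rim residues that touch the opposite core but keep well
over 36 % of their reference area, and shell residues that bury the
cores from behind without ever reaching across the interface (their
clearance is the tightest constraint in the layout and is placed without
jitter). Residues are minimal stubs (N, CA, C, O, CB apex; shells use
numbered carbons): sufficient for gap and SASA computations, with no
side-chain rotamers, no realistic backbone, and no crystallographic
artifacts. The generator verifies every planted claim itself
(brute-force gap scan plus SASA) and refuses infeasible requests — e.g.
cores too wide to stay fully cross-contacting, or rim-less layouts too
large to stay exposed. Passing the planted-recovery tests therefore
shows the pipeline implements its definitions exactly; it does not show
anything about recovery rates on real interfaces, where burial is
gradual and contacts are noisy.

`random_bipartite_db` plants complete-biclique patterns into labelled
random graphs. Planted copies are a lower bound on mined support (random
background can add occurrences); at density 0 the bound is exact, and
tests assert accordingly. Multiple patterns planted into one graph
occupy disjoint vertex ranges, so guarantees compose.

## Problem sizes and determinism

Default verification scales: 200 random graphs with ≤ 12 vertices per
side for the enumeration oracle, planted interfaces up to 4×5 cores with
8 rim residues, and 20–40-graph databases for mining and contrast — all
chosen so the whole suite and the acceptance script run in seconds while
still exercising every code path. All generators take explicit seeds;
mining output is sorted by canonical pattern key, making every pipeline
product independent of input order.

## Known limitations

* No mmCIF input, no symmetry expansion: crystal-packing chain pairs
  must be provided as explicit chains.
* SASA targets NACCESS-level agreement, not bit-compatibility; analyses
  sitting exactly at the 36 % threshold could flip between programs.
* Pattern support is per interaction; per-instance counting would need a
  different SupportRecord semantics.
* The composition background is a fixed historical release
  (Swiss-Prot 55.0), deliberately, for comparability.
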