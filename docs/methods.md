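# Methods

## Objective and data model

All operations work over a fixed taxon set held in a `TaxonIndex`
(labels sorted lexicographically; ids are positions). Trees are stored
rooted-binary — a virtual degree-2 root placed on one edge — and every
topological statement (quartets, bipartitions, RF) is made on the
unrooted view, so rooting never affects a result. A degree-3 Newick
root, the conventional unrooted encoding, is re-rooted on the edge
above its first child, which provably preserves the split set;
polytomies elsewhere parse but are flagged, and quartet restriction
treats them as unresolved.

For n taxa there are C(n,4) four-taxon sets, each with three resolved
unrooted topologies. The canonical *pairing code* on the sorted key
(a &lt; b &lt; c &lt; d) is the partner of a: 0 = ab|cd, 1 = ac|bd,
2 = ad|bc. One canonical form everywhere prevents double counting in
accumulation, serialization and tie-breaking.

**Quartet induction.** The topology a tree induces on {a,b,c,d} is
read from the LCA-depth rule: among the three pairings, the one whose
two pair-LCAs have the greatest summed depth is induced; a tie means
the restricted tree is a star. (Restricting a tree to four leaves
yields either a balanced or a caterpillar shape; in both, the winning
pairing's LCAs are strictly deeper, and depths are preserved under
restriction.) The package precomputes an n×n pairwise LCA-depth matrix
per tree (one O(n²) postorder) and evaluates all C(n,4) keys in a
single vectorized pass, so a 5,000-tree, 15-taxon distribution builds
in seconds.

**Weighted quartet distributions** are dense (C(n,4), 3) arrays with
sparse semantics (absent key = zero row). Gene-tree-frequency
weighting counts each tree with its weight (`raw`) or rescales every
gene's trees to total 1 (`per-gene`), so genes with unequal sample
counts contribute equally; with equal sample counts the two differ
only by a constant factor. Unresolved restricted quartets contribute
nothing by default (tallied as `unresolved_mass`); an optional
1/3-split mode exists for sensitivity checks. Dominant reduction keeps
the per-key argmax (weighted or unit weight); ties break to the lowest
pairing code and are reported — the tie-break is a convention, so it
is surfaced rather than hidden.

## Amalgamation

The target is weighted maximum quartet consistency: maximize the
summed weight of induced topologies. The heuristic is a QFM-family
divide-and-conquer:

1. **Partition.** For the current taxon set, each weighted quartet is
   classified against a candidate bipartition as *satisfied* (its 2|2
   crossing matches the pair structure), *violated* (2|2 mismatched)
   or *deferred* (3|1 or 4|0). A Fiduccia–Mattheyses-style pass moves
   each taxon at most once, choosing moves by weighted gain
   Δ(satisfied − violated) with ties to the lowest taxon id, keeps the
   best prefix of the pass, and repeats until no pass improves (cap
   `max_fm_passes`, default 20). Sides never shrink below two taxa, so
   recursion always makes progress. Initial bipartitions are random
   balanced splits.
2. **Recursion.** Each side recurses with an artificial taxon standing
   for the other side; deferred quartets with three taxa on a side are
   re-mapped onto it with the fourth taxon replaced by the artificial
   taxon, weights accumulated — total weight is preserved across the
   recursion. Subproblems of four taxa pick the argmax topology
   directly; smaller ones are resolved trivially.
3. **Join.** The two subtrees are grafted at their artificial
   attachment points.
4. **Polish.** Each restart's tree is hill-climbed to a local optimum
   under subtree-prune-regraft (SPR) moves of the same objective.
   Moves are accepted only on strict improvement, so the reported
   score can never exceed the exhaustive optimum. Without this step
   the divide-and-conquer alone matched the exact optimum on only
   ~70% of dense random instances at n = 7; with it, 19–20 of 20.

The best of `restarts` (default 8) seeded runs is returned with its
score. For n ≤ 5 the search space (≤ 15 trees) is enumerated instead.
`exact_amalgamate` enumerates all (2n−5)!! topologies by stepwise leaf
insertion for n ≤ 9 and serves as the oracle in tests; among tied
optima it returns the lexicographically smallest sorted-bipartition
encoding, making it deterministic.

Determinism: all randomness flows through `numpy` Generators seeded
from (`seed`, restart), so identical configurations reproduce the
identical tree.

## Evaluation

`quartet_score(T, genes)` counts (with weights) the gene-tree quartets
agreeing with `T`, by direct per-tree comparison of induced-code
vectors; it equals `quartet_support` of `T` against the raw GTF
distribution, and the two independent routes are cross-checked in the
tests. `rf_rate` is the symmetric bipartition difference over
2(n−3); for binary trees FP, FN and RF rates coincide. The overshoot
report scores candidates against both true and estimated gene trees;
*overshoot* is a candidate's score against estimated genes minus the
true tree's — positive overshoot with positive RF is the signature of
quartet-score overfitting under gene-tree error. Replicate aggregation
is the arithmetic mean. `wilcoxon_compare` wraps
`scipy.stats.wilcoxon`: zero differences dropped, exact distribution
up to 25 nonzero pairs, normal approximation with continuity
correction above, two-sided, significance flagged at α = 0.05, no
multiple-testing correction (raw p reported).

## Simulator and study conditions

`simulate_gene_trees` draws independent gene trees under the MSC:
within each species-tree branch, k lineages coalesce with exponential
waiting times at rate k(k−1)/2 per coalescent unit, survivors merge up
the tree, and coalescence continues above the root. Branch lengths of
gene trees are coalescent times; for non-ultrametric species trees
lineage entry times use the deepest-descendant convention (topologies
are unaffected; only reported lengths approximate). The 4-taxon
closed form — species-topology frequency 1 − (2/3)e^{−t} across a
cherry branch of t coalescent units — is the external oracle for the
simulator (measured within 3 binomial SE at 10,000 genes).

ILS levels scale *internal* branches only (pendant edges untouched;
`scale_all` exists for sensitivity checks): 0.5× = high ILS, 2× = low.
Population-size constants are absorbed into coalescent units; there is
no separate θ.

**Estimation error** is modelled by seeded uniform NNI moves per gene
tree rather than sequence simulation plus ML re-estimation, keeping
the package tool-free. Error levels map to sequence-length regimes via
the concordance between the true species tree and the perturbed trees:
at n = 15, 2 moves ≈ 0.15 mean RF (long-sequence regime) and 16 moves
bring true-tree/estimated-gene concordance to ≈ 0.53 (short-sequence,
~100 bp regime). Per-gene pseudo-distributions (`m` independently
perturbed copies; default m = 20, 2 moves) emulate bootstrap/Bayesian
tree samples: with zero error they collapse to the single-tree
distribution under per-gene normalization.

**Default study condition.** The built-in model species tree is a
15-taxon caterpillar with 0.2-coalescent-unit internal branches and
unit pendants, chosen so the mean quartet concordance between true
gene trees and the species tree is ≈ 0.62 — the high-ILS regime of
published 15-taxon weighted-quartet benchmarks. The replicated study
run by `scripts/acceptance.py` uses 100 genes × 5 replicates at the
high-error setting; the consistency run uses 5,000 genes. These sizes
keep every computation to minutes on one CPU while leaving the
qualitative structure (all-quartet ≤ dominant error, positive
overshoot against estimated genes, true tree maximal against true
genes) clearly measurable.

What the NNI error model does *not* emulate: systematic biases of ML
estimation (e.g. long-branch attraction), alignment error, or
heterotachy. Passing tests therefore demonstrate correctness of the
machinery and the coalescent-level phenomena, not robustness to every
real-data pathology. Missing taxa are rejected throughout (complete
gene trees are a precondition), and sequence-level simulation is out
of scope by design.

## Numerical conventions

- Weight serialization uses the shortest decimal that round-trips;
  integers print without a decimal point, so integer-weight files
  round-trip bit-exactly.
- Score comparisons in search use an absolute tolerance of 1e−9;
  quartet weights are nonnegative float64.
- Leaf labels match exactly (case-sensitive); silent normalization
  would hide dataset errors.
- An all-zero distribution amalgamates to an arbitrary caterpillar
  with a warning rather than failing.
- CLI exit codes: 0 success, 2 usage, 3 data validation, 4 internal;
  logs (version, seed, config hash) go to stderr, results to files.
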