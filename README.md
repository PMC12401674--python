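# wquartet

Weighted-quartet species tree estimation from gene trees under
incomplete lineage sorting (ILS).

## The problem

Gene trees sampled across a genome disagree with each other and with
the species tree, most prominently because of ILS as modelled by the
multispecies coalescent (MSC). Quartet-based summary methods exploit
the fact that for every set of four species the most probable gene-tree
quartet topology matches the species tree: estimate (weighted) quartets
for all C(n,4) four-taxon sets, then *amalgamate* them into one tree on
all n taxa.

`wquartet` implements that pipeline end to end for researchers studying
how quartet weighting choices affect species tree accuracy:

- **Quartet engine** — gene-tree-frequency (GTF) weights for all
  3·C(n,4) quartet topologies from single gene trees ("best-ML" style)
  or from per-gene tree distributions (bootstrap/Bayesian style), with
  all-quartet, dominant, and unweighted-dominant variants; reads and
  writes the wQFM and QMC weighted-quartet file dialects so externally
  generated weights (SVD scores, concordance factors) plug in too.
- **Amalgamation** — a QFM-family divide-and-conquer heuristic for the
  weighted maximum quartet consistency objective: find the binary tree
  `T` maximizing `S(T) = Σ_q w(q)·[T induces q]`, with an exhaustive
  `(2n−5)!!` enumerator as ground-truth oracle for n ≤ 9.
- **Evaluation** — quartet scores against true and estimated gene
  trees, normalized Robinson–Foulds rates
  `|B₁ Δ B₂| / (2(n−3))`, the quartet-score *overshoot* diagnostic, and
  paired two-sided Wilcoxon signed-rank comparisons (α = 0.05).
- **MSC simulator** — true gene trees from a species tree with branch
  lengths in coalescent units (k lineages coalesce at rate k(k−1)/2),
  ILS scaling of internal branches (0.5×/1×/2×), and a seeded NNI
  perturbation model standing in for gene-tree estimation error and
  for per-gene tree distributions.

## Worked example

Simulate a 10-taxon dataset (200 genes, 4 NNI moves of estimation
error per gene tree), build the all-quartet GTF distribution from the
error-prone trees, amalgamate, and evaluate:

```sh
wquartet simulate --n-taxa 10 --n-genes 200 --error-nni 4 --seed 7 --out-dir data
wquartet quartets --trees-in data/estimated_gene_trees.txt --strategy gtf-all --out quartets.wqfm
wquartet amalgamate --quartets-in quartets.wqfm --seed 1 --out species.nwk
wquartet rf species.nwk data/species_tree.nwk
wquartet evaluate --candidates species.nwk --true-tree data/species_tree.nwk \
    --true-genes data/gene_trees.txt --est-genes data/estimated_gene_trees.txt
```

The quartet file holds one weighted topology per line; the first
4-taxon set comes out as

```
((T01,T02),(T03,T04)); 77
((T01,T03),(T02,T04)); 69
((T01,T04),(T02,T03)); 54
```

meaning 77 of the 200 noisy gene trees support `T01,T02|T03,T04` — the
species-tree topology wins, but barely, which is exactly why keeping
*all* three weighted alternatives (rather than only the dominant one)
preserves signal. Amalgamation prints `score=21366` (the summed weight
of satisfied quartets) and writes

```
((((((T01,T02),T03),T04),T05),T06),(T07,(T08,(T09,T10))));
```

`wquartet rf` reports `0`: the true species tree was recovered despite
the gene-tree error. The evaluation row

```
tree_id  score_vs_true  score_vs_estimated  true_tree_score_vs_true  true_tree_score_vs_estimated  overshoot  rf_rate
tree1    23454          21366               23454                    21366                         0          0
```

shows the estimate attaining the true tree's quartet score against both
gene-tree sets (overshoot 0). Under harsher conditions (fewer genes,
more error) estimated trees can *overshoot* — score higher than the
true tree against the estimated gene trees while being topologically
wrong — which is the diagnostic `overshoot` quantifies.

The same operations are available as a library
(`wquartet.distribution_from_collection`, `wquartet.amalgamate`,
`wquartet.quartet_score`, `wquartet.simulate_gene_trees`, ...).

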