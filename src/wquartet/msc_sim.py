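"""Multispecies-coalescent simulation and gene-tree error models.

Generates desk-scale analogues of coalescent simulation studies: true
gene trees from a species tree with branch lengths in coalescent units
(k lineages coalesce at rate k(k-1)/2 per unit), ILS-level scaling of
internal branches (halving doubles discordance pressure, doubling
lowers it), and NNI perturbation standing in for gene-tree estimation
error and for per-gene tree distributions of the bootstrap/Bayesian
kind.

All randomness flows through numpy Generators seeded from the config,
so identical configs give byte-identical serialized datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .tree_io import GeneTreeCollection, PhyloTree, TaxonIndex, _Node, write_newick

__all__ = [
    "SimConfig",
    "model_species_tree",
    "scale_internal_branches",
    "simulate_gene_trees",
    "perturb_trees",
    "sample_pseudo_distribution",
    "write_tree_list",
    "write_dataset",
]


@dataclass
class SimConfig:
    """One simulated dataset condition.

    ils_scale multiplies internal branch lengths of the species tree
    (0.5 = high ILS, 1 = as given, 2 = low ILS); error_nni is the
    number of random NNI moves applied per estimated gene tree;
    trees_per_gene > 1 requests a pseudo-distribution of sampled trees
    per gene.
    """

    species_tree: PhyloTree
    n_genes: int
    ils_scale: float = 1.0
    trees_per_gene: int = 1
    error_nni: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.trees_per_gene < 1 or self.error_nni < 0:
            raise ValidationError("n_genes, trees_per_gene >= 1 and error_nni >= 0 required")
        if self.ils_scale <= 0:
            raise ValidationError("ils_scale must be positive")


def model_species_tree(
    n_taxa: int = 15,
    internal_length: float = 0.2,
    pendant_length: float = 1.0,
    shape: str = "caterpillar",
    index: TaxonIndex | None = None,
) -> PhyloTree:
    """A deterministic model species tree with coalescent-unit lengths.

    The caterpillar shape with short (0.2 coalescent unit) internal
    branches is the package's stand-in for a high-ILS condition: the
    quartet concordance across an internal branch of length t is
    1 - (2/3)exp(-t), and at the default the mean concordance between
    true gene trees and a 15-taxon species tree is about 0.62, the
    high-ILS regime studied by weighted-quartet benchmarks.  Labels are
    T01..Tnn unless an index is supplied.
    """
    if n_taxa < 4:
        raise ValidationError("need at least 4 taxa")
    if index is None:
        width = max(2, len(str(n_taxa)))
        index = TaxonIndex([f"T{i + 1:0{width}d}" for i in range(n_taxa)])
    if index.n != n_taxa:
        raise ValidationError("index size does not match n_taxa")

    def leaf(i):
        return _Node(leaf=i, length=pendant_length)

    if shape == "caterpillar":
        node = _Node(length=internal_length)
        node.children = [leaf(0), leaf(1)]
        for i in range(2, n_taxa):
            parent = _Node(length=internal_length)
            parent.children = [node, leaf(i)]
            node = parent
        node.length = None
        return PhyloTree(node, index)
    if shape == "balanced":
        def build(ids):
            if len(ids) == 1:
                return leaf(ids[0])
            mid = len(ids) // 2
            v = _Node(length=internal_length)
            v.children = [build(ids[:mid]), build(ids[mid:])]
            return v
        root = build(list(range(n_taxa)))
        root.length = None
        return PhyloTree(root, index)
    raise ValidationError(f"unknown shape {shape!r}")


def scale_internal_branches(
    tree: PhyloTree, factor: float, scale_all: bool = False
) -> PhyloTree:
    """Multiply internal (non-pendant) branch lengths by ``factor``.

    Pendant edges are untouched unless ``scale_all``; the topology never
    changes.  Missing lengths raise.
    """
    out = tree.copy()

    def visit(node, is_root):
        if not is_root:
            if node.length is None:
                raise ValidationError("tree has missing branch lengths")
            if scale_all or node.leaf is None:
                node.length *= factor
        for c in node.children:
            visit(c, False)

    visit(out.root, True)
    out._invalidate()
    return out


# ---------------------------------------------------------------------------
# coalescent simulation


def _node_ages(tree: PhyloTree) -> dict:
    ages = {}

    def visit(node):
        if node.leaf is not None:
            ages[id(node)] = 0.0
            return 0.0
        a = max(visit(c) + (c.length or 0.0) for c in node.children)
        ages[id(node)] = a
        return a

    visit(tree.root)
    return ages


def _simulate_one(tree: PhyloTree, rng: np.random.Generator) -> PhyloTree:
    ages = _node_ages(tree)

    def coalesce(lineages, t0, duration):
        """lineages: list of (gene _Node, birth_time); merge within a branch."""
        t = t0
        while len(lineages) > 1:
            k = len(lineages)
            t += rng.exponential(2.0 / (k * (k - 1)))
            if t > t0 + duration:
                break
            i, j = rng.choice(k, size=2, replace=False)
            u, ut = lineages[i]
            v, vt = lineages[j]
            u.length = t - ut
            v.length = t - vt
            parent = _Node()
            parent.children = [u, v]
            lineages = [l for idx, l in enumerate(lineages) if idx not in (i, j)]
            lineages.append((parent, t))
        return lineages

    def visit(sp_node):
        if sp_node.leaf is not None:
            entering = [(_Node(leaf=sp_node.leaf), 0.0)]
        else:
            entering = []
            for c in sp_node.children:
                entering.extend(visit(c))
        bottom = ages[id(sp_node)]
        duration = np.inf if sp_node is tree.root else (sp_node.length or 0.0)
        return coalesce(entering, bottom, duration)

    ((root, _),) = visit(tree.root)
    root.length = None
    return PhyloTree(root, tree.index)


def simulate_gene_trees(cfg: SimConfig) -> GeneTreeCollection:
    """Independent true gene trees under the multispecies coalescent.

    Within each species-tree branch, k lineages coalesce with
    exponential waiting times at rate k(k-1)/2 per coalescent unit;
    surviving lineages merge up the tree and coalescence continues
    above the root until one lineage remains.  Branch lengths of the
    returned gene trees are coalescent times (exact for ultrametric
    species trees; for non-ultrametric input, lineage entry times use
    the deepest-descendant convention and topologies are unaffected).
    """
    sp = cfg.species_tree
    if sp.has_polytomy:
        raise ValidationError("species tree must be binary")
    if not sp.is_complete():
        raise ValidationError("species tree must cover its full taxon index")
    if not sp.has_branch_lengths():
        raise ValidationError("species tree needs coalescent-unit branch lengths")
    sp = scale_internal_branches(sp, cfg.ils_scale)
    base = abs(cfg.seed) % (2**31)
    genes = []
    for g in range(cfg.n_genes):
        rng = np.random.default_rng([base, g])
        genes.append([(_simulate_one(sp, rng), 1.0)])
    return GeneTreeCollection(index=sp.index, genes=genes, mode="single")


# ---------------------------------------------------------------------------
# estimation-error model (random NNI)


def _tree_to_adjacency(tree: PhyloTree):
    adj = {}
    counter = [0]

    def add_edge(u, v):
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def build(node):
        if node.leaf is not None:
            adj.setdefault(node.leaf, [])
            return node.leaf
        counter[0] -= 1
        nid = counter[0]
        adj.setdefault(nid, [])
        for c in node.children:
            add_edge(nid, build(c))
        return nid

    root = build(tree.root)
    if len(adj[root]) == 2:  # suppress the rooted-representation root
        a, b = adj[root]
        adj[a] = [x if x != root else b for x in adj[a]]
        adj[b] = [x if x != root else a for x in adj[b]]
        del adj[root]
    return adj


def _adjacency_to_tree(adj, index: TaxonIndex) -> PhyloTree:
    ref = min(v for v in adj if v >= 0)

    def sub(u, parent):
        node = _Node(leaf=u if u >= 0 else None)
        node.children = [sub(x, u) for x in adj[u] if x != parent]
        return node

    (attach,) = adj[ref]
    root = _Node()
    root.children = [_Node(leaf=ref), sub(attach, ref)]
    return PhyloTree(root, index)


def _random_nni(adj, rng: np.random.Generator):
    """One uniform NNI: uniform internal edge, uniform rearrangement."""
    internal_edges = [
        (u, v) for u in adj for v in adj[u] if u < v and u < 0 and v < 0
    ]
    if not internal_edges:
        return
    u, v = internal_edges[rng.integers(len(internal_edges))]
    a, b = [x for x in adj[u] if x != v]
    c, d = [x for x in adj[v] if x != u]
    swap_with = c if rng.integers(2) == 0 else d
    # exchange subtree b (at u) with swap_with (at v)
    adj[u] = [x if x != b else swap_with for x in adj[u]]
    adj[v] = [x if x != swap_with else b for x in adj[v]]
    adj[b] = [x if x != u else v for x in adj[b]]
    adj[swap_with] = [x if x != v else u for x in adj[swap_with]]


def _perturb_one(tree: PhyloTree, error_nni: int, rng) -> PhyloTree:
    if error_nni == 0:
        return tree.copy()
    adj = _tree_to_adjacency(tree)
    for _ in range(error_nni):
        _random_nni(adj, rng)
    return _adjacency_to_tree(adj, tree.index)


def perturb_trees(
    col: GeneTreeCollection, error_nni: int, seed: int = 0
) -> GeneTreeCollection:
    """Apply ``error_nni`` random NNI moves to each gene tree.

    A topological stand-in for gene-tree estimation error: each move
    crosses one uniformly chosen internal edge with one of its two
    rearrangements.  Perturbed trees are topology-only (branch lengths
    are dropped); ``error_nni = 0`` is the identity.
    """
    if col.mode != "single":
        raise ValidationError("perturbation expects a single-tree collection")
    base = abs(seed) % (2**31)
    genes = []
    for g, trees in enumerate(col.genes):
        rng = np.random.default_rng([base, g])
        tree, w = trees[0]
        genes.append([(_perturb_one(tree, error_nni, rng), w)])
    return GeneTreeCollection(index=col.index, genes=genes, mode="single")


def sample_pseudo_distribution(
    col: GeneTreeCollection, m: int, error_nni: int, seed: int = 0
) -> GeneTreeCollection:
    """Emulate an m-tree bootstrap/Bayesian sample per gene.

    Each gene yields m independently NNI-perturbed copies of its source
    tree; with ``error_nni = 0`` the sample collapses to m duplicates,
    so per-gene-normalized quartet frequencies equal the single-tree
    ones.
    """
    if col.mode != "single":
        raise ValidationError("pseudo-distribution expects a single-tree collection")
    if m < 1:
        raise ValidationError("m must be >= 1")
    base = abs(seed) % (2**31)
    genes = []
    for g, trees in enumerate(col.genes):
        rng = np.random.default_rng([base, g, 1])
        tree, _ = trees[0]
        genes.append([(_perturb_one(tree, error_nni, rng), 1.0) for _ in range(m)])
    return GeneTreeCollection(index=col.index, genes=genes, mode="distribution")


# ---------------------------------------------------------------------------
# dataset files


def write_tree_list(trees, path, with_lengths: bool = False) -> None:
    """Write one Newick per line (tree_io tree-list format)."""
    with open(path, "w") as fh:
        for t in trees:
            fh.write(write_newick(t, with_lengths=with_lengths) + "\n")


def write_dataset(cfg: SimConfig, outdir) -> dict:
    """Simulate one condition and write its files plus a manifest.

    Emits species_tree.nwk, gene_trees.txt (true trees), and when
    requested estimated_gene_trees.txt (error_nni > 0) and per-gene
    distribution files gene_<i>.txt (trees_per_gene > 1).  The manifest
    records every config field and the seed for replication.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    sp_scaled = scale_internal_branches(cfg.species_tree, cfg.ils_scale)
    write_tree_list([sp_scaled], os.path.join(outdir, "species_tree.nwk"), with_lengths=True)
    col = simulate_gene_trees(cfg)
    write_tree_list(
        [g[0][0] for g in col.genes], os.path.join(outdir, "gene_trees.txt"),
        with_lengths=True,
    )
    files = ["species_tree.nwk", "gene_trees.txt"]
    if cfg.error_nni > 0:
        est = perturb_trees(col, cfg.error_nni, seed=cfg.seed + 1)
        write_tree_list(
            [g[0][0] for g in est.genes],
            os.path.join(outdir, "estimated_gene_trees.txt"),
        )
        files.append("estimated_gene_trees.txt")
    if cfg.trees_per_gene > 1:
        src = perturb_trees(col, cfg.error_nni, seed=cfg.seed + 1) if cfg.error_nni else col
        dist = sample_pseudo_distribution(
            src, cfg.trees_per_gene, cfg.error_nni, seed=cfg.seed + 2
        )
        for g, trees in enumerate(dist.genes):
            name = f"gene_{g:04d}.txt"
            write_tree_list([t for t, _ in trees], os.path.join(outdir, name))
            files.append(name)
    manifest = {
        "n_taxa": cfg.species_tree.index.n,
        "n_genes": cfg.n_genes,
        "ils_scale": cfg.ils_scale,
        "trees_per_gene": cfg.trees_per_gene,
        "error_nni": cfg.error_nni,
        "seed": cfg.seed,
        "files": files,
    }
    with open(os.path.join(outdir, "manifest.txt"), "w") as fh:
        for k, v in manifest.items():
            fh.write(f"{k} = {v}\n")
    return manifest
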