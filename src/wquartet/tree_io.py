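"""Newick I/O, taxon indexing and the shared phylogenetic tree structure.

Trees are stored in a rooted-binary representation (a virtual root of
degree 2 placed on one edge); every topological comparison downstream
(quartets, bipartitions, Robinson-Foulds) uses the unrooted view, so the
placement of the root never influences a result.  Leaf labels are mapped
to dense integer ids through a :class:`TaxonIndex` shared by every tree
of an analysis.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .errors import NewickParseError, ValidationError

__all__ = [
    "TaxonIndex",
    "PhyloTree",
    "GeneTreeCollection",
    "parse_newick",
    "write_newick",
    "read_tree_collection",
    "read_tree_list",
]


class TaxonIndex:
    """Bijection between taxon labels and dense integer ids.

    Labels are stored sorted lexicographically; the id of a label is its
    position in that ordering, so two indexes built from the same label
    set are interchangeable.
    """

    def __init__(self, labels: Iterable[str]):
        labels = list(labels)
        if any((not isinstance(l, str)) or l == "" for l in labels):
            raise ValidationError("taxon labels must be nonempty strings")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate taxon labels: {dupes}")
        self.labels: tuple[str, ...] = tuple(sorted(labels))
        self._ids = {lab: i for i, lab in enumerate(self.labels)}

    @property
    def n(self) -> int:
        return len(self.labels)

    def id_of(self, label: str) -> int:
        try:
            return self._ids[label]
        except KeyError:
            raise ValidationError(f"unknown taxon label {label!r}") from None

    def label_of(self, taxon_id: int) -> str:
        return self.labels[taxon_id]

    def __contains__(self, label: str) -> bool:
        return label in self._ids

    def __len__(self) -> int:
        return self.n

    def __eq__(self, other) -> bool:
        return isinstance(other, TaxonIndex) and self.labels == other.labels

    def __hash__(self):
        return hash(self.labels)

    def __repr__(self):
        return f"TaxonIndex(n={self.n}, labels={self.labels[:4]}...)"


class _Node:
    __slots__ = ("children", "leaf", "length")

    def __init__(self, leaf=None, length=None):
        self.children: list[_Node] = []
        self.leaf = leaf          # taxon id for leaves, None for internals
        self.length = length      # edge length above this node, or None

    def copy(self) -> "_Node":
        n = _Node(self.leaf, self.length)
        n.children = [c.copy() for c in self.children]
        return n


class PhyloTree:
    """A phylogenetic tree over (a subset of) a :class:`TaxonIndex`.

    The structure is rooted and, apart from an optional flagged polytomy,
    binary; all comparisons treat it as unrooted.
    """

    def __init__(self, root: _Node, index: TaxonIndex, has_polytomy: bool = False):
        self.root = root
        self.index = index
        self.has_polytomy = has_polytomy
        self._leaf_ids: frozenset[int] | None = None
        self._lca_depth: np.ndarray | None = None
        self._biparts: frozenset[int] | None = None

    # -- basic structure ------------------------------------------------

    def leaf_ids(self) -> frozenset[int]:
        if self._leaf_ids is None:
            out = []
            stack = [self.root]
            while stack:
                v = stack.pop()
                if v.leaf is not None:
                    out.append(v.leaf)
                stack.extend(v.children)
            self._leaf_ids = frozenset(out)
        return self._leaf_ids

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids())

    def is_complete(self) -> bool:
        """True when the tree covers every taxon of its index."""
        return len(self.leaf_ids()) == self.index.n

    def has_branch_lengths(self) -> bool:
        stack = [self.root]
        while stack:
            v = stack.pop()
            if v is not self.root and v.length is None:
                return False
            stack.extend(v.children)
        return True

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy(), self.index, self.has_polytomy)

    # -- topological views ----------------------------------------------

    def lca_depth_matrix(self) -> np.ndarray:
        """n x n matrix of topological depths of pairwise leaf LCAs.

        Entry [i, j] is the edge-count depth (from the root) of the most
        recent common ancestor of leaves i and j; -1 marks absent leaves.
        For any four leaves, the pairing maximizing the sum of its two
        LCA depths is the induced unrooted quartet topology (ties mean
        the quartet is unresolved), which is the primitive behind all
        quartet counting in the package.
        """
        if self._lca_depth is not None:
            return self._lca_depth
        n = self.index.n
        M = np.full((n, n), -1, dtype=np.int32)

        def visit(node: _Node, depth: int) -> list[int]:
            if node.leaf is not None:
                M[node.leaf, node.leaf] = depth
                return [node.leaf]
            groups = [visit(c, depth + 1) for c in node.children]
            for i in range(len(groups)):
                gi = np.asarray(groups[i])
                for j in range(i + 1, len(groups)):
                    gj = np.asarray(groups[j])
                    M[np.ix_(gi, gj)] = depth
                    M[np.ix_(gj, gi)] = depth
            merged = [x for g in groups for x in g]
            return merged

        visit(self.root, 0)
        self._lca_depth = M
        return M

    def bipartitions(self) -> frozenset[int]:
        """Nontrivial unrooted bipartitions as canonical bitmasks.

        Each split is encoded as the integer mask of the side *not*
        containing the smallest leaf id present in the tree.
        """
        if self._biparts is not None:
            return self._biparts
        leaves = self.leaf_ids()
        full = 0
        for l in leaves:
            full |= 1 << l
        ref_bit = 1 << min(leaves)
        out = set()

        def visit(node: _Node) -> int:
            if node.leaf is not None:
                return 1 << node.leaf
            mask = 0
            for c in node.children:
                mask |= visit(c)
            if node is not self.root:
                side = mask if not (mask & ref_bit) else full ^ mask
                if 2 <= bin(side).count("1") <= len(leaves) - 2:
                    out.add(side)
            return mask

        visit(self.root)
        self._biparts = frozenset(out)
        return self._biparts

    def is_binary(self) -> bool:
        return not self.has_polytomy

    def _invalidate(self):
        self._leaf_ids = None
        self._lca_depth = None
        self._biparts = None

    def __repr__(self):
        return f"PhyloTree(n_leaves={self.n_leaves}, newick={write_newick(self)!r})"


# ---------------------------------------------------------------------------
# parsing


def _from_dendropy(dnode, index: TaxonIndex, state: dict) -> _Node:
    if dnode.is_leaf():
        if dnode.taxon is None or not dnode.taxon.label:
            raise NewickParseError("leaf without a label")
        node = _Node(leaf=index.id_of(dnode.taxon.label), length=dnode.edge.length)
        return node
    children = [_from_dendropy(c, index, state) for c in dnode.child_nodes()]
    if len(children) == 1:  # unifurcation: splice out
        child = children[0]
        if child.length is not None and dnode.edge.length is not None:
            child.length += dnode.edge.length
        elif dnode.edge.length is not None:
            child.length = dnode.edge.length
        return child
    node = _Node(length=dnode.edge.length)
    node.children = children
    if len(children) > 2:
        state["polytomy_nodes"] += 1
    return node


def parse_newick(text: str, index: TaxonIndex | None = None) -> PhyloTree:
    """Parse a single Newick statement into a :class:`PhyloTree`.

    A degree-3 root (the conventional encoding of an unrooted tree) is
    re-rooted on the edge above its first child, which leaves the
    unrooted topology untouched.  Polytomies elsewhere parse fine but
    set ``has_polytomy``; downstream operations decide how to treat
    unresolved quartets.

    Parameters
    ----------
    text
        One well-formed Newick statement ending in ';'.
    index
        Optional pre-built taxon index; labels absent from it raise
        :class:`ValidationError`.  When omitted an index is built from
        the tree's own (sorted) leaf labels.
    """
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickParseError("Newick statement must end in ';'", offset=len(text))
    bal = 0
    for pos, ch in enumerate(stripped):
        if ch == "(":
            bal += 1
        elif ch == ")":
            bal -= 1
            if bal < 0:
                raise NewickParseError("unbalanced parentheses", offset=pos)
    if bal != 0:
        raise NewickParseError("unbalanced parentheses", offset=len(stripped))
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted DataError subclasses
        if "Duplicate taxon labels" in str(exc):
            raise ValidationError(f"duplicate leaf labels: {exc}") from exc
        raise NewickParseError(str(exc)) from exc

    labels = [lf.taxon.label for lf in dtree.leaf_node_iter() if lf.taxon is not None]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValidationError(f"duplicate leaf labels: {dupes}")
    if index is None:
        index = TaxonIndex(labels)
    else:
        for l in labels:
            if l not in index:
                raise ValidationError(f"leaf label {l!r} not in the supplied taxon index")

    state = {"polytomy_nodes": 0}
    root = _from_dendropy(dtree.seed_node, index, state)
    root.length = None
    polytomy = state["polytomy_nodes"] > 0
    if root.leaf is None and len(root.children) == 3:
        # a degree-3 root is the conventional unrooted encoding, not a polytomy
        polytomy = state["polytomy_nodes"] > 1
    if root.leaf is None and len(root.children) > 2:
        # unrooted encoding: root on the edge above the first child
        polytomy = polytomy or len(root.children) > 3
        first, rest = root.children[0], root.children[1:]
        other = _Node(length=0.0 if first.length is not None else None)
        other.children = rest
        new_root = _Node()
        new_root.children = [first, other]
        root = new_root
    return PhyloTree(root, index, has_polytomy=polytomy)


# ---------------------------------------------------------------------------
# writing


def _format_length(x: float) -> str:
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def write_newick(tree: PhyloTree, with_lengths: bool = False) -> str:
    """Serialize a tree to Newick; deterministic up to the rooted shape.

    Children are ordered by their smallest descendant label so that
    structurally equal trees serialize identically.  ``with_lengths`` is
    honoured only for edges that actually carry a length.
    """
    index = tree.index

    def fmt(node: _Node) -> tuple[int, str]:
        if node.leaf is not None:
            s = index.label_of(node.leaf)
            if with_lengths and node.length is not None:
                s += f":{_format_length(node.length)}"
            return node.leaf, s
        parts = sorted(fmt(c) for c in node.children)
        s = "(" + ",".join(p[1] for p in parts) + ")"
        if with_lengths and node.length is not None:
            s += f":{_format_length(node.length)}"
        return parts[0][0], s

    return fmt(tree.root)[1] + ";"


# ---------------------------------------------------------------------------
# collections


@dataclass
class GeneTreeCollection:
    """Ordered genes, each a list of (tree, weight) pairs.

    ``mode`` is ``"single"`` (one tree per gene, e.g. best-ML estimates)
    or ``"distribution"`` (m sampled trees per gene, emulating Bayesian
    or bootstrap samples).  Every tree is complete over the shared index.
    """

    index: TaxonIndex
    genes: list[list[tuple[PhyloTree, float]]]
    mode: str = "single"

    def __post_init__(self):
        if self.mode not in ("single", "distribution"):
            raise ValidationError(f"unknown collection mode {self.mode!r}")
        for g, trees in enumerate(self.genes):
            if not trees:
                raise ValidationError(f"gene {g} holds no trees")
            if self.mode == "single" and len(trees) != 1:
                raise ValidationError(f"gene {g} has {len(trees)} trees in single-tree mode")
            for t, w in trees:
                if w <= 0:
                    raise ValidationError(f"gene {g}: nonpositive tree weight {w}")
                if t.index != self.index or not t.is_complete():
                    raise ValidationError(f"gene {g}: tree leaf set does not match the taxon index")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def trees_per_gene(self) -> list[int]:
        return [len(g) for g in self.genes]

    def iter_trees(self):
        """Yield (gene_idx, tree, weight) over every tree."""
        for g, trees in enumerate(self.genes):
            for t, w in trees:
                yield g, t, w


def read_tree_list(path, index: TaxonIndex | None = None) -> list[PhyloTree]:
    """Read a plain-text tree list: one Newick per line, '#' comments skipped."""
    trees = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                tree = parse_newick(line, index)
            except (NewickParseError, ValidationError) as exc:
                raise type(exc)(f"{path}, line {lineno}: {exc}") from exc
            if index is None:
                index = tree.index
            trees.append(tree)
    if not trees:
        raise ValidationError(f"{path}: no trees found")
    return trees


def read_tree_collection(
    paths: Sequence, mode: str = "single", index: TaxonIndex | None = None
) -> GeneTreeCollection:
    """Read gene trees from disk into a validated collection.

    single-tree mode: one file, line i = the tree of gene i.
    distribution mode: one file per gene, each line one sampled tree.
    All trees must share one complete leaf set; the error for a
    violation names the offending file.
    """
    paths = list(paths)
    if mode == "single":
        if len(paths) != 1:
            raise ValidationError("single-tree mode takes exactly one file")
        trees = read_tree_list(paths[0], index)
        index = trees[0].index
        genes = [[(t, 1.0)] for t in trees]
    elif mode == "distribution":
        genes = []
        for p in paths:
            trees = read_tree_list(p, index)
            if index is None:
                index = trees[0].index
            genes.append([(t, 1.0) for t in trees])
    else:
        raise ValidationError(f"unknown mode {mode!r}")

    for g, trees in enumerate(genes):
        src = paths[0] if mode == "single" else paths[g]
        for t, _ in trees:
            if t.index != index or not t.is_complete():
                missing = set(index.labels) - {index.label_of(i) for i in t.leaf_ids()}
                raise ValidationError(
                    f"{src}: gene {g} tree leaf set inconsistent (missing {sorted(missing)})"
                )
    return GeneTreeCollection(index=index, genes=genes, mode=mode)
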