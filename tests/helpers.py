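"""Independent oracles and small generators shared by the test suite.

The oracles here deliberately avoid the package's own quartet/RF code
paths: quartet restriction goes through dendropy pruning, RF through
dendropy's bipartition machinery, tree enumeration through a recursive
subset construction, and quartet support through split-separation
logic on frozensets — so agreement with the package is a genuine
two-route check.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np

from wquartet import TaxonIndex, parse_newick


def random_tree_newick(n: int, rng: np.random.Generator, labels=None) -> str:
    """Random binary topology via random sequential joins."""
    if labels is None:
        labels = [f"x{i:02d}" for i in range(n)]
    items = list(labels)
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        a, b = items[i], items[j]
        items = [x for k, x in enumerate(items) if k not in (i, j)]
        items.append(f"({a},{b})")
    return items[0] + ";"


def random_tree(n: int, rng: np.random.Generator, index: TaxonIndex | None = None):
    return parse_newick(random_tree_newick(
        n, rng, labels=None if index is None else list(index.labels)), index)


# ---------------------------------------------------------------------------
# dendropy-based oracles


def dendropy_quartet_pairing(newick: str, labels4) -> int | None:
    """Induced pairing code on 4 labels via naive prune-and-compare.

    Prunes all other taxa with dendropy and reads the single nontrivial
    split of the 4-leaf remainder; the code is the index (0/1/2) of the
    partner of the lexicographically smallest label among the rest.
    Returns None when the restriction is a star.
    """
    t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    t.retain_taxa_with_labels(list(labels4))
    a, b, c, d = sorted(labels4)
    t.encode_bipartitions()
    quartet = {a, b, c, d}
    for edge in t.preorder_edge_iter():
        bp = edge.bipartition
        if bp is None:
            continue
        side = {tax.label for tax in bp.leafset_taxa(t.taxon_namespace)}
        if len(side) != 2 or side == quartet:
            continue
        mate = (side - {a}).pop() if a in side else ((quartet - side) - {a}).pop()
        return [b, c, d].index(mate)
    return None


def dendropy_rf_rate(nw1: str, nw2: str) -> float:
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=nw1, schema="newick", taxon_namespace=tns,
                           preserve_underscores=True)
    t2 = dendropy.Tree.get(data=nw2, schema="newick", taxon_namespace=tns,
                           preserve_underscores=True)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    d = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
    n = len(tns)
    return d / (2 * (n - 3))


# ---------------------------------------------------------------------------
# second, independent enumeration and split-based quartet support


def rooted_shapes(leaves: tuple):
    """All rooted binary shapes over ``leaves`` as nested tuples.

    Canonical recursion: the left subtree is the one containing the
    smallest leaf, so every shape appears exactly once ((2m-3)!! for m
    leaves).
    """
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    for k in range(0, len(rest)):
        for extra in itertools.combinations(rest, k):
            left_set = (first,) + extra
            right_set = tuple(x for x in rest if x not in extra)
            if not right_set:
                continue
            for l in rooted_shapes(left_set):
                for r in rooted_shapes(right_set):
                    yield (l, r)


def unrooted_shapes(n: int):
    """All unrooted binary topologies on 0..n-1: leaf 0 joined to each
    rooted shape over 1..n-1."""
    for rest in rooted_shapes(tuple(range(1, n))):
        yield (0, rest)


def shape_splits(shape, n: int) -> frozenset:
    """Nontrivial splits (side excluding taxon 0) of a nested-tuple tree."""
    out = set()

    def visit(node) -> frozenset:
        if isinstance(node, int):
            return frozenset([node])
        here = frozenset()
        for c in node:
            here |= visit(c)
        if 2 <= len(here) <= n - 2 and 0 not in here:
            out.add(here)
        elif 2 <= len(frozenset(range(n)) - here) <= n - 2 and 0 in here:
            out.add(frozenset(range(n)) - here)
        return here

    visit(shape)
    return frozenset(out)


def split_quartet_pairing(splits: frozenset, key) -> int | None:
    """Pairing induced at ``key`` by a split set: pairing ab|cd holds iff
    some split separates {a,b} from {c,d}."""
    a, b, c, d = key
    for code, (p, q, r, s) in enumerate(((a, b, c, d), (a, c, b, d), (a, d, b, c))):
        for M in splits:
            inn = (p in M) + (q in M)
            out = (r in M) + (s in M)
            if (inn == 2 and out == 0) or (inn == 0 and out == 2):
                return code
    return None


def brute_force_support(shape, weights: np.ndarray, n: int) -> float:
    """Quartet support of a nested-tuple tree by per-key split logic."""
    splits = shape_splits(shape, n)
    total = 0.0
    for row, key in enumerate(itertools.combinations(range(n), 4)):
        code = split_quartet_pairing(splits, key)
        if code is not None:
            total += weights[row, code]
    return total
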