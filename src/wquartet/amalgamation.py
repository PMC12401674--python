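"""Amalgamation of weighted quartets into a species tree.

The target objective is weighted maximum quartet consistency: find the
binary tree on the full taxon set maximizing the summed weight of the
quartet topologies it induces.  The heuristic is a recursive
divide-and-conquer in the QFM family: a Fiduccia-Mattheyses-style
iterative-improvement loop partitions the current taxon set, quartets
are classified against the candidate bipartition as satisfied, violated
or deferred, and each side recurses with an artificial taxon standing
for the other side.  An exact enumerator over all (2n-5)!! topologies
serves as the ground-truth oracle at small n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .quartet_engine import (
    QuartetTopology,
    WeightedQuartetDistribution,
    induced_codes,
    quartet_keys,
)
from .tree_io import PhyloTree, TaxonIndex, _Node

__all__ = [
    "AmalgamationConfig",
    "quartet_support",
    "exact_amalgamate",
    "amalgamate",
    "caterpillar_tree",
]

log = logging.getLogger(__name__)


@dataclass
class AmalgamationConfig:
    """Knobs of the heuristic search.

    restarts: independent seeded random initial bipartitions at the top
    level; the best-scoring result is returned.  max_fm_passes bounds
    the improvement passes per partitioning problem.  exact_threshold
    caps the taxon count for exhaustive enumeration (the (2n-5)!! tree
    count must stay desk-scale).
    """

    restarts: int = 8
    seed: int = 0
    max_fm_passes: int = 20
    exact_threshold: int = 9
    spr_refine: bool = True

    def __post_init__(self):
        if self.restarts < 1 or self.max_fm_passes < 1:
            raise ValidationError("restarts and max_fm_passes must be positive")
        if self.exact_threshold > 9:
            raise ValidationError("exact_threshold must be <= 9")


# ---------------------------------------------------------------------------
# objective


def quartet_support(tree: PhyloTree, dist: WeightedQuartetDistribution) -> float:
    """Total weight of the quartet topologies ``tree`` induces.

    This is the (weighted) quartet score of a candidate species tree:
    the sum over all 4-taxon sets of the weight the distribution assigns
    to the topology the tree exhibits there.
    """
    if tree.index != dist.index:
        raise ValidationError("tree and distribution use different taxon indexes")
    if not tree.is_complete():
        raise ValidationError("tree must cover the full taxon set")
    keys, _ = quartet_keys(tree.index.n)
    codes = induced_codes(tree, keys)
    ok = codes >= 0
    rows = np.arange(len(keys))
    return float(dist.weights[rows[ok], codes[ok]].sum())


# ---------------------------------------------------------------------------
# tuple-tree plumbing (leaves are ints; internals are 2-tuples)


def _tuple_to_tree(t, index: TaxonIndex) -> PhyloTree:
    def build(node):
        if isinstance(node, (int, np.integer)):
            return _Node(leaf=int(node))
        v = _Node()
        v.children = [build(c) for c in node]
        return v

    return PhyloTree(build(t), index)


def _replace_leaf(t, leaf, repl):
    if isinstance(t, (int, np.integer)):
        return repl if t == leaf else t
    return tuple(_replace_leaf(c, leaf, repl) for c in t)


def _remove_leaf_and_reroot(t, leaf):
    """Drop ``leaf`` and return the remainder rooted at its attachment."""
    adj: dict = {}
    counter = [0]

    def add_edge(u, v):
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def build(node):
        if isinstance(node, (int, np.integer)):
            return int(node)
        counter[0] -= 1
        nid = counter[0]
        for ch in node:
            add_edge(nid, build(ch))
        return nid

    root = build(t)
    if len(adj[root]) == 2:  # suppress the degree-2 rooted-representation root
        a, b = adj[root]
        adj[a] = [x if x != root else b for x in adj[a]]
        adj[b] = [x if x != root else a for x in adj[b]]
        del adj[root]
    (v,) = adj[leaf]
    nbrs = [u for u in adj[v] if u != leaf]

    def sub(u, parent):
        ns = [x for x in adj[u] if x != parent]
        if not ns:
            return u
        return tuple(sub(x, u) for x in ns)

    if len(nbrs) != 2:
        raise ValidationError("attachment point is not binary")
    return (sub(nbrs[0], v), sub(nbrs[1], v))


def _normalize_record(ids):
    """(p,q,r,s) with p<q, r<s, p<r for a quartet pq|rs."""
    p1 = tuple(sorted(ids[:2]))
    p2 = tuple(sorted(ids[2:]))
    return p1 + p2 if p1[0] < p2[0] else p2 + p1


# ---------------------------------------------------------------------------
# FM-style partitioning


def _record_contrib(rec, side):
    s0, s1 = side[rec[0]], side[rec[1]]
    s2, s3 = side[rec[2]], side[rec[3]]
    tot = s0 + s1 + s2 + s3
    if tot != 2:
        return 0.0  # deferred (3|1 or 4|0)
    if s0 == s1:  # pair together on one side -> the 2|2 crossing matches
        return rec[4]
    if s2 == s3:
        return rec[4]
    return -rec[4]


def _partition(taxa, records, rng, max_fm_passes):
    """Bipartition ``taxa`` maximizing satisfied - violated quartet weight.

    Single-taxon moves are chosen by weighted gain, each taxon moves at
    most once per pass, the best prefix of a pass is retained, and
    passes repeat until none improves.  Sides never shrink below 2.
    """
    ts = sorted(taxa)
    perm = list(rng.permutation(len(ts)))
    half = len(ts) // 2
    side = {}
    for pos, i in enumerate(perm):
        side[ts[i]] = 0 if pos < half else 1
    sizes = [half, len(ts) - half]

    recs_of = {t: [] for t in ts}
    for rec in records:
        for t in rec[:4]:
            recs_of[t].append(rec)

    def gain(t):
        g = 0.0
        for rec in recs_of[t]:
            before = _record_contrib(rec, side)
            side[t] ^= 1
            after = _record_contrib(rec, side)
            side[t] ^= 1
            g += after - before
        return g

    for _ in range(max_fm_passes):
        locked = set()
        seq = []
        cum = 0.0
        best_cum = 0.0
        best_len = 0
        while len(locked) < len(ts):
            best_t = None
            best_g = 0.0
            for t in ts:
                if t in locked or sizes[side[t]] <= 2:
                    continue
                g = gain(t)
                if best_t is None or g > best_g:
                    best_t, best_g = t, g
            if best_t is None:
                break
            sizes[side[best_t]] -= 1
            side[best_t] ^= 1
            sizes[side[best_t]] += 1
            locked.add(best_t)
            seq.append(best_t)
            cum += best_g
            if cum > best_cum + 1e-9:
                best_cum = cum
                best_len = len(seq)
        for t in reversed(seq[best_len:]):  # roll back past the best prefix
            sizes[side[t]] -= 1
            side[t] ^= 1
            sizes[side[t]] += 1
        if best_cum <= 1e-9:
            break
    X = frozenset(t for t in ts if side[t] == 0)
    Y = frozenset(t for t in ts if side[t] == 1)
    return X, Y, side


def _solve(taxa, records, rng, counter, cfg):
    ts = sorted(taxa)
    k = len(ts)
    if k == 1:
        return ts[0]
    if k == 2:
        return (ts[0], ts[1])
    if k == 3:
        return (ts[0], (ts[1], ts[2]))
    if k == 4:
        wsum = [0.0, 0.0, 0.0]
        for rec in records:
            key = tuple(sorted(rec[:4]))
            mate = rec[1] if rec[0] == key[0] else (
                rec[0] if rec[1] == key[0] else (rec[3] if rec[2] == key[0] else rec[2])
            )
            wsum[key.index(mate) - 1] += rec[4]
        code = max(range(3), key=lambda c: (wsum[c], -c))
        a, b, c, d = ts
        pairs = {0: ((a, b), (c, d)), 1: ((a, c), (b, d)), 2: ((a, d), (b, c))}
        return pairs[code]

    X, Y, side = _partition(taxa, records, rng, cfg.max_fm_passes)
    art_x = counter[0]
    art_y = counter[0] + 1
    counter[0] += 2
    sub = ({}, {})
    for rec in records:
        in_x = [t for t in rec[:4] if side[t] == 0]
        cnt = len(in_x)
        if cnt in (4, 0):
            target = sub[0] if cnt == 4 else sub[1]
            key = _normalize_record(rec[:4])
            target[key] = target.get(key, 0.0) + rec[4]
        elif cnt == 3:
            ids = tuple(art_x if side[t] == 1 else t for t in rec[:4])
            key = _normalize_record(ids)
            sub[0][key] = sub[0].get(key, 0.0) + rec[4]
        elif cnt == 1:
            ids = tuple(art_y if side[t] == 0 else t for t in rec[:4])
            key = _normalize_record(ids)
            sub[1][key] = sub[1].get(key, 0.0) + rec[4]
        # cnt == 2: resolved (satisfied or violated) at this level
    recs_x = [k + (w,) for k, w in sub[0].items()]
    recs_y = [k + (w,) for k, w in sub[1].items()]
    tx = _solve(X | {art_x}, recs_x, rng, counter, cfg)
    ty = _solve(Y | {art_y}, recs_y, rng, counter, cfg)
    return _replace_leaf(tx, art_x, _remove_leaf_and_reroot(ty, art_y))


# ---------------------------------------------------------------------------
# SPR refinement


def _tree_to_tuple_adj(tree: PhyloTree):
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
    if len(adj[root]) == 2:
        a, b = adj[root]
        adj[a] = [x if x != root else b for x in adj[a]]
        adj[b] = [x if x != root else a for x in adj[b]]
        del adj[root]
    return adj


def _adj_to_tree(adj, index: TaxonIndex) -> PhyloTree:
    ref = min(v for v in adj if v >= 0)

    def sub(u, parent):
        node = _Node(leaf=u if u >= 0 else None)
        node.children = [sub(x, u) for x in adj[u] if x != parent]
        return node

    (attach,) = adj[ref]
    root = _Node()
    root.children = [_Node(leaf=ref), sub(attach, ref)]
    return PhyloTree(root, index)


def _spr_neighbors(adj):
    """Yield adjacency maps of all subtree-prune-regraft neighbours."""
    directed = [(u, v) for u in adj for v in adj[u]]
    for u, v in directed:
        # prune the component containing u after cutting edge (u, v);
        # v must be internal so the remainder keeps at least one edge
        if len(adj[v]) != 3:
            continue
        p, q = [x for x in adj[v] if x != u]
        # collect the remaining component (v spliced out: p-q replaces p-v-q)
        seen = {v, u}
        stack, comp = [p, q], []
        while stack:
            w = stack.pop()
            if w in seen:
                continue
            seen.add(w)
            comp.append(w)
            stack.extend(x for x in adj[w] if x not in seen)
        remaining = {(p, q)}
        for w in comp:
            for x in adj[w]:
                if x not in (v,) and x in seen and x != u and (x, w) not in remaining:
                    remaining.add((w, x))
        for x, y in remaining:
            if {x, y} == {p, q}:
                continue  # regrafting onto the spliced edge recreates the input
            new = {k: list(vs) for k, vs in adj.items()}
            new[p] = [z if z != v else q for z in new[p]]
            new[q] = [z if z != v else p for z in new[q]]
            new[x] = [z if z != y else v for z in new[x]]
            new[y] = [z if z != x else v for z in new[y]]
            new[v] = [u, x, y]
            yield new


def _spr_refine(tree: PhyloTree, dist: WeightedQuartetDistribution):
    """Greedy hill-climb over SPR neighbours of the quartet-support objective.

    Polishes the divide-and-conquer output to a local optimum under
    subtree-prune-regraft moves; a move is accepted only on strict
    improvement, so the returned score never decreases and never
    exceeds the exact optimum.
    """
    score = quartet_support(tree, dist)
    while True:
        adj = _tree_to_tuple_adj(tree)
        best_sc, best_tree = score, None
        for cand_adj in _spr_neighbors(adj):
            cand = _adj_to_tree(cand_adj, tree.index)
            sc = quartet_support(cand, dist)
            if sc > best_sc + 1e-9:
                best_sc, best_tree = sc, cand
        if best_tree is None:
            return tree, score
        tree, score = best_tree, best_sc


# ---------------------------------------------------------------------------
# public entry points


def caterpillar_tree(index: TaxonIndex) -> PhyloTree:
    """The caterpillar over the index's taxa in label order."""
    ids = list(range(index.n))
    t = (ids[0], ids[1])
    for i in ids[2:]:
        t = (t, i)
    return _tuple_to_tree(t, index)


def _records_from_dist(dist: WeightedQuartetDistribution):
    recs = []
    for key, code, w in dist.nonzero_entries():
        (p1, p2), (p3, p4) = QuartetTopology(key, code).pairs()
        recs.append((p1, p2, p3, p4, w))
    return recs


def _bipart_encoding(tree: PhyloTree):
    return tuple(sorted(tree.bipartitions()))


def exact_amalgamate(
    dist: WeightedQuartetDistribution, exact_threshold: int = 9
) -> tuple[PhyloTree, float]:
    """Exhaustive search over all (2n-5)!! unrooted binary topologies.

    Returns a maximizer of :func:`quartet_support`; ties break toward
    the lexicographically smallest sorted-bipartition encoding, making
    the result unique and reproducible.
    """
    n = dist.index.n
    if exact_threshold > 9:
        raise ValidationError("exact_threshold must be <= 9")
    if n > exact_threshold:
        raise ValidationError(
            f"exact search refused for n={n} > threshold {exact_threshold}"
        )

    def insertions(t, leaf):
        yield (t, leaf)
        if not isinstance(t, (int, np.integer)):
            left, right = t
            for l2 in insertions(left, leaf):
                yield (l2, right)
            for r2 in insertions(right, leaf):
                yield (left, r2)

    def gen(k):  # all shapes over leaves 1..k (leaf 0 handled outside)
        if k == 1:
            yield 1
            return
        for t in gen(k - 1):
            yield from insertions(t, k)

    best_score = -np.inf
    best_tree = None
    best_enc = None
    for rest in gen(n - 1):
        tree = _tuple_to_tree((0, rest), dist.index)
        sc = quartet_support(tree, dist)
        if sc > best_score + 1e-9:
            best_score, best_tree, best_enc = sc, tree, None
        elif abs(sc - best_score) <= 1e-9:
            if best_enc is None:
                best_enc = _bipart_encoding(best_tree)
            enc = _bipart_encoding(tree)
            if enc < best_enc:
                best_tree, best_enc = tree, enc
    return best_tree, float(best_score)


def amalgamate(
    dist: WeightedQuartetDistribution, cfg: AmalgamationConfig | None = None
) -> tuple[PhyloTree, float]:
    """Heuristic weighted quartet amalgamation.

    Runs the recursive FM-style search from ``cfg.restarts`` seeded
    random balanced initial bipartitions, polishes each restart's tree
    by SPR hill-climbing (unless ``cfg.spr_refine`` is off), and returns
    the best tree with its quartet support.  Delegates to exhaustive
    search for n <= 5, where enumeration is trivially cheap.
    """
    if cfg is None:
        cfg = AmalgamationConfig()
    n = dist.index.n
    if n < 4:
        raise ValidationError("amalgamation needs at least 4 taxa")
    if not dist.weights.any():
        log.warning("all-zero quartet distribution; returning an arbitrary caterpillar")
        return caterpillar_tree(dist.index), 0.0
    if n <= 5:
        return exact_amalgamate(dist, exact_threshold=max(5, min(9, n)))

    records = _records_from_dist(dist)
    taxa = frozenset(range(n))
    best_tree = None
    best_score = -np.inf
    for r in range(cfg.restarts):
        rng = np.random.default_rng([abs(cfg.seed) % (2**31), r])
        counter = [n]
        t = _solve(taxa, records, rng, counter, cfg)
        tree = _tuple_to_tree(t, dist.index)
        if cfg.spr_refine:
            tree, sc = _spr_refine(tree, dist)
        else:
            sc = quartet_support(tree, dist)
        if sc > best_score:
            best_score, best_tree = sc, tree
    return best_tree, float(best_score)
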