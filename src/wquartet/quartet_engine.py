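"""Weighted quartet distributions: induction, counting, and serialization.

For n taxa there are C(n,4) four-taxon sets and each admits exactly
three resolved unrooted topologies.  The canonical pairing code of a
topology on the sorted key (a < b < c < d) records the partner of the
smallest taxon: 0 = ab|cd, 1 = ac|bd, 2 = ad|bc.  All counting,
tie-breaking and serialization in the package derive from this single
canonical form.

Gene-tree-frequency (GTF) weights are the number (or weight) of input
trees inducing each topology; the "all quartets" distribution keeps all
three weights per key, the "dominant" variants keep only the argmax.
"""

from __future__ import annotations

import itertools
import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .tree_io import GeneTreeCollection, PhyloTree, TaxonIndex

__all__ = [
    "QuartetTopology",
    "WeightedQuartetDistribution",
    "MismatchReport",
    "quartet_keys",
    "induced_topology",
    "induced_codes",
    "distribution_from_collection",
    "to_dominant",
    "dominant_mismatch_count",
    "write_weighted_quartets",
    "read_weighted_quartets",
]

log = logging.getLogger(__name__)

_PAIRINGS = ((0, 1, 2, 3), (0, 2, 1, 3), (0, 3, 1, 2))  # positions paired with a

_keys_cache: dict[int, tuple[np.ndarray, dict]] = {}


def quartet_keys(n: int) -> tuple[np.ndarray, dict]:
    """All C(n,4) sorted 4-taxon keys as an array, plus key -> row lookup."""
    if n < 4:
        raise ValidationError(f"quartet operations need n >= 4 taxa, got {n}")
    if n not in _keys_cache:
        keys = np.array(list(itertools.combinations(range(n), 4)), dtype=np.int64)
        rank = {tuple(k): i for i, k in enumerate(keys)}
        _keys_cache[n] = (keys, rank)
    return _keys_cache[n]


@dataclass(frozen=True)
class QuartetTopology:
    """A resolved topology on one 4-taxon set."""

    key: tuple[int, int, int, int]
    pairing: int  # 0 = ab|cd, 1 = ac|bd, 2 = ad|bc

    def pairs(self) -> tuple[tuple[int, int], tuple[int, int]]:
        p = _PAIRINGS[self.pairing]
        k = self.key
        return (k[p[0]], k[p[1]]), (k[p[2]], k[p[3]])


class WeightedQuartetDistribution:
    """Sparse map from each 4-taxon set to the weights of its 3 topologies.

    Backed by a dense (C(n,4), 3) float array; absent keys are all-zero
    rows.  ``total_weight`` is the summed weight of the contributing
    input trees; for binary complete inputs each present row sums to it.
    """

    def __init__(self, index: TaxonIndex, weights: np.ndarray | None = None,
                 total_weight: float = 0.0, unresolved_mass: float = 0.0):
        keys, _ = quartet_keys(index.n)
        if weights is None:
            weights = np.zeros((len(keys), 3), dtype=np.float64)
        if weights.shape != (len(keys), 3):
            raise ValidationError("weight array shape does not match C(n,4) x 3")
        if np.any(weights < 0):
            raise ValidationError("quartet weights must be nonnegative")
        self.index = index
        self.weights = weights
        self.total_weight = float(total_weight)
        self.unresolved_mass = float(unresolved_mass)

    # -- access ----------------------------------------------------------

    @property
    def n_keys(self) -> int:
        return self.weights.shape[0]

    def get(self, key) -> tuple[float, float, float]:
        _, rank = quartet_keys(self.index.n)
        return tuple(self.weights[rank[tuple(key)]])

    def set(self, key, w0: float, w1: float, w2: float) -> None:
        _, rank = quartet_keys(self.index.n)
        self.weights[rank[tuple(key)]] = (w0, w1, w2)

    def nonzero_entries(self):
        """Yield (key tuple, pairing code, weight) for every nonzero weight."""
        keys, _ = quartet_keys(self.index.n)
        rows, codes = np.nonzero(self.weights)
        for r, c in zip(rows, codes):
            yield tuple(keys[r]), int(c), float(self.weights[r, c])

    def copy(self) -> "WeightedQuartetDistribution":
        return WeightedQuartetDistribution(
            self.index, self.weights.copy(), self.total_weight, self.unresolved_mass
        )

    def __eq__(self, other):
        return (
            isinstance(other, WeightedQuartetDistribution)
            and self.index == other.index
            and np.allclose(self.weights, other.weights)
        )


# ---------------------------------------------------------------------------
# induction


def induced_codes(tree: PhyloTree, keys: np.ndarray | None = None) -> np.ndarray:
    """Vector of induced pairing codes over all keys; -1 marks unresolved.

    Uses the LCA-depth rule: among the three pairings of a 4-taxon set,
    the one whose two pair-LCAs are jointly deepest is the topology the
    tree induces; a tie means the restricted tree is a star.
    """
    if keys is None:
        keys, _ = quartet_keys(tree.index.n)
    M = tree.lca_depth_matrix()
    a, b, c, d = keys[:, 0], keys[:, 1], keys[:, 2], keys[:, 3]
    s = np.stack(
        [M[a, b] + M[c, d], M[a, c] + M[b, d], M[a, d] + M[b, c]], axis=1
    )
    present = (M[a, a] >= 0) & (M[b, b] >= 0) & (M[c, c] >= 0) & (M[d, d] >= 0)
    best = s.max(axis=1, keepdims=True)
    ties = (s == best).sum(axis=1)
    codes = np.where((ties == 1) & present, s.argmax(axis=1), -1)
    codes[~present] = -2  # taxa absent from the tree
    return codes.astype(np.int8)


def induced_topology(tree: PhyloTree, key) -> QuartetTopology | None:
    """Topology ``tree`` induces on one 4-taxon set; None if unresolved."""
    key = tuple(key)
    if len(key) != 4 or len(set(key)) != 4 or list(key) != sorted(key):
        raise ValidationError(f"key must be a strictly increasing 4-tuple, got {key}")
    leaves = tree.leaf_ids()
    for t in key:
        if t not in leaves:
            raise ValidationError(
                f"taxon {tree.index.label_of(t)!r} absent from tree"
            )
    M = tree.lca_depth_matrix()
    a, b, c, d = key
    s = (M[a, b] + M[c, d], M[a, c] + M[b, d], M[a, d] + M[b, c])
    best = max(s)
    if s.count(best) > 1:
        return None
    return QuartetTopology(key, s.index(best))


# ---------------------------------------------------------------------------
# distributions


def distribution_from_collection(
    col: GeneTreeCollection,
    normalization: str = "raw",
    unresolved: str = "zero",
) -> WeightedQuartetDistribution:
    """Gene-tree-frequency weights for every 4-taxon set.

    ``normalization="raw"`` counts each tree with its stored weight
    (unit by default), so a gene with m sampled trees contributes m per
    key; ``"per-gene"`` rescales every gene's trees to total weight 1,
    so genes with unequal sample counts contribute equally.

    Unresolved restricted quartets (possible only for polytomous input)
    contribute nothing under ``unresolved="zero"`` (tallied in
    ``unresolved_mass``) or 1/3 to each topology under ``"split"``.
    """
    if normalization not in ("raw", "per-gene"):
        raise ValidationError(f"unknown normalization {normalization!r}")
    if unresolved not in ("zero", "split"):
        raise ValidationError(f"unknown unresolved policy {unresolved!r}")
    index = col.index
    keys, _ = quartet_keys(index.n)
    W = np.zeros((len(keys), 3), dtype=np.float64)
    total = 0.0
    unresolved_mass = 0.0
    rows = np.arange(len(keys))
    for g, trees in enumerate(col.genes):
        gene_w = sum(w for _, w in trees)
        for tree, w in trees:
            eff = w if normalization == "raw" else w / gene_w
            codes = induced_codes(tree, keys)
            if np.any(codes == -2):
                raise ValidationError(f"gene {g}: tree is not complete")
            ok = codes >= 0
            np.add.at(W, (rows[ok], codes[ok]), eff)
            n_unres = int((~ok).sum())
            if n_unres:
                if unresolved == "split":
                    W[~ok] += eff / 3.0
                else:
                    unresolved_mass += eff * n_unres
            total += eff
    return WeightedQuartetDistribution(index, W, total, unresolved_mass)


@dataclass
class DominantInfo:
    """Bookkeeping from :func:`to_dominant`."""

    tie_keys: list = field(default_factory=list)
    dropped_keys: list = field(default_factory=list)


def to_dominant(
    dist: WeightedQuartetDistribution, weighted: bool = True
) -> WeightedQuartetDistribution:
    """Keep only each key's highest-weight topology.

    ``weighted`` retains the winning weight; otherwise every dominant
    quartet gets unit weight.  Ties go to the lowest pairing code and
    are logged; all-zero keys are dropped (logged).  The result records
    tie/drop bookkeeping on ``.dominant_info`` and is idempotent under
    repeated application.
    """
    keys, _ = quartet_keys(dist.index.n)
    W = dist.weights
    sums = W.sum(axis=1)
    dom = W.argmax(axis=1)  # argmax takes the lowest index on ties
    best = W[np.arange(len(W)), dom]
    present = sums > 0
    ties = present & ((W == best[:, None]).sum(axis=1) > 1)
    out = np.zeros_like(W)
    out[present, dom[present]] = best[present] if weighted else 1.0
    info = DominantInfo(
        tie_keys=[tuple(k) for k in keys[ties]],
        dropped_keys=[tuple(k) for k in keys[~present]] if (~present).any() else [],
    )
    if info.tie_keys:
        log.info("to_dominant: %d tied keys broken toward lowest pairing code",
                 len(info.tie_keys))
    if info.dropped_keys:
        log.info("to_dominant: %d all-zero keys dropped", len(info.dropped_keys))
    res = WeightedQuartetDistribution(
        dist.index, out, dist.total_weight, dist.unresolved_mass
    )
    res.dominant_info = info
    return res


@dataclass
class MismatchReport:
    """Dominant-quartet disagreement between two distributions."""

    topology_mismatches: list
    undefined_mismatches: list  # dominant defined on one side only

    @property
    def count(self) -> int:
        return len(self.topology_mismatches) + len(self.undefined_mismatches)


def dominant_mismatch_count(
    dist_a: WeightedQuartetDistribution, dist_b: WeightedQuartetDistribution
) -> MismatchReport:
    """Count 4-taxon sets whose dominant topology differs between A and B.

    The same lowest-code tie-break as :func:`to_dominant` applies to
    both sides; keys with a dominant defined on only one side count as
    mismatches and are reported separately.
    """
    if dist_a.index != dist_b.index:
        raise ValidationError("distributions are over different taxon indexes")
    keys, _ = quartet_keys(dist_a.index.n)
    da, db = dist_a.weights.argmax(axis=1), dist_b.weights.argmax(axis=1)
    pa, pb = dist_a.weights.sum(axis=1) > 0, dist_b.weights.sum(axis=1) > 0
    topo = pa & pb & (da != db)
    undef = pa ^ pb
    return MismatchReport(
        topology_mismatches=[tuple(k) for k in keys[topo]],
        undefined_mismatches=[tuple(k) for k in keys[undef]],
    )


# ---------------------------------------------------------------------------
# serialization (wQFM and QMC dialects)


def _format_weight(w: float) -> str:
    if float(w) == int(w):
        return str(int(w))
    return repr(float(w))


def write_weighted_quartets(
    dist: WeightedQuartetDistribution, dialect: str, path
) -> None:
    """Write nonzero weighted quartets in an amalgamation-tool dialect.

    wqfm dialect: one ``((L1,L2),(L3,L4)); W`` line per topology, taxa
    of each pair sorted, the pair holding the smallest label first.
    qmc dialect: ``i1,i2|i3,i4:W`` with 1-based integer ids; the
    label<TAB>integer map is emitted alongside at ``<path>.map``.
    """
    index = dist.index
    if dialect == "wqfm":
        with open(path, "w") as fh:
            for key, code, w in dist.nonzero_entries():
                (p1, p2), (p3, p4) = QuartetTopology(key, code).pairs()
                fh.write(
                    f"(({index.label_of(p1)},{index.label_of(p2)}),"
                    f"({index.label_of(p3)},{index.label_of(p4)})); {_format_weight(w)}\n"
                )
    elif dialect == "qmc":
        with open(str(path) + ".map", "w") as mh:
            for i, lab in enumerate(index.labels):
                mh.write(f"{lab}\t{i + 1}\n")
        with open(path, "w") as fh:
            for key, code, w in dist.nonzero_entries():
                (p1, p2), (p3, p4) = QuartetTopology(key, code).pairs()
                fh.write(f"{p1 + 1},{p2 + 1}|{p3 + 1},{p4 + 1}:{_format_weight(w)}\n")
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")


def _canonical_code(ids) -> tuple[tuple, int]:
    """Sorted key + pairing code from 4 taxa where (ids[0],ids[1]) and
    (ids[2],ids[3]) are the together-pairs."""
    key = tuple(sorted(ids))
    a = key[0]
    if a == ids[0] or a == ids[1]:
        mate = ids[1] if a == ids[0] else ids[0]
    else:
        mate = ids[3] if a == ids[2] else ids[2]
    return key, key.index(mate) - 1


def read_weighted_quartets(
    path, dialect: str, index: TaxonIndex
) -> WeightedQuartetDistribution:
    """Read a weighted-quartet file; duplicate lines accumulate by summation.

    ``total_weight`` is set to the maximum per-key topology sum, the
    tightest bound consistent with an unknown number of source trees.
    """
    if dialect not in ("wqfm", "qmc"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    keys, rank = quartet_keys(index.n)
    W = np.zeros((len(keys), 3), dtype=np.float64)
    qmc_map = None
    if dialect == "qmc" and os.path.exists(str(path) + ".map"):
        qmc_map = {}
        with open(str(path) + ".map") as mh:
            for line in mh:
                lab, num = line.rstrip("\n").split("\t")
                qmc_map[int(num)] = index.id_of(lab)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                if dialect == "wqfm":
                    topo_s, w_s = line.rsplit(";", 1)
                    inner = topo_s.strip().strip("()")
                    left, right = inner.split("),(")
                    l1, l2 = (s.strip() for s in left.strip("()").split(","))
                    l3, l4 = (s.strip() for s in right.strip("()").split(","))
                    ids = [index.id_of(l) for l in (l1, l2, l3, l4)]
                    w = float(w_s)
                else:
                    topo_s, w_s = line.rsplit(":", 1)
                    left, right = topo_s.split("|")
                    nums = [int(x) for x in left.split(",")] + [
                        int(x) for x in right.split(",")
                    ]
                    if qmc_map is not None:
                        ids = [qmc_map[x] for x in nums]
                    else:
                        ids = [x - 1 for x in nums]
                    w = float(w_s)
            except Exception as exc:
                raise ValidationError(f"{path}, line {lineno}: {exc}") from exc
            if w < 0 or math.isnan(w):
                raise ValidationError(f"{path}, line {lineno}: bad weight {w}")
            if len(set(ids)) != 4:
                raise ValidationError(f"{path}, line {lineno}: taxa not distinct")
            key, code = _canonical_code(ids)
            W[rank[key], code] += w
    total = float(W.sum(axis=1).max()) if W.any() else 0.0
    return WeightedQuartetDistribution(index, W, total_weight=total)
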