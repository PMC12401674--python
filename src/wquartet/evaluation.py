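"""Scoring species trees against gene-tree sets.

Covers the quartet score (number of gene-tree quartets agreeing with a
candidate species tree), the normalized Robinson-Foulds rate, the
"overshoot" diagnostic (an estimated tree beating the true tree's
quartet score against error-prone estimated gene trees, even though the
true tree is optimal against true gene trees), and the paired Wilcoxon
signed-rank comparison of per-replicate error vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .errors import ValidationError
from .quartet_engine import induced_codes, quartet_keys
from .tree_io import GeneTreeCollection, PhyloTree

__all__ = [
    "ScoreReport",
    "WilcoxonResult",
    "quartet_score",
    "rf_rate",
    "overshoot_report",
    "wilcoxon_compare",
    "format_report",
    "report_to_json",
]


def quartet_score(tree: PhyloTree, col: GeneTreeCollection) -> float:
    """Summed (weighted) count of gene-tree quartets agreeing with ``tree``.

    Computed by direct per-gene-tree comparison of induced topologies;
    it equals ``quartet_support(tree, distribution_from_collection(col,
    "raw"))``, and the two routes are kept as independent paths.
    """
    if tree.index != col.index or not tree.is_complete():
        raise ValidationError("tree and collection must share one complete taxon set")
    keys, _ = quartet_keys(tree.index.n)
    ref = induced_codes(tree, keys)
    score = 0.0
    for _, gt, w in col.iter_trees():
        if not gt.is_complete():
            raise ValidationError("gene tree is not complete")
        codes = induced_codes(gt, keys)
        score += w * float(((codes == ref) & (codes >= 0)).sum())
    return score


def rf_rate(t1: PhyloTree, t2: PhyloTree) -> float:
    """Normalized Robinson-Foulds distance between two binary trees.

    |B1 symm-diff B2| / (2(n-3)) over nontrivial bipartitions; for
    binary trees false-positive, false-negative and RF rates coincide.
    """
    if t1.index != t2.index or t1.leaf_ids() != t2.leaf_ids():
        raise ValidationError("trees are over different leaf sets")
    if t1.has_polytomy or t2.has_polytomy:
        raise ValidationError("RF rate is defined here for binary trees only")
    n = len(t1.leaf_ids())
    if n < 4:
        raise ValidationError("RF rate needs at least 4 leaves")
    b1, b2 = t1.bipartitions(), t2.bipartitions()
    return len(b1 ^ b2) / (2 * (n - 3))


@dataclass
class ScoreReport:
    """Per-candidate quartet scores and their excess over the true tree's."""

    tree_id: str
    score_vs_true: float
    score_vs_estimated: float
    true_tree_score_vs_true: float
    true_tree_score_vs_estimated: float
    overshoot: float  # score_vs_estimated - true tree's score vs estimated
    rf_rate: float


def overshoot_report(
    candidates,
    true_tree: PhyloTree,
    true_genes: GeneTreeCollection,
    est_genes: GeneTreeCollection,
) -> list[ScoreReport]:
    """Score each candidate against true and estimated gene trees.

    ``candidates`` is a sequence of (tree_id, PhyloTree).  The report
    rows carry the data behind quartet-score-vs-RF-rate plots: with
    error-prone estimated gene trees, candidates can overshoot the true
    tree's score even while being topologically worse.
    """
    tt_true = quartet_score(true_tree, true_genes)
    tt_est = quartet_score(true_tree, est_genes)
    out = []
    for tree_id, tree in candidates:
        s_true = quartet_score(tree, true_genes)
        s_est = quartet_score(tree, est_genes)
        out.append(
            ScoreReport(
                tree_id=str(tree_id),
                score_vs_true=s_true,
                score_vs_estimated=s_est,
                true_tree_score_vs_true=tt_true,
                true_tree_score_vs_estimated=tt_est,
                overshoot=s_est - tt_est,
                rf_rate=rf_rate(tree, true_tree),
            )
        )
    return out


@dataclass
class WilcoxonResult:
    statistic: float
    pvalue: float
    n_nonzero: int
    n_dropped: int
    significant: bool  # at alpha = 0.05


def wilcoxon_compare(errs_a, errs_b, alpha: float = 0.05) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired error vectors.

    Zero differences are dropped (and reported); the exact distribution
    is used for up to 25 nonzero pairs, the normal approximation with
    continuity correction above that.  All-zero differences yield the
    "no difference" result p = 1.
    """
    a = np.asarray(errs_a, dtype=float)
    b = np.asarray(errs_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired vectors of equal length required")
    if len(a) < 5:
        raise ValidationError("at least 5 pairs required")
    d = a - b
    nz = int((d != 0).sum())
    dropped = len(d) - nz
    if nz == 0:
        return WilcoxonResult(0.0, 1.0, 0, dropped, False)
    method = "exact" if nz <= 25 else "approx"
    res = stats.wilcoxon(
        a, b, zero_method="wilcox", correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    p = min(1.0, float(res.pvalue))
    return WilcoxonResult(float(res.statistic), p, nz, dropped, p < alpha)


# ---------------------------------------------------------------------------
# report output

_COLUMNS = [
    "tree_id",
    "score_vs_true",
    "score_vs_estimated",
    "true_tree_score_vs_true",
    "true_tree_score_vs_estimated",
    "overshoot",
    "rf_rate",
]


def format_report(reports: list[ScoreReport]) -> str:
    """Deterministic tab-separated table, one row per candidate."""
    lines = ["\t".join(_COLUMNS)]
    for r in reports:
        d = asdict(r)
        row = []
        for c in _COLUMNS:
            v = d[c]
            row.append(f"{v:.6g}" if isinstance(v, float) else str(v))
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def report_to_json(reports: list[ScoreReport]) -> str:
    return json.dumps([asdict(r) for r in reports], indent=2) + "\n"
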