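"""Quartet induction, GTF distributions, dominant reduction, serialization."""

import itertools

import numpy as np
import pytest

from helpers import dendropy_quartet_pairing, random_tree, random_tree_newick
from wquartet import (
    GeneTreeCollection,
    TaxonIndex,
    ValidationError,
    distribution_from_collection,
    dominant_mismatch_count,
    induced_topology,
    parse_newick,
    read_weighted_quartets,
    to_dominant,
    write_newick,
    write_weighted_quartets,
)
from wquartet.quartet_engine import WeightedQuartetDistribution, quartet_keys


class TestInducedTopology:
    def test_cherry_pairs(self):
        t = parse_newick("((A,B),(C,(D,E)));")
        assert induced_topology(t, (0, 1, 2, 3)).pairing == 0  # AB|CD
        # {A,C,D,E}: cherry (D,E) -> DE|AC, partner of A is C -> code 0
        assert induced_topology(t, (0, 2, 3, 4)).pairing == 0

    def test_star_is_unresolved(self):
        t = parse_newick("(A,B,C,D);")
        assert induced_topology(t, (0, 1, 2, 3)) is None

    def test_absent_taxon_raises(self):
        idx = TaxonIndex(["A", "B", "C", "D", "E"])
        t = parse_newick("((A,B),(C,D));", idx)
        with pytest.raises(ValidationError):
            induced_topology(t, (0, 1, 2, 4))

    def test_agrees_with_prune_oracle_on_random_trees(self, rng):
        """LCA-depth induction vs dendropy prune-and-compare, all keys."""
        for n in (5, 6, 8):
            labels = [f"x{i:02d}" for i in range(n)]
            for _ in range(5):
                nw = random_tree_newick(n, rng, labels)
                t = parse_newick(nw)
                for key in itertools.combinations(range(n), 4):
                    labs = [t.index.label_of(i) for i in key]
                    expect = dendropy_quartet_pairing(nw, labs)
                    got = induced_topology(t, key)
                    assert (got.pairing if got else None) == expect


class TestDistribution:
    def test_raw_counts(self, abcd_collection):
        d = distribution_from_collection(abcd_collection, "raw")
        assert d.get((0, 1, 2, 3)) == (2.0, 1.0, 0.0)
        assert d.total_weight == 3.0

    def test_per_gene_normalization_within_distribution(self, abcd_index):
        trees = ["((A,B),(C,D));"] * 3 + ["((A,D),(B,C));"]
        gene = [(parse_newick(t, abcd_index), 1.0) for t in trees]
        col = GeneTreeCollection(abcd_index, [gene], "distribution")
        d = distribution_from_collection(col, "per-gene")
        assert d.get((0, 1, 2, 3)) == (0.75, 0.0, 0.25)

    def test_five_taxon_tree_covers_all_keys(self):
        t = parse_newick("(((A,B),C),(D,E));")
        col = GeneTreeCollection(t.index, [[(t, 1.0)]], "single")
        d = distribution_from_collection(col)
        assert (d.weights.sum(axis=1) == 1.0).all()
        assert d.weights.shape == (5, 3)

    def test_conservation_per_key(self, rng):
        """Binary complete input: weights per key sum to the tree count."""
        idx = TaxonIndex([f"x{i:02d}" for i in range(7)])
        genes = [[(random_tree(7, rng, idx), 1.0)] for _ in range(12)]
        col = GeneTreeCollection(idx, genes, "single")
        d = distribution_from_collection(col, "raw")
        assert np.allclose(d.weights.sum(axis=1), 12.0)
        assert d.unresolved_mass == 0.0

    def test_scaling_linearity(self, abcd_index, rng):
        """g copies of one tree give g times the single-tree distribution."""
        t = random_tree(6, rng)
        col1 = GeneTreeCollection(t.index, [[(t, 1.0)]], "single")
        colg = GeneTreeCollection(t.index, [[(t, 1.0)] for _ in range(5)], "single")
        d1 = distribution_from_collection(col1)
        dg = distribution_from_collection(colg)
        assert np.allclose(dg.weights, 5 * d1.weights)


class TestDominant:
    def test_weighted_keeps_winner_weight(self, abcd_collection):
        d = distribution_from_collection(abcd_collection)
        assert to_dominant(d, weighted=True).get((0, 1, 2, 3)) == (2.0, 0.0, 0.0)
        assert to_dominant(d, weighted=False).get((0, 1, 2, 3)) == (1.0, 0.0, 0.0)

    def test_tie_broken_to_lowest_code_and_logged(self, abcd_index):
        d = WeightedQuartetDistribution(abcd_index)
        d.set((0, 1, 2, 3), 1.5, 1.5, 0.0)
        dom = to_dominant(d)
        assert dom.get((0, 1, 2, 3)) == (1.5, 0.0, 0.0)
        assert dom.dominant_info.tie_keys == [(0, 1, 2, 3)]

    def test_idempotent(self, abcd_collection):
        d = distribution_from_collection(abcd_collection)
        once = to_dominant(d)
        assert to_dominant(once) == once


class TestDominantMismatch:
    def test_self_mismatch_zero_and_symmetry(self, abcd_collection):
        d = distribution_from_collection(abcd_collection)
        assert dominant_mismatch_count(d, d).count == 0

    def test_single_key_disagreement(self, abcd_index):
        a = WeightedQuartetDistribution(abcd_index)
        b = WeightedQuartetDistribution(abcd_index)
        a.set((0, 1, 2, 3), 2, 1, 0)
        b.set((0, 1, 2, 3), 0, 1, 2)
        rep = dominant_mismatch_count(a, b)
        assert rep.count == 1 and rep.topology_mismatches == [(0, 1, 2, 3)]
        assert dominant_mismatch_count(b, a).count == 1

    def test_matches_brute_force_on_random_six_taxon_sets(self, rng):
        """Mismatch count vs an explicit per-key argmax over all 15 keys."""
        idx = TaxonIndex([f"x{i:02d}" for i in range(6)])
        for _ in range(5):
            cols = []
            for _ in range(2):
                genes = [[(random_tree(6, rng, idx), 1.0)] for _ in range(7)]
                cols.append(GeneTreeCollection(idx, genes, "single"))
            da, db = (distribution_from_collection(c) for c in cols)
            expected = 0
            for row, key in enumerate(itertools.combinations(range(6), 4)):
                wa, wb = da.weights[row], db.weights[row]
                if int(np.argmax(wa)) != int(np.argmax(wb)):
                    expected += 1
            assert dominant_mismatch_count(da, db).count == expected

    def test_index_mismatch_rejected(self, abcd_index):
        other = TaxonIndex(["A", "B", "C", "E"])
        with pytest.raises(ValidationError):
            dominant_mismatch_count(
                WeightedQuartetDistribution(abcd_index),
                WeightedQuartetDistribution(other),
            )


class TestSerialization:
    def test_wqfm_dialect_format(self, abcd_collection, tmp_path):
        d = distribution_from_collection(abcd_collection)
        p = tmp_path / "q.wqfm"
        write_weighted_quartets(d, "wqfm", p)
        lines = p.read_text().splitlines()
        assert "((A,B),(C,D)); 2" in lines
        assert "((A,C),(B,D)); 1" in lines
        assert len(lines) == 2

    def test_qmc_dialect_and_label_map(self, abcd_index, tmp_path):
        d = WeightedQuartetDistribution(abcd_index)
        d.set((0, 1, 2, 3), 2, 0, 0)
        p = tmp_path / "q.qmc"
        write_weighted_quartets(d, "qmc", p)
        assert p.read_text() == "1,2|3,4:2\n"
        assert "A\t1" in (tmp_path / "q.qmc.map").read_text()

    @pytest.mark.parametrize("dialect", ["wqfm", "qmc"])
    def test_round_trip_exact_for_integer_weights(self, dialect, rng, tmp_path):
        idx = TaxonIndex([f"x{i:02d}" for i in range(6)])
        genes = [[(random_tree(6, rng, idx), 1.0)] for _ in range(9)]
        d = distribution_from_collection(GeneTreeCollection(idx, genes, "single"))
        p = tmp_path / f"q.{dialect}"
        write_weighted_quartets(d, dialect, p)
        back = read_weighted_quartets(p, dialect, idx)
        assert np.array_equal(back.weights, d.weights)

    def test_duplicate_lines_accumulate(self, abcd_index, tmp_path):
        p = tmp_path / "dup.wqfm"
        p.write_text("((A,B),(C,D)); 1\n((A,B),(C,D)); 1\n")
        d = read_weighted_quartets(p, "wqfm", abcd_index)
        assert d.get((0, 1, 2, 3)) == (2.0, 0.0, 0.0)

    def test_malformed_weight_reports_line(self, abcd_index, tmp_path):
        p = tmp_path / "bad.wqfm"
        p.write_text("((A,B),(C,D)); 1\n((A,B),(C,E)); x\n")
        with pytest.raises(ValidationError, match="line 2"):
            read_weighted_quartets(p, "wqfm", abcd_index)
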