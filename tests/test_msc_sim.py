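"""Coalescent simulation, ILS scaling, NNI error model, pseudo-distributions."""


import numpy as np
import pytest

from wquartet import (
    GeneTreeCollection,
    SimConfig,
    ValidationError,
    distribution_from_collection,
    induced_topology,
    parse_newick,
    perturb_trees,
    rf_rate,
    sample_pseudo_distribution,
    scale_internal_branches,
    simulate_gene_trees,
    write_newick,
)
from wquartet.msc_sim import model_species_tree, write_dataset


def _concordance(sp, col, key=(0, 1, 2, 3)):
    ref = induced_topology(sp, key).pairing
    hits = [induced_topology(g[0][0], key).pairing == ref for g in col.genes]
    return float(np.mean(hits))


class TestScaleInternalBranches:
    def test_identity_and_doubling(self):
        sp = model_species_tree(5, internal_length=0.5)
        same = scale_internal_branches(sp, 1.0)
        assert write_newick(same, with_lengths=True) == write_newick(sp, with_lengths=True)
        doubled = scale_internal_branches(sp, 2.0)
        assert "):1," in write_newick(doubled, with_lengths=True)
        # pendant edges unchanged
        assert "T1:1" in write_newick(doubled, with_lengths=True).replace("T01", "T1")

    def test_composition(self):
        sp = model_species_tree(6, internal_length=0.4)
        a = scale_internal_branches(scale_internal_branches(sp, 0.5), 0.5)
        b = scale_internal_branches(sp, 0.25)
        assert write_newick(a, with_lengths=True) == write_newick(b, with_lengths=True)

    def test_missing_lengths_rejected(self):
        t = parse_newick("((A,B),(C,D));")
        with pytest.raises(ValidationError):
            scale_internal_branches(t, 2.0)


class TestSimulateGeneTrees:
    def test_star_limit_symmetry(self):
        """Internal branch ~0: the three quartet topologies are equifrequent."""
        sp = model_species_tree(4, internal_length=1e-9)
        col = simulate_gene_trees(SimConfig(species_tree=sp, n_genes=3000, seed=2))
        counts = np.zeros(3)
        for g in col.genes:
            counts[induced_topology(g[0][0], (0, 1, 2, 3)).pairing] += 1
        freqs = counts / counts.sum()
        se = 3 * np.sqrt((1 / 3) * (2 / 3) / 3000)
        assert np.all(np.abs(freqs - 1 / 3) < se)

    def test_concordance_closed_form_half_unit(self):
        """t = 0.5 cherry branch: concordance = 1 - (2/3)e^{-0.5}."""
        sp = model_species_tree(4, internal_length=0.5)
        col = simulate_gene_trees(SimConfig(species_tree=sp, n_genes=6000, seed=3))
        expect = 1 - (2 / 3) * np.exp(-0.5)
        se = np.sqrt(expect * (1 - expect) / 6000)
        assert abs(_concordance(sp, col) - expect) < 3 * se

    def test_long_branch_is_nearly_always_concordant(self):
        sp = model_species_tree(4, internal_length=10.0)
        col = simulate_gene_trees(SimConfig(species_tree=sp, n_genes=2000, seed=4))
        assert _concordance(sp, col) >= 0.999 - 3 * np.sqrt(0.001 / 2000)

    def test_seed_determinism_byte_identical(self):
        sp = model_species_tree(8)
        cfg = SimConfig(species_tree=sp, n_genes=10, seed=99)
        a = simulate_gene_trees(cfg)
        b = simulate_gene_trees(cfg)
        for (x,), (y,) in zip(a.genes, b.genes):
            assert write_newick(x[0], True) == write_newick(y[0], True)

    def test_ils_monotonicity(self):
        """Gene-tree/species-tree RF rises as internal branches shrink."""
        sp = model_species_tree(10)
        means = []
        for scale in (2.0, 1.0, 0.5):
            col = simulate_gene_trees(
                SimConfig(species_tree=sp, n_genes=300, ils_scale=scale, seed=7)
            )
            means.append(np.mean([rf_rate(g[0][0], sp) for g in col.genes]))
        assert means[0] < means[1] < means[2]

    def test_polytomous_species_tree_rejected(self):
        t = parse_newick("(A:1,B:1,C:1,D:1);")
        with pytest.raises(ValidationError):
            simulate_gene_trees(SimConfig(species_tree=t, n_genes=1))


class TestPerturbTrees:
    def test_zero_moves_is_identity(self, rng):
        sp = model_species_tree(10)
        col = simulate_gene_trees(SimConfig(species_tree=sp, n_genes=5, seed=1))
        out = perturb_trees(col, 0, seed=9)
        assert all(rf_rate(a[0][0], b[0][0]) == 0.0 for a, b in zip(col.genes, out.genes))

    def test_single_nni_changes_exactly_one_split(self):
        """Exhaustive over seeds at n=6: one move flips one bipartition."""
        sp = model_species_tree(6)
        col = simulate_gene_trees(SimConfig(species_tree=sp, n_genes=30, seed=5))
        out = perturb_trees(col, 1, seed=6)
        for a, b in zip(col.genes, out.genes):
            assert rf_rate(a[0][0], b[0][0]) == pytest.approx(1 / 3)  # 2/(2(6-3))

    def test_mean_rf_nondecreasing_in_error(self):
        sp = model_species_tree(15)
        col = simulate_gene_trees(SimConfig(species_tree=sp, n_genes=40, seed=8))
        means = []
        for k in (0, 1, 4, 10):
            out = perturb_trees(col, k, seed=11)
            means.append(np.mean([rf_rate(a[0][0], b[0][0])
                                  for a, b in zip(col.genes, out.genes)]))
        assert all(x <= y + 1e-12 for x, y in zip(means, means[1:]))


class TestPseudoDistribution:
    def test_error_free_sample_collapses_under_normalization(self, rng):
        sp = model_species_tree(8)
        col = simulate_gene_trees(SimConfig(species_tree=sp, n_genes=6, seed=12))
        dist = sample_pseudo_distribution(col, m=50, error_nni=0, seed=13)
        assert dist.mode == "distribution"
        assert dist.trees_per_gene() == [50] * 6
        d1 = distribution_from_collection(col, "raw")
        d2 = distribution_from_collection(dist, "per-gene")
        assert np.allclose(d1.weights, d2.weights)

    def test_moderate_error_preserves_dominant_signal(self):
        """Dominant topology per key still matches the source tree for a
        large majority of keys under 2-NNI sampling noise."""
        sp = model_species_tree(10)
        col = simulate_gene_trees(SimConfig(species_tree=sp, n_genes=8, seed=14))
        dist = sample_pseudo_distribution(col, m=60, error_nni=2, seed=15)
        agree = 0
        total = 0
        for g_src, g_dist in zip(col.genes, dist.genes):
            src_col = GeneTreeCollection(col.index, [g_src], "single")
            one = GeneTreeCollection(col.index, [g_dist], "distribution")
            ds = distribution_from_collection(src_col)
            dd = distribution_from_collection(one, "per-gene")
            dom_s = ds.weights.argmax(axis=1)
            dom_d = dd.weights.argmax(axis=1)
            agree += int((dom_s == dom_d).sum())
            total += len(dom_s)
        assert agree / total >= 0.8


class TestWriteDataset:
    def test_fixed_seed_runs_identical(self, tmp_path):
        sp = model_species_tree(6)
        cfg = SimConfig(species_tree=sp, n_genes=8, error_nni=2,
                        trees_per_gene=3, seed=21)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_dataset(cfg, d1)
        write_dataset(cfg, d2)
        for name in ("species_tree.nwk", "gene_trees.txt",
                     "estimated_gene_trees.txt", "gene_0000.txt"):
            assert (d1 / name).read_text() == (d2 / name).read_text()
        assert "seed = 21" in (d1 / "manifest.txt").read_text()
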