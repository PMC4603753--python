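"""Simulation cascade: Yule species trees, HGT locus trees, coalescent gene
trees, GTR+Gamma alignments, and the distance-based gene-tree estimator."""

import math

import numpy as np
import pytest

from hgtquartets.quartets import build_quartet_table
from hgtquartets.simulate import (
    COALESCENT_TIME_FACTOR,
    Alignment,
    GTRParams,
    LocusTree,
    SimulationConfig,
    assign_ages,
    estimate_gene_tree,
    events_to_rate,
    expected_tree_length,
    simulate_alignment,
    simulate_gene_tree,
    simulate_locus_tree,
    simulate_species_tree,
    simulate_replicate,
)
from hgtquartets.trees import (
    PhyloTree,
    TreeNode,
    bipartition_set,
    parse_newick,
    rf_distance,
)

CFG = SimulationConfig()


class TestSpeciesTree:
    def test_ultrametric_with_requested_height(self, rng):
        t = simulate_species_tree(CFG, rng)
        assert t.n_leaves == 51
        assert t.is_binary()
        depths = {}
        depths[id(t.root)] = 0.0
        for node in t.preorder():
            for c in node.children:
                depths[id(c)] = depths[id(node)] + c.length
        leaf_depths = [depths[id(l)] for l in t.leaves()]
        # outgroup depth = ratio * ingroup height
        assert max(leaf_depths) == pytest.approx(4e6, rel=1e-9)
        assert min(leaf_depths) == pytest.approx(max(leaf_depths), rel=1e-9)

    def test_seeded_determinism(self):
        t1 = simulate_species_tree(CFG, np.random.default_rng(5))
        t2 = simulate_species_tree(CFG, np.random.default_rng(5))
        assert t1.newick() == t2.newick()

    def test_mean_total_length_matches_analytic_value(self, rng):
        # the analytic expectation (~4.3e7 generations under defaults) is
        # what converts transfer rates into expected events per gene
        total = 0.0
        reps = 200
        for _ in range(reps):
            t = simulate_species_tree(CFG, rng)
            total += sum(n.length for n in t.preorder() if n.parent is not None)
        mean = total / reps
        assert mean == pytest.approx(expected_tree_length(CFG), rel=0.25)
        assert expected_tree_length(CFG) == pytest.approx(4e7, rel=0.25)

    def test_too_few_taxa_rejected(self, rng):
        with pytest.raises(ValueError):
            SimulationConfig(n_ingroup=3)


class TestLocusTree:
    def test_zero_rate_is_identity(self, rng):
        st = simulate_species_tree(CFG, rng)
        lt = simulate_locus_tree(st, 0.0, rng=rng)
        assert lt.events == []
        assert rf_distance(lt.tree, st) == 0

    def test_mean_event_count_tracks_rate(self, rng):
        st = simulate_species_tree(CFG, rng)
        total_len = sum(n.length for n in st.preorder() if n.parent is not None)
        rate = 2e-8
        events = [len(simulate_locus_tree(st, rate, rng=rng).events)
                  for _ in range(400)]
        assert np.mean(events) == pytest.approx(rate * total_len, rel=0.2)

    def test_forced_transfer_rewires_recipient_clade(self):
        # balanced 4-taxon tree; a transfer from a's lineage capturing c's
        # lineage at time t below their divergence must pull c next to a
        st = parse_newick("((a:1000,b:1000):1000,(c:1000,d:1000):1000);")
        assign_ages(st)
        from hgtquartets.simulate import _apply_transfer

        locus = st.copy()
        nodes = {n.label: n for n in locus.preorder() if n.is_leaf}
        _apply_transfer(locus, nodes["a"], nodes["c"], 500.0)
        perturbed = PhyloTree(locus.root)
        assert bipartition_set(perturbed) == bipartition_set(
            parse_newick("((a,c),(b,d));"))

    def test_non_ultrametric_input_rejected(self, rng):
        bad = parse_newick("((a:1,b:2):1,(c:1,d:1):1);")
        with pytest.raises(ValueError, match="ultrametric"):
            simulate_locus_tree(bad, 1e-9, rng=rng)

    def test_leafset_preserved_and_still_ultrametric(self, rng):
        st = simulate_species_tree(CFG, rng)
        lt = simulate_locus_tree(st, 5e-7, rng=rng)
        assert lt.tree.leaf_labels == st.leaf_labels
        assert len(lt.events) > 0
        # a transfer capturing a root-adjacent lineage may suppress the old
        # root, so the locus-tree height can only shrink, never grow
        assert lt.tree.root.age <= st.root.age + 1e-6
        for leaf in lt.tree.leaves():
            assert leaf.age == pytest.approx(0.0, abs=1e-6)


class TestGeneTree:
    def test_tiny_population_forces_species_topology(self, rng):
        st = simulate_species_tree(SimulationConfig(n_ingroup=10), rng)
        gt = simulate_gene_tree(st, pop_size=1e-3, rng=rng)
        assert rf_distance(gt, st) == 0

    def test_pairwise_coalescent_mean(self, rng):
        # closed form: E[T] = tau + coalescent unit for two lineages
        tau, pop = 1000.0, 500.0
        two = parse_newick(f"(a:{tau},b:{tau});")
        assign_ages(two)
        times = []
        for _ in range(5000):
            gt = simulate_gene_tree(two, pop, rng)
            times.append(gt.root.age)
        expected = tau + COALESCENT_TIME_FACTOR * pop
        assert np.mean(times) == pytest.approx(expected, rel=0.05)

    def test_node_ages_respect_locus_divergences(self, rng):
        st = simulate_species_tree(SimulationConfig(n_ingroup=8), rng)
        gt = simulate_gene_tree(st, 200000.0, rng)
        assert gt.is_binary()
        assert gt.root.age >= st.root.age
        assert gt.leaf_labels == st.leaf_labels

    def test_invalid_pop_size_rejected(self, rng):
        st = simulate_species_tree(SimulationConfig(n_ingroup=6), rng)
        with pytest.raises(ValueError):
            simulate_gene_tree(st, 0.0, rng)

    def test_discordance_monotone_in_pop_size(self):
        cfg = SimulationConfig(n_ingroup=10)
        means = []
        for pop in (1e4, 2e5, 1e6):
            rng = np.random.default_rng(77)
            st = simulate_species_tree(cfg, rng)
            rfs = [rf_distance(simulate_gene_tree(st, pop, rng), st,
                               normalized=True) for _ in range(100)]
            means.append(np.mean(rfs))
        assert means[0] <= means[1] <= means[2]


class TestAlignment:
    def test_zero_branches_give_identical_sequences(self, rng):
        gt = parse_newick("((a:0,b:0):0,(c:0,d:0):0);")
        aln = simulate_alignment(gt, SimulationConfig(seq_length=100), rng)
        assert all((aln.data[0] == aln.data[i]).all() for i in range(4))

    def test_jc_expected_difference_on_one_branch(self, rng):
        # JC69: P(diff) = 3/4 (1 - exp(-4d/3)) for branch length d subs/site
        d = 0.3
        jc_no_rate_variation = GTRParams(
            rates=(1.0,) * 6, freqs=(0.25,) * 4, alpha=1e7)
        cfg = SimulationConfig(
            seq_length=60000, subst_rate=1.0, gtr=jc_no_rate_variation)
        gt = parse_newick(f"(a:{d/2},b:{d/2});")
        aln = simulate_alignment(gt, cfg, rng)
        p = np.mean(aln.data[0] != aln.data[1])
        assert p == pytest.approx(0.75 * (1 - math.exp(-4 * d / 3)), abs=0.01)

    def test_stationary_base_frequencies(self, rng):
        cfg = SimulationConfig(seq_length=50000, subst_rate=1.0)
        gt = parse_newick("((a:0.5,b:0.5):0.5,(c:0.5,d:0.5):0.5);")
        aln = simulate_alignment(gt, cfg, rng)
        freqs = np.bincount(aln.data.ravel(), minlength=4) / aln.data.size
        assert freqs == pytest.approx(np.asarray(cfg.gtr.freqs), abs=0.02)

    def test_fasta_roundtrip(self, rng, tmp_path):
        gt = parse_newick("((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1);")
        aln = simulate_alignment(gt, SimulationConfig(seq_length=50), rng)
        aln.to_fasta(tmp_path / "x.fasta")
        back = Alignment.from_fasta(tmp_path / "x.fasta")
        assert back.labels == aln.labels
        assert (back.data == aln.data).all()

    def test_invalid_gtr_rejected(self):
        with pytest.raises(ValueError):
            GTRParams(rates=(1, 1, 1, 1, 1, -1))
        with pytest.raises(ValueError):
            GTRParams(freqs=(0.5, 0.5, 0.2, 0.2))


class TestGeneTreeEstimation:
    def test_recovers_topology_with_long_sequences(self, rng):
        labels = [f"x{i}" for i in range(6)]
        true = parse_newick(
            "((x0:0.05,x1:0.05):0.05,((x2:0.05,x3:0.05):0.05,"
            "(x4:0.05,x5:0.05):0.05):0.05);")
        cfg = SimulationConfig(
            seq_length=10000, subst_rate=1.0, gtr=GTRParams.jukes_cantor())
        aln = simulate_alignment(true, cfg, rng)
        est = estimate_gene_tree(aln)
        assert rf_distance(est, true) == 0

    def test_identical_sequences_flagged_degenerate(self):
        data = np.zeros((4, 100), dtype=np.uint8)
        aln = Alignment(["a", "b", "c", "d"], data)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            estimate_gene_tree(aln)

    def test_saturated_distances_clamped(self, rng):
        data = rng.integers(0, 4, size=(4, 200)).astype(np.uint8)
        aln = Alignment(["a", "b", "c", "d"], data)
        with pytest.warns(RuntimeWarning, match="saturated"):
            estimate_gene_tree(aln)

    def test_estimation_error_increases_pipeline_rf(self):
        # species-tree error from estimated gene trees >= from true gene
        # trees (short noisy alignments), mirroring the true-vs-estimated gap
        from hgtquartets.methods import njst

        cfg = SimulationConfig(n_ingroup=9, seq_length=300)
        rng = np.random.default_rng(4)
        st = simulate_species_tree(cfg, rng)
        true_genes, est_genes = [], []
        for _ in range(30):
            gt = simulate_gene_tree(st, 200000.0, rng)
            true_genes.append(gt)
            est_genes.append(estimate_gene_tree(simulate_alignment(gt, cfg, rng)))
        err_true = rf_distance(njst(true_genes), st, normalized=True)
        err_est = rf_distance(njst(est_genes), st, normalized=True)
        assert err_est >= err_true


class TestCascade:
    def test_leafset_conserved_and_deterministic(self):
        cfg = SimulationConfig(n_ingroup=6, hgt_rate=2e-7, n_loci=5)
        rep1 = simulate_replicate(cfg, np.random.default_rng(9))
        rep2 = simulate_replicate(cfg, np.random.default_rng(9))
        labels = rep1.species_tree.leaf_labels
        for lt, gt in zip(rep1.locus_trees, rep1.gene_trees):
            assert lt.tree.leaf_labels == labels
            assert gt.leaf_labels == labels
        assert [g.newick() for g in rep1.gene_trees] == \
               [g.newick() for g in rep2.gene_trees]

    def test_events_to_rate_inverts_expected_length(self):
        cfg = SimulationConfig(n_ingroup=11)
        rate = events_to_rate(0.8, cfg)
        assert rate * expected_tree_length(cfg) == pytest.approx(0.8)
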