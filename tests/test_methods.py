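"""Species-tree estimators: exhaustive MQSST, constrained DP, max-cut style
amalgamation, NJst, and the score-comparison record."""

import itertools

import numpy as np
import pytest

from hgtquartets.methods import (
    ClusterSet,
    average_topological_distance_matrix,
    build_constraint_set,
    compare_quartet_scores,
    enumerate_unrooted_topologies,
    greedy_consensus,
    mqsst_constrained_dp,
    mqsst_exact,
    neighbor_joining,
    njst,
    wqmc_style,
)
from hgtquartets.quartets import build_quartet_table, quartet_support
from hgtquartets.simulate import SimulationConfig, simulate_gene_tree, simulate_species_tree
from hgtquartets.trees import (
    bipartition_set,
    parse_newick,
    random_binary_tree,
    rf_distance,
    topological_distance_matrix,
)
from conftest import make_random_trees


def full_cluster_set(labels):
    labels = sorted(labels)
    anchor, rest = labels[0], labels[1:]
    clusters = frozenset(
        frozenset(c) for r in range(1, len(rest) + 1)
        for c in itertools.combinations(rest, r))
    return ClusterSet(tuple(labels), anchor, clusters)


class TestExhaustive:
    def test_topology_count(self):
        assert sum(1 for _ in enumerate_unrooted_topologies("abcde")) == 15
        assert sum(1 for _ in enumerate_unrooted_topologies("abcdefg")) == 945

    def test_single_tree_is_optimal_with_full_support(self):
        t = make_random_trees([f"t{i}" for i in range(6)], 1, seed=8)[0]
        table = build_quartet_table([t])
        best, score = mqsst_exact(table)
        assert score == len(table.quads)
        assert rf_distance(best, t) == 0

    def test_matches_independent_enumerator_n5(self):
        # independent oracle: score all 15 five-taxon topologies written out
        # as explicit newick strings
        labels = ["a", "b", "c", "d", "e"]
        genes = make_random_trees(labels, 3, seed=17)
        table = build_quartet_table(genes)
        topologies = []
        for x, y in itertools.combinations(range(5), 2):
            rest = [l for i, l in enumerate(labels) if i not in (x, y)]
            for z in range(3):
                pair = f"({labels[x]},{labels[y]})"
                others = rest[:z] + rest[z + 1:]
                topologies.append(
                    f"(({pair},{rest[z]}),({others[0]},{others[1]}));")
        scored = [(quartet_support(parse_newick(s), table), s) for s in set(topologies)]
        best_score = max(s for s, _ in scored)
        tree, score = mqsst_exact(table)
        assert score == best_score

    def test_true_tree_never_beats_optimum(self, rng):
        cfg = SimulationConfig(n_ingroup=6, outgroup=False)
        st = simulate_species_tree(cfg, rng)
        genes = [simulate_gene_tree(st, 200000.0, rng) for _ in range(20)]
        table = build_quartet_table(genes)
        _, score = mqsst_exact(table)
        assert score >= quartet_support(st, table)

    def test_size_guard(self):
        genes = make_random_trees([f"t{i}" for i in range(10)], 1, seed=0)
        with pytest.raises(ValueError, match="n=10"):
            mqsst_exact(build_quartet_table(genes))


class TestConstraintSet:
    def test_single_tree_clusters_feasible(self):
        t = make_random_trees([f"t{i}" for i in range(6)], 1, seed=2)[0]
        cs = build_constraint_set([t], extra_trees=[])
        # n-3 nontrivial bipartitions -> clusters, plus cherries with the
        # anchor collapse to singletons; feasibility regardless
        assert cs.is_feasible()
        tree, score = mqsst_constrained_dp(build_quartet_table([t]), cs)
        assert rf_distance(tree, t) == 0

    def test_union_of_conflicting_trees(self):
        t1 = parse_newick("(((a,b),c),(d,e));")
        t2 = parse_newick("(((a,c),b),(d,e));")
        cs = build_constraint_set([t1, t2], extra_trees=[])
        # anchored at 'a': ab|cde contributes {c,d,e}; ac|bde contributes
        # {b,d,e}; the DP may mix clusters from both trees
        assert frozenset("cde") in cs and frozenset("bde") in cs
        assert frozenset("de") in cs

    def test_contains_true_clusters_with_high_probability(self, rng):
        cfg = SimulationConfig(n_ingroup=9, outgroup=False)
        hits = trials = 0
        for _ in range(5):
            st = simulate_species_tree(cfg, rng)
            genes = [simulate_gene_tree(st, 200000.0, rng) for _ in range(100)]
            cs = build_constraint_set(genes)
            anchor = cs.anchor
            for bp in bipartition_set(st):
                side = bp.side_b if anchor in bp.side_a else bp.side_a
                trials += 1
                hits += side in cs or len(side) == len(st.leaf_labels) - 1
        assert hits / trials >= 0.99

    def test_greedy_consensus_is_binary(self, rng):
        trees = make_random_trees([f"t{i}" for i in range(8)], 9, seed=12)
        g = greedy_consensus(trees)
        assert g.is_binary()
        assert len(bipartition_set(g)) == 5


class TestConstrainedDP:
    def test_equals_exhaustive_with_full_cluster_set(self):
        labels = [f"t{i}" for i in range(7)]
        cs = full_cluster_set(labels)
        for seed in range(10):
            genes = make_random_trees(labels, 5, seed=100 + seed)
            table = build_quartet_table(genes)
            t_ex, s_ex = mqsst_exact(table)
            t_dp, s_dp = mqsst_constrained_dp(table, cs)
            assert s_dp == s_ex

    def test_factor_two_identity(self):
        # returned score is V(S)/2 and must equal independently recomputed
        # quartet support of the returned tree
        labels = [f"t{i}" for i in range(8)]
        for seed in range(5):
            genes = make_random_trees(labels, 7, seed=seed)
            table = build_quartet_table(genes)
            cs = build_constraint_set(genes)
            tree, score = mqsst_constrained_dp(table, cs)
            assert score == quartet_support(tree, table)

    def test_constraint_monotonicity(self):
        labels = [f"t{i}" for i in range(8)]
        genes = make_random_trees(labels, 10, seed=44)
        table = build_quartet_table(genes)
        small = build_constraint_set(genes[:3], extra_trees=[])
        large = small.with_clusters(
            c for t in genes[3:]
            for c in build_constraint_set([t], extra_trees=[]).clusters)
        _, s_small = mqsst_constrained_dp(table, small)
        _, s_large = mqsst_constrained_dp(table, large)
        assert s_large >= s_small

    def test_constrained_score_bounded_by_exact(self):
        labels = [f"t{i}" for i in range(8)]
        genes = make_random_trees(labels, 10, seed=7)
        table = build_quartet_table(genes)
        cs = build_constraint_set(genes)
        _, s_dp = mqsst_constrained_dp(table, cs)
        _, s_ex = mqsst_exact(table, max_n=8)
        assert s_dp <= s_ex

    def test_rooting_invariance_of_optimum(self):
        # the anchored-weight identity makes the DP optimum independent of
        # which taxon anchors the clusters
        labels = [f"t{i}" for i in range(6)]
        genes = make_random_trees(labels, 6, seed=21)
        table = build_quartet_table(genes)
        scores = set()
        for anchor in labels[:3]:
            cs = build_constraint_set(genes, outgroup=anchor)
            cs = cs.with_clusters(full_cluster_set_for(labels, anchor))
            scores.add(mqsst_constrained_dp(table, cs)[1])
        assert len(scores) == 1

    def test_infeasible_set_rejected(self):
        labels = ["a", "b", "c", "d", "e"]
        cs = ClusterSet(tuple(labels), "a",
                        frozenset({frozenset("b"), frozenset("c"),
                                   frozenset("d"), frozenset("e"),
                                   frozenset("bcde")}))
        genes = make_random_trees(labels, 2, seed=1)
        with pytest.raises(ValueError, match="infeasible"):
            mqsst_constrained_dp(build_quartet_table(genes), cs)


def full_cluster_set_for(labels, anchor):
    rest = [l for l in labels if l != anchor]
    return [frozenset(c) for r in range(1, len(rest) + 1)
            for c in itertools.combinations(rest, r)]


class TestWQMC:
    def test_single_tree_recovery(self):
        for n in (6, 8, 10):
            for seed in range(8):
                t = make_random_trees([f"x{i:02d}" for i in range(n)], 1,
                                      seed=50 * n + seed)[0]
                table = build_quartet_table([t])
                assert rf_distance(wqmc_style(table, seed=seed), t) == 0

    def test_four_taxa_returns_dominant(self):
        trees = [parse_newick("((a,b),(c,d));")] * 3 + [parse_newick("((a,c),(b,d));")]
        table = build_quartet_table(trees)
        got = wqmc_style(table)
        assert rf_distance(got, parse_newick("((a,b),(c,d));")) == 0

    def test_deterministic_given_seed(self):
        genes = make_random_trees([f"t{i}" for i in range(9)], 15, seed=3)
        table = build_quartet_table(genes)
        assert wqmc_style(table, seed=5).newick() == wqmc_style(table, seed=5).newick()

    def test_bounded_by_exact_optimum(self):
        labels = [f"t{i}" for i in range(7)]
        gaps = []
        for seed in range(5):
            genes = make_random_trees(labels, 8, seed=seed)
            table = build_quartet_table(genes)
            w = quartet_support(wqmc_style(table, seed=seed), table)
            _, s_ex = mqsst_exact(table)
            assert w <= s_ex
            gaps.append(s_ex - w)
        assert min(gaps) >= 0


class TestNJst:
    def test_identical_gene_trees_recover_topology(self):
        t = make_random_trees([f"t{i}" for i in range(9)], 1, seed=13)[0]
        assert rf_distance(njst([t] * 5), t) == 0

    def test_hand_computed_average_distances(self):
        trees = [parse_newick(s) for s in
                 ["((a,b),(c,(d,e)));", "((a,c),(b,(d,e)));", "((a,b),(c,(d,e)));"]]
        d, labels = average_topological_distance_matrix(trees)
        i = {l: k for k, l in enumerate(labels)}
        # hand counts: tree1/tree3 have d(a,b)=2, tree2 has d(a,b)=3
        assert d[i["a"], i["b"]] == pytest.approx((2 + 3 + 2) / 3)
        assert d[i["d"], i["e"]] == pytest.approx(2.0)
        assert d[i["a"], i["e"]] == pytest.approx((4 + 4 + 4) / 3)
        assert (d == d.T).all() and (np.diag(d) == 0).all()

    def test_nj_exact_on_additive_matrices(self, rng):
        for n in (5, 8, 12):
            t = random_binary_tree([f"t{i:02d}" for i in range(n)], rng)
            d = topological_distance_matrix(t)
            back = neighbor_joining(d.astype(float), sorted(t.leaf_labels))
            assert rf_distance(back, t) == 0

    def test_edge_vs_node_count_invariance(self):
        genes = make_random_trees([f"t{i}" for i in range(8)], 11, seed=2)
        t_edge = njst(genes, distance="edge")
        t_node = njst(genes, distance="node")
        assert rf_distance(t_edge, t_node) == 0

    def test_consistency_under_ils(self):
        cfg = SimulationConfig(n_ingroup=9, outgroup=False)
        successes = 0
        for rep in range(8):
            rng = np.random.default_rng(700 + rep)
            st = simulate_species_tree(cfg, rng)
            genes = [simulate_gene_tree(st, 200000.0, rng) for _ in range(300)]
            successes += rf_distance(njst(genes), st) == 0
        assert successes >= 7


class TestScoreComparison:
    def test_self_comparison_is_zero(self):
        genes = make_random_trees([f"t{i}" for i in range(6)], 5, seed=9)
        table = build_quartet_table(genes)
        rec = compare_quartet_scores(genes[0], genes[0], table)
        assert rec.difference == 0

    def test_exact_never_loses(self):
        labels = [f"t{i}" for i in range(6)]
        genes = make_random_trees(labels, 9, seed=23)
        table = build_quartet_table(genes)
        t_ex, _ = mqsst_exact(table)
        rec = compare_quartet_scores(t_ex, wqmc_style(table), table,
                                     reference=genes[0])
        assert rec.difference >= 0
        assert rec.rf_a is not None and 0 <= rec.rf_a <= 1
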