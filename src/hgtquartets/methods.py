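"""Species-tree estimators over gene-tree sets.

Four summary methods are implemented against the quartet machinery in
:mod:`hgtquartets.quartets`:

* ``mqsst_exact`` — exhaustive Maximum Quartet Support Species Tree search
  (small n only);
* ``mqsst_constrained_dp`` — exact dynamic programming over a constraint
  set of clusters drawn from the input gene trees (the search-space
  restriction used by constrained quartet-support optimizers);
* ``wqmc_style`` — a documented greedy divide-and-conquer variant of
  weighted quartet amalgamation (max-cut style), with no optimality
  guarantee;
* ``njst`` — average topological leaf-to-leaf distances followed by
  canonical Saitou–Nei neighbor joining.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .quartets import QuartetTable, quartet_support
from .trees import PhyloTree, TreeNode, bipartition_set, rf_distance

__all__ = [
    "ClusterSet",
    "build_constraint_set",
    "mqsst_exact",
    "mqsst_constrained_dp",
    "wqmc_style",
    "njst",
    "average_topological_distance_matrix",
    "neighbor_joining",
    "greedy_consensus",
    "ScoreComparison",
    "compare_quartet_scores",
    "enumerate_unrooted_topologies",
    "canonical_newick",
]


# ---------------------------------------------------------------------------
# Anchored tripartition weights (shared by the DP)
# ---------------------------------------------------------------------------

# duo-position bit pattern -> topology index (positions i<j<k<l; pairing of
# the two duo members): {i,j} or {k,l} -> 0, {i,k}/{j,l} -> 1, {i,l}/{j,k} -> 2
_DUO_TOPOLOGY = np.full(16, -1, dtype=np.int64)
for _pat, _topo in ((0b1100, 0), (0b0011, 0), (0b1010, 1), (0b0101, 1),
                    (0b1001, 2), (0b0110, 2)):
    _DUO_TOPOLOGY[_pat] = _topo
_BITVAL = np.array([8, 4, 2, 1], dtype=np.int64)


def _tripartition_weight(table: QuartetTable, parts: np.ndarray) -> int:
    """Sum of n(G, xy|cd) over quartets anchored at a tripartition.

    ``parts`` assigns each taxon (in ``table.taxa`` order) to part 0, 1 or
    2.  A quartet is anchored here iff one part contributes the pair
    {c, d} and the other two parts one leaf each (x and y); the counted
    topology is xy|cd.  Every quartet displayed by a binary tree is
    anchored at exactly two of its internal nodes, which gives the DP its
    factor-2 score identity.
    """
    P = parts[table.quads]  # (m, 4)
    c0 = (P == 0).sum(axis=1)
    c1 = (P == 1).sum(axis=1)
    c2 = (P == 2).sum(axis=1)
    mask = ((c0 == 2) & (c1 == 1) & (c2 == 1)) | \
           ((c0 == 1) & (c1 == 2) & (c2 == 1)) | \
           ((c0 == 1) & (c1 == 1) & (c2 == 2))
    if not mask.any():
        return 0
    Pm = P[mask]
    duo_part = np.where((Pm == 0).sum(axis=1) == 2, 0,
                        np.where((Pm == 1).sum(axis=1) == 2, 1, 2))
    duo_mask = (Pm == duo_part[:, None])
    pattern = (duo_mask * _BITVAL).sum(axis=1)
    topo = _DUO_TOPOLOGY[pattern]
    rows = np.nonzero(mask)[0]
    return int(table.counts[rows, topo].sum())


# ---------------------------------------------------------------------------
# Cluster constraint sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterSet:
    """The constraint set X for the constrained MQSST search.

    Clusters are subsets of the taxon set minus the anchor (the designated
    outgroup, or the lexicographically smallest taxon), i.e. the rooted
    clades allowed in the output tree.  Contains all singletons and the
    full non-anchor set; feasibility means at least one binary rooted tree
    can be assembled from members of the set.
    """

    taxa: tuple[str, ...]
    anchor: str
    clusters: frozenset[frozenset[str]]

    @property
    def dp_taxa(self) -> tuple[str, ...]:
        return tuple(t for t in self.taxa if t != self.anchor)

    def __len__(self) -> int:
        return len(self.clusters)

    def __contains__(self, cluster) -> bool:
        return frozenset(cluster) in self.clusters

    def with_clusters(self, extra: Iterable[frozenset[str]]) -> "ClusterSet":
        extra = {frozenset(c) for c in extra}
        full = set(self.dp_taxa)
        for c in extra:
            if not c or not c <= full:
                raise ValueError("clusters must be non-empty subsets excluding the anchor")
        return ClusterSet(self.taxa, self.anchor, self.clusters | extra)

    def is_feasible(self) -> bool:
        """Can a binary rooted tree on the non-anchor taxa be assembled?"""
        masks, _, full = self._bitmasks()
        mask_set = set(masks)
        ok: dict[int, bool] = {}
        for m in sorted(masks, key=lambda x: bin(x).count("1")):
            if bin(m).count("1") == 1:
                ok[m] = True
                continue
            ok[m] = any(
                a != m and (a & m) == a and (m ^ a) in mask_set
                and ok.get(a, False) and ok.get(m ^ a, False)
                for a in masks)
        return ok.get(full, False)

    def _bitmasks(self) -> tuple[list[int], dict[str, int], int]:
        pos = {t: i for i, t in enumerate(self.dp_taxa)}
        masks = sorted(
            sum(1 << pos[t] for t in c) for c in self.clusters)
        full = (1 << len(pos)) - 1
        return masks, pos, full


def _rooted_clusters(tree: PhyloTree, anchor: str) -> set[frozenset[str]]:
    """Clades of the tree rooted at the anchor leaf (anchor excluded)."""
    taxa = frozenset(tree.leaf_labels)
    out: set[frozenset[str]] = set()
    for bp in bipartition_set(tree):
        side = bp.side_b if anchor in bp.side_a else bp.side_a
        out.add(side)
    # trivial clusters from cherries with the anchor are implicit singletons
    return {c for c in out if len(c) >= 2}


def build_constraint_set(
    gene_trees: Sequence[PhyloTree],
    extra_trees: Sequence[PhyloTree] | None = None,
    outgroup: str | None = None,
) -> ClusterSet:
    """Constraint set from gene-tree clusters plus guaranteed-feasible extras.

    The set contains every cluster of every input gene tree (rooted at the
    outgroup when designated, else at the lexicographically smallest
    taxon).  By default the NJst tree and one resolved greedy-consensus
    tree are added, which guarantees feasibility; callers may pass their
    own ``extra_trees`` instead.
    """
    if not gene_trees:
        raise ValueError("need at least one gene tree")
    taxa = gene_trees[0].leaf_labels
    anchor = outgroup if outgroup is not None else min(taxa)
    if anchor not in taxa:
        raise ValueError(f"outgroup {anchor!r} is not a leaf")
    clusters: set[frozenset[str]] = set()
    for t in gene_trees:
        if t.leaf_labels != taxa:
            raise ValueError("gene trees must share one leaf set")
        clusters |= _rooted_clusters(t, anchor)
    if extra_trees is None:
        extra_trees = [njst(gene_trees), greedy_consensus(gene_trees)]
    for t in extra_trees:
        clusters |= _rooted_clusters(t, anchor)
    dp_taxa = [t for t in taxa if t != anchor]
    clusters |= {frozenset([t]) for t in dp_taxa}
    clusters.add(frozenset(dp_taxa))
    cs = ClusterSet(tuple(taxa), anchor, frozenset(clusters))
    if not cs.is_feasible():
        raise RuntimeError("internal error: constraint set is infeasible")
    return cs


def greedy_consensus(trees: Sequence[PhyloTree]) -> PhyloTree:
    """Greedy (majority-rule extended) consensus, deterministically resolved.

    Bipartitions are admitted in decreasing frequency (lexicographic
    tie-break) when compatible with those already kept; remaining
    polytomies are resolved by repeatedly joining the two children with
    the smallest minimum labels.
    """
    if not trees:
        raise ValueError("need at least one tree")
    taxa = sorted(trees[0].leaf_labels)
    anchor = taxa[0]
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for c in _rooted_clusters(t, anchor):
            counts[c] = counts.get(c, 0) + 1
    accepted: list[frozenset[str]] = []
    for c, _ in sorted(counts.items(), key=lambda kv: (-kv[1], sorted(kv[0]))):
        if all(c <= a or a <= c or not (c & a) for a in accepted):
            accepted.append(c)
    from .trees import tree_from_clusters

    tree = tree_from_clusters(taxa, accepted)
    _resolve_polytomies(tree.root)
    return PhyloTree(tree.root, rooted=False)


def _resolve_polytomies(root: TreeNode) -> None:
    def min_label(node: TreeNode) -> str:
        return min(l.label for l in node.leaves())

    for node in list(root.postorder()):
        limit = 3 if node is root else 2
        while len(node.children) > limit:
            kids = sorted(node.children, key=min_label)
            a, b = kids[0], kids[1]
            joint = TreeNode()
            node.children.remove(a)
            node.children.remove(b)
            joint.add_child(a)
            joint.add_child(b)
            node.add_child(joint)


# ---------------------------------------------------------------------------
# Exhaustive MQSST
# ---------------------------------------------------------------------------


def canonical_newick(tree: PhyloTree) -> str:
    """A rooting-independent canonical topology string (for tie-breaking)."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return node.label
        parts = sorted(fmt(c) for c in node.children)
        return "(" + ",".join(parts) + ")"

    # re-root deterministically at the smallest label's neighbor edge:
    # the sorted-children form below is stable for our anchored construction
    return fmt(tree.root) + ";"


def enumerate_unrooted_topologies(labels: Sequence[str]):
    """Yield every unrooted binary topology on the labels as a PhyloTree.

    Trees come anchored at the lexicographically first label; there are
    (2n-5)!! of them.
    """
    labels = sorted(labels)
    if len(labels) < 4:
        raise ValueError("need at least 4 labels")
    anchor, rest = labels[0], labels[1:]

    def grow(shapes: list, remaining: list[str]):
        if not remaining:
            yield from shapes
            return
        lab = remaining[0]
        new_shapes = []
        for s in shapes:
            for t in _insert_everywhere(s, lab):
                new_shapes.append(t)
        yield from grow(new_shapes, remaining[1:])

    def _insert_everywhere(shape, lab):
        # shape is a leaf label or a (left, right) tuple; insertion on the
        # root edge plus recursively on every internal edge
        yield (shape, lab)
        if isinstance(shape, tuple):
            left, right = shape
            for t in _insert_everywhere(left, lab):
                yield (t, right)
            for t in _insert_everywhere(right, lab):
                yield (left, t)

    for shape in grow([rest[0]], rest[1:]):
        root = TreeNode()
        root.add_child(TreeNode(label=anchor))
        root.add_child(_shape_to_node(shape))
        yield PhyloTree(root, rooted=False)


def _shape_to_node(shape) -> TreeNode:
    if isinstance(shape, str):
        return TreeNode(label=shape)
    node = TreeNode()
    node.add_child(_shape_to_node(shape[0]))
    node.add_child(_shape_to_node(shape[1]))
    return node


def mqsst_exact(table: QuartetTable, max_n: int = 9) -> tuple[PhyloTree, int]:
    """Global MQSST optimum by exhaustive search over unrooted topologies.

    Guarded at ``max_n`` taxa ((2n-5)!! topologies are scored).  Ties are
    broken toward the smallest canonical topology string, so the result is
    deterministic.
    """
    n = table.n_taxa
    if n > max_n:
        raise ValueError(
            f"exhaustive MQSST refused for n={n} > {max_n}; "
            "raise max_n explicitly if you really want this")
    best_tree, best_score, best_key = None, -1, None
    for tree in enumerate_unrooted_topologies(table.taxa):
        s = quartet_support(tree, table)
        key = None
        if s > best_score:
            best_tree, best_score, best_key = tree, s, None
        elif s == best_score:
            if best_key is None:
                best_key = canonical_newick(best_tree)
            key = canonical_newick(tree)
            if key < best_key:
                best_tree, best_key = tree, key
    return best_tree, best_score


# ---------------------------------------------------------------------------
# Constrained MQSST dynamic programming
# ---------------------------------------------------------------------------


def mqsst_constrained_dp(
    table: QuartetTable, clusters: ClusterSet
) -> tuple[PhyloTree, int]:
    """Exact optimum over binary trees whose rooted clusters all lie in X.

    Recurrence: V(singleton) = 0;
    V(A) = max over set partitions A = A1 + A2 with A1, A2 in X of
    V(A1) + V(A2) + W(A1, A2), where W counts gene quartets anchored at
    the tripartition (A1, A2, complement-of-A).  V(full set) equals twice
    the quartet support of the optimal tree (every displayed quartet is
    anchored at exactly two internal nodes); the returned score is the
    quartet support itself.  Tie-breaking is deterministic (lexicographic
    smallest partition first, strict improvement required).
    """
    if tuple(sorted(clusters.taxa)) != table.taxa:
        raise ValueError("cluster set and quartet table taxa differ")
    masks, pos, full = clusters._bitmasks()
    mask_set = set(masks)
    if not clusters.is_feasible():
        raise ValueError("infeasible cluster set: no binary tree assemblable")
    taxa = table.taxa
    tpos = {t: i for i, t in enumerate(taxa)}
    dp_taxa = clusters.dp_taxa
    bit_taxon = {1 << pos[t]: t for t in dp_taxa}

    def parts_vector(a1: int, a2: int) -> np.ndarray:
        parts = np.full(len(taxa), 2, dtype=np.int64)
        for t in dp_taxa:
            b = 1 << pos[t]
            if a1 & b:
                parts[tpos[t]] = 0
            elif a2 & b:
                parts[tpos[t]] = 1
        return parts

    V: dict[int, int] = {}
    choice: dict[int, tuple[int, int]] = {}
    for m in sorted(mask_set, key=lambda x: (bin(x).count("1"), x)):
        if bin(m).count("1") == 1:
            V[m] = 0
            continue
        best = None
        for a1 in masks:
            if a1 >= m or (a1 & m) != a1:
                continue
            a2 = m ^ a1
            if a1 > a2 or a2 not in mask_set:
                continue
            if a1 not in V or a2 not in V:
                continue
            w = V[a1] + V[a2] + _tripartition_weight(table, parts_vector(a1, a2))
            if best is None or w > best:
                best = w
                choice[m] = (a1, a2)
        if best is not None:
            V[m] = best
    if full not in V:
        raise ValueError("infeasible cluster set: full taxon set unreachable")

    def build(m: int) -> TreeNode:
        if bin(m).count("1") == 1:
            return TreeNode(label=bit_taxon[m])
        a1, a2 = choice[m]
        node = TreeNode()
        node.add_child(build(a1))
        node.add_child(build(a2))
        return node

    root = TreeNode()
    root.add_child(TreeNode(label=clusters.anchor))
    root.add_child(build(full))
    tree = PhyloTree(root, rooted=False)
    value = V[full]
    if value % 2 != 0:
        raise AssertionError("anchored-quartet total must be even")
    return tree, value // 2


# ---------------------------------------------------------------------------
# Weighted quartet max-cut style amalgamation
# ---------------------------------------------------------------------------


def _reduce_instance(quads: np.ndarray, weights: np.ndarray,
                     mapping: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project quartet weights through an element merge map.

    ``mapping[e]`` is the new index of old element e (several old elements
    may share a new index — the placeholder).  Quartets with two or more
    members mapping to the same new element are dropped; the rest are
    re-canonicalized and their weights accumulated.
    """
    acc: dict[tuple[int, int, int, int], np.ndarray] = {}
    for quad, w in zip(quads, weights):
        new = mapping[quad]
        if len(set(new.tolist())) < 4:
            continue
        order = np.argsort(new)
        sq = tuple(int(new[o]) for o in order)
        # pairing partner of the smallest element decides the new index
        inv = np.empty(4, dtype=np.int64)
        inv[order] = np.arange(4)
        neww = np.zeros(3, dtype=weights.dtype)
        for t in range(3):
            (i, j), _ = _pairings()[t]
            a, b = inv[i], inv[j]  # new positions of an old pair
            pair = {int(a), int(b)}
            if 0 in pair:
                partner = (pair - {0}).pop()
                neww[partner - 1] += w[t]
            else:
                other = {0, 1, 2, 3} - pair
                partner = min(other - {0})
                neww[partner - 1] += w[t]
        if sq in acc:
            acc[sq] += neww
        else:
            acc[sq] = neww
    if not acc:
        return np.zeros((0, 4), dtype=np.int64), np.zeros((0, 3), dtype=weights.dtype)
    keys = sorted(acc)
    return (np.array(keys, dtype=np.int64),
            np.stack([acc[k] for k in keys]))


def _pairings():
    return (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))


def _cut_objective(side: np.ndarray, quads: np.ndarray, weights: np.ndarray,
                   wsum: np.ndarray) -> float:
    """Satisfied-minus-violated weight of a cut, in edge-crossing form.

    A quartet topology (p,q)|(r,s) wants the four cross-pair edges to cross
    the cut and the two within-pair edges not to; the score per topology is
    w * (#good-crossings - 2 * #bad-crossings).  On cuts splitting a
    quartet 2+2 this is the satisfied-minus-violated weight (scaled by 4
    for satisfied, -2 per violating topology); 3+1 and 4+0 placements
    contribute zero (deferred), but the per-edge form changes smoothly
    under single-element moves, which the hill-climb exploits.
    """
    if len(quads) == 0:
        return 0.0
    S = side[quads].astype(np.int64)  # (m, 4) in {0, 1}
    total = 0.0
    for t, ((i, j), (k, l)) in enumerate(_pairings()):
        bad = (S[:, i] != S[:, j]).astype(np.int64) + (S[:, k] != S[:, l])
        good = ((S[:, i] != S[:, k]).astype(np.int64) + (S[:, i] != S[:, l])
                + (S[:, j] != S[:, k]) + (S[:, j] != S[:, l]))
        total += float((weights[:, t] * (good - 2 * bad)).sum())
    return total


def _best_cut(k: int, quads: np.ndarray, weights: np.ndarray,
              rng: np.random.Generator, restarts: int) -> np.ndarray:
    """Hill-climbing max-cut: singleton seeds plus random restarts, steepest
    single-element moves, both sides kept at size >= 2 (size 1 allowed only
    when k < 4 which never reaches here)."""
    wsum = weights.sum(axis=1)
    min_side = 2 if k >= 4 else 1

    def climb(side: np.ndarray) -> tuple[np.ndarray, float]:
        side = side.copy()
        best = _cut_objective(side, quads, weights, wsum)
        improved = True
        while improved:
            improved = False
            move_best, move_val = -1, best
            sizes = (int(side.sum()), k - int(side.sum()))
            for e in range(k):
                src = sizes[1 - int(side[e])]
                if src <= min_side:
                    continue
                side[e] = not side[e]
                val = _cut_objective(side, quads, weights, wsum)
                side[e] = not side[e]
                if val > move_val:
                    move_best, move_val = e, val
            if move_best >= 0:
                side[move_best] = not side[move_best]
                best = move_val
                improved = True
        return side, best

    starts: list[np.ndarray] = []
    for e in range(k):  # grow-from-singleton seeds (deterministic)
        s = np.zeros(k, dtype=bool)
        s[e] = True
        if min_side > 1:  # pad with the nearest other element
            s[(e + 1) % k] = True
        starts.append(s)
    for _ in range(restarts):
        while True:
            s = rng.random(k) < 0.5
            if min_side <= s.sum() <= k - min_side:
                break
        starts.append(s)

    best_side, best_val = None, -np.inf
    for s in starts:
        side, val = climb(s)
        if val > best_val:
            best_side, best_val = side, val
    return best_side


@dataclass
class _Instance:
    """One divide-and-conquer subproblem: element classes (sets of original
    taxa), their quartet weights, subtree per class, and an optional marker
    class standing for everything outside the subproblem."""

    classes: list[frozenset]
    quads: np.ndarray
    weights: np.ndarray
    sub: dict[frozenset, TreeNode]
    marker: frozenset | None


def wqmc_style(
    table: QuartetTable, seed: int = 0, restarts: int = 3
) -> PhyloTree:
    """Greedy divide-and-conquer quartet amalgamation (max-cut style).

    At each subproblem a bipartition of the elements is chosen by seeded
    hill-climbing on the satisfied-minus-violated weight of the 2+2
    quartets the cut resolves; each side then recurses with the entire
    off-side merged into a single placeholder element.  Deterministic
    given ``seed``; no optimality guarantee — the binding contract is
    exact recovery of a tree from that tree's own quartet set.
    """
    rng = np.random.default_rng(seed)
    classes = [frozenset([t]) for t in table.taxa]
    sub = {c: TreeNode(label=next(iter(c))) for c in classes}
    inst = _Instance(classes, table.quads.copy(), table.counts.astype(float),
                     sub, marker=None)
    root = _wqmc_solve(inst, rng, restarts)
    return PhyloTree(root, rooted=False)


def _wqmc_solve(inst: _Instance, rng: np.random.Generator,
                restarts: int) -> TreeNode:
    """Returns the tree over the instance's non-marker classes; when a
    marker is present the tree is rooted at the marker's attachment."""
    others = [c for c in inst.classes if c != inst.marker]
    if len(others) <= 2:
        if len(others) == 1:
            return inst.sub[others[0]]
        node = TreeNode()
        node.add_child(inst.sub[others[0]])
        node.add_child(inst.sub[others[1]])
        return node
    if inst.marker is not None and len(others) == 3:
        return _resolve_triple(inst)
    if inst.marker is None and len(others) == 4:
        return _resolve_quartet(inst)

    k = len(inst.classes)
    side = _best_cut(k, inst.quads, inst.weights, rng, restarts)
    idx_a = [i for i in range(k) if side[i]]
    idx_b = [i for i in range(k) if not side[i]]

    def make_sub(keep: list[int], off: list[int], marker, extra_sub=None):
        placeholder = frozenset().union(*(inst.classes[i] for i in off))
        new_classes = [inst.classes[i] for i in keep] + [placeholder]
        mapping = np.empty(k, dtype=np.int64)
        for newpos, i in enumerate(keep):
            mapping[i] = newpos
        for i in off:
            mapping[i] = len(keep)
        nq, nw = _reduce_instance(inst.quads, inst.weights, mapping)
        # the marker class carries no subtree; everything else does
        new_sub = {inst.classes[i]: inst.sub[inst.classes[i]]
                   for i in keep if inst.classes[i] in inst.sub}
        if extra_sub is not None:
            new_sub[placeholder] = extra_sub
        return _Instance(new_classes, nq, nw, new_sub,
                         marker=placeholder if marker else None), placeholder

    if inst.marker is None:
        # top level: both placeholders are markers; join the two halves
        ia, _ = make_sub(idx_a, idx_b, marker=True)
        ib, _ = make_sub(idx_b, idx_a, marker=True)
        root = TreeNode()
        root.add_child(_wqmc_solve(ia, rng, restarts))
        root.add_child(_wqmc_solve(ib, rng, restarts))
        return root
    # the marker sits on one side; solve the other side first (rooted at the
    # cut), then hand its tree to the marker side as an ordinary element
    if any(inst.classes[i] == inst.marker for i in idx_a):
        with_marker, without = idx_a, idx_b
    else:
        with_marker, without = idx_b, idx_a
    inst_far, _ = make_sub(without, with_marker, marker=True)
    t_far = _wqmc_solve(inst_far, rng, restarts)
    inst_near, _ = make_sub(with_marker, without, marker=False,
                            extra_sub=t_far)
    inst_near.marker = inst.marker
    return _wqmc_solve(inst_near, rng, restarts)


def _resolve_quartet(inst: _Instance) -> TreeNode:
    t = int(np.argmax(inst.weights[0])) if len(inst.weights) else 0
    (i, j), (k, l) = _pairings()[t]
    left, right = TreeNode(), TreeNode()
    left.add_child(inst.sub[inst.classes[i]])
    left.add_child(inst.sub[inst.classes[j]])
    right.add_child(inst.sub[inst.classes[k]])
    right.add_child(inst.sub[inst.classes[l]])
    root = TreeNode()
    root.add_child(left)
    root.add_child(right)
    return root


def _resolve_triple(inst: _Instance) -> TreeNode:
    """Three non-marker elements rooted at the marker's attachment: pick the
    cherry pair maximizing the weight of topologies pairing it (from the
    single quartet these four elements span)."""
    oidx = [i for i, c in enumerate(inst.classes) if c != inst.marker]
    best_pair, best_w = (oidx[0], oidx[1]), -np.inf
    for a, b in itertools.combinations(sorted(oidx), 2):
        w = _pair_weight(inst.quads, inst.weights, a, b)
        if w > best_w:
            best_pair, best_w = (a, b), w
    a, b = best_pair
    (c,) = [i for i in oidx if i not in best_pair]
    cherry = TreeNode()
    cherry.add_child(inst.sub[inst.classes[a]])
    cherry.add_child(inst.sub[inst.classes[b]])
    node = TreeNode()
    node.add_child(cherry)
    node.add_child(inst.sub[inst.classes[c]])
    return node


def _pair_weight(quads: np.ndarray, weights: np.ndarray, a: int, b: int) -> float:
    """Total weight of quartet topologies pairing elements a and b."""
    total = 0.0
    for quad, w in zip(quads, weights):
        ql = quad.tolist()
        if a in ql and b in ql:
            ia, ib = ql.index(a), ql.index(b)
            for t, (p1, p2) in enumerate(_pairings()):
                if {ia, ib} == set(p1) or {ia, ib} == set(p2):
                    total += float(w[t])
    return total


# ---------------------------------------------------------------------------
# NJst
# ---------------------------------------------------------------------------


def average_topological_distance_matrix(
    gene_trees: Sequence[PhyloTree], distance: str = "edge"
) -> tuple[np.ndarray, list[str]]:
    """D[x, y]: average leaf-to-leaf topological distance over gene trees.

    ``distance="edge"`` counts edges on the path (a cherry pair is at
    distance 2); ``"node"`` counts internal nodes (one less).  On complete
    binary gene trees the two differ by an additive constant off the
    diagonal, so the NJ topology is invariant to the choice.
    """
    if not gene_trees:
        raise ValueError("need at least one gene tree")
    labels = sorted(gene_trees[0].leaf_labels)
    from .trees import topological_distance_matrix

    acc = np.zeros((len(labels), len(labels)))
    for t in gene_trees:
        if sorted(t.leaf_labels) != labels:
            raise ValueError("gene trees must share one leaf set")
        acc += topological_distance_matrix(t, labels)
    acc /= len(gene_trees)
    if distance == "node":
        acc = acc - 1.0
        np.fill_diagonal(acc, 0.0)
    elif distance != "edge":
        raise ValueError("distance must be 'edge' or 'node'")
    return acc, labels


def neighbor_joining(d: np.ndarray, labels: Sequence[str]) -> PhyloTree:
    """Canonical Saitou–Nei neighbor joining with deterministic tie-breaks.

    Q(i, j) = (r-2) d(i, j) - sum_k d(i, k) - sum_k d(j, k); the minimal-Q
    pair is joined (ties broken lexicographically on the smallest leaf
    label each node subtends).  Exact on additive matrices: returns the
    unique displaying topology.
    """
    d = np.asarray(d, dtype=float)
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError("matrix/label size mismatch")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes = [TreeNode(label=l) for l in labels]
    keys = [l for l in labels]  # tie-break key: smallest subtended label
    d = d.copy()
    active = list(range(n))
    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                key = (q, *sorted((keys[i], keys[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        vi = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        vj = d[i, j] - vi
        parent = TreeNode()
        nodes[i].length = max(vi, 0.0)
        nodes[j].length = max(vj, 0.0)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # reuse slot i for the new node
        newrow = np.zeros(d.shape[0])
        for k in active:
            if k in (i, j):
                continue
            newrow[k] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        d[i, :] = newrow
        d[:, i] = newrow
        nodes[i] = parent
        keys[i] = min(keys[i], keys[j])
        active.remove(j)
    root = TreeNode()
    if len(active) == 3:
        i, j, k = active
        for (a, rest) in ((i, (j, k)), (j, (i, k)), (k, (i, j))):
            b, c = rest
            nodes[a].length = max(0.5 * (d[a, b] + d[a, c] - d[b, c]), 0.0)
            root.add_child(nodes[a])
    else:
        i, j = active
        nodes[i].length = max(d[i, j] / 2, 0.0)
        nodes[j].length = max(d[i, j] / 2, 0.0)
        root.add_child(nodes[i])
        root.add_child(nodes[j])
    return PhyloTree(root, rooted=False)


def njst(gene_trees: Sequence[PhyloTree], distance: str = "edge") -> PhyloTree:
    """NJst: neighbor joining on average topological gene-tree distances."""
    d, labels = average_topological_distance_matrix(gene_trees, distance)
    return neighbor_joining(d, labels)


# ---------------------------------------------------------------------------
# Score comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScoreComparison:
    """Quartet supports of two trees, their difference, and (optionally)
    both trees' normalized RF error against a reference tree."""

    support_a: int
    support_b: int
    difference: int
    rf_a: float | None = None
    rf_b: float | None = None


def compare_quartet_scores(
    tree_a: PhyloTree,
    tree_b: PhyloTree,
    table: QuartetTable,
    reference: PhyloTree | None = None,
) -> ScoreComparison:
    wa = quartet_support(tree_a, table)
    wb = quartet_support(tree_b, table)
    rf_a = rf_b = None
    if reference is not None:
        rf_a = rf_distance(tree_a, reference, normalized=True)
        rf_b = rf_distance(tree_b, reference, normalized=True)
    return ScoreComparison(wa, wb, wa - wb, rf_a, rf_b)
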