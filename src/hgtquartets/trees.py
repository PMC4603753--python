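"""Core phylogenetic tree structures and topology machinery.

Trees are stored rooted (simulation is naturally rooted) but every topology
comparison — bipartitions, Robinson-Foulds distance, induced quartets — is
computed on the unrooted topology, which is the convention for evaluating
species-tree estimates.  Leaf labels are unique non-empty strings; branch
lengths are optional non-negative reals whose unit depends on context
(generations for simulated trees, substitutions/site or arbitrary for
estimated trees).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np

__all__ = [
    "TreeNode",
    "PhyloTree",
    "Bipartition",
    "QuartetTopology",
    "NewickError",
    "parse_newick",
    "read_newick_file",
    "write_newick_file",
    "bipartition_set",
    "rf_distance",
    "induced_quartet",
    "majority_consensus",
    "tree_from_clusters",
    "random_binary_tree",
    "topological_distance_matrix",
    "lca_depth_matrix",
]


class NewickError(ValueError):
    """Raised for malformed Newick input or duplicate leaf labels."""


class TreeNode:
    """A node with parent/child links, an optional label and branch length."""

    __slots__ = ("children", "parent", "label", "length", "age")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.label = label
        self.length = length
        # age = time before present; used by the simulator, None elsewhere
        self.age: float | None = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        stack: list[tuple[TreeNode, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> Iterator["TreeNode"]:
        for n in self.postorder():
            if n.is_leaf:
                yield n


class PhyloTree:
    """A rooted container for an (optionally unrooted) phylogenetic tree.

    ``rooted=False`` records that the root is an artifact of storage; all
    comparison operations in this module ignore rootedness anyway.
    """

    def __init__(self, root: TreeNode, rooted: bool = True):
        self.root = root
        self.rooted = rooted
        labels = [leaf.label for leaf in root.leaves()]
        if any(lab is None or lab == "" for lab in labels):
            raise NewickError("every leaf must carry a non-empty label")
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise NewickError(f"duplicate leaf labels: {dup}")
        self._labels = tuple(sorted(labels))

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        """Leaf labels in lexicographic order."""
        return self._labels

    @property
    def n_leaves(self) -> int:
        return len(self._labels)

    def leaves(self) -> list[TreeNode]:
        return list(self.root.leaves())

    def postorder(self) -> Iterator[TreeNode]:
        return self.root.postorder()

    def preorder(self) -> Iterator[TreeNode]:
        return self.root.preorder()

    def is_binary(self) -> bool:
        """True if the unrooted topology is fully resolved.

        A rooted representation is accepted with either a bifurcating root
        (degree-2, suppressed on unrooting) or a trifurcating root.
        """
        for node in self.postorder():
            if node.is_leaf:
                continue
            k = len(node.children)
            if node is self.root:
                if k not in (2, 3):
                    return False
            elif k != 2:
                return False
        return True

    def copy(self) -> "PhyloTree":
        def clone(n: TreeNode) -> TreeNode:
            m = TreeNode(n.label, n.length)
            m.age = n.age
            for c in n.children:
                m.add_child(clone(c))
            return m

        return PhyloTree(clone(self.root), rooted=self.rooted)

    def newick(self, lengths: bool = True, precision: int = 12) -> str:
        def fmt(n: TreeNode) -> str:
            if n.is_leaf:
                s = n.label or ""
            else:
                s = "(" + ",".join(fmt(c) for c in n.children) + ")"
            if lengths and n.length is not None:
                s += f":{n.length:.{precision}g}"
            return s

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PhyloTree({self.newick(lengths=False)})"


# ---------------------------------------------------------------------------
# Newick I/O (parsing via dendropy; writing via PhyloTree.newick)
# ---------------------------------------------------------------------------


def parse_newick(text: str) -> PhyloTree:
    """Parse a single Newick string into a :class:`PhyloTree`.

    Branch lengths are preserved when present; internal node labels are
    ignored.  Raises :class:`NewickError` on malformed input or duplicate
    leaf labels, naming the offending token.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> TreeNode:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else None
            node = TreeNode(label=label, length=dnode.edge.length)
        else:
            node = TreeNode(length=dnode.edge.length)
            for child in dnode.child_nodes():
                node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    return PhyloTree(root)


def read_newick_file(path) -> list[PhyloTree]:
    """Read a file with one Newick tree per line (blank lines skipped)."""
    trees = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                trees.append(parse_newick(line))
            except NewickError as exc:
                raise NewickError(f"{path}:{lineno}: {exc}") from exc
    return trees


def write_newick_file(path, trees: Iterable[PhyloTree], lengths: bool = True) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.newick(lengths=lengths) + "\n")


# ---------------------------------------------------------------------------
# Bipartitions and Robinson-Foulds distance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Bipartition:
    """An unrooted split of the full taxon set into two disjoint sides.

    Canonical form: ``side_a`` is the side containing the lexicographically
    smallest taxon, so equality and hashing are well defined.
    """

    side_a: frozenset[str]
    side_b: frozenset[str]

    @staticmethod
    def of(side: Iterable[str], taxa: Iterable[str]) -> "Bipartition":
        side = frozenset(side)
        taxa = frozenset(taxa)
        other = taxa - side
        if not side or not other:
            raise ValueError("both sides of a bipartition must be non-empty")
        if min(side) < min(other):
            return Bipartition(side, other)
        return Bipartition(other, side)

    @property
    def is_trivial(self) -> bool:
        return len(self.side_a) == 1 or len(self.side_b) == 1

    def __repr__(self) -> str:
        a = ",".join(sorted(self.side_a))
        b = ",".join(sorted(self.side_b))
        return f"{a}|{b}"


def bipartition_set(tree: PhyloTree) -> frozenset[Bipartition]:
    """Non-trivial bipartitions of the unrooted topology, one per internal edge.

    Returns an empty set for trees with fewer than 4 leaves.  A binary tree
    on n leaves yields exactly n-3 bipartitions.
    """
    taxa = frozenset(tree.leaf_labels)
    if len(taxa) < 4:
        return frozenset()
    below: dict[int, frozenset[str]] = {}
    out: set[Bipartition] = set()
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.label])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
    for node in tree.postorder():
        if node.is_leaf or node is tree.root:
            continue
        side = below[id(node)]
        if 1 < len(side) < len(taxa) - 1:
            out.add(Bipartition.of(side, taxa))
    return frozenset(out)


def rf_distance(t1: PhyloTree, t2: PhyloTree, normalized: bool = False) -> float:
    """Robinson-Foulds distance: |symmetric difference of bipartition sets|.

    With ``normalized=True`` the count is divided by 2n-6, the maximum for
    binary trees, giving a rate in [0, 1] that equals the missing-branch
    rate when both trees are binary.
    """
    if set(t1.leaf_labels) != set(t2.leaf_labels):
        only1 = sorted(set(t1.leaf_labels) - set(t2.leaf_labels))
        only2 = sorted(set(t2.leaf_labels) - set(t1.leaf_labels))
        raise ValueError(
            f"leaf sets differ: only in first {only1}, only in second {only2}"
        )
    n = t1.n_leaves
    if n < 4:
        raise ValueError("RF distance requires at least 4 taxa")
    raw = len(bipartition_set(t1) ^ bipartition_set(t2))
    if not normalized:
        return float(raw)
    return raw / (2 * n - 6)


# ---------------------------------------------------------------------------
# Quartets
# ---------------------------------------------------------------------------

# The three unrooted resolutions of a sorted 4-set (a,b,c,d), indexed:
#   0: ab|cd    1: ac|bd    2: ad|bc
_PAIRINGS = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))


@dataclass(frozen=True)
class QuartetTopology:
    """One of the 3 unrooted topologies on 4 taxa, canonicalized.

    ``taxa`` is the sorted 4-tuple of labels; ``index`` selects the pairing
    of the smallest taxon: 0 pairs taxa[0] with taxa[1], 1 with taxa[2],
    2 with taxa[3].
    """

    taxa: tuple[str, str, str, str]
    index: int

    def __post_init__(self):
        if tuple(sorted(self.taxa)) != self.taxa:
            raise ValueError("taxa must be sorted")
        if len(set(self.taxa)) != 4:
            raise ValueError("taxa must be 4 distinct labels")
        if self.index not in (0, 1, 2):
            raise ValueError("index must be 0, 1 or 2")

    @staticmethod
    def of(pair1: Sequence[str], pair2: Sequence[str]) -> "QuartetTopology":
        labels = tuple(sorted([*pair1, *pair2]))
        p1 = frozenset(pair1)
        for idx, ((i, j), (k, l)) in enumerate(_PAIRINGS):
            if {labels[i], labels[j]} == p1 or {labels[k], labels[l]} == p1:
                return QuartetTopology(labels, idx)
        raise ValueError("pairs must partition the 4 labels")

    def split(self) -> tuple[tuple[str, str], tuple[str, str]]:
        (i, j), (k, l) = _PAIRINGS[self.index]
        t = self.taxa
        return (t[i], t[j]), (t[k], t[l])

    def __repr__(self) -> str:
        (a, b), (c, d) = self.split()
        return f"{a}{b}|{c}{d}"


def lca_depth_matrix(tree: PhyloTree, labels: Sequence[str] | None = None) -> np.ndarray:
    """Matrix of topological depths (edge counts from the root) of pairwise LCAs.

    Diagonal holds each leaf's own depth.  Computed in one post-order pass:
    two leaves' LCA is the node at which their subtrees first meet.
    """
    if labels is None:
        labels = tree.leaf_labels
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    lca = np.zeros((n, n), dtype=np.int64)
    depth: dict[int, int] = {id(tree.root): 0}
    for node in tree.preorder():
        for c in node.children:
            depth[id(c)] = depth[id(node)] + 1
    groups: dict[int, list[int]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            if node.label not in idx:
                continue
            i = idx[node.label]
            lca[i, i] = depth[id(node)]
            groups[id(node)] = [i]
        else:
            d = depth[id(node)]
            child_groups = [groups.pop(id(c), []) for c in node.children]
            for g1, g2 in itertools.combinations(child_groups, 2):
                for i in g1:
                    for j in g2:
                        lca[i, j] = lca[j, i] = d
            merged = [i for g in child_groups for i in g]
            groups[id(node)] = merged
    return lca


def topological_distance_matrix(
    tree: PhyloTree, labels: Sequence[str] | None = None
) -> np.ndarray:
    """Pairwise leaf-to-leaf path lengths in edges, on the unrooted topology.

    A degree-2 root is suppressed (paths crossing such a root count one edge
    fewer than in the rooted representation).
    """
    if labels is None:
        labels = tree.leaf_labels
    lca = lca_depth_matrix(tree, labels)
    depths = np.diag(lca)
    dist = depths[:, None] + depths[None, :] - 2 * lca
    if len(tree.root.children) == 2:
        dist = np.where(lca == 0, dist - 1, dist)
    np.fill_diagonal(dist, 0)
    return dist


def induced_quartet(tree: PhyloTree, four_labels: Sequence[str]) -> QuartetTopology:
    """The quartet topology displayed by a binary tree on 4 of its leaves.

    Determined by the four-point condition on topological path lengths: the
    pairing with the strictly smallest sum of within-pair distances is the
    displayed split.
    """
    labels = tuple(sorted(four_labels))
    if len(set(labels)) != 4:
        raise ValueError("need 4 distinct labels")
    missing = [l for l in labels if l not in set(tree.leaf_labels)]
    if missing:
        raise ValueError(f"labels not in tree: {missing}")
    if not tree.is_binary():
        raise ValueError("induced_quartet requires a binary tree")
    d = topological_distance_matrix(tree, labels)
    sums = [d[i, j] + d[k, l] for (i, j), (k, l) in _PAIRINGS]
    return QuartetTopology(labels, int(np.argmin(sums)))


# ---------------------------------------------------------------------------
# Building trees from clusters; consensus
# ---------------------------------------------------------------------------


def tree_from_clusters(
    taxa: Sequence[str], clusters: Iterable[frozenset[str]]
) -> PhyloTree:
    """Assemble a rooted tree displaying exactly the given nested clusters.

    ``clusters`` must be pairwise compatible (nested or disjoint); proper
    subsets of ``taxa`` with at least 2 elements.  Singletons and the full
    set are implicit.  The result may be non-binary.
    """
    taxa = sorted(taxa)
    cl = sorted(
        {frozenset(c) for c in clusters if 1 < len(c) < len(taxa)},
        key=lambda c: (-len(c), sorted(c)),
    )
    root = TreeNode()
    # insert clusters largest-first; each goes under the smallest strict
    # superset already placed, so no re-parenting is ever needed
    nodes: list[tuple[frozenset[str], TreeNode]] = []
    for c in cl:
        parent = root
        parent_set = frozenset(taxa)
        for s, nd in nodes:
            if c < s and len(s) < len(parent_set):
                parent, parent_set = nd, s
        for s, _ in nodes:
            if not (c <= s or s <= c or not (c & s)):
                raise ValueError(f"incompatible clusters: {sorted(c)} vs {sorted(s)}")
        nd = TreeNode()
        parent.add_child(nd)
        nodes.append((c, nd))
    for leaf_label in taxa:
        parent = root
        parent_set = frozenset(taxa)
        for s, nd in nodes:
            if leaf_label in s and len(s) < len(parent_set):
                parent, parent_set = nd, s
        parent.add_child(TreeNode(label=leaf_label))
    return PhyloTree(root, rooted=False)


def majority_consensus(
    trees: Sequence[PhyloTree], threshold: float = 0.5
) -> PhyloTree:
    """Majority consensus: bipartitions in more than ``threshold`` of the inputs.

    All inputs must share a leaf set.  With the default strict-majority
    threshold the retained bipartitions are automatically compatible; the
    result may be non-binary.
    """
    if not trees:
        raise ValueError("majority_consensus requires at least one tree")
    taxa = set(trees[0].leaf_labels)
    counts: dict[Bipartition, int] = {}
    for t in trees:
        if set(t.leaf_labels) != taxa:
            raise ValueError("all trees must share the same leaf set")
        for bp in bipartition_set(t):
            counts[bp] = counts.get(bp, 0) + 1
    keep = [bp for bp, c in counts.items() if c / len(trees) > threshold]
    anchor = min(taxa)
    clusters = []
    for bp in keep:
        side = bp.side_b if anchor in bp.side_a else bp.side_a
        clusters.append(side)
    return tree_from_clusters(sorted(taxa), clusters)


def random_binary_tree(
    labels: Sequence[str], rng: np.random.Generator
) -> PhyloTree:
    """A random binary topology by sequential joining (for tests and seeds)."""
    if len(labels) < 2:
        raise ValueError("need at least 2 labels")
    nodes = [TreeNode(label=l) for l in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    for n in nodes:
        root.add_child(n)
    return PhyloTree(root, rooted=False)
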