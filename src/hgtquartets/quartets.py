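"""Quartet bookkeeping: frequency tables n(G,q), quartet support w_G(T),
dominant quartets, and tree construction from a compatible dominant set.

For a gene-tree set G and a quartet topology q on four species, n(G,q) is
the number of gene trees inducing q.  The quartet support of a species tree
T is w_G(T) = sum over the quartets displayed by T of n(G,q); the species
tree maximizing it is the Maximum Quartet Support Species Tree (MQSST).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trees import (
    PhyloTree,
    QuartetTopology,
    TreeNode,
    topological_distance_matrix,
)

__all__ = [
    "QuartetTable",
    "build_quartet_table",
    "quartet_support",
    "DominantQuartets",
    "dominant_quartets",
    "DominantTieError",
    "IncompatibilityReport",
    "tree_from_dominant_quartets",
]


def _quartet_index(n: int) -> np.ndarray:
    """All C(n,4) sorted 4-subsets of range(n), as an (m, 4) int array."""
    return np.fromiter(
        (i for q in itertools.combinations(range(n), 4) for i in q),
        dtype=np.int64,
    ).reshape(-1, 4)


def _induced_topologies(tree: PhyloTree, labels: Sequence[str], quads: np.ndarray) -> np.ndarray:
    """Topology index (0: ab|cd, 1: ac|bd, 2: ad|bc) per sorted 4-subset.

    Uses the four-point condition on topological distances: the pairing
    with the smallest within-pair distance sum is displayed.
    """
    d = topological_distance_matrix(tree, labels)
    i, j, k, l = quads[:, 0], quads[:, 1], quads[:, 2], quads[:, 3]
    sums = np.stack(
        [d[i, j] + d[k, l], d[i, k] + d[j, l], d[i, l] + d[j, k]], axis=1)
    return np.argmin(sums, axis=1)


class QuartetTable:
    """Counts n(G,q) for every 4-subset of the taxon set.

    ``counts[m, t]`` is the number of gene trees inducing topology ``t`` on
    the m-th 4-subset (subsets in lexicographic order of taxon indices;
    topologies indexed as in :class:`~hgtquartets.trees.QuartetTopology`).
    For complete binary inputs each row sums to the gene count ``k``.
    """

    def __init__(self, taxa: Sequence[str], counts: np.ndarray, k: int):
        self.taxa = tuple(sorted(taxa))
        self.index = {t: i for i, t in enumerate(self.taxa)}
        self.quads = _quartet_index(len(self.taxa))
        if counts.shape != (len(self.quads), 3):
            raise ValueError("counts must be (C(n,4), 3)")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        self.counts = counts
        self.k = k

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def _row(self, four_labels: Sequence[str]) -> int:
        quad = tuple(sorted(four_labels))
        pos = np.array([self.index[t] for t in quad])
        hit = np.nonzero((self.quads == pos).all(axis=1))[0]
        if len(hit) != 1:
            raise KeyError(f"not a 4-subset of the taxon set: {quad}")
        return int(hit[0])

    def count(self, topology: QuartetTopology) -> int:
        return int(self.counts[self._row(topology.taxa), topology.index])

    def row(self, four_labels: Sequence[str]) -> np.ndarray:
        return self.counts[self._row(four_labels)].copy()

    def add(self, other: "QuartetTable") -> "QuartetTable":
        """Entrywise sum: the table of the disjoint union of two gene sets."""
        if self.taxa != other.taxa:
            raise ValueError("taxon sets differ")
        return QuartetTable(self.taxa, self.counts + other.counts, self.k + other.k)

    def to_tsv(self, path) -> None:
        """Dump one row per (4-subset, topology) with its weight, in the
        topology-plus-weight convention used by weighted quartet tools."""
        with open(path, "w") as fh:
            fh.write("taxon1\ttaxon2\ttaxon3\ttaxon4\ttopology\tweight\n")
            for quad, row in zip(self.quads, self.counts):
                labs = [self.taxa[i] for i in quad]
                for t in range(3):
                    topo = QuartetTopology(tuple(labs), t)
                    fh.write("\t".join(labs) + f"\t{topo}\t{int(row[t])}\n")


def build_quartet_table(gene_trees: Sequence[PhyloTree]) -> QuartetTable:
    """Exact n(G,q) for all 4-subsets, from complete binary gene trees."""
    if not gene_trees:
        raise ValueError("need at least one gene tree")
    taxa = gene_trees[0].leaf_labels
    if len(taxa) < 4:
        raise ValueError("need at least 4 taxa")
    quads = _quartet_index(len(taxa))
    counts = np.zeros((len(quads), 3), dtype=np.int64)
    rows = np.arange(len(quads))
    for g in gene_trees:
        if g.leaf_labels != taxa:
            raise ValueError(
                f"gene tree leaf set mismatch: {sorted(set(g.leaf_labels) ^ set(taxa))}")
        if not g.is_binary():
            raise ValueError("gene trees must be binary")
        topo = _induced_topologies(g, taxa, quads)
        np.add.at(counts, (rows, topo), 1)
    return QuartetTable(taxa, counts, len(gene_trees))


def quartet_support(tree: PhyloTree, table: QuartetTable) -> int:
    """w_G(T): total table count over the quartets displayed by ``tree``."""
    if tuple(sorted(tree.leaf_labels)) != table.taxa:
        raise ValueError("tree leaf set does not match the table's taxon set")
    if not tree.is_binary():
        raise ValueError("quartet support requires a binary tree")
    topo = _induced_topologies(tree, table.taxa, table.quads)
    return int(table.counts[np.arange(len(table.quads)), topo].sum())


# ---------------------------------------------------------------------------
# Dominant quartets and the compatibility construction
# ---------------------------------------------------------------------------


@dataclass
class DominantQuartets:
    """Per 4-subset, the strict-majority topology (ties left unresolved)."""

    taxa: tuple[str, ...]
    mapping: dict[tuple[str, str, str, str], int | None]

    @property
    def ties(self) -> list[tuple[str, ...]]:
        return [q for q, t in self.mapping.items() if t is None]

    def topology(self, quad: Sequence[str]) -> QuartetTopology | None:
        t = self.mapping[tuple(sorted(quad))]
        return None if t is None else QuartetTopology(tuple(sorted(quad)), t)


def dominant_quartets(table: QuartetTable) -> DominantQuartets:
    """The most frequent topology per 4-subset; ties reported, never broken."""
    mapping: dict[tuple[str, str, str, str], int | None] = {}
    for quad, row in zip(table.quads, table.counts):
        labs = tuple(table.taxa[i] for i in quad)
        best = int(np.argmax(row))
        if np.sum(row == row[best]) > 1:
            mapping[labs] = None
        else:
            mapping[labs] = best
    return DominantQuartets(table.taxa, mapping)


class DominantTieError(ValueError):
    """Raised when dominant quartets contain ties; carries the tied subsets."""

    def __init__(self, ties: list[tuple[str, ...]]):
        self.ties = ties
        preview = ", ".join("".join(t) for t in ties[:5])
        super().__init__(
            f"{len(ties)} four-taxon subsets have tied quartet counts "
            f"(e.g. {preview}); the dominant-quartet construction is undefined")


@dataclass
class IncompatibilityReport:
    """Evidence that no binary tree displays every dominant quartet.

    ``conflicts`` lists quartets on which a candidate construction failed:
    either pairs blocking every cherry at some stage, or quartets whose
    dominant topology differs from the topology induced by the assembled
    tree.
    """

    stage_taxa: tuple[str, ...]
    conflicts: list[tuple[QuartetTopology, QuartetTopology | None]]

    def __bool__(self) -> bool:  # reports are falsy so `if result:` means success
        return False


def tree_from_dominant_quartets(
    dominant: DominantQuartets,
) -> PhyloTree | IncompatibilityReport:
    """Reconstruct the unique binary tree displaying all dominant quartets.

    Recursive cherry detection: (x, y) is a cherry iff xy|cd is dominant for
    every pair {c, d} disjoint from {x, y}; the cherry is merged (the
    lexicographically smaller label represents it), the map restricted, and
    the recursion continues.  The assembled tree is verified against every
    dominant quartet; on failure, or if no cherry exists at some stage, an
    :class:`IncompatibilityReport` is returned.  Ties raise
    :class:`DominantTieError` (the construction is only defined for a
    complete, tie-free dominant map).
    """
    if dominant.ties:
        raise DominantTieError(dominant.ties)
    taxa = sorted(dominant.taxa)
    if len(taxa) < 4:
        raise ValueError("need at least 4 taxa")

    mapping = dict(dominant.mapping)
    subtree: dict[str, TreeNode] = {t: TreeNode(label=t) for t in taxa}
    active = list(taxa)

    def is_cherry(x: str, y: str) -> tuple[bool, QuartetTopology | None]:
        rest = [t for t in active if t not in (x, y)]
        for c, d in itertools.combinations(rest, 2):
            quad = tuple(sorted((x, y, c, d)))
            topo = QuartetTopology(quad, mapping[quad])
            if frozenset((x, y)) not in map(frozenset, topo.split()):
                return False, topo
        return True, None

    while len(active) > 4:
        merged = False
        blockers: list[tuple[QuartetTopology, QuartetTopology | None]] = []
        for x, y in itertools.combinations(active, 2):
            ok, blocker = is_cherry(x, y)
            if ok:
                node = TreeNode()
                node.add_child(subtree[x])
                node.add_child(subtree[y])
                subtree[x] = node
                del subtree[y]
                active.remove(y)
                mapping = {
                    q: t for q, t in mapping.items() if y not in q}
                merged = True
                break
            blockers.append((blocker, None))
        if not merged:
            return IncompatibilityReport(tuple(active), blockers[:10])

    # base case: 4 active groups resolve by their dominant topology
    quad = tuple(sorted(active))
    topo = QuartetTopology(quad, mapping[quad])
    (a, b), (c, d) = topo.split()
    left, right = TreeNode(), TreeNode()
    left.add_child(subtree[a]); left.add_child(subtree[b])
    right.add_child(subtree[c]); right.add_child(subtree[d])
    root = TreeNode()
    root.add_child(left); root.add_child(right)
    tree = PhyloTree(root, rooted=False)

    # verify the construction displays every dominant quartet
    from .trees import induced_quartet

    conflicts = []
    for quad, t in dominant.mapping.items():
        want = QuartetTopology(quad, t)
        got = induced_quartet(tree, quad)
        if got != want:
            conflicts.append((want, got))
    if conflicts:
        return IncompatibilityReport(tuple(dominant.taxa), conflicts[:10])
    return tree
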