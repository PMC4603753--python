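"""Synthetic data cascade: species trees, HGT locus trees, coalescent gene
trees, GTR+Gamma alignments, and a distance-based gene-tree estimator.

The cascade emulates a standard prokaryote-style study design:

* 51-taxon (50 ingroup + 1 outgroup) ultrametric species trees from a Yule
  (pure-birth) process conditioned on the tip count, with birth rate 1e-6
  per generation and ingroup root height 2e6 generations;
* per-locus trees that differ from the species tree by replacing horizontal
  transfers drawn as a Poisson process at a per-lineage per-generation rate
  (the study rates 0, 2e-9, 5e-9, 2e-8, 2e-7, 5e-7 give expected transfer
  counts per gene of roughly 0, 0.08, 0.2, 0.8, 8 and 20);
* multispecies-coalescent gene trees within each locus tree (one haploid
  sample per species, pairwise coalescence rate
  1/(COALESCENT_TIME_FACTOR * pop_size) per generation, default population
  size 200,000);
* 1000-bp gap-free alignments under GTR with continuous gamma rate
  variation across sites;
* gene-tree estimation from corrected pairwise distances plus neighbor
  joining.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .trees import PhyloTree, TreeNode

__all__ = [
    "GTRParams",
    "DEFAULT_GTR",
    "SimulationConfig",
    "TransferEvent",
    "LocusTree",
    "Alignment",
    "Replicate",
    "assign_ages",
    "expected_tree_length",
    "events_to_rate",
    "simulate_species_tree",
    "simulate_locus_tree",
    "simulate_gene_tree",
    "simulate_alignment",
    "estimate_gene_tree",
    "sample_pop_size",
    "simulate_replicate",
]

NUCLEOTIDES = "ACGT"

# Coalescent time-unit convention: one coalescent unit equals
# COALESCENT_TIME_FACTOR * pop_size generations (pairwise coalescence rate
# is the reciprocal).  The haploid convention (factor 1) fits the
# prokaryote-style study design and reproduces the expected ILS level; the
# diploid-style alternative is factor 2.
COALESCENT_TIME_FACTOR = 1.0


@dataclass(frozen=True)
class GTRParams:
    """GTR exchangeabilities (AC, AG, AT, CG, CT, GT), base frequencies
    (A, C, G, T) and the gamma shape for among-site rate variation."""

    rates: tuple[float, float, float, float, float, float] = (
        1.35, 4.10, 0.75, 1.25, 4.45, 1.0)
    freqs: tuple[float, float, float, float] = (0.30, 0.21, 0.24, 0.25)
    alpha: float = 1.0

    def __post_init__(self):
        if len(self.rates) != 6 or any(r <= 0 for r in self.rates):
            raise ValueError("GTR requires 6 positive exchangeabilities")
        if len(self.freqs) != 4 or any(f <= 0 for f in self.freqs):
            raise ValueError("GTR requires 4 positive base frequencies")
        if abs(sum(self.freqs) - 1.0) > 1e-8:
            raise ValueError(f"base frequencies must sum to 1, got {sum(self.freqs)}")
        if self.alpha <= 0:
            raise ValueError("gamma shape must be positive")

    def rate_matrix(self) -> np.ndarray:
        """The instantaneous rate matrix scaled to 1 substitution/site/unit."""
        s = np.zeros((4, 4))
        idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for (i, j), r in zip(idx, self.rates):
            s[i, j] = s[j, i] = r
        pi = np.asarray(self.freqs)
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(pi * np.diag(q)).sum()
        return q / mu

    @staticmethod
    def jukes_cantor() -> "GTRParams":
        return GTRParams(rates=(1.0,) * 6, freqs=(0.25,) * 4, alpha=1.0)


DEFAULT_GTR = GTRParams()

# Named preset: the default substitution rate puts the expected ingroup
# root-to-tip path at 2e6 * 2.5e-8 = 0.05 substitutions/site.
DEFAULT_SUBST_RATE = 2.5e-8

RecipientBias = Literal["uniform", "proportional_to_distance", "inverse_to_distance"]


@dataclass(frozen=True)
class SimulationConfig:
    """All tunable parameters of the simulation cascade.

    ``pop_size`` is either a fixed haploid-effective count or a
    ``(low, high)`` tuple for a per-replicate uniform draw (both study
    conventions are in circulation; the fixed value is the default).
    """

    n_ingroup: int = 50
    outgroup: bool = True
    birth_rate: float = 1e-6
    tree_height: float = 2e6
    pop_size: float | tuple[float, float] = 200_000.0
    hgt_rate: float = 0.0
    n_loci: int = 1000
    seq_length: int = 1000
    subst_rate: float = DEFAULT_SUBST_RATE
    gtr: GTRParams = field(default_factory=GTRParams)
    gtr_resample: bool = False
    recipient_bias: RecipientBias = "proportional_to_distance"
    outgroup_height_ratio: float = 2.0
    seed: int | None = None

    def __post_init__(self):
        if self.n_ingroup < 4:
            raise ValueError("n_ingroup must be at least 4")
        for name in ("birth_rate", "tree_height", "subst_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.hgt_rate < 0:
            raise ValueError("hgt_rate must be non-negative")
        ps = self.pop_size
        if isinstance(ps, tuple):
            if len(ps) != 2 or ps[0] <= 0 or ps[1] < ps[0]:
                raise ValueError("pop_size range must be (low, high) with 0 < low <= high")
        elif ps <= 0:
            raise ValueError("pop_size must be positive")
        if self.n_loci < 1 or self.seq_length < 1:
            raise ValueError("n_loci and seq_length must be positive")
        if self.recipient_bias not in (
            "uniform", "proportional_to_distance", "inverse_to_distance"):
            raise ValueError(f"unknown recipient_bias {self.recipient_bias!r}")
        if self.outgroup_height_ratio <= 1:
            raise ValueError("outgroup_height_ratio must exceed 1")

    @property
    def n_taxa(self) -> int:
        return self.n_ingroup + (1 if self.outgroup else 0)


@dataclass(frozen=True)
class TransferEvent:
    """A replacing transfer: the recipient lineage below ``time`` is regrafted
    onto the donor lineage.  Branches are identified by the leaf set below
    them at the moment of the event; ``time`` is in generations before present
    and lies within both branches' time spans."""

    donor: tuple[str, ...]
    recipient: tuple[str, ...]
    time: float


@dataclass
class LocusTree:
    """An ultrametric per-locus tree plus the transfer events applied to it."""

    tree: PhyloTree
    events: list[TransferEvent]


@dataclass
class Alignment:
    """A gap-free nucleotide alignment: one row per leaf label."""

    labels: list[str]
    data: np.ndarray  # (n_seq, n_sites) uint8 codes into "ACGT"

    def __post_init__(self):
        if self.data.ndim != 2 or self.data.shape[0] != len(self.labels):
            raise ValueError("data must be (n_labels, n_sites)")

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def sequence(self, label: str) -> str:
        row = self.data[self.labels.index(label)]
        return "".join(NUCLEOTIDES[x] for x in row)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for lab in self.labels:
                fh.write(f">{lab}\n{self.sequence(lab)}\n")

    @staticmethod
    def from_fasta(path) -> "Alignment":
        labels: list[str] = []
        rows: list[list[int]] = []
        code = {c: i for i, c in enumerate(NUCLEOTIDES)}
        with open(path) as fh:
            seq: list[int] = []
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if labels:
                        rows.append(seq)
                    labels.append(line[1:].split()[0])
                    seq = []
                elif line:
                    seq.extend(code[c] for c in line.upper())
            if labels:
                rows.append(seq)
        return Alignment(labels, np.asarray(rows, dtype=np.uint8))


# ---------------------------------------------------------------------------
# Species tree: conditioned Yule
# ---------------------------------------------------------------------------


def _ingroup_labels(n: int) -> list[str]:
    width = len(str(n))
    return [f"s{i:0{width}d}" for i in range(1, n + 1)]

OUTGROUP_LABEL = "out"


def simulate_species_tree(
    config: SimulationConfig, rng: np.random.Generator
) -> PhyloTree:
    """A rooted binary ultrametric Yule tree conditioned on the tip count.

    Construction: conditioned on ``n_ingroup`` tips at height ``tree_height``
    with the root split at the top, the remaining n-2 speciation times are
    i.i.d. with density proportional to exp(birth_rate * t) on [0, H]
    (forward time from the root); the ranked branching order splits a
    uniformly chosen extant lineage at each event.  The outgroup, if
    enabled, attaches above the ingroup root so its leaf depth equals
    ``outgroup_height_ratio`` times the ingroup height.
    """
    n = config.n_ingroup
    if n < 4:
        raise ValueError("n_ingroup must be at least 4")
    H = config.tree_height
    lam = config.birth_rate
    u = rng.random(n - 2)
    if lam * H > 1e-12:
        grow = math.expm1(lam * H)
        times = np.log1p(u * grow) / lam
    else:  # birth rate ~ 0: times uniform
        times = u * H
    times.sort()

    root = TreeNode()
    root.age = H
    active: list[TreeNode] = [root.add_child(TreeNode()), root.add_child(TreeNode())]
    for t in times:
        k = int(rng.integers(len(active)))
        node = active[k]
        node.age = H - t
        active[k] = node.add_child(TreeNode())
        active.append(node.add_child(TreeNode()))
    for node, label in zip(active, _ingroup_labels_for(active, rng, n)):
        node.age = 0.0
        node.label = label

    if config.outgroup:
        top = TreeNode()
        top.age = config.outgroup_height_ratio * H
        top.add_child(root)
        og = top.add_child(TreeNode(label=OUTGROUP_LABEL))
        og.age = 0.0
        root = top
    _lengths_from_ages(root)
    return PhyloTree(root, rooted=True)


def _ingroup_labels_for(active, rng, n):
    """Random label assignment so the label order carries no topology signal."""
    labels = _ingroup_labels(n)
    perm = rng.permutation(n)
    return [labels[p] for p in perm]


def _lengths_from_ages(root: TreeNode) -> None:
    for node in root.preorder():
        for c in node.children:
            c.length = node.age - c.age
            if c.length < -1e-6:
                raise ValueError("negative branch from inconsistent ages")
            c.length = max(c.length, 0.0)
    root.length = None


def assign_ages(tree: PhyloTree, tol: float = 1e-6) -> None:
    """Set node ages (time before present) from branch lengths.

    Requires an ultrametric tree: all leaves equidistant from the root
    (relative tolerance ``tol``); raises ValueError otherwise.
    """
    depth: dict[int, float] = {id(tree.root): 0.0}
    for node in tree.preorder():
        for c in node.children:
            depth[id(c)] = depth[id(node)] + (c.length or 0.0)
    leaf_depths = [depth[id(l)] for l in tree.root.leaves()]
    height = max(leaf_depths)
    if height > 0 and (height - min(leaf_depths)) > tol * height:
        raise ValueError("tree is not ultrametric: unequal root-to-leaf depths")
    for node in tree.preorder():
        node.age = height - depth[id(node)]
    for leaf in tree.root.leaves():
        leaf.age = 0.0


def expected_tree_length(config: SimulationConfig) -> float:
    """Analytic expected total branch length of the species tree, generations.

    Under the conditioned Yule construction the expected number of extant
    ingroup lineages at forward time t is 2 + (n-2)F(t) with
    F(t) = (exp(lam t)-1)/(exp(lam H)-1), so the ingroup length integrates
    to 2H + (n-2)(1/lam - H/(exp(lam H)-1)); the outgroup adds its stem and
    pendant.  Under the defaults this is about 4.3e7, which times the study
    transfer rates gives the expected transfer counts per gene.
    """
    n, H, lam = config.n_ingroup, config.tree_height, config.birth_rate
    if lam * H > 1e-12:
        integral = 1.0 / lam - H / math.expm1(lam * H)
    else:
        integral = H / 2.0
    total = 2.0 * H + (n - 2) * integral
    if config.outgroup:
        total += (2.0 * config.outgroup_height_ratio - 1.0) * H
    return total


def events_to_rate(expected_events: float, config: SimulationConfig) -> float:
    """Transfer rate giving ``expected_events`` per locus under ``config``.

    Used to define rate conditions "analogous" to the 51-taxon study
    conditions on smaller trees, by matching expected events per gene
    rather than the raw per-lineage rate.
    """
    return expected_events / expected_tree_length(config)


# ---------------------------------------------------------------------------
# Locus tree: stochastic replacing HGT
# ---------------------------------------------------------------------------


def _edges(root: TreeNode) -> list[TreeNode]:
    """All child nodes, each standing for the edge above it."""
    return [n for n in root.preorder() if n.parent is not None]


def _clade(node: TreeNode) -> tuple[str, ...]:
    return tuple(sorted(l.label for l in node.leaves()))


def _mrca_age(a: TreeNode, b: TreeNode) -> float:
    anc = set()
    x = a
    while x is not None:
        anc.add(id(x))
        x = x.parent
    y = b
    while y is not None:
        if id(y) in anc:
            return y.age
        y = y.parent
    raise RuntimeError("nodes share no ancestor")


def simulate_locus_tree(
    species_tree: PhyloTree,
    hgt_rate: float,
    recipient_bias: RecipientBias = "proportional_to_distance",
    rng: np.random.Generator | None = None,
) -> LocusTree:
    """Perturb an ultrametric species tree with replacing transfers.

    The event count is Poisson with mean ``hgt_rate`` times the species
    tree's total branch length (the per-lineage, per-generation rate
    integrated over the tree); event times fall on the tree with density
    proportional to the number of contemporaneous lineages.  Events are
    applied oldest-first; each picks its donor uniformly among the branches
    of the *current* locus tree alive at that time, and its recipient among
    the remaining live branches with probability given by
    ``recipient_bias`` (default: proportional to the patristic distance
    from the donor, i.e. distant lineages are favored; the inverse and
    uniform conventions are available for ablation).  The recipient's
    subtree below the event time is detached and regrafted onto the donor.
    """
    if rng is None:
        rng = np.random.default_rng()
    if hgt_rate < 0:
        raise ValueError("hgt_rate must be non-negative")
    locus = species_tree.copy()
    if any(n.age is None for n in locus.preorder()):
        assign_ages(locus)

    edges = _edges(locus.root)
    lengths = np.array([e.parent.age - e.age for e in edges])
    total = float(lengths.sum())
    n_events = int(rng.poisson(hgt_rate * total)) if total > 0 else 0
    if n_events == 0:
        return LocusTree(locus, [])

    # event ages: uniform over total branch length => density ~ lineage count
    which = rng.choice(len(edges), size=n_events, p=lengths / total)
    ages = np.array(
        [edges[i].age + rng.random() * (edges[i].parent.age - edges[i].age)
         for i in which]
    )
    order = np.argsort(-ages)  # oldest (root-most) first

    events: list[TransferEvent] = []
    for t in ages[order]:
        live = [e for e in _edges(locus.root) if e.age < t < e.parent.age]
        if len(live) < 2:
            continue
        donor = live[int(rng.integers(len(live)))]
        candidates = [e for e in live if e is not donor]
        if recipient_bias == "uniform":
            w = np.ones(len(candidates))
        else:
            dists = np.array(
                [2.0 * (_mrca_age(donor, c) - t) for c in candidates])
            dists = np.maximum(dists, 1e-12)
            w = dists if recipient_bias == "proportional_to_distance" else 1.0 / dists
        w = w / w.sum()
        recipient = candidates[int(rng.choice(len(candidates), p=w))]
        events.append(
            TransferEvent(donor=_clade(donor), recipient=_clade(recipient),
                          time=float(t)))
        _apply_transfer(locus, donor, recipient, float(t))
    _lengths_from_ages(locus.root)
    return LocusTree(PhyloTree(locus.root, rooted=True), events)


def _apply_transfer(
    locus: PhyloTree, donor: TreeNode, recipient: TreeNode, t: float
) -> None:
    """Regraft the recipient subtree onto the donor edge at age ``t``."""
    # split the donor edge with a new node at age t
    mid = TreeNode()
    mid.age = t
    d_parent = donor.parent
    d_parent.children[d_parent.children.index(donor)] = mid
    mid.parent = d_parent
    mid.add_child(donor)
    # detach the recipient and hang it under the new node
    r_parent = recipient.parent
    r_parent.children.remove(recipient)
    mid.add_child(recipient)
    # suppress the recipient's old parent (now degree 2)
    if len(r_parent.children) == 1:
        only = r_parent.children[0]
        grand = r_parent.parent
        if grand is None:
            only.parent = None
            locus.root = only
        else:
            grand.children[grand.children.index(r_parent)] = only
            only.parent = grand


# ---------------------------------------------------------------------------
# Gene tree: multispecies coalescent within the locus tree
# ---------------------------------------------------------------------------


def simulate_gene_tree(
    locus_tree: PhyloTree | LocusTree,
    pop_size: float,
    rng: np.random.Generator | None = None,
) -> PhyloTree:
    """One haploid sample per species coalescing within the locus tree.

    Within every branch, k lineages coalesce at total rate
    k(k-1)/2 * 1/(COALESCENT_TIME_FACTOR * pop_size) per generation
    (coalescent unit = COALESCENT_TIME_FACTOR * pop_size generations);
    lineages entering a parent branch are the union of the children's
    survivors; above the root the remaining lineages coalesce to one.
    Branch lengths are in generations, so every gene-tree node is at least
    as old as the corresponding locus-tree divergence.
    """
    if rng is None:
        rng = np.random.default_rng()
    if pop_size <= 0:
        raise ValueError("pop_size must be positive")
    tree = locus_tree.tree if isinstance(locus_tree, LocusTree) else locus_tree
    if any(n.age is None for n in tree.preorder()):
        assign_ages(tree)

    two_ne = COALESCENT_TIME_FACTOR * pop_size

    def coalesce(lineages: list[TreeNode], t0: float, t1: float) -> list[TreeNode]:
        t = t0
        lineages = list(lineages)
        while len(lineages) > 1:
            k = len(lineages)
            rate = k * (k - 1) / 2.0 / two_ne
            t = t + rng.exponential(1.0 / rate)
            if t >= t1:
                break
            i, j = sorted(rng.choice(k, size=2, replace=False))
            parent = TreeNode()
            parent.age = t
            parent.add_child(lineages[i])
            parent.add_child(lineages[j])
            lineages = [l for m, l in enumerate(lineages) if m not in (i, j)]
            lineages.append(parent)
        return lineages

    def survivors(node: TreeNode) -> list[TreeNode]:
        if node.is_leaf:
            tip = TreeNode(label=node.label)
            tip.age = node.age
            base = [tip]
        else:
            base = [l for c in node.children for l in survivors(c)]
        top = node.parent.age if node.parent is not None else math.inf
        return coalesce(base, node.age, top)

    (root,) = survivors(tree.root)
    _lengths_from_ages(root)
    return PhyloTree(root, rooted=True)


# ---------------------------------------------------------------------------
# Alignments: GTR + continuous gamma rates
# ---------------------------------------------------------------------------


def simulate_alignment(
    gene_tree: PhyloTree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    gtr: GTRParams | None = None,
) -> Alignment:
    """Evolve ``seq_length`` sites root-to-tips under GTR+Gamma.

    Branch lengths (generations) convert to expected substitutions/site via
    ``subst_rate``; each site carries an i.i.d. gamma(alpha, 1/alpha) rate
    multiplier.  Transition matrices come from the spectral decomposition
    of the reversible rate matrix.
    """
    if rng is None:
        rng = np.random.default_rng()
    params = gtr if gtr is not None else config.gtr
    if config.gtr_resample and gtr is None:
        params = resample_gtr(config.gtr, rng)
    q = params.rate_matrix()
    pi = np.asarray(params.freqs)
    ps = np.sqrt(pi)
    sym = q * (ps[:, None] / ps[None, :])
    eigval, eigvec = np.linalg.eigh((sym + sym.T) / 2.0)

    L = config.seq_length
    site_rate = rng.gamma(shape=params.alpha, scale=1.0 / params.alpha, size=L)

    states: dict[int, np.ndarray] = {}
    root_states = rng.choice(4, size=L, p=pi)
    states[id(gene_tree.root)] = root_states
    labels, rows = [], []
    for node in gene_tree.preorder():
        if node.parent is not None:
            d = (node.length or 0.0) * config.subst_rate
            parent_states = states[id(node.parent)]
            t = d * site_rate
            expd = np.exp(eigval[None, :] * t[:, None])  # (L, 4)
            m = eigvec[parent_states, :] * expd
            probs = m @ eigvec.T
            probs *= ps[None, :]
            probs /= ps[parent_states][:, None]
            probs = np.clip(probs, 0.0, None)
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random(L)
            states[id(node)] = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
        if node.is_leaf:
            labels.append(node.label)
            rows.append(states[id(node)])
    order = np.argsort(labels)
    return Alignment(
        [labels[i] for i in order],
        np.asarray([rows[i] for i in order], dtype=np.uint8),
    )


def resample_gtr(base: GTRParams, rng: np.random.Generator) -> GTRParams:
    """Per-gene GTR parameter draw around a preset (loose lognormal/Dirichlet
    priors), mimicking between-gene model heterogeneity."""
    rates = tuple(float(r * rng.lognormal(0.0, 0.25)) for r in base.rates)
    freqs = rng.dirichlet(np.asarray(base.freqs) * 100.0)
    freqs = tuple(float(f) for f in freqs / freqs.sum())
    alpha = float(base.alpha * rng.lognormal(0.0, 0.25))
    return GTRParams(rates=rates, freqs=freqs, alpha=alpha)


# ---------------------------------------------------------------------------
# Gene-tree estimation: corrected distances + neighbor joining
# ---------------------------------------------------------------------------


def estimate_gene_tree(
    alignment: Alignment,
    correction: Literal["jc", "logdet"] = "jc",
    max_distance: float = 5.0,
) -> PhyloTree:
    """Distance-based gene-tree estimate: corrected pairwise distances plus
    canonical neighbor joining.  Deterministic given the alignment.

    Saturated distances (undefined correction) clamp to ``max_distance``
    with a warning; an all-identical alignment yields a zero distance
    matrix, which is flagged degenerate and resolved arbitrarily (but
    deterministically) by NJ.
    """
    from .methods import neighbor_joining

    n = len(alignment.labels)
    if n < 4:
        raise ValueError("need at least 4 sequences")
    data = alignment.data
    L = alignment.n_sites
    d = np.zeros((n, n))
    saturated = False
    for i in range(n):
        for j in range(i + 1, n):
            p = float(np.mean(data[i] != data[j]))
            if correction == "jc":
                if p < 0.75 - 1e-9:
                    dist = -0.75 * math.log1p(-4.0 * p / 3.0)
                else:
                    dist, saturated = max_distance, True
            elif correction == "logdet":
                F = np.zeros((4, 4))
                np.add.at(F, (data[i], data[j]), 1.0)
                F /= L
                det = np.linalg.det(F)
                if det <= 0:
                    dist, saturated = max_distance, True
                else:
                    gx = np.bincount(data[i], minlength=4) / L
                    gy = np.bincount(data[j], minlength=4) / L
                    if np.any(gx <= 0) or np.any(gy <= 0):
                        dist, saturated = max_distance, True
                    else:
                        dist = -0.25 * (
                            math.log(det)
                            - 0.5 * (np.log(gx).sum() + np.log(gy).sum())
                        )
            else:
                raise ValueError(f"unknown correction {correction!r}")
            d[i, j] = d[j, i] = min(max(dist, 0.0), max_distance)
    if saturated:
        warnings.warn("saturated pairwise distances clamped", RuntimeWarning)
    if np.allclose(d, 0.0):
        warnings.warn(
            "degenerate alignment: all sequences identical; topology arbitrary",
            RuntimeWarning,
        )
    return neighbor_joining(d, alignment.labels)


# ---------------------------------------------------------------------------
# Replicate cascade
# ---------------------------------------------------------------------------


@dataclass
class Replicate:
    """One simulated replicate: a species tree with per-locus descendants."""

    config: SimulationConfig
    species_tree: PhyloTree
    locus_trees: list[LocusTree]
    gene_trees: list[PhyloTree]
    pop_size: float


def sample_pop_size(config: SimulationConfig, rng: np.random.Generator) -> float:
    ps = config.pop_size
    if isinstance(ps, tuple):
        return float(rng.uniform(ps[0], ps[1]))
    return float(ps)


def simulate_replicate(
    config: SimulationConfig,
    rng: np.random.Generator,
    n_loci: int | None = None,
) -> Replicate:
    """Run species tree -> locus trees -> gene trees for one replicate."""
    n_loci = config.n_loci if n_loci is None else n_loci
    species = simulate_species_tree(config, rng)
    pop = sample_pop_size(config, rng)
    locus_trees, gene_trees = [], []
    for _ in range(n_loci):
        lt = simulate_locus_tree(
            species, config.hgt_rate, config.recipient_bias, rng)
        locus_trees.append(lt)
        gene_trees.append(simulate_gene_tree(lt, pop, rng))
    return Replicate(config, species, locus_trees, gene_trees, pop)
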