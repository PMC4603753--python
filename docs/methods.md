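# Methods

This package studies how quartet-based summary methods estimate a species
tree when gene trees disagree with it for two reasons at once: incomplete
lineage sorting (ILS) and horizontal gene transfer (HGT). It contains a
three-layer simulator (species tree → per-locus tree with transfers →
coalescent gene tree, optionally → sequences → re-estimated gene trees),
four species-tree estimators built on a common quartet machinery, and a
benchmarking harness. Everything below is the package's own account of the
models, conventions and design choices; no empirical number is stated here
that the tests or `scripts/acceptance.py` do not themselves compute.

## The estimation problem

For a gene-tree set *G* on species set *S* and a quartet topology *q* on
four species, *n(G, q)* is the number of gene trees inducing *q*. The
quartet support of a candidate species tree *T* is

  w_G(T) = Σ_{q ∈ Q(T)} n(G, q),

the sum over the C(n,4) quartets *T* displays. The Maximum Quartet Support
Species Tree (MQSST) problem asks for the *T* maximizing w_G(T). Its appeal
under both ILS and bounded HGT is that the *most probable* quartet topology
on any four species matches the species tree, so with enough gene trees the
true tree attains the maximum support and quartet-based optimizers are
statistically consistent. The package tests this consistency empirically
rather than proving it.

## Estimators

**Exhaustive MQSST** (`mqsst_exact`) scores all (2n−5)!! unrooted
topologies; guarded at n ≤ 9 by default. It exists as the oracle against
which the constrained DP is verified.

**Cluster-constrained DP** (`mqsst_constrained_dp`) is an ASTRAL-style
search: a constraint set X of rooted clusters (anchored at the designated
outgroup, else the lexicographically smallest taxon) is built from all
input gene trees plus, by default, the NJst tree and one deterministically
resolved greedy-consensus tree — the extras guarantee that at least one
binary tree is assemblable from X. The DP is exact over all binary trees
whose clusters lie in X:

  V(singleton) = 0,
  V(A) = max over A = A1 ⊔ A2, A1, A2 ∈ X of V(A1) + V(A2) + W(A1, A2),

where W(A1, A2) counts gene quartets *anchored* at the tripartition
(A1, A2, S∖A): one leaf from each of two parts and a pair from the third,
counted at the topology joining the two singles. Every quartet a binary
tree displays is anchored at exactly two internal nodes, so V(S) equals
twice the quartet support of the optimum; the implementation returns
V(S)/2 and the test suite asserts this equals an independent recount via
quartet induction on the returned tree. Ties break deterministically
(smallest partition in a fixed bitmask order). Enlarging X can only raise
the optimum (asserted as a test).

**Max-cut-style amalgamation** (`wqmc_style`) is an openly documented
variant of weighted quartet amalgamation, not a reimplementation of any
released binary: at each subproblem it bipartitions the current elements by
steepest-ascent hill-climbing from deterministic singleton seeds plus a few
seeded random cuts (default 3), then recurses on each side with the entire
off-side merged into one placeholder element (quartets with ≥2 members in
the off-side are deferred to other subproblems). The cut objective is the
satisfied-minus-violated quartet weight written in per-edge form: a quartet
topology (p,q)|(r,s) scores w·(#cross-pair edges crossing the cut − 2·#
within-pair edges crossing). On 2+2 placements this is the plain
satisfied-minus-violated weight up to scale, and 3+1/4+0 placements score
zero, but the per-edge form changes smoothly under single-element moves,
which makes the hill-climb markedly more reliable than scoring whole
quartets only. The method is deterministic given its seed and carries no
optimality guarantee; its binding contract — exact recovery of any binary
tree from that tree's own quartet set (n ≤ 10 tested over many random
trees) — is enforced in the acceptance suite.

**NJst** (`njst`) averages leaf-to-leaf *topological* distances (edge
counts on the unrooted gene tree; a cherry pair is at distance 2) over the
gene trees and runs canonical Saitou–Nei neighbor joining with a
deterministic lexicographic tie-break. Whether one counts edges or internal
nodes on the path differs by 1 on complete binary trees and cannot change
the NJ topology; both are offered and the invariance is asserted. NJ is
exact on additive matrices, which is the basis of NJst's consistency under
the coalescent; no such guarantee exists under HGT, and the harness probes
exactly that gap.

**Dominant-quartet construction** (`tree_from_dominant_quartets`) realizes
the compatibility method: if for every 4-subset a strict-majority topology
exists and the collection is compatible, the unique displaying tree is
assembled by recursive cherry detection ((x,y) is a cherry iff xy|cd is
dominant for every disjoint pair) and verified against every dominant
quartet. Ties are refused with an explicit report, and incompatible inputs
return a report naming offending quartets — never a silently repaired tree.
Because ties and incompatibilities are routine at small gene counts, the
*benchmarking* wrapper (`evaluation.dominant_quartet_estimate`) falls back
to the constrained DP run on dominant-indicator weights (1 for each unique
majority topology, 0 otherwise), which coincides with the pure construction
in the large-sample regime. Rows record which path was taken.

## The simulator

**Species trees.** Yule (pure-birth) trees conditioned on the tip count:
with n tips at height H and the root split at the top, the remaining n−2
speciation times are i.i.d. with density ∝ exp(λt) on [0, H] (forward time
from the root; λ is the birth rate), and the ranked branching order splits
a uniformly chosen extant lineage at each event. Defaults: 50 ingroup taxa,
λ = 10⁻⁶ per generation, H = 2×10⁶ generations. One outgroup attaches above
the ingroup root with total depth `outgroup_height_ratio` (default 2) times
H. The expected total branch length has the closed form
2H + (n−2)(1/λ − H/(e^{λH}−1)) plus the outgroup stem and pendant — about
4.3×10⁷ generations under the defaults — and the test suite checks the
simulated mean against it. This length converts per-lineage transfer rates
into expected transfer counts per gene (rates 2×10⁻⁹ … 5×10⁻⁷ give ≈0.08 …
≈21 events per locus; `scripts/acceptance.py` recomputes these).

**Locus trees.** Transfers follow a stochastic (non-highways) model. The
event count per locus is Poisson with mean rate × total species-tree branch
length; event times land on the tree with density proportional to the
number of contemporaneous lineages. Events apply oldest-first to the
*current* locus tree: the donor is uniform among branches alive at the
event time, the recipient is drawn from the remaining live branches with
weight proportional to its patristic distance from the donor (the package
default, taking the protocol sentence literally; `inverse_to_distance`
implements the opposite biological convention — transfer is likelier
between close relatives — and `uniform` supports ablation). The transfer is
*replacing*: the recipient's subtree below the event time is detached and
regrafted onto the donor; the vacated degree-2 node is suppressed.
Consequences worth noting: a transfer capturing a root-adjacent lineage
suppresses the old root, so a locus tree's height can shrink; and because
surgery slightly reshapes branch lengths, the per-lineage rate is exact on
the species tree and only approximate on the evolving locus tree — the
Poisson mean (what the calibration checks) is exact by construction.
Duplicative (additive) transfers, gene duplication/loss and missing taxa
are out of scope.

**Gene trees.** One haploid sample per species coalesces within the locus
tree: k lineages in a branch coalesce at total rate k(k−1)/2 × 1/(c·N) per
generation, survivors merge at each divergence, and the root branch runs to
a single lineage. The time-unit convention is exposed as
`COALESCENT_TIME_FACTOR` (= c above): the package default is the haploid
convention c = 1 (coalescent unit = N generations), which suits a
prokaryote-style design; c = 2 gives the diploid-style convention. With the
default c = 1 and the fixed population size N = 200,000, the ILS-only
condition produces the intended "moderately high" discordance level
(`scripts/acceptance.py`, target t1; the per-replicate-uniform
N ~ U(200,000, 2,000,000) alternative is also supported and produces far
more discordance — `analysis/01_calibrate_simulator.py` reports both).

**Alignments and estimated gene trees.** Sequences evolve root-to-tips
under GTR with i.i.d. per-site gamma(α, 1/α) rate multipliers (continuous,
not discretized), via the spectral decomposition of the reversible rate
matrix. Branch lengths in generations convert to substitutions/site by
`subst_rate`; the default 2.5×10⁻⁸ puts the expected ingroup root-to-tip
path at 0.05 substitutions/site. The GTR preset (exchangeabilities,
frequencies, α = 1) is a named default, since no canonical empirical values
attach to this design; optional per-gene resampling draws loose
lognormal/Dirichlet perturbations around the preset to mimic between-gene
heterogeneity. Gene-tree estimation is deliberately a transparent
distance method — JC-corrected (or log-det) pairwise distances plus the
same NJ used by NJst — not a maximum-likelihood stand-in's equal: it is
faster, deterministic, and noisier, which the harness only uses to show
the direction of the estimation-error effect. Saturated distances clamp to
a configurable maximum with a warning; an all-identical alignment is
flagged degenerate.

## What the generator does and does not emulate

It reproduces the study conditions this package benchmarks under: tip
counts, tree height, birth rate, the six transfer rates and their expected
events per gene, the coalescent population-size settings, 1000-bp gap-free
alignments. It does not model rate heterogeneity across lineages or loci
beyond the gamma-across-sites and optional GTR resampling, indels, missing
taxa, gene duplication/loss, or preferential transfer "highways". Passing
tests therefore speak to method behavior under clean ILS+HGT discordance
with complete, correctly-rooted-by-outgroup data — not to robustness
against alignment error, fragmentary genes or orthology mistakes.

## Scaled study conditions

The full 51-taxon, 50-replicate, 1000-gene design is a configuration
choice, not a test requirement. The default benchmarking profile used by
the analysis scripts and the acceptance suite is 12 taxa (11 ingroup + 1
outgroup), 5–15 replicates, 10–200 true gene trees, with HGT conditions
defined by expected transfers per gene {0, 0.08, 0.2, 0.8, 8, 20} — the
transfer rate is rescaled by the smaller tree's expected length
(`events_to_rate`) so the per-gene transfer load matches the full-scale
conditions. Note that 8–20 transfers per gene perturb a 12-taxon tree
proportionally far more than a 51-taxon tree, so the two most extreme
scaled conditions are *harder* than their full-scale counterparts; the
high-HGT method comparison in the acceptance suite therefore uses the
study's highest per-lineage rate (5×10⁻⁷, ≈8 transfers per gene at this
size). Calibration statistics (transfer counts, ILS level) always run at
full 51-taxon scale, where they are cheap.

## Numerical and design details

* Topology comparisons are unrooted throughout; trees are stored rooted.
  Robinson-Foulds distances normalize by 2n−6 (the maximum for binary
  trees), making the normalized RF equal the missing-branch rate.
* Quartet induction uses the four-point condition on topological distance
  matrices computed in one pass per tree, so tables over all C(n,4)
  subsets are exact (no subsampling is used anywhere in the tests).
* All canonical forms (bipartitions, quartet topologies, tie-breaks) order
  by lexicographic label; determinism is asserted, not assumed.
* One global seed drives everything through counter-keyed substreams
  (`rng_for(seed, stage, replicate, condition, locus)`), so adding a method
  or condition never perturbs simulation draws, and any run manifest
  re-executes bit-identically (runtime columns aside).
* NJ branch lengths are floored at zero (topology is what the harness
  consumes); estimated trees carry lengths only as a by-product.
* Degenerate inputs fail loudly: non-ultrametric trees into the locus
  simulator, mismatched leaf sets, infeasible constraint sets, ties in the
  dominant map. The experiment sweep records per-row failures and
  continues.

## Known limitations

The max-cut variant is a heuristic: on adversarial weight tables it can
return trees scoring below the constrained-DP optimum (the score-comparison
report quantifies this). The exhaustive oracle is exponential and capped at
small n. The distance-based gene-tree estimator is noisier than
likelihood-based estimation, so absolute error levels on estimated gene
trees are not comparable to studies using ML gene trees — only the
true-vs-estimated direction is meaningful here. Locus-tree surgery is
O(events × n) per locus, and quartet tables are O(k·n² + C(n,4)) per gene
set; both are comfortable at the scaled profile but the DP's O(|X|²)
partition enumeration grows quickly past ~20 taxa with many gene trees.
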