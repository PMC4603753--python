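"""Experiment harness: factorial sweeps over HGT conditions, gene counts and
methods, with per-replicate error rates and quartet-support scores.

The harness mirrors a standard species-tree benchmarking design: per
replicate one species tree is drawn and shared across HGT conditions; per
condition a set of loci is simulated (locus trees, then coalescent gene
trees, optionally alignments and re-estimated gene trees); each estimator
runs on nested prefixes of the gene set; normalized Robinson-Foulds error
against the true species tree and the achieved quartet support are
recorded per row.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import methods as M
from .quartets import (
    DominantTieError,
    IncompatibilityReport,
    QuartetTable,
    build_quartet_table,
    dominant_quartets,
    quartet_support,
    tree_from_dominant_quartets,
)
from .simulate import (
    SimulationConfig,
    estimate_gene_tree,
    events_to_rate,
    sample_pop_size,
    simulate_alignment,
    simulate_gene_tree,
    simulate_locus_tree,
    simulate_species_tree,
)
from .trees import PhyloTree, rf_distance, write_newick_file

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "KNOWN_METHODS",
    "run_experiment",
    "gene_tree_discordance",
    "estimate_species_tree",
    "dominant_quartet_estimate",
    "aggregate",
    "ScoreComparisonReport",
    "score_comparison_report",
]

# seeding stage codes: one global seed spawns independent substreams keyed by
# (stage, replicate, condition, locus), so adding methods or conditions never
# perturbs earlier simulation draws
STAGE_SPECIES = 1
STAGE_POP = 2
STAGE_LOCUS = 3
STAGE_GENE = 4
STAGE_SEQ = 5
STAGE_METHOD = 6


def rng_for(seed: int, *path: int) -> np.random.Generator:
    """Independent substream for a (stage, replicate, ...) counter path."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *map(int, path)]))


KNOWN_METHODS = ("dp", "wqmc", "njst", "dominant", "exact")


@dataclass(frozen=True)
class ExperimentConfig:
    """Simulation settings plus the factorial sweep definition.

    ``hgt_rates`` are per-lineage per-generation transfer rates; if
    ``expected_events`` is given instead, rates are derived per condition
    so the expected transfer count per gene matches (useful for running
    rate conditions "analogous" to the 51-taxon study on smaller trees).
    """

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    hgt_rates: tuple[float, ...] | None = None
    expected_events: tuple[float, ...] | None = None
    gene_counts: tuple[int, ...] = (10, 50, 200)
    n_replicates: int = 1
    methods: tuple[str, ...] = ("dp", "wqmc", "njst")
    use_true_gene_trees: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")
        if not self.gene_counts or min(self.gene_counts) < 1:
            raise ValueError("gene_counts must be positive")
        if max(self.gene_counts) > self.sim.n_loci:
            raise ValueError("gene_counts may not exceed sim.n_loci")
        if self.hgt_rates is None and self.expected_events is None:
            object.__setattr__(self, "hgt_rates", (0.0,))
        elif self.hgt_rates is not None and self.expected_events is not None:
            raise ValueError("give at most one of hgt_rates or expected_events")
        for m in self.methods:
            if m not in KNOWN_METHODS:
                raise ValueError(f"unknown method {m!r}; choose from {KNOWN_METHODS}")

    def rates(self) -> tuple[float, ...]:
        if self.hgt_rates is not None:
            return tuple(self.hgt_rates)
        return tuple(events_to_rate(e, self.sim) for e in self.expected_events)


@dataclass
class ExperimentResult:
    """Per-row sweep results plus the provoking configuration.

    ``rows`` columns: replicate, condition, hgt_rate, n_genes, method,
    rf_error, support, runtime_s, status, discordance (per-condition mean
    gene-tree vs species-tree RF, repeated on each row of the condition).
    """

    config: ExperimentConfig
    rows: pd.DataFrame
    species_trees: dict[int, PhyloTree] = field(default_factory=dict)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.rows.to_csv(out / "results.tsv", sep="\t", index=False)
        if self.species_trees:
            write_newick_file(
                out / "species_trees.nwk",
                [self.species_trees[r] for r in sorted(self.species_trees)])


def gene_tree_discordance(
    species_tree: PhyloTree, gene_trees: Sequence[PhyloTree]
) -> float:
    """Mean normalized RF distance between gene trees and the species tree."""
    if not gene_trees:
        raise ValueError("need at least one gene tree")
    return float(np.mean(
        [rf_distance(g, species_tree, normalized=True) for g in gene_trees]))


def dominant_quartet_estimate(
    table: QuartetTable,
    gene_trees: Sequence[PhyloTree],
    clusters: M.ClusterSet | None = None,
) -> tuple[PhyloTree, str]:
    """Dominant-quartet compatibility construction with a defined fallback.

    The pure construction refuses ties and incompatible dominant sets (at
    small gene counts both are routine).  For benchmarking we fall back to
    the constrained DP run on dominant-indicator weights (1 for each
    unique-majority topology, 0 elsewhere), which agrees with the pure
    construction in the large-sample regime where dominants are compatible
    and their tree's clusters appear among the gene trees.
    """
    dom = dominant_quartets(table)
    if not dom.ties:
        res = tree_from_dominant_quartets(dom)
        if isinstance(res, PhyloTree):
            return res, "dominant"
    counts = np.zeros_like(table.counts)
    best = np.argmax(table.counts, axis=1)
    unique = (table.counts == table.counts[np.arange(len(best)), best][:, None]
              ).sum(axis=1) == 1
    counts[np.arange(len(best))[unique], best[unique]] = 1
    indicator = QuartetTable(table.taxa, counts, k=1)
    if clusters is None:
        clusters = M.build_constraint_set(gene_trees)
    tree, _ = M.mqsst_constrained_dp(indicator, clusters)
    return tree, "dominant-dp-fallback"


def estimate_species_tree(
    method: str,
    gene_trees: Sequence[PhyloTree],
    table: QuartetTable | None = None,
    seed: int = 0,
) -> PhyloTree:
    """Run one named estimator on a set of gene trees."""
    if method == "njst":
        return M.njst(gene_trees)
    if table is None:
        table = build_quartet_table(gene_trees)
    if method == "dp":
        clusters = M.build_constraint_set(gene_trees)
        tree, _ = M.mqsst_constrained_dp(table, clusters)
        return tree
    if method == "wqmc":
        return M.wqmc_style(table, seed=seed)
    if method == "dominant":
        tree, _ = dominant_quartet_estimate(table, gene_trees)
        return tree
    if method == "exact":
        tree, _ = M.mqsst_exact(table)
        return tree
    raise ValueError(f"unknown method {method!r}")


def run_experiment(
    config: ExperimentConfig, out_dir=None
) -> ExperimentResult:
    """Full factorial sweep: replicates x conditions x gene counts x methods.

    Seeded and resumable: per-row substreams are keyed by counters, rows
    already present in ``out_dir/results.tsv`` are skipped, and method
    failures are recorded per row without aborting the sweep.
    """
    rates = config.rates()
    done: set[tuple] = set()
    old_rows: list[dict] = []
    out_path = Path(out_dir) / "results.tsv" if out_dir is not None else None
    if out_path is not None and out_path.exists():
        prev = pd.read_csv(out_path, sep="\t")
        old_rows = prev.to_dict("records")
        done = {(r["replicate"], r["condition"], r["n_genes"], r["method"])
                for r in old_rows}

    rows: list[dict] = list(old_rows)
    species_trees: dict[int, PhyloTree] = {}
    for rep in range(config.n_replicates):
        species = simulate_species_tree(
            config.sim, rng_for(config.seed, STAGE_SPECIES, rep))
        species_trees[rep] = species
        pop = sample_pop_size(config.sim, rng_for(config.seed, STAGE_POP, rep))
        for ci, rate in enumerate(rates):
            needed = [
                (rep, ci, ng, m)
                for ng in config.gene_counts for m in config.methods
                if (rep, ci, ng, m) not in done]
            if not needed:
                continue
            n_loci = max(config.gene_counts)
            gene_trees: list[PhyloTree] = []
            for l in range(n_loci):
                lt = simulate_locus_tree(
                    species, rate, config.sim.recipient_bias,
                    rng_for(config.seed, STAGE_LOCUS, rep, ci, l))
                gt = simulate_gene_tree(
                    lt, pop, rng_for(config.seed, STAGE_GENE, rep, ci, l))
                if not config.use_true_gene_trees:
                    aln = simulate_alignment(
                        gt, config.sim,
                        rng_for(config.seed, STAGE_SEQ, rep, ci, l))
                    gt = estimate_gene_tree(aln)
                gene_trees.append(gt)
            discordance = gene_tree_discordance(species, gene_trees)
            for ng in config.gene_counts:
                genes = gene_trees[:ng]
                table = build_quartet_table(genes)
                for m in config.methods:
                    if (rep, ci, ng, m) in done:
                        continue
                    mseed = int(rng_for(
                        config.seed, STAGE_METHOD, rep, ci, ng
                    ).integers(2**31))
                    t0 = time.perf_counter()
                    try:
                        est = estimate_species_tree(m, genes, table, seed=mseed)
                        rf = rf_distance(est, species, normalized=True)
                        support = quartet_support(est, table)
                        status = "ok"
                    except Exception as exc:  # recorded, never aborts the sweep
                        est, rf, support = None, np.nan, np.nan
                        status = f"error: {exc}"
                    rows.append({
                        "replicate": rep,
                        "condition": ci,
                        "hgt_rate": rate,
                        "n_genes": ng,
                        "method": m,
                        "rf_error": rf,
                        "support": support,
                        "runtime_s": time.perf_counter() - t0,
                        "status": status,
                        "discordance": discordance,
                    })
            if out_path is not None:
                out_path.parent.mkdir(parents=True, exist_ok=True)
                pd.DataFrame(rows).to_csv(out_path, sep="\t", index=False)
    result = ExperimentResult(config, pd.DataFrame(rows), species_trees)
    if out_dir is not None:
        result.save(out_dir)
    return result


def aggregate(rows: pd.DataFrame) -> pd.DataFrame:
    """Mean RF error with standard errors per (condition, gene count, method).

    Standard error of the mean over replicates matches the error-bar
    convention of the usual benchmark figures; aggregates are always
    recomputable from the persisted per-replicate rows.
    """
    ok = rows[rows["status"] == "ok"]
    g = ok.groupby(["condition", "hgt_rate", "n_genes", "method"])["rf_error"]
    out = g.agg(
        mean_rf="mean",
        sem_rf=lambda x: float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0,
        n="size",
    ).reset_index()
    return out


@dataclass
class ScoreComparisonReport:
    """Quartet-score comparison of two methods over matched sweep rows."""

    method_a: str
    method_b: str
    n_cases: int
    frac_equal: float
    frac_a_better: float
    frac_b_better: float
    pairs: pd.DataFrame  # per-case score difference and RF-error difference

    def fractions(self) -> tuple[float, float, float]:
        return self.frac_equal, self.frac_a_better, self.frac_b_better


def score_comparison_report(
    rows: pd.DataFrame, method_a: str, method_b: str
) -> ScoreComparisonReport:
    """Fractions of matched cases with equal / a-better / b-better quartet
    support, plus per-case (score difference, RF-difference) pairs for the
    usual scatter diagnostic."""
    keys = ["replicate", "condition", "n_genes"]
    a = rows[(rows["method"] == method_a) & (rows["status"] == "ok")]
    b = rows[(rows["method"] == method_b) & (rows["status"] == "ok")]
    if a.empty or b.empty:
        raise ValueError("both methods must have successful rows")
    merged = a.merge(b, on=keys, suffixes=("_a", "_b"))
    diff = merged["support_a"] - merged["support_b"]
    rf_diff = merged["rf_error_a"] - merged["rf_error_b"]
    n = len(merged)
    pairs = pd.DataFrame({
        **{k: merged[k] for k in keys},
        "support_diff": diff,
        "rf_diff": rf_diff,
    })
    return ScoreComparisonReport(
        method_a, method_b, n,
        float((diff == 0).mean()),
        float((diff > 0).mean()),
        float((diff < 0).mean()),
        pairs,
    )
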