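#!/usr/bin/env python
"""Simulate the scaled benchmark datasets (12 taxa, six HGT conditions).

Per condition and replicate: one shared species tree, 200 locus trees with
replacing transfers, and 200 coalescent gene trees.  Conditions are defined
by expected transfers per gene {0, 0.08, 0.2, 0.8, 8, 20} (the transfer
rate is rescaled to the smaller tree).  Writes Newick trees and transfer
manifests under results/data/.
"""

import sys
from pathlib import Path

import pandas as pd

from hgtquartets.evaluation import (
    STAGE_GENE,
    STAGE_LOCUS,
    STAGE_SPECIES,
    rng_for,
)
from hgtquartets.simulate import (
    SimulationConfig,
    events_to_rate,
    simulate_gene_tree,
    simulate_locus_tree,
    simulate_species_tree,
)
from hgtquartets.trees import write_newick_file

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"
CFG = SimulationConfig(n_ingroup=11, n_loci=200)
EXPECTED_EVENTS = (0.0, 0.08, 0.2, 0.8, 8.0, 20.0)
N_REPLICATES = 5


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rates = [events_to_rate(e, CFG) if e else 0.0 for e in EXPECTED_EVENTS]
    for rep in range(N_REPLICATES):
        species = simulate_species_tree(CFG, rng_for(SEED, STAGE_SPECIES, rep))
        write_newick_file(OUT / f"rep{rep}.species.nwk", [species])
        for ci, rate in enumerate(rates):
            genes, events = [], []
            for l in range(CFG.n_loci):
                lt = simulate_locus_tree(
                    species, rate, CFG.recipient_bias,
                    rng_for(SEED, STAGE_LOCUS, rep, ci, l))
                genes.append(simulate_gene_tree(
                    lt, 200000.0, rng_for(SEED, STAGE_GENE, rep, ci, l)))
                for ev in lt.events:
                    events.append({"locus": l, "donor": "|".join(ev.donor),
                                   "recipient": "|".join(ev.recipient),
                                   "time": ev.time})
            write_newick_file(OUT / f"rep{rep}.cond{ci}.genes.nwk", genes)
            pd.DataFrame(events, columns=["locus", "donor", "recipient", "time"]
                         ).to_csv(OUT / f"rep{rep}.cond{ci}.transfers.tsv",
                                  sep="\t", index=False)
            print(f"rep {rep} condition {ci} ({EXPECTED_EVENTS[ci]} expected "
                  f"events/gene): {len(events)} transfers over {CFG.n_loci} loci")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
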