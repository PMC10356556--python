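#!/usr/bin/env python
"""Build the consensus interactome, call anchor-binding miRNAs, and test
per-miRNA enrichment of the consensus genes.

Finding on the planted study: every sponge miRNA is called on the anchor at
the 3-of-4 database threshold and is strongly enriched; decoy miRNAs show
no enrichment, and the consensus fraction rises with the shared-MRE count.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from cernet.consensus import consensus_pipeline
from cernet.enrichment import enrich_all_mirnas, enrichment_by_shared_sites, targetable_vs_nontargetable
from cernet.interactome import anchor_mirnas
from cernet.io_formats import FLOAT_FORMAT
from cernet.synthetic import SimulationConfig, simulate_study


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    study = simulate_study(SimulationConfig(seed=args.seed))
    sim, truth = study["interactome"], study["truth"]
    inter = sim.consensus(min_auxiliary=1)
    print(f"consensus interactome: {len(inter)} interactions over "
          f"{len(inter.universe)} genes ({len(sim.primary)} primary)")

    anchor_set = anchor_mirnas(inter, truth.anchor, min_databases=3)
    print(f"anchor-binding miRNAs (>=3 of 4 databases): {sorted(anchor_set)}")

    consensus = consensus_pipeline(study["datasets"])
    universe = set(consensus.table.index) & inter.universe
    cons = set(consensus.consensus_genes()) & universe
    results = enrich_all_mirnas(sorted(inter.mirnas), cons, inter, universe)
    df = pd.DataFrame(
        {
            "mirna": [r.mirna for r in results],
            "targetable": [r.mirna in anchor_set for r in results],
            "n_correlated_targets": [r.a for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "p": [r.p for r in results],
            "adjusted_p": [r.adjusted_p for r in results],
        }
    ).sort_values(["p", "mirna"])
    df.to_csv(args.outdir / "mirna_enrichment.tsv", sep="\t", index=False,
              float_format=FLOAT_FORMAT)

    cmp = targetable_vs_nontargetable(cons, inter, anchor_set, universe)
    med_t = np.median(cmp["targetable"]["odds_ratio"])
    med_nt = np.median(cmp["nontargetable"]["odds_ratio"])
    print(f"median enrichment OR: targetable {med_t}, non-targetable {med_nt}; "
          f"rank-sum p = {cmp['rank_sum_p']:.2e}")

    strata = enrichment_by_shared_sites(consensus, inter, truth.anchor)
    strata.to_csv(args.outdir / "shared_mre_strata.tsv", sep="\t", index=False,
                  float_format=FLOAT_FORMAT)
    occ = strata[strata["n_genes"] > 0]
    print("consensus fraction by shared-MRE stratum:",
          {int(r.stratum_low): round(r.consensus_fraction, 3) for r in occ.itertuples()})
    print(f"wrote {args.outdir}/mirna_enrichment.tsv and shared_mre_strata.tsv")


if __name__ == "__main__":
    main()
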