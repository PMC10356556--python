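#!/usr/bin/env python
"""3' UTR census of the simulated transcriptome: length and MRE-count
rankings, MRE density, and a six-frame ORF scan of a synthetic anchor UTR.

Finding on the planted study: the anchor's 14,575 nt UTR ranks first by
length and carries the most binding sites; a random synthetic UTR sequence
of that length yields dozens of short spurious ORFs across the six frames,
showing why candidate peptides need downstream proteomic support.
"""

import argparse
from pathlib import Path

import numpy as np

from cernet.io_formats import FLOAT_FORMAT
from cernet.synthetic import SimulationConfig, simulate_interactome
from cernet.utr import build_census, rank_table, six_frame_orf_scan


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cfg = SimulationConfig(seed=args.seed)
    sim = simulate_interactome(cfg)
    census = build_census(sim.utr_records, sim.primary)
    print(f"census: {len(census.table)} genes; median UTR {census.median_length:.0f} nt, "
          f"median MRE density {census.median_density:.1f} nt/site")

    by_len = rank_table(census, by="length", top_n=10)
    by_mre = rank_table(census, by="mre_count", top_n=10)
    by_len.to_csv(args.outdir / "utr_rank_length.tsv", sep="\t", index=False,
                  float_format=FLOAT_FORMAT)
    by_mre.to_csv(args.outdir / "utr_rank_mre.tsv", sep="\t", index=False,
                  float_format=FLOAT_FORMAT)
    anchor_row = by_len.iloc[0]
    print(f"longest UTR: {anchor_row.gene} at {int(anchor_row.utr_length)} nt (rank 1); "
          f"anchor ratio to median: {anchor_row.utr_length / census.median_length:.1f}x")

    # synthetic anchor-length UTR sequence for the ORF scan (random, labelled
    # synthetic: the generator carries lengths, not real nucleotide sequences)
    rng = np.random.default_rng(cfg.seed)
    seq = "".join(rng.choice(list("ACGT"), size=cfg.anchor_utr_length))
    orfs = six_frame_orf_scan(seq, min_length_aa=50)
    print(f"six-frame scan of a synthetic {len(seq)} nt UTR: "
          f"{len(orfs)} ORFs of >= 50 aa "
          f"(longest {max((o.length_aa for o in orfs), default=0)} aa)")
    print(f"wrote {args.outdir}/utr_rank_length.tsv and utr_rank_mre.tsv")


if __name__ == "__main__":
    main()
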