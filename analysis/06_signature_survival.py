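#!/usr/bin/env python
"""Score tumors by the ceRNA-network gene signature, split at the median,
and quantify outcome association.

Finding on the planted study: with a simulated hazard of exp(0.7 z), the
high-score group shows clearly elevated cumulative hazard (log-rank p well
below 0.05) and the Cox fit recovers the generative log hazard ratio.
"""

import argparse
import math
from pathlib import Path

import pandas as pd

from cernet.consensus import consensus_pipeline
from cernet.io_formats import FLOAT_FORMAT, write_survival_table
from cernet.survival import cox_fit, km_cumhaz, signature_zscore, stratify_median
from cernet.synthetic import SimulationConfig, simulate_study, simulate_survival


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cfg = SimulationConfig(seed=args.seed)
    study = simulate_study(cfg)
    consensus = consensus_pipeline(study["datasets"])
    signature = consensus.consensus_genes()
    print(f"signature: {len(signature)} consensus network genes")

    scores = signature_zscore(study["datasets"][0], signature, "ceRNA network")
    surv = simulate_survival(cfg, scores.scores)
    write_survival_table(surv, args.outdir / "survival.tsv")

    groups = stratify_median(scores.scores)
    km = km_cumhaz(groups, surv)
    high_end = km["curves"]["high"]["cumhaz"].iloc[-1] if len(km["curves"]["high"]) else 0
    low_end = km["curves"]["low"]["cumhaz"].iloc[-1] if len(km["curves"]["low"]) else 0
    sizes = {k: int(v) for k, v in groups.value_counts().items()}
    print(f"groups: {sizes}; events {surv.n_events}/{len(surv)}")
    print(f"cumulative hazard at end of follow-up: high {high_end:.2f}, low {low_end:.2f}")
    print(f"log-rank p = {km['logrank_p']:.3g}")

    uni = cox_fit(surv, pd.DataFrame({"signature_z": scores.scores}), "univariable")[0]
    print(f"Cox (univariable): HR {uni.hr:.3f} "
          f"[{uni.ci_low:.3f}, {uni.ci_high:.3f}], p = {uni.p:.3g}; "
          f"log HR {math.log(uni.hr):.3f} vs generative 0.7")

    rows = [
        {"variable": uni.variable, "hr": uni.hr, "ci_low": uni.ci_low,
         "ci_high": uni.ci_high, "p": uni.p, "model": uni.model}
    ]
    pd.DataFrame(rows).to_csv(args.outdir / "hazards.tsv", sep="\t", index=False,
                              float_format=FLOAT_FORMAT)
    print(f"wrote {args.outdir}/survival.tsv and hazards.tsv")


if __name__ == "__main__":
    main()
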