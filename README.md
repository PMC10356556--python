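# cernet — anchor-centered ceRNA network inference

`cernet` infers a competing-endogenous-RNA (ceRNA) network around a single
*anchor* transcript — a long-3′-UTR mRNA (the motivating case is ONECUT2 in
prostate cancer, with a 14,575 nt 3′ UTR carrying dozens of microRNA
response elements) suspected of sponging miRNAs away from the other
transcripts that share its binding sites. It is written for computational
biologists who want to run, test or extend this style of analysis on
expression cohorts plus a miRNA-target database, and to validate every
stage on synthetic data with known planted structure.

## The method

Given K expression cohorts (genes × samples, log scale) and an anchor gene
A, the pipeline:

1. **Correlation consensus.** Per cohort, computes Spearman's ρ and p
   between A and every gene; genes with ρ > 0.25 and p < 0.05 are
   per-cohort hits, and genes hit in ≥ 4 cohorts form the consensus set.
   Each consensus gene i gets a combined correlation score over its
   N_i detecting cohorts,

       CCS_i = Σ_{n=1..N_i} ρ_{i,n} / N_i ,

   reported together with N_i (an unnormalized Σρ mode is available).
2. **Consensus interactome.** Site-count predictions (TargetScan-style
   "summary counts" dialect) are kept only when supported by ≥ 1 of the
   auxiliary binary databases; miRNAs binding the anchor are called by a
   3-of-4 database vote; shared-MRE statistics count shared miRNA families
   (or summed shared sites).
3. **Enrichment.** For each miRNA, a one-sided Fisher exact test of the
   consensus genes within its target set over the measured∩annotated gene
   universe: p = P(X ≥ a) for X hypergeometric, computed in exact rational
   arithmetic on small universes.
4. **Network assembly.** The top-5 significantly enriched anchor-binding
   miRNAs, their consensus-gene targets and the anchor become nodes; edges
   carry binding-site counts; nodes carry CCS and 3′ UTR length. Exported
   as GraphML / SIF / node-link JSON, with a user-supplied category filter.
5. **UTR census.** Per-gene longest-variant 3′ UTR length, total MRE
   count, MRE density (nt per site), rank tables, and a six-frame
   ATG-to-stop ORF scanner.
6. **Survival.** Samples scored by the mean per-gene z-score of a
   signature, split at the median, compared by Nelson–Aalen cumulative
   hazard (Σ d_j/n_j) + log-rank, with hazard ratios from Cox regression
   (Efron ties).

A seeded synthetic-study generator plants all of this structure — a
latent-activity repression model in which partner genes share sponge
miRNAs with the anchor and are therefore positively co-expressed with it —
so every stage is testable end-to-end without any external download. See
`docs/methods.md` for the model and the parameter choices.

## Worked example

Run the numbered analysis drivers (each is a thin script over the library;
all accept `--seed` and `--outdir`):

```bash
python analysis/01_simulate_study.py --seed 1 --outdir results/study
python analysis/02_consensus_correlation.py --seed 1
python analysis/03_interactome_enrichment.py --seed 1
python analysis/04_assemble_network.py --seed 1
python analysis/05_utr_census.py --seed 1
python analysis/06_signature_survival.py --seed 1
```

At seed 1 the drivers print, among other lines:

```
cohort DS1: median planted anchor-partner Spearman rho = 0.448
consensus set: 50 genes; precision 1.000, recall 1.000
anchor-binding miRNAs (>=3 of 4 databases): ['miR-S1', 'miR-S2', 'miR-S3', 'miR-S4', 'miR-S5']
median enrichment OR: targetable inf, non-targetable 0.0; rank-sum p = 6.17e-07
network: 56 nodes (50 genes, 5 miRNAs), 232 edges; 50/50 gene nodes are planted partners
longest UTR: ONECUT2 at 14575 nt (rank 1); anchor ratio to median: 5.4x
Cox (univariable): HR 2.008 [1.528, 2.638], p = 5.61e-07; log HR 0.697 vs generative 0.7
```

Reading: the consensus detector recovers exactly the 50 planted ceRNA
partners; the five planted sponge miRNA families are called on the anchor
and are the only enriched target sets; the assembled network is
1 anchor + 5 miRNAs + 50 partners; and the survival stage recovers the
generative log hazard ratio (0.697 vs 0.7) of the signature score.

The same pipeline runs as one command over a YAML config:

```bash
cernet all --seed 1 --out results/run
```

which writes the cohort matrices, consensus table, enrichment table,
network files, UTR census and hazard table plus a `manifest.json`
recording every threshold; reruns with the same seed are byte-identical.

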