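# Methods

## Problem setting

A competing endogenous RNA (ceRNA) hypothesis around an anchor transcript
makes one statistical prediction: transcripts that share microRNA response
elements (MREs) with a highly expressed, MRE-rich anchor should be
*positively* co-expressed with it across tumors, because the anchor
titrates their common miRNAs. `cernet` operationalizes that prediction as
a multi-cohort correlation consensus plus target-set enrichment, and ships
a generator that plants exactly this structure so the whole chain can be
validated quantitatively.

## Correlation consensus

Per cohort, Spearman's ρ between the anchor and every gene is computed on
pairwise-complete observations with average ranks for ties. P-values use
the t approximation t = ρ√((n−2)/(1−ρ²)) for n > 10 pairs and exact
enumeration of the permutation null for n ≤ 10 (permuting one rank vector;
the rank multiset is permutation-invariant, so ties are handled
correctly). Genes require ≥ 3 complete pairs; a zero-variance anchor is an
error.

Detection is strict on both gates (ρ > 0.25 AND p < 0.05), positives only:
negative correlates are never candidates under the sponging model.
Consensus requires detection in ≥ 4 cohorts (defaults; both thresholds and
the cohort minimum are parameters). No multiple-testing correction is
applied at the per-cohort step — replication across cohorts is the error
control — but a Benjamini–Hochberg column is computed where p-values are
tabulated.

The combined correlation score of gene i is the mean of its per-cohort ρ
over the N_i detecting cohorts (so CCS ∈ (0.25, 1] by construction), with
N_i always reported alongside; a literal unnormalized sum mode is
selectable where a single score that grows with replication count is
preferred. Quartile variants (top/bottom anchor-expression quartiles,
boundary ties included) and a single-cohort variant (ρ > 0.5 or 0.65 plus
≥ 5 shared MREs) cover the stricter constructions used on individual
cohorts.

## Interactome and enrichment

The site-count source (a TargetScan-6-style "summary counts" table —
gene, transcript, miRNA family, total and conserved site counts, UTR
length; column names remappable) provides per-pair binding-site counts;
auxiliary databases contribute only binary evidence. A primary interaction
survives when ≥ 1 auxiliary database supports it; duplicate pairs merge by
maximum site count with unioned sources. Anchor-binding miRNAs are called
by a k-of-n vote over the merged sources (default 3 of 4). "Shared MREs"
between two genes defaults to the number of shared miRNA families (the
unit the network draws edges in); a summed min-site-count mode is
available. MRE density is UTR length / total sites (nt per site), with
zero-site genes reported as missing rather than a division error.

Enrichment of the consensus set in a miRNA's targets is the one-sided
hypergeometric upper tail P(X ≥ a) over a universe of genes both measured
in enough cohorts and annotated in the interactome (the smallest set on
which both margins are defined; configurable). For universes up to 2000
genes the tail is summed in exact rational arithmetic (so closed-form
fixtures are reproduced to the last bit); larger universes use the
log-space survival function. The odds ratio (a·d)/(b·c) is descriptive:
degenerate cells yield inf/0/NaN flags rather than a Haldane correction,
keeping the exact p primary. Ranking keeps p < 0.05, orders by p with ties
broken by correlated-target count then label, and returns the top five by
default.

## Network and UTR census

The network has one anchor node, the top-k miRNA nodes, and the consensus
genes targeted by at least one top miRNA; edges are miRNA→gene and
miRNA→anchor with binding-site counts; gene nodes carry CCS and UTR
length. Anchor–partner edges are implied through shared miRNA nodes and
only materialized on request (weighted by shared-MRE count). Node and edge
insertion is sorted, so assembly and serialization are deterministic.
GraphML and node-link JSON round-trip all attributes exactly; SIF is the
conventional topology-only triple format and is write-only.

The census keeps each gene's longest UTR variant, sums its annotated
sites, and ranks descending with dense ranks and alphabetical tie-breaks.
The ORF scanner reports every maximal ATG-to-in-frame-stop reading frame
of a minimum peptide length in all six frames (both strands — the
convention of the standard six-frame translators, even where only the
sense strand is biological); codons containing N match neither start nor
stop, coordinates are 0-based half-open on the input strand, and stop-less
tails are excluded (complete coding units only).

## Survival

Signature scores are the mean of per-gene z-scores (population SD;
zero-variance genes excluded with a warning). The median split sends
boundary ties to the low-risk group, making stratification deterministic.
The cumulative hazard is the Nelson–Aalen estimator Σ d_j/n_j, computed
directly so increments equal d/n exactly even under ties (−log of the
Kaplan–Meier curve is the usual near-equivalent); group comparison is the
log-rank test and Cox proportional-hazards regression with Efron tie
handling (via lifelines), univariable or joint. Fewer than 10 events
triggers a warning; constant predictors and all-censored comparisons are
errors.

## Synthetic study generator

The generator produces the simplest process satisfying the method's
assumptions — and nothing stronger:

- **Interactome.** The anchor (14,575 nt UTR) carries sites for each of 5
  sponge miRNA families and none for the 20 decoy families. Each of 50
  partner genes shares 4–5 sponge families with the anchor; each of 950
  decoy genes is targeted by 1–3 decoy families only (an optional
  contamination rate lets sponge miRNAs leak onto decoys; default 0).
  Per-pair site counts are uniform on {4..8}. Planted interactions always
  carry enough auxiliary-database support to survive the consensus filter
  (anchor interactions carry all four databases); half the decoy
  interactions carry none and are filtered out, emulating database noise.
- **Expression.** Each miRNA family m has latent activity a_m ~ N(0,1) per
  sample; gene g obeys x_g = μ_g + δ_{d,g} − β·(Σ_m s_{g,m} a_m)/s̄ + ε
  with ε ~ N(0,1), s̄ the site-range midpoint (making β a per-site,
  scale-free repression strength), μ_g ~ N(8,2) and per-cohort offsets
  δ ~ N(0,0.5) as the only cohort heterogeneity. Genes sharing sponge
  miRNAs with the anchor are thereby positively correlated with it; decoys
  are uncorrelated in expectation. β = 0.4 was calibrated once, by direct
  measurement over seeds and cohorts, to put the median planted
  anchor–partner Spearman ρ at ≈ 0.40 — the regime the consensus detector
  is designed for. The 4–5-family sharing and the {4..8} site range keep
  per-partner coupling homogeneous, which is what makes the planted signal
  recoverable with both precision and recall ≥ 0.8 at ρ > 0.25; a wider
  design (1–5 families, sites {1..10}) leaves the weakest partners below
  the detection threshold by construction, which tests a different, harder
  regime than the one studied here.
- **Survival.** Event times are exponential with hazard
  λ_j = λ₀·exp(β_h z_j) (λ₀ = 0.02/month, β_h = 0.7), administratively
  censored at 120 months — closed forms for every survival-stage oracle.
- **Streams.** Interactome, expression and survival each draw from an rng
  derived from the master seed by a fixed offset, so regenerating one
  artifact never perturbs the others; a fixed (config, seed) pair
  determines every output byte.

**What the generator does not emulate:** measurement platform effects
(probe saturation, batch structure beyond mean shifts), mRNA-level
mass-action titration kinetics (couplings are linear-Gaussian, not
kinetic), correlated miRNA activities, non-exponential hazards, and
informative censoring. Passing tests therefore demonstrate that the
inference chain is correct under its own model assumptions and recovers
planted structure at realistic effect sizes — not that those assumptions
hold in any particular tumor cohort.

## Numerical choices and degenerate inputs

- Spearman exact p uses cached permutation arrays per n (n ≤ 10); the
  observed |ρ| is compared with a 1e−12 slack so boundary permutations are
  counted.
- Thresholds are strict inequalities exactly as specified by the
  correlation gates; quartile boundaries include ties (deterministic, no
  random dropping).
- Duplicate expression rows collapse by maximum mean expression (the
  dominant probe-collapse convention); first/mean rules are selectable.
  Gene symbols compare case-insensitively after trimming.
- Missing expression cells are allowed and handled pairwise-complete, with
  the pair count n recorded per correlation record.
- Degenerate enrichment cells: empty target sets give a = 0, p = 1; the
  odds ratio reports 0/inf/NaN flags.
- Tables are written with `%.10g` floats and fixed column order, and the
  run manifest contains no timestamps, so identical config + seed yields
  byte-identical artifacts.

## Problem sizes

The reference study conditions are 6 cohorts × 200 samples × 1,001 genes
(50 partners, 950 decoys, 5 + 20 miRNA families). The validation suite
runs the full conditions for recovery, calibration and determinism checks,
10 seeds for the replicate-level enrichment and null-calibration
properties, 20 replicates of n = 2,000 for Cox recovery, and exhaustive
enumeration of all 2×2 tables with N ≤ 30 for the Fisher oracle. A
complete default run takes a few seconds on one CPU.

## Known limitations

- The SIF export cannot carry node/edge attributes; use GraphML or JSON
  when the network must round-trip.
- The exact Spearman permutation null is enumerated only to n = 10
  (10! permutations); beyond that the t approximation is standard but
  approximate in the extreme tails.
- Cox fitting inherits lifelines' behavior under separation (an error
  advising a different design rather than automatic penalization).
- The category filter expects externally supplied gene→category labels;
  no ontology service is bundled.
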