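"""Synthetic multi-cohort study generator with planted ceRNA structure.

The generator emulates exactly the statistical structure the inference
assumes, nothing stronger: a latent activity per miRNA, linear-Gaussian
repression proportional to binding-site counts, so that genes sharing
sponge miRNAs with the anchor are positively co-expressed with it while
decoy genes (targeted only by decoy miRNAs) are uncorrelated in
expectation. Survival times are exponential with a log-hazard linear in a
signature z-score, giving closed-form oracles for the survival stages.

Streams: the interactome, expression and survival artifacts each use an rng
derived from the master seed by a fixed offset, so regenerating one never
perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionDataset, Interaction, SurvivalTable, UtrRecord
from .interactome import Interactome, consensus_filter

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedInteractome",
    "simulate_interactome",
    "simulate_expression",
    "simulate_survival",
    "simulate_study",
]

PRIMARY_DB = "sitecountdb"
AUX_DBS = ("auxdb1", "auxdb2", "auxdb3")

_STREAM_INTERACTOME = 11
_STREAM_EXPRESSION = 22
_STREAM_SURVIVAL = 33


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the planted-structure simulation.

    Defaults are the reference conditions used throughout the test suite:
    six cohorts of 200 tumors, 50 planted partners among 950 decoys, 5
    sponge and 20 decoy miRNA families, with the repression coupling set so
    the median planted anchor-partner Spearman rho is ~0.4.
    """

    seed: int = 0
    n_datasets: int = 6
    n_samples: int = 200
    n_partners: int = 50
    n_decoys: int = 950
    n_sponge_mirnas: int = 5
    n_decoy_mirnas: int = 20
    coupling: float = 0.4            # repression strength per (scaled) site
    noise_sd: float = 1.0
    anchor: str = "ONECUT2"
    anchor_utr_length: int = 14575
    site_count_range: tuple[int, int] = (4, 8)
    min_shared_per_partner: int = 4  # sponge families shared with the anchor
    mirnas_per_decoy_range: tuple[int, int] = (1, 3)
    contamination_rate: float = 0.0  # P(sponge miRNA also hits a decoy gene)
    partner_aux_support_p: float = 0.7   # per-aux-DB support of planted pairs
    decoy_aux_support_rate: float = 0.5  # fraction of decoy pairs with any aux
    hazard_beta: float = 0.7         # log-hazard per signature-score unit
    baseline_hazard: float = 0.02    # events per month
    censor_time: float = 120.0       # months of administrative follow-up
    cohort_shift_sd: float = 0.5     # per-cohort per-gene mean offsets
    baseline_mean: float = 8.0       # log2-scale expression baseline
    baseline_sd: float = 2.0
    decoy_utr_range: tuple[int, int] = (200, 5000)

    def __post_init__(self) -> None:
        counts = (
            self.n_datasets, self.n_samples, self.n_partners, self.n_decoys,
            self.n_sponge_mirnas, self.n_decoy_mirnas,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if min(self.coupling, self.noise_sd, self.baseline_hazard) < 0:
            raise ValueError("coupling, noise_sd and baseline_hazard must be >= 0")
        if self.site_count_range[0] < 1:
            raise ValueError("site_count_range lower bound must be >= 1")
        if self.site_count_range[0] > self.site_count_range[1]:
            raise ValueError("empty site_count_range")
        if not 0 <= self.min_shared_per_partner <= max(self.n_sponge_mirnas, 1):
            raise ValueError("min_shared_per_partner must lie in [0, n_sponge_mirnas]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), stream])

    @property
    def partner_genes(self) -> list[str]:
        return [f"PTNR{i:04d}" for i in range(1, self.n_partners + 1)]

    @property
    def decoy_genes(self) -> list[str]:
        return [f"DCOY{i:04d}" for i in range(1, self.n_decoys + 1)]

    @property
    def sponge_mirnas(self) -> list[str]:
        return [f"miR-S{i}" for i in range(1, self.n_sponge_mirnas + 1)]

    @property
    def decoy_mirnas(self) -> list[str]:
        return [f"miR-D{i:02d}" for i in range(1, self.n_decoy_mirnas + 1)]

    @property
    def all_genes(self) -> list[str]:
        return [self.anchor] + self.partner_genes + self.decoy_genes


@dataclass
class GroundTruth:
    """What was planted: the recovery targets for every downstream stage."""

    anchor: str
    partner_genes: set[str]
    decoy_genes: set[str]
    sponge_mirnas: set[str]
    decoy_mirnas: set[str]
    site_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    hazard_beta: float = 0.0


@dataclass
class SimulatedInteractome:
    """Primary (site-count) interactions, auxiliary binary predictions, UTRs."""

    primary: list[Interaction]
    auxiliary: dict[str, set[tuple[str, str]]]
    utr_records: list[UtrRecord]
    truth: GroundTruth

    def consensus(self, min_auxiliary: int = 1) -> Interactome:
        return consensus_filter(self.primary, self.auxiliary, min_auxiliary=min_auxiliary)


def simulate_interactome(config: SimulationConfig) -> SimulatedInteractome:
    """Plant the miRNA-target structure.

    The anchor carries sites for every sponge miRNA (none for decoy miRNAs);
    each partner shares ``min_shared_per_partner``..all sponge families with
    the anchor; decoy genes receive sites only from decoy miRNAs, except for
    an optional contamination rate of sponge->decoy interactions. Planted
    interactions always satisfy the auxiliary-database consensus rule;
    anchor interactions are supported by every database.
    """
    rng = config.rng(_STREAM_INTERACTOME)
    lo, hi = config.site_count_range

    def draw_sites() -> int:
        return int(rng.integers(lo, hi + 1))

    site_counts: dict[tuple[str, str], int] = {}
    aux: dict[str, set[tuple[str, str]]] = {db: set() for db in AUX_DBS}
    primary: list[Interaction] = []

    def add(mirna: str, gene: str, support: str) -> None:
        total = draw_sites()
        site_counts[(mirna, gene)] = total
        conserved = int(rng.integers(0, total + 1))
        primary.append(
            Interaction(mirna=mirna, gene=gene, total_sites=total,
                        conserved_sites=conserved, sources={PRIMARY_DB})
        )
        pair = (mirna, gene.upper())
        if support == "full":
            for db in AUX_DBS:
                aux[db].add(pair)
        elif support == "planted":
            hits = [db for db in AUX_DBS if rng.random() < config.partner_aux_support_p]
            if not hits:
                hits = [AUX_DBS[int(rng.integers(len(AUX_DBS)))]]
            for db in hits:
                aux[db].add(pair)
        elif support == "decoy":
            if rng.random() < config.decoy_aux_support_rate:
                aux[AUX_DBS[int(rng.integers(len(AUX_DBS)))]].add(pair)

    for m in config.sponge_mirnas:
        add(m, config.anchor, "full")
    for gene in config.partner_genes:
        n_shared = int(rng.integers(config.min_shared_per_partner,
                                    config.n_sponge_mirnas + 1))
        n_shared = max(n_shared, 1)
        shared = rng.choice(config.sponge_mirnas, size=n_shared, replace=False)
        for m in sorted(shared):
            add(m, gene, "planted")
    d_lo, d_hi = config.mirnas_per_decoy_range
    for gene in config.decoy_genes:
        k = int(rng.integers(d_lo, d_hi + 1)) if config.n_decoy_mirnas else 0
        k = min(k, config.n_decoy_mirnas)
        if k:
            chosen = rng.choice(config.decoy_mirnas, size=k, replace=False)
            for m in sorted(chosen):
                add(m, gene, "decoy")
        if config.contamination_rate > 0:
            for m in config.sponge_mirnas:
                if rng.random() < config.contamination_rate:
                    add(m, gene, "decoy")

    utr_lo, utr_hi = config.decoy_utr_range
    utr_records = [
        UtrRecord(gene=config.anchor, utr_length=config.anchor_utr_length,
                  transcript_id=f"tx_{config.anchor}")
    ]
    for gene in config.partner_genes + config.decoy_genes:
        utr_records.append(
            UtrRecord(gene=gene, utr_length=int(rng.integers(utr_lo, utr_hi + 1)),
                      transcript_id=f"tx_{gene}")
        )

    truth = GroundTruth(
        anchor=config.anchor,
        partner_genes=set(g.upper() for g in config.partner_genes),
        decoy_genes=set(g.upper() for g in config.decoy_genes),
        sponge_mirnas=set(config.sponge_mirnas),
        decoy_mirnas=set(config.decoy_mirnas),
        site_counts=site_counts,
        hazard_beta=config.hazard_beta,
    )
    return SimulatedInteractome(primary=primary, auxiliary=aux,
                                utr_records=utr_records, truth=truth)


def simulate_expression(
    config: SimulationConfig, sim: SimulatedInteractome
) -> list[ExpressionDataset]:
    """Latent-factor expression for every cohort.

    Per sample, each miRNA has activity a_m ~ N(0,1) and each gene g obeys
    x_g = mu_g + delta_{d,g} - coupling * sum_m (s_{g,m}/s_bar) a_m + eps,
    eps ~ N(0, noise_sd), with s_bar the midpoint of the site-count range so
    the per-site coupling is scale-free. Cohort heterogeneity enters only
    through the per-cohort mean offsets delta_{d,g}.
    """
    rng = config.rng(_STREAM_EXPRESSION)
    genes = config.all_genes
    mirnas = config.sponge_mirnas + config.decoy_mirnas
    gene_idx = {g: i for i, g in enumerate(genes)}
    mirna_idx = {m: j for j, m in enumerate(mirnas)}
    S = np.zeros((len(genes), len(mirnas)))
    for (m, g), s in sim.truth.site_counts.items():
        S[gene_idx[g], mirna_idx[m]] = s
    s_bar = 0.5 * (config.site_count_range[0] + config.site_count_range[1])
    loadings = config.coupling * S / s_bar

    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=len(genes))
    datasets = []
    for d in range(1, config.n_datasets + 1):
        delta = rng.normal(0.0, config.cohort_shift_sd, size=len(genes))
        activity = rng.normal(size=(len(mirnas), config.n_samples))
        noise = rng.normal(0.0, config.noise_sd, size=(len(genes), config.n_samples))
        X = (mu + delta)[:, None] - loadings @ activity + noise
        values = pd.DataFrame(
            X,
            index=pd.Index(genes, name="gene"),
            columns=[f"DS{d}_S{j:03d}" for j in range(1, config.n_samples + 1)],
        )
        datasets.append(
            ExpressionDataset(dataset_id=f"DS{d}", values=values, anchor=config.anchor)
        )
    return datasets


def simulate_survival(
    config: SimulationConfig, signature_scores: pd.Series
) -> SurvivalTable:
    """Exponential event times with hazard baseline*exp(beta*z), censored
    administratively at ``censor_time`` months."""
    rng = config.rng(_STREAM_SURVIVAL)
    z = signature_scores.to_numpy(dtype=float)
    rate = config.baseline_hazard * np.exp(config.hazard_beta * z)
    with np.errstate(divide="ignore"):
        t_event = np.where(rate > 0, rng.exponential(1.0, size=len(z)) / np.maximum(rate, 1e-300), np.inf)
    time = np.minimum(t_event, config.censor_time)
    event = (t_event <= config.censor_time).astype(int)
    df = pd.DataFrame({"time": time, "event": event}, index=signature_scores.index)
    return SurvivalTable(data=df)


def simulate_study(config: SimulationConfig) -> dict:
    """Interactome + expression in one call (survival needs scores first)."""
    sim = simulate_interactome(config)
    datasets = simulate_expression(config, sim)
    return {"interactome": sim, "datasets": datasets, "truth": sim.truth}
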