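"""Consensus miRNA-target interactome and shared-MRE statistics.

The site-count source (a TargetScan-style summary) provides per-pair binding
site counts; auxiliary databases contribute only binary supported/unsupported
evidence. A primary interaction enters the consensus interactome when enough
auxiliary databases agree, and anchor-binding miRNAs are called by a k-of-n
database vote.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .datatypes import Interaction, UtrRecord, normalize_symbol

__all__ = [
    "Interactome",
    "build_interactome",
    "consensus_filter",
    "anchor_mirnas",
    "shared_mre_count",
    "mre_density",
]


@dataclass
class Interactome:
    """Interactions indexed by miRNA and by gene; duplicates merged."""

    interactions: list[Interaction] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.by_mirna: dict[str, list[Interaction]] = {}
        self.by_gene: dict[str, list[Interaction]] = {}
        seen: dict[tuple[str, str], int] = {}
        merged: list[Interaction] = []
        for inter in self.interactions:
            key = (inter.mirna, inter.gene)
            if key in seen:
                old = merged[seen[key]]
                # multiple sources for the same pair: keep max site counts,
                # union the evidence
                merged[seen[key]] = Interaction(
                    mirna=inter.mirna,
                    gene=inter.gene,
                    total_sites=max(old.total_sites, inter.total_sites),
                    conserved_sites=max(old.conserved_sites, inter.conserved_sites),
                    sources=old.sources | inter.sources,
                )
            else:
                seen[key] = len(merged)
                merged.append(inter)
        self.interactions = merged
        for inter in merged:
            self.by_mirna.setdefault(inter.mirna, []).append(inter)
            self.by_gene.setdefault(inter.gene, []).append(inter)

    @property
    def universe(self) -> set[str]:
        return set(self.by_gene)

    @property
    def mirnas(self) -> set[str]:
        return set(self.by_mirna)

    def get(self, mirna: str, gene: str) -> Interaction | None:
        gene = normalize_symbol(gene)
        for inter in self.by_mirna.get(mirna, []):
            if inter.gene == gene:
                return inter
        return None

    def targets_of(self, mirna: str) -> set[str]:
        return {inter.gene for inter in self.by_mirna.get(mirna, [])}

    def __len__(self) -> int:
        return len(self.interactions)


def build_interactome(interactions: Iterable[Interaction]) -> Interactome:
    return Interactome(interactions=list(interactions))


def consensus_filter(
    primary: Iterable[Interaction],
    auxiliary: Mapping[str, Iterable[tuple[str, str]]],
    min_auxiliary: int = 1,
) -> Interactome:
    """Keep primary interactions supported by >= ``min_auxiliary`` auxiliary DBs.

    ``auxiliary`` maps database label -> iterable of (mirna, gene) pairs it
    predicts. Merged sources record which databases supported each kept pair.
    Auxiliary entries with no matching primary interaction are ignored.
    """
    aux_sets = {
        db: {(m, normalize_symbol(g)) for m, g in pairs} for db, pairs in auxiliary.items()
    }
    kept: list[Interaction] = []
    for inter in primary:
        support = {db for db, pairs in aux_sets.items() if (inter.mirna, inter.gene) in pairs}
        if len(support) >= min_auxiliary:
            kept.append(
                Interaction(
                    mirna=inter.mirna,
                    gene=inter.gene,
                    total_sites=inter.total_sites,
                    conserved_sites=inter.conserved_sites,
                    sources=inter.sources | support,
                )
            )
    return Interactome(interactions=kept)


def anchor_mirnas(interactome: Interactome, anchor: str, min_databases: int = 3) -> set[str]:
    """miRNAs predicted to bind the anchor by >= ``min_databases`` databases.

    The count is over the merged ``sources`` of the anchor interaction
    (k-of-n consensus; the paper-style default is 3 of 4).
    """
    anchor = normalize_symbol(anchor)
    if anchor not in interactome.universe:
        raise KeyError(f"anchor {anchor!r} absent from interactome universe")
    return {
        inter.mirna
        for inter in interactome.by_gene[anchor]
        if len(inter.sources) >= min_databases
    }


def shared_mre_count(
    interactome: Interactome, anchor: str, gene: str, mode: str = "families"
) -> int:
    """MRE sharing between two genes.

    ``families``: number of distinct miRNAs targeting both. ``sites``: sum
    over shared miRNAs of min(site count on each gene). Symmetric in the two
    gene arguments; genes without any annotation contribute 0.
    """
    if mode not in ("families", "sites"):
        raise ValueError(f"unknown mode {mode!r}; use 'families' or 'sites'")
    a, g = normalize_symbol(anchor), normalize_symbol(gene)
    sites_a = {i.mirna: i.total_sites for i in interactome.by_gene.get(a, [])}
    sites_g = {i.mirna: i.total_sites for i in interactome.by_gene.get(g, [])}
    shared = sites_a.keys() & sites_g.keys()
    if mode == "families":
        return len(shared)
    return sum(min(sites_a[m], sites_g[m]) for m in shared)


def mre_density(utr: UtrRecord, total_sites: int) -> float:
    """Nucleotides of 3' UTR per binding site; NaN when the gene has no sites."""
    if total_sites < 0:
        raise ValueError("total_sites must be >= 0")
    if total_sites == 0:
        return math.nan
    return utr.utr_length / total_sites
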