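"""Genome-scale 3' UTR census and six-frame ORF scanning.

The census keeps one row per gene (the longest UTR variant), sums that
gene's annotated binding sites into a total MRE count, and derives the MRE
density (nucleotides per site). Rank tables sort descending with dense ranks
and alphabetical tie-breaks. The ORF scanner reports every maximal
ATG-to-stop open reading frame of a minimum peptide length in all six
frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .datatypes import Interaction, UtrRecord
from .interactome import mre_density

__all__ = ["UtrCensus", "OrfCandidate", "build_census", "rank_table", "six_frame_orf_scan"]

_STOPS = set(standard_dna_table.stop_codons)  # {TAA, TAG, TGA}
_CODON_AA = dict(standard_dna_table.forward_table)


@dataclass
class UtrCensus:
    """Per-gene UTR length / MRE count / density table plus length histogram."""

    table: pd.DataFrame  # index gene; columns utr_length, mre_count, mre_density
    median_length: float
    median_density: float

    def histogram(self, n_bins: int = 30) -> pd.DataFrame:
        """Logarithmic length histogram (the distribution spans ~4 decades)."""
        lengths = self.table["utr_length"].to_numpy(dtype=float)
        edges = np.logspace(0, math.log10(max(lengths.max(), 10)), n_bins + 1)
        counts, edges = np.histogram(lengths, bins=edges)
        return pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts})


@dataclass(frozen=True)
class OrfCandidate:
    """A maximal ATG..stop ORF; coordinates are 0-based half-open on the
    input strand, frame 1-3 forward, 4-6 on the reverse complement."""

    frame: int
    start: int
    end: int
    length_aa: int
    peptide: str


def build_census(
    utr_records: Iterable[UtrRecord], interactions: Iterable[Interaction]
) -> UtrCensus:
    """One row per gene: longest UTR variant, summed MRE count, density."""
    longest: dict[str, int] = {}
    for rec in utr_records:
        longest[rec.gene] = max(rec.utr_length, longest.get(rec.gene, 0))
    sites: dict[str, int] = {}
    for inter in interactions:
        if inter.gene in longest:
            sites[inter.gene] = sites.get(inter.gene, 0) + inter.total_sites
    genes = sorted(longest)
    table = pd.DataFrame(
        {
            "utr_length": [longest[g] for g in genes],
            "mre_count": [sites.get(g, 0) for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    table["mre_density"] = [
        mre_density(UtrRecord(gene=g, utr_length=longest[g]), sites.get(g, 0))
        for g in genes
    ]
    dens = table["mre_density"].dropna()
    return UtrCensus(
        table=table,
        median_length=float(table["utr_length"].median()) if len(table) else math.nan,
        median_density=float(dens.median()) if len(dens) else math.nan,
    )


def rank_table(census: UtrCensus, by: str = "length", top_n: int | None = None) -> pd.DataFrame:
    """Descending rank table by length, MRE count, or density.

    Dense ranks (equal values share a rank, next value gets rank+1); within a
    rank, rows are ordered alphabetically by gene.
    """
    keys = {"length": "utr_length", "mre_count": "mre_count", "density": "mre_density"}
    if by not in keys:
        raise ValueError(f"unknown sort key {by!r}; choose from {sorted(keys)}")
    col = keys[by]
    tab = census.table.dropna(subset=[col]).reset_index()
    tab = tab.sort_values([col, "gene"], ascending=[False, True], kind="stable")
    tab["rank"] = tab[col].rank(method="dense", ascending=False).astype(int)
    if top_n is not None:
        tab = tab.head(top_n)
    return tab.reset_index(drop=True)


def _scan_strand(seq: str, min_length_aa: int, frames: tuple[int, ...]) -> list[tuple[int, int, int, str]]:
    """Maximal ORFs on one strand: per in-frame stop, the earliest ATG after
    the previous stop. Codons containing N match neither start nor stop."""
    out = []
    L = len(seq)
    for offset, frame in zip((0, 1, 2), frames):
        start: int | None = None
        for pos in range(offset, L - 2, 3):
            codon = seq[pos : pos + 3]
            if start is None and codon == "ATG":
                start = pos
            elif start is not None and codon in _STOPS:
                aa = (pos - start) // 3
                if aa >= min_length_aa:
                    pep = "".join(
                        _CODON_AA.get(seq[i : i + 3], "X") for i in range(start, pos, 3)
                    )
                    out.append((frame, start, pos, pep))
                start = None
    return out


def six_frame_orf_scan(sequence: str, min_length_aa: int = 1) -> list[OrfCandidate]:
    """All maximal ATG..stop ORFs of >= ``min_length_aa`` residues, six frames.

    Frames 1-3 read the input; frames 4-6 read its reverse complement.
    Coordinates are reported on the input strand (0-based half-open span of
    the ORF codons, stop excluded); for reverse frames the in-frame stop lies
    immediately 5' of ``start`` on the input strand.
    """
    seq = str(sequence).upper().replace("U", "T")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"unexpected characters in sequence: {sorted(bad)}")
    L = len(seq)
    candidates: list[OrfCandidate] = []
    for frame, s0, e0, pep in _scan_strand(seq, min_length_aa, (1, 2, 3)):
        candidates.append(
            OrfCandidate(frame=frame, start=s0, end=e0, length_aa=len(pep), peptide=pep)
        )
    rc = str(Seq(seq).reverse_complement())
    for frame, s0, e0, pep in _scan_strand(rc, min_length_aa, (4, 5, 6)):
        candidates.append(
            OrfCandidate(
                frame=frame, start=L - e0, end=L - s0, length_aa=len(pep), peptide=pep
            )
        )
    candidates.sort(key=lambda c: (c.frame, c.start))
    return candidates
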