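"""Fisher-exact enrichment of anchor-correlated genes in miRNA target sets.

For each miRNA the 2x2 table (correlated x targeted) over a fixed gene
universe is tested one-sided for over-representation: the p-value is the
hypergeometric upper tail P(X >= a). Small universes go through exact
rational arithmetic so that closed-form cases are reproduced to the last
bit; large ones use scipy's log-space survival function.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import ConsensusTable
from .interactome import Interactome, shared_mre_count

__all__ = [
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "fisher_enrichment",
    "rank_mirnas",
    "targetable_vs_nontargetable",
    "enrichment_by_shared_sites",
    "benjamini_hochberg",
]

_EXACT_N_MAX = 2000


@dataclass(frozen=True)
class EnrichmentResult:
    """One miRNA's 2x2 enrichment table and test results.

    a = correlated & targeted, b = correlated only, c = targeted only,
    d = neither; odds_ratio = (a*d)/(b*c) with inf/0 flags for degenerate
    cells; p is the one-sided exact upper tail.
    """

    mirna: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    adjusted_p: float | None = None

    @property
    def n_correlated_targets(self) -> int:
        return self.a

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d


def hypergeom_upper_tail(a: int, N: int, K: int, n: int) -> float:
    """P(X >= a) for X ~ Hypergeom(N population, K successes, n draws).

    Exact rational arithmetic for N <= 2000, stable log-space tail beyond.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    lo = max(0, n + K - N)
    hi = min(n, K)
    if a <= lo:
        return 1.0
    if a > hi:
        return 0.0
    if N <= _EXACT_N_MAX:
        total = math.comb(N, n)
        acc = sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(a, hi + 1))
        return float(Fraction(acc, total))
    return float(stats.hypergeom.sf(a - 1, N, K, n))


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        if a * d == 0:
            return math.nan
        return math.inf
    return (a * d) / (b * c)


def fisher_enrichment(
    correlated: set[str],
    targets: set[str],
    universe: set[str],
    mirna: str = "",
) -> EnrichmentResult:
    """One-sided over-representation test of ``correlated`` within ``targets``."""
    if not universe:
        raise ValueError("empty universe")
    extra_c = correlated - universe
    extra_t = targets - universe
    if extra_c or extra_t:
        offenders = sorted(extra_c | extra_t)
        raise ValueError(f"sets not subsets of universe: {offenders[:5]}")
    a = len(correlated & targets)
    b = len(correlated - targets)
    c = len(targets - correlated)
    d = len(universe) - a - b - c
    p = hypergeom_upper_tail(a, N=len(universe), K=len(targets), n=len(correlated))
    # a <= min(|targets|, |correlated|) always, so the tail is never empty
    p = min(max(p, 5e-324), 1.0)
    return EnrichmentResult(
        mirna=mirna, a=a, b=b, c=c, d=d, odds_ratio=_odds_ratio(a, b, c, d), p=p
    )


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    return stats.false_discovery_control(np.asarray(pvalues, dtype=float), method="bh")


def rank_mirnas(
    results: Iterable[EnrichmentResult], k: int = 5, p_max: float = 0.05
) -> list[str]:
    """Top-k significantly enriched miRNAs.

    Keep p < ``p_max``; order by p ascending, break ties by the number of
    correlated targets (descending) then label. Fewer than k significant
    hits returns them all with a warning.
    """
    significant = [r for r in results if r.p < p_max]
    significant.sort(key=lambda r: (r.p, -r.n_correlated_targets, r.mirna))
    if len(significant) < k:
        warnings.warn(
            f"only {len(significant)} significant miRNAs available (requested {k})"
        )
    return [r.mirna for r in significant[:k]]


def enrich_all_mirnas(
    mirnas: Iterable[str],
    correlated: set[str],
    interactome: Interactome,
    universe: set[str],
    adjust: bool = True,
) -> list[EnrichmentResult]:
    """Enrichment test for each miRNA's target set, BH column included."""
    mirnas = sorted(mirnas)
    results = [
        fisher_enrichment(
            correlated & universe, interactome.targets_of(m) & universe, universe, mirna=m
        )
        for m in mirnas
    ]
    if adjust and results:
        adj = benjamini_hochberg([r.p for r in results])
        results = [
            EnrichmentResult(
                mirna=r.mirna, a=r.a, b=r.b, c=r.c, d=r.d,
                odds_ratio=r.odds_ratio, p=r.p, adjusted_p=float(q),
            )
            for r, q in zip(results, adj)
        ]
    return results


def targetable_vs_nontargetable(
    consensus_genes: set[str],
    interactome: Interactome,
    anchor_mirna_set: set[str],
    universe: set[str],
) -> dict:
    """Compare enrichment between anchor-targetable and non-targetable miRNAs.

    Returns per-group odds-ratio/p distributions plus a Mann-Whitney rank-sum
    comparison of the odds ratios (the ceRNA prediction: target sets of
    anchor-binding miRNAs are richer in anchor-correlated genes).
    """
    all_mirnas = sorted(interactome.mirnas)
    targetable = [m for m in all_mirnas if m in anchor_mirna_set]
    nontargetable = [m for m in all_mirnas if m not in anchor_mirna_set]

    def summarize(group: list[str]) -> pd.DataFrame:
        res = enrich_all_mirnas(group, consensus_genes, interactome, universe, adjust=False)
        return pd.DataFrame(
            {
                "mirna": [r.mirna for r in res],
                "odds_ratio": [r.odds_ratio for r in res],
                "p": [r.p for r in res],
                "n_correlated_targets": [r.n_correlated_targets for r in res],
            }
        )

    out: dict = {"targetable": None, "nontargetable": None, "rank_sum_p": math.nan,
                 "rank_sum_stat": math.nan}
    if targetable:
        out["targetable"] = summarize(targetable)
    if nontargetable:
        out["nontargetable"] = summarize(nontargetable)
    if not targetable or not nontargetable:
        warnings.warn("one miRNA partition is empty; no two-group comparison")
        return out
    if len(targetable) + len(nontargetable) < 3 or min(len(targetable), len(nontargetable)) < 1:
        return out
    x = out["targetable"]["odds_ratio"].to_numpy()
    y = out["nontargetable"]["odds_ratio"].to_numpy()
    # rank-based test tolerates infinite odds ratios (they just take top ranks)
    if len(x) >= 1 and len(y) >= 1 and len(x) + len(y) >= 3:
        stat, p = stats.mannwhitneyu(x, y, alternative="greater")
        out["rank_sum_stat"], out["rank_sum_p"] = float(stat), float(p)
    return out


def enrichment_by_shared_sites(
    consensus: ConsensusTable,
    interactome: Interactome,
    anchor: str,
    strata: Sequence[tuple[int, float]] | None = None,
    shared_mode: str = "families",
) -> pd.DataFrame:
    """Consensus fraction and mean CCS per shared-MRE-count stratum.

    ``strata`` is a list of (low, high] ... actually [low, high) bin bounds
    over the shared-MRE count; default: one bin per observed count value
    0,1,2,... Empty strata are reported with zero counts, not dropped.
    """
    genes = [g for g in consensus.table.index if g != anchor]
    shared = {
        g: shared_mre_count(interactome, anchor, g, mode=shared_mode) for g in genes
    }
    max_shared = max(shared.values(), default=0)
    if strata is None:
        strata = [(k, k + 1) for k in range(max_shared + 1)]
    is_consensus = consensus.table["consensus"]
    ccs = consensus.table["ccs"]
    rows = []
    for low, high in strata:
        members = [g for g in genes if low <= shared[g] < high]
        n = len(members)
        frac = float(np.mean([bool(is_consensus[g]) for g in members])) if n else 0.0
        in_cons = [g for g in members if is_consensus[g]]
        mean_ccs = float(np.mean([ccs[g] for g in in_cons])) if in_cons else math.nan
        rows.append(
            {
                "stratum_low": low,
                "stratum_high": high,
                "n_genes": n,
                "consensus_fraction": frac,
                "mean_ccs": mean_ccs,
            }
        )
    return pd.DataFrame(rows)
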