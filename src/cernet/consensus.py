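"""Anchor-correlation detection, multi-cohort consensus, and the combined
correlation score (CCS).

Per cohort, every gene is tested for Spearman correlation with the anchor;
genes passing ``rho > rho_min`` and ``p < p_max`` (strict on both sides) in
at least ``min_datasets`` cohorts form the consensus set. The CCS of a gene
summarizes its per-cohort rho values over the detecting cohorts — the mean
by default, with an unnormalized sum as an alternative reading.

Spearman p-values use the t approximation for n > 10 pairs and exact
enumeration of the permutation null for n <= 10, so small hand fixtures are
exact.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionDataset, normalize_symbol
from .interactome import Interactome, shared_mre_count

__all__ = [
    "ConsensusTable",
    "spearman_rho_p",
    "correlate_with_anchor",
    "detect_correlated",
    "build_consensus",
    "combined_correlation_score",
    "quartile_subset",
    "single_cohort_partners",
    "consensus_pipeline",
    "null_detection_rate",
    "null_consensus_bound",
]

_EXACT_N_MAX = 10
_perm_cache: dict[int, np.ndarray] = {}

_TINY = float(np.finfo(np.float64).tiny)


def _permutations(n: int) -> np.ndarray:
    if n not in _perm_cache:
        _perm_cache[n] = np.array(list(itertools.permutations(range(n))), dtype=np.int8)
    return _perm_cache[n]


def _exact_spearman_p(rank_x: np.ndarray, rank_y: np.ndarray, rho_obs: float) -> float:
    """Two-sided p from full enumeration of the permutation null.

    Permuting one variable's rank vector (the rank multiset is permutation
    invariant, ties included) and computing the Pearson correlation of ranks
    gives the exact null distribution of Spearman's rho.
    """
    n = len(rank_x)
    cx = rank_x - rank_x.mean()
    cy = rank_y - rank_y.mean()
    denom = np.sqrt((cx @ cx) * (cy @ cy))
    if denom == 0:
        return 1.0
    perms = _permutations(n)
    count = 0
    threshold = abs(rho_obs) - 1e-12
    for start in range(0, len(perms), 500_000):
        block = perms[start : start + 500_000]
        rhos = (cy[block] @ cx) / denom
        count += int(np.sum(np.abs(rhos) >= threshold))
    return count / len(perms)


def spearman_rho_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Spearman rho and two-sided p on pairwise-complete observations.

    Returns (rho, p, n_pairs). Ties get average ranks. Requires >= 3 complete
    pairs and a non-constant x after masking.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    rx = stats.rankdata(x[mask])
    ry = stats.rankdata(y[mask])
    cx = rx - rx.mean()
    cy = ry - ry.mean()
    denom = np.sqrt((cx @ cx) * (cy @ cy))
    if cx @ cx == 0:
        raise ValueError("anchor has zero variance: rho undefined")
    if denom == 0:
        return np.nan, 1.0, n
    rho = float((cx @ cy) / denom)
    rho = max(-1.0, min(1.0, rho))
    if n <= _EXACT_N_MAX:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        p = _t_approx_p(np.array([rho]), n)[0]
    return rho, float(min(max(p, _TINY), 1.0)), n


def _t_approx_p(rho: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.clip(p, _TINY, 1.0)


def correlate_with_anchor(dataset: ExpressionDataset) -> pd.DataFrame:
    """Spearman rho/p between the anchor and every other gene of one cohort.

    Returns a frame with columns gene, dataset_id, rho, p, n_pairs; genes with
    fewer than 3 complete pairs are omitted and listed in
    ``result.attrs["skipped_genes"]``. Complete matrices take a vectorized
    path (one rank transform, one matrix product).
    """
    anchor_vals = dataset.anchor_values().to_numpy(dtype=float)
    others = dataset.values.drop(index=dataset.anchor)
    genes = list(others.index)
    mat = others.to_numpy(dtype=float)
    n_samples = mat.shape[1]

    if np.var(anchor_vals[~np.isnan(anchor_vals)]) == 0:
        raise ValueError("anchor has zero variance: rho undefined for all genes")

    skipped: list[str] = []
    rows: list[tuple[str, float, float, int]] = []

    complete = not (np.isnan(mat).any() or np.isnan(anchor_vals).any())
    if complete and n_samples > _EXACT_N_MAX:
        ra = stats.rankdata(anchor_vals)
        rg = stats.rankdata(mat, axis=1)
        ca = ra - ra.mean()
        cg = rg - rg.mean(axis=1, keepdims=True)
        denom = np.sqrt((cg**2).sum(axis=1) * (ca @ ca))
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = (cg @ ca) / denom
        rho = np.clip(rho, -1.0, 1.0)
        p = _t_approx_p(rho, n_samples)
        constant = denom == 0
        rho = np.where(constant, np.nan, rho)
        p = np.where(constant, 1.0, p)
        for i, gene in enumerate(genes):
            rows.append((gene, float(rho[i]), float(p[i]), n_samples))
    else:
        for i, gene in enumerate(genes):
            try:
                rho, p, n = spearman_rho_p(anchor_vals, mat[i])
            except ValueError as exc:
                if "anchor" in str(exc):
                    raise
                skipped.append(gene)
                continue
            rows.append((gene, rho, p, n))

    out = pd.DataFrame(rows, columns=["gene", "rho", "p", "n_pairs"])
    out.insert(1, "dataset_id", dataset.dataset_id)
    out.attrs["skipped_genes"] = skipped
    return out


def detect_correlated(
    records: pd.DataFrame, rho_min: float = 0.25, p_max: float = 0.05
) -> set[str]:
    """Genes with rho strictly above ``rho_min`` and p strictly below ``p_max``.

    Negative correlations never pass (the threshold is on rho itself, not
    |rho|).
    """
    hit = (records["rho"] > rho_min) & (records["p"] < p_max)
    return set(records.loc[hit, "gene"])


def combined_correlation_score(
    rhos: Iterable[float], mode: str = "mean"
) -> float:
    """CCS over the detecting cohorts' rho values: their mean (default) or sum."""
    rhos = [r for r in rhos if r == r]
    if not rhos:
        return float("nan")
    if mode == "mean":
        return float(np.mean(rhos))
    if mode == "sum":
        return float(np.sum(rhos))
    raise ValueError(f"unknown CCS mode {mode!r}; use 'mean' or 'sum'")


@dataclass
class ConsensusTable:
    """Per-gene detection flags across cohorts, N detecting cohorts, and CCS.

    ``table`` is indexed by gene with one ``det:<id>`` / ``rho:<id>`` column
    pair per cohort plus ``n_detected``, ``ccs`` and the boolean
    ``consensus`` flag. All measured genes are retained (consensus or not)
    for downstream null comparisons.
    """

    table: pd.DataFrame
    min_datasets: int
    ccs_mode: str = "mean"
    dataset_ids: list[str] = field(default_factory=list)

    def consensus_genes(self) -> list[str]:
        return sorted(self.table.index[self.table["consensus"]])

    def ccs(self) -> pd.Series:
        return self.table["ccs"]

    def n_detected(self) -> pd.Series:
        return self.table["n_detected"]

    def __len__(self) -> int:
        return len(self.table)


def build_consensus(
    detected: Mapping[str, set[str]],
    records: pd.DataFrame,
    min_datasets: int = 4,
    ccs_mode: str = "mean",
) -> ConsensusTable:
    """Combine per-cohort detections into the consensus table.

    ``detected`` maps dataset_id -> detected gene set; ``records`` is the
    concatenation of every cohort's correlation records. A gene is consensus
    when detected in >= ``min_datasets`` cohorts; its CCS summarizes the rho
    values of exactly those detecting cohorts.
    """
    dataset_ids = sorted(detected)
    if len(dataset_ids) < min_datasets:
        raise ValueError(
            f"need >= {min_datasets} datasets, got {len(dataset_ids)}"
        )
    rho_wide = records.pivot_table(index="gene", columns="dataset_id", values="rho")
    genes = sorted(rho_wide.index)
    table = pd.DataFrame(index=pd.Index(genes, name="gene"))
    for ds in dataset_ids:
        table[f"det:{ds}"] = [g in detected[ds] for g in genes]
        table[f"rho:{ds}"] = rho_wide[ds] if ds in rho_wide else np.nan
    det_cols = [f"det:{ds}" for ds in dataset_ids]
    table["n_detected"] = table[det_cols].sum(axis=1).astype(int)
    ccs_vals = []
    for g in genes:
        rhos = [
            table.at[g, f"rho:{ds}"] for ds in dataset_ids if table.at[g, f"det:{ds}"]
        ]
        ccs_vals.append(combined_correlation_score(rhos, mode=ccs_mode))
    table["ccs"] = ccs_vals
    table["consensus"] = table["n_detected"] >= min_datasets
    return ConsensusTable(
        table=table, min_datasets=min_datasets, ccs_mode=ccs_mode, dataset_ids=dataset_ids
    )


def null_detection_rate(n_samples: int, rho_min: float = 0.25, p_max: float = 0.05) -> float:
    """P(rho > rho_min and p < p_max) for one gene under independence.

    Uses the same t approximation as the detector, so the bound matches the
    detector's own null: the joint event is the intersection of a one-sided
    rho exceedance and the two-sided p gate.
    """
    n = n_samples
    t_rho = rho_min * np.sqrt((n - 2) / (1.0 - rho_min**2))
    p_exceed = float(stats.t.sf(t_rho, df=n - 2))  # one-sided: rho > rho_min
    # p < p_max on the positive side corresponds to rho above the p_max/2 quantile
    t_p = stats.t.isf(p_max / 2.0, df=n - 2)
    p_gate = float(stats.t.sf(max(t_rho, t_p), df=n - 2))
    return min(p_exceed, p_gate)


def null_consensus_bound(
    n_genes: int,
    n_datasets: int,
    n_samples: int,
    rho_min: float = 0.25,
    p_max: float = 0.05,
    min_datasets: int = 4,
    n_sd: float = 3.0,
) -> float:
    """Upper bound on the null consensus-set size: expected count under
    cohort independence plus ``n_sd`` binomial standard deviations."""
    q = null_detection_rate(n_samples, rho_min=rho_min, p_max=p_max)
    per_gene = float(stats.binom.sf(min_datasets - 1, n_datasets, q))
    mean = n_genes * per_gene
    sd = float(np.sqrt(n_genes * per_gene * (1.0 - per_gene)))
    return mean + n_sd * sd


def quartile_subset(dataset: ExpressionDataset, which: str) -> ExpressionDataset:
    """Samples in the top (>= 75th pct) or bottom (<= 25th pct) anchor quartile.

    Ties at the percentile boundary are included, so the subset is
    deterministic; requires >= 8 samples and a non-constant anchor.
    """
    if which not in ("top", "bottom"):
        raise ValueError(f"which must be 'top' or 'bottom', got {which!r}")
    anchor_vals = dataset.anchor_values().to_numpy(dtype=float)
    if len(anchor_vals) < 8:
        raise ValueError(f"need >= 8 samples to quartile, got {len(anchor_vals)}")
    if np.nanvar(anchor_vals) == 0:
        raise ValueError("anchor has zero variance: quartiles undefined")
    if which == "top":
        cut = np.nanpercentile(anchor_vals, 75)
        keep = anchor_vals >= cut
    else:
        cut = np.nanpercentile(anchor_vals, 25)
        keep = anchor_vals <= cut
    samples = [s for s, k in zip(dataset.samples, keep) if k]
    return dataset.subset_samples(samples, dataset_id=f"{dataset.dataset_id}:{which}")


def single_cohort_partners(
    dataset: ExpressionDataset,
    interactome: Interactome,
    rho_min: float = 0.5,
    p_max: float = 0.05,
    min_shared_mres: int = 5,
    shared_mode: str = "families",
) -> set[str]:
    """Single-cohort ceRNA partner call: strong positive correlation with the
    anchor plus >= ``min_shared_mres`` shared MREs."""
    records = correlate_with_anchor(dataset)
    correlated = detect_correlated(records, rho_min=rho_min, p_max=p_max)
    anchor = dataset.anchor
    return {
        g
        for g in correlated
        if shared_mre_count(interactome, anchor, g, mode=shared_mode) >= min_shared_mres
    }


def consensus_pipeline(
    datasets: Iterable[ExpressionDataset],
    rho_min: float = 0.25,
    p_max: float = 0.05,
    min_datasets: int = 4,
    ccs_mode: str = "mean",
) -> ConsensusTable:
    """End-to-end: correlate each cohort, threshold, combine."""
    all_records = []
    detected: dict[str, set[str]] = {}
    for ds in datasets:
        rec = correlate_with_anchor(ds)
        all_records.append(rec)
        detected[ds.dataset_id] = detect_correlated(rec, rho_min=rho_min, p_max=p_max)
    records = pd.concat(all_records, ignore_index=True)
    return build_consensus(detected, records, min_datasets=min_datasets, ccs_mode=ccs_mode)
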