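"""Core in-memory containers shared across the pipeline.

Everything tabular is backed by pandas; the classes here only add the
validation and naming the pipeline relies on (an anchor gene, per-pair
binding-site counts, survival columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "SurvivalTable",
    "UtrRecord",
    "Interaction",
    "normalize_symbol",
]


def normalize_symbol(symbol: str) -> str:
    """Canonical gene/miRNA key: trimmed, upper-cased.

    Cross-database joins (expression cohorts vs. target databases) are done
    case-insensitively on trimmed symbols.
    """
    return str(symbol).strip().upper()


@dataclass
class ExpressionDataset:
    """One cohort's genes x samples expression matrix with a named anchor gene.

    Values are continuous, log-scale by convention; NaN marks a missing cell
    (handled pairwise-complete downstream).
    """

    dataset_id: str
    values: pd.DataFrame  # index = gene symbols, columns = sample IDs
    anchor: str

    def __post_init__(self) -> None:
        idx = pd.Index([normalize_symbol(g) for g in self.values.index])
        self.values = self.values.copy()
        self.values.index = idx
        self.anchor = normalize_symbol(self.anchor)
        if idx.has_duplicates:
            dupes = sorted(idx[idx.duplicated()].unique())
            raise ValueError(f"duplicate gene symbols in {self.dataset_id!r}: {dupes[:5]}")
        if self.values.columns.has_duplicates:
            raise ValueError(f"duplicate sample IDs in {self.dataset_id!r}")
        if self.anchor not in idx:
            raise KeyError(f"anchor not found: {self.anchor!r} absent from {self.dataset_id!r}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise TypeError(f"non-numeric expression values in {self.dataset_id!r}")
        if np.isinf(arr).any():
            raise ValueError(f"non-finite (infinite) expression values in {self.dataset_id!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def anchor_values(self) -> pd.Series:
        return self.values.loc[self.anchor]

    def subset_samples(self, samples: list[str], dataset_id: str | None = None) -> "ExpressionDataset":
        return ExpressionDataset(
            dataset_id=dataset_id or self.dataset_id,
            values=self.values.loc[:, samples],
            anchor=self.anchor,
        )


@dataclass
class SurvivalTable:
    """Per-sample follow-up time (months), binary event flag, optional covariates."""

    data: pd.DataFrame  # index = sample IDs; columns: time, event, covariates...

    def __post_init__(self) -> None:
        df = self.data
        for col in ("time", "event"):
            if col not in df.columns:
                raise KeyError(f"survival table missing required column {col!r}")
        if df.index.has_duplicates:
            raise ValueError("duplicate sample IDs in survival table")
        if (df["time"] < 0).any():
            bad = df.index[df["time"] < 0][0]
            raise ValueError(f"negative follow-up time for sample {bad!r}")
        if not df["event"].isin([0, 1]).all():
            bad = sorted(df.loc[~df["event"].isin([0, 1]), "event"].unique())
            raise ValueError(f"event values outside {{0,1}}: {bad}")
        self.data = df.copy()
        self.data["event"] = self.data["event"].astype(int)
        self.data["time"] = self.data["time"].astype(float)

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_events(self) -> int:
        return int(self.data["event"].sum())

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SurvivalTable):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(self.data, other.data, check_like=True)
        except AssertionError:
            return False
        return True


@dataclass(frozen=True)
class UtrRecord:
    """One transcript's 3' UTR: length in nucleotides, optional sequence."""

    gene: str
    utr_length: int
    transcript_id: str | None = None
    sequence: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", normalize_symbol(self.gene))
        if self.utr_length <= 0:
            raise ValueError(f"utr_length must be > 0 for {self.gene!r}, got {self.utr_length}")
        if self.sequence is not None and len(self.sequence) != self.utr_length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != utr_length {self.utr_length} for {self.gene!r}"
            )


@dataclass(frozen=True)
class Interaction:
    """A predicted miRNA -> gene interaction with binding-site counts.

    ``sources`` lists the databases supporting the pair (the site-count
    database plus any auxiliary binary predictors).
    """

    mirna: str
    gene: str
    total_sites: int
    conserved_sites: int = 0
    sources: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", normalize_symbol(self.gene))
        object.__setattr__(self, "mirna", str(self.mirna).strip())
        object.__setattr__(self, "sources", frozenset(self.sources))
        if self.total_sites < 1:
            raise ValueError(
                f"total_sites must be >= 1 ({self.mirna}->{self.gene}: {self.total_sites})"
            )
        if not (0 <= self.conserved_sites <= self.total_sites):
            raise ValueError(
                f"conserved_sites must lie in [0, total_sites] "
                f"({self.mirna}->{self.gene}: {self.conserved_sites}/{self.total_sites})"
            )
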