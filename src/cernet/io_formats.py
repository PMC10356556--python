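"""Readers and writers for every external representation the pipeline touches.

Expression matrices and survival tables are delimited text with auto-detected
tab/comma delimiters; the miRNA-target table follows a TargetScan-style
"summary counts" dialect with configurable column names; gene signatures are
GMT; networks go to GraphML, SIF or node-link JSON.

Every reader/writer pair is a lossless round trip on its own output (label
equality, numeric equality to stored precision); parsers never silently drop
rows — collapsed or rejected rows are logged with their coordinates.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import ExpressionDataset, Interaction, SurvivalTable, UtrRecord, normalize_symbol
from .network import CeRNANetwork

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_targetscan_summary",
    "write_targetscan_summary",
    "read_gene_signature",
    "write_gene_signature",
    "read_survival_table",
    "write_survival_table",
    "read_network",
    "write_network",
    "DEFAULT_TARGETSCAN_COLUMNS",
]

FLOAT_FORMAT = "%.10g"

# Dialect defaults follow the TargetScan 6 "summary counts" headers; remap via
# the `columns` argument when the source drifts.
DEFAULT_TARGETSCAN_COLUMNS: dict[str, str] = {
    "gene": "Gene Symbol",
    "transcript_id": "Transcript ID",
    "mirna": "miRNA family",
    "total_sites": "Total num sites",
    "conserved_sites": "Total num conserved sites",
    "utr_length": "UTR length",
}


def _detect_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    with open(path, newline="") as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_expression_matrix(
    path: str | Path,
    dataset_id: str,
    anchor: str,
    delimiter: str | None = None,
    duplicate_rule: str = "max_mean",
) -> ExpressionDataset:
    """Read a genes x samples matrix (first column gene symbols, header row
    sample IDs) into a validated :class:`ExpressionDataset`.

    Duplicate gene rows are collapsed by ``duplicate_rule``: ``max_mean``
    keeps the row with the highest mean expression (the usual probe-collapse
    convention), ``first`` keeps the first occurrence, ``mean`` averages.
    Empty cells become missing values; any other non-numeric cell is an
    error naming its coordinates.
    """
    path = Path(path)
    sep = _detect_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = [normalize_symbol(g) for g in df.index]
    values = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            gene = df.index[bad][0]
            raise ValueError(
                f"non-numeric cell at row {gene!r}, column {col!r}: {df.loc[bad, col].iloc[0]!r}"
            )
        values[col] = converted

    if values.index.has_duplicates:
        dupes = sorted(set(values.index[values.index.duplicated()]))
        logger.warning(
            "collapsing %d duplicate gene rows in %s by rule %r: %s",
            len(dupes), dataset_id, duplicate_rule, dupes[:5],
        )
        if duplicate_rule == "max_mean":
            values = values.assign(_mean=values.mean(axis=1, skipna=True))
            values = (
                values.sort_values("_mean", ascending=False)
                .groupby(level=0, sort=False)
                .head(1)
                .drop(columns="_mean")
            )
            values = values.loc[sorted(values.index)]
        elif duplicate_rule == "first":
            values = values[~values.index.duplicated(keep="first")]
        elif duplicate_rule == "mean":
            values = values.groupby(level=0).mean()
        else:
            raise ValueError(f"unknown duplicate rule {duplicate_rule!r}")

    return ExpressionDataset(dataset_id=dataset_id, values=values, anchor=anchor)


def write_expression_matrix(dataset: ExpressionDataset, path: str | Path) -> None:
    dataset.values.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="gene")


def read_targetscan_summary(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    source_label: str = "sitecountdb",
) -> tuple[list[Interaction], list[UtrRecord]]:
    """Parse a summary-counts-style miRNA-target table.

    Returns the interactions (total/conserved site counts validated) and one
    UTR record per distinct transcript. Negative, non-integer, or
    conserved > total site counts are hard errors with the line number.
    """
    path = Path(path)
    cols = dict(DEFAULT_TARGETSCAN_COLUMNS)
    if columns:
        cols.update(columns)
    sep = _detect_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [v for v in cols.values() if v not in df.columns]
    if missing:
        raise ValueError(f"missing columns in {path.name}: {missing}")

    interactions: list[Interaction] = []
    utrs: dict[tuple[str, str], UtrRecord] = {}
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            total = _parse_count(row[cols["total_sites"]])
            conserved = _parse_count(row[cols["conserved_sites"]])
            utr_len = _parse_count(row[cols["utr_length"]])
        except ValueError as exc:
            raise ValueError(f"{path.name} line {line_no}: {exc}") from None
        if conserved > total:
            raise ValueError(
                f"{path.name} line {line_no}: conserved sites ({conserved}) exceed total ({total})"
            )
        gene = normalize_symbol(row[cols["gene"]])
        tx = str(row[cols["transcript_id"]]).strip()
        interactions.append(
            Interaction(
                mirna=str(row[cols["mirna"]]).strip(),
                gene=gene,
                total_sites=total,
                conserved_sites=conserved,
                sources={source_label},
            )
        )
        utrs.setdefault((gene, tx), UtrRecord(gene=gene, utr_length=utr_len, transcript_id=tx))
    return interactions, list(utrs.values())


def _parse_count(raw: object) -> int:
    text = str(raw).strip()
    try:
        value = float(text)
    except ValueError:
        raise ValueError(f"non-numeric count {text!r}")
    if value < 0 or value != int(value):
        raise ValueError(f"count must be a non-negative integer, got {text!r}")
    return int(value)


def write_targetscan_summary(
    interactions: Iterable[Interaction],
    utr_records: Iterable[UtrRecord],
    path: str | Path,
    columns: Mapping[str, str] | None = None,
) -> None:
    cols = dict(DEFAULT_TARGETSCAN_COLUMNS)
    if columns:
        cols.update(columns)
    utr_by_gene: dict[str, UtrRecord] = {}
    for rec in utr_records:
        # summary-count rows carry the longest variant's UTR length
        if rec.gene not in utr_by_gene or rec.utr_length > utr_by_gene[rec.gene].utr_length:
            utr_by_gene[rec.gene] = rec
    rows = []
    for inter in sorted(interactions, key=lambda x: (x.gene, x.mirna)):
        rec = utr_by_gene.get(inter.gene)
        rows.append(
            {
                cols["gene"]: inter.gene,
                cols["transcript_id"]: (rec.transcript_id if rec else "") or "",
                cols["mirna"]: inter.mirna,
                cols["total_sites"]: inter.total_sites,
                cols["conserved_sites"]: inter.conserved_sites,
                cols["utr_length"]: rec.utr_length if rec else 0,
            }
        )
    pd.DataFrame(rows, columns=list(cols.values() if not rows else rows[0].keys())).to_csv(
        path, sep="\t", index=False
    )


def read_gene_signature(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into {set name: unique gene list, order preserved}."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {line_no}: expected >= 3 tab-separated fields")
            name, _desc, *genes = fields
            seen: list[str] = []
            for g in genes:
                g = normalize_symbol(g)
                if not g:
                    continue
                if g in seen:
                    logger.warning("GMT set %r line %d: duplicate gene %s dropped", name, line_no, g)
                    continue
                seen.append(g)
            out[name] = seen
    return out


def write_gene_signature(signatures: Mapping[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in signatures.items():
            fh.write("\t".join([name, ""] + [normalize_symbol(g) for g in genes]) + "\n")


def read_survival_table(
    path: str | Path,
    sample_col: str = "sample",
    time_col: str = "time",
    event_col: str = "event",
    event_map: Mapping[str, int] | None = None,
    delimiter: str | None = None,
) -> SurvivalTable:
    """Read sample/time/event columns (names configurable) into a
    :class:`SurvivalTable`; extra columns become covariates.

    ``event_map`` coerces categorical event labels (e.g. yes/no) to 1/0.
    """
    path = Path(path)
    sep = _detect_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep)
    for col in (sample_col, time_col, event_col):
        if col not in df.columns:
            raise ValueError(f"survival table missing column {col!r}")
    df = df.set_index(sample_col)
    df.index.name = "sample"
    df = df.rename(columns={time_col: "time", event_col: "event"})
    if event_map is not None:
        df["event"] = df["event"].map(
            lambda v: event_map.get(str(v).strip().lower(), v)
        )
    df["event"] = pd.to_numeric(df["event"], errors="raise")
    df["time"] = pd.to_numeric(df["time"], errors="raise")
    return SurvivalTable(data=df)


def write_survival_table(table: SurvivalTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="sample")


NETWORK_FORMATS = ("graphml", "sif", "json")


def write_network(network: CeRNANetwork, path: str | Path, format: str = "graphml") -> None:
    """Serialize a network: GraphML and JSON carry all node/edge attributes
    (exact round trip); SIF is the conventional topology-only triple format
    with relations ``targets`` (miRNA->gene/anchor) and ``anchors``
    (anchor->partner)."""
    fmt = format.lower()
    if fmt not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {format!r}; supported: {NETWORK_FORMATS}")
    path = Path(path)
    network.validate()
    if fmt == "graphml":
        nx.write_graphml(network.graph, path)
    elif fmt == "json":
        doc = nx.node_link_data(network.graph, edges="edges")
        path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            for u, v, d in sorted(network.graph.edges(data=True)):
                writer.writerow([u, d.get("relation", "targets"), v])


def read_network(path: str | Path, format: str = "graphml") -> CeRNANetwork:
    fmt = format.lower()
    if fmt not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {format!r}; supported: {NETWORK_FORMATS}")
    path = Path(path)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        g = nx.DiGraph(g)
        for _, _, d in g.edges(data=True):
            if "n_sites" in d:
                d["n_sites"] = int(d["n_sites"])
        for _, d in g.nodes(data=True):
            if "utr_length" in d:
                d["utr_length"] = int(d["utr_length"])
    elif fmt == "json":
        g = nx.node_link_graph(json.loads(path.read_text()), edges="edges")
    else:
        raise ValueError("SIF is topology-only and cannot be read back as a full network")
    return CeRNANetwork(graph=g)
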