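"""Assembly of the anchor-miRNA-partner ceRNA network.

The network is bipartite-plus-anchor: miRNA nodes point at the gene nodes
they target (edge weight = number of binding sites) and at the anchor.
Anchor-gene "partner" edges are implied through shared miRNA nodes and are
only materialized on request (``include_partner_edges``), weighted by the
shared-MRE count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .consensus import ConsensusTable
from .datatypes import UtrRecord, normalize_symbol
from .interactome import Interactome, shared_mre_count

__all__ = ["CeRNANetwork", "build_network", "filter_by_category"]

NODE_CLASSES = ("anchor", "gene", "mirna")


@dataclass
class CeRNANetwork:
    """Anchor + gene + miRNA nodes with attributes, site-count-weighted edges.

    Wraps a :class:`networkx.DiGraph`; node attribute ``kind`` is one of
    ``anchor``/``gene``/``mirna``, genes carry ``ccs`` and (when known)
    ``utr_length``, edges carry ``n_sites`` and a ``relation`` label
    (``targets`` for miRNA->gene/anchor, ``anchors`` for anchor-partner).
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def anchor(self) -> str:
        anchors = [n for n, d in self.graph.nodes(data=True) if d.get("kind") == "anchor"]
        return anchors[0]

    def nodes_of_kind(self, kind: str) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d.get("kind") == kind)

    @property
    def gene_nodes(self) -> list[str]:
        return self.nodes_of_kind("gene")

    @property
    def mirna_nodes(self) -> list[str]:
        return self.nodes_of_kind("mirna")

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def validate(self) -> None:
        kinds = [d.get("kind") for _, d in self.graph.nodes(data=True)]
        if self.graph.number_of_nodes() and kinds.count("anchor") != 1:
            raise ValueError(f"network must have exactly one anchor node, found {kinds.count('anchor')}")
        for n, d in self.graph.nodes(data=True):
            if d.get("kind") not in NODE_CLASSES:
                raise ValueError(f"node {n!r} has unknown class {d.get('kind')!r}")
        for u, v, d in self.graph.edges(data=True):
            if d.get("relation") == "targets" and d.get("n_sites", 0) < 1:
                raise ValueError(f"targets edge {u}->{v} must carry n_sites >= 1")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CeRNANetwork):
            return NotImplemented
        g, h = self.graph, other.graph
        return (
            dict(g.nodes(data=True)) == dict(h.nodes(data=True))
            and {(u, v): d for u, v, d in g.edges(data=True)}
            == {(u, v): d for u, v, d in h.edges(data=True)}
        )


def build_network(
    anchor: str,
    consensus: ConsensusTable,
    top_mirnas: Iterable[str],
    interactome: Interactome,
    utr_records: Iterable[UtrRecord] = (),
    *,
    include_partner_edges: bool = False,
    shared_mre_mode: str = "families",
) -> CeRNANetwork:
    """Assemble the ceRNA network around the anchor.

    Gene nodes are the consensus genes targeted by at least one of the top
    miRNAs; each (top miRNA -> gene) interaction becomes an edge weighted by
    its binding-site count, alongside the (top miRNA -> anchor) edges. Node
    and edge insertion is sorted, so assembly is deterministic.
    """
    anchor = normalize_symbol(anchor)
    top_mirnas = sorted(set(top_mirnas))
    if not top_mirnas:
        raise ValueError("no miRNAs to build on")

    utr_length: dict[str, int] = {}
    for rec in utr_records:
        utr_length[rec.gene] = max(rec.utr_length, utr_length.get(rec.gene, 0))

    consensus_genes = set(consensus.consensus_genes()) - {anchor}
    ccs = consensus.ccs()

    g = nx.DiGraph()
    g.add_node(anchor, kind="anchor")
    if anchor in utr_length:
        g.nodes[anchor]["utr_length"] = utr_length[anchor]

    gene_nodes: set[str] = set()
    edges: list[tuple[str, str, int]] = []
    for m in top_mirnas:
        for inter in interactome.by_mirna.get(m, []):
            if inter.gene == anchor:
                edges.append((m, anchor, inter.total_sites))
            elif inter.gene in consensus_genes:
                gene_nodes.add(inter.gene)
                edges.append((m, inter.gene, inter.total_sites))

    for m in top_mirnas:
        g.add_node(m, kind="mirna")
    for gene in sorted(gene_nodes):
        attrs: dict = {"kind": "gene"}
        if gene in ccs and ccs[gene] == ccs[gene]:  # not NaN
            attrs["ccs"] = float(ccs[gene])
        if gene in utr_length:
            attrs["utr_length"] = utr_length[gene]
        g.add_node(gene, **attrs)
    for u, v, n_sites in sorted(edges):
        g.add_edge(u, v, relation="targets", n_sites=int(n_sites))

    if include_partner_edges:
        for gene in sorted(gene_nodes):
            shared = shared_mre_count(interactome, anchor, gene, mode=shared_mre_mode)
            if shared >= 1:
                g.add_edge(anchor, gene, relation="anchors", n_sites=int(shared))

    return CeRNANetwork(graph=g)


def filter_by_category(
    network: CeRNANetwork,
    gene_categories: Mapping[str, Iterable[str]],
    keep: Iterable[str],
) -> CeRNANetwork:
    """Restrict gene nodes to user-supplied categories (e.g. GO groupings).

    Gene nodes without a label in ``keep`` are dropped; miRNA nodes left with
    no gene edges (the anchor edge alone does not count) are pruned. The
    anchor is never removed. Idempotent.
    """
    keep = set(keep)
    if not keep:
        raise ValueError("keep set must be non-empty")
    labels = {normalize_symbol(g): set(v) for g, v in gene_categories.items()}

    g = network.graph.copy()
    anchor = network.anchor
    for gene in network.gene_nodes:
        cats = labels.get(gene, set())
        if cats & keep:
            hit = sorted(cats & keep)[0]
            g.nodes[gene]["category"] = hit
        else:
            g.remove_node(gene)
    for m in network.mirna_nodes:
        gene_degree = sum(
            1 for _, v in g.out_edges(m) if g.nodes[v].get("kind") == "gene"
        )
        if gene_degree == 0:
            g.remove_node(m)
    if anchor not in g:
        warnings.warn("anchor lost all edges after category filtering; kept as isolated node")
        g.add_node(anchor, kind="anchor")
    return CeRNANetwork(graph=g)
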