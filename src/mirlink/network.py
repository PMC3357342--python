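"""Module interactome construction, miRNA overlay, and hub analysis.

From a user-supplied table of experimentally supported gene-product
interactions, a module's interactome keeps the edges whose endpoints both
lie in the module (plus optional anchor molecules such as insulin, attached
to highlight their central relationships).  Differentially expressed miRNAs
linked to the module are then superimposed as regulator nodes with
"targeting" edges to their anti-correlated leading-edge targets.  Hubs are
ranked by protein-interaction degree only, so the miRNA overlay never
changes hub ranks; the most-targeted gene is ranked by incident targeting
edges.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx

from .containers import InteractionTable
from .gsea import ModuleResult
from .integrate import MiRNAModuleLink

__all__ = [
    "Interactome",
    "build_interactome",
    "overlay_mirnas",
    "top_hubs",
    "most_targeted_genes",
    "motif_components",
    "write_graphml",
    "write_node_edge_tables",
]

logger = logging.getLogger(__name__)

GENE = "gene"
MIRNA = "mirna"
ANCHOR = "anchor"
PPI = "ppi"
TARGETING = "targeting"


class Interactome:
    """Undirected graph of module genes, anchors and overlaid miRNA regulators.

    Node attributes: ``kind`` (gene/mirna/anchor) and optional ``direction``.
    Edge attribute ``kind`` is ``ppi`` (gene-gene or gene-anchor) or
    ``targeting`` (mirna-gene).
    """

    def __init__(self, graph: Optional[nx.Graph] = None):
        self.graph = graph if graph is not None else nx.Graph()
        self._validate()

    def _validate(self) -> None:
        for n in self.graph.nodes:
            if self.graph.has_edge(n, n):
                raise ValueError(f"self-loop on node {n!r}")
        for a, b, data in self.graph.edges(data=True):
            kinds = {self.graph.nodes[a]["kind"], self.graph.nodes[b]["kind"]}
            if data["kind"] == TARGETING:
                if kinds != {MIRNA, GENE}:
                    raise ValueError(f"targeting edge {a!r}-{b!r} must be mirna<->gene")
            elif data["kind"] == PPI:
                if MIRNA in kinds:
                    raise ValueError(f"ppi edge {a!r}-{b!r} may not touch a miRNA")
            else:
                raise ValueError(f"unknown edge kind {data['kind']!r}")

    # -- accessors -------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_of_kind(self, kind: str) -> List[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["kind"] == kind
        )

    def ppi_degree(self, node: str) -> int:
        return sum(
            1
            for _, _, d in self.graph.edges(node, data=True)
            if d["kind"] == PPI
        )

    def targeting_count(self, node: str) -> int:
        return sum(
            1
            for _, _, d in self.graph.edges(node, data=True)
            if d["kind"] == TARGETING
        )

    def copy(self) -> "Interactome":
        return Interactome(self.graph.copy())


def build_interactome(
    module: ModuleResult,
    table: InteractionTable,
    anchors: Sequence[str] = (),
) -> Interactome:
    """Interactome of a module: table edges with both endpoints in module+anchors.

    Module genes touching no retained edge are excluded (their count is
    logged); anchors are included whenever an edge reaches them.  An empty
    resulting network is an error.
    """
    module_genes = set(module.leading_edge)
    anchor_set = set(anchors)
    allowed = module_genes | anchor_set
    g = nx.Graph()
    for a, b, src in table:
        if a in allowed and b in allowed:
            kind_a = ANCHOR if a in anchor_set else GENE
            kind_b = ANCHOR if b in anchor_set else GENE
            g.add_node(a, kind=kind_a)
            g.add_node(b, kind=kind_b)
            g.add_edge(a, b, kind=PPI, source=src)
    isolated = module_genes - set(g.nodes)
    if isolated:
        logger.info(
            "excluded %d isolated module gene(s) with no retained interaction",
            len(isolated),
        )
    if g.number_of_edges() == 0:
        raise ValueError(
            f"module {module.module_name!r}: no interaction edge falls inside "
            "the module; network is empty"
        )
    for n, d in g.nodes(data=True):
        if d["kind"] == GENE:
            d["direction"] = module.gene_directions.get(n, "")
    return Interactome(g)


def overlay_mirnas(
    g: Interactome,
    links: Sequence[MiRNAModuleLink],
    module_name: str,
) -> Interactome:
    """Superimpose linked miRNA regulators onto a module interactome.

    Adds one miRNA node per link of the module and a targeting edge to each
    of its linking genes present in the graph; linking genes absent from the
    graph are skipped with a log message.  Existing ppi edges are untouched.
    """
    out = g.copy()
    for link in links:
        if link.module_name != module_name:
            continue
        added = 0
        for gene, _gdir in link.linking_genes:
            if not out.graph.has_node(gene):
                logger.info(
                    "linking gene %r of %r not in the interactome; skipped",
                    gene,
                    link.mirna_id,
                )
                continue
            if not out.graph.has_node(link.mirna_id):
                out.graph.add_node(
                    link.mirna_id, kind=MIRNA, direction=link.mirna_direction
                )
            out.graph.add_edge(link.mirna_id, gene, kind=TARGETING, source="")
            added += 1
        if added == 0:
            logger.info("miRNA %r had no linking gene in the graph", link.mirna_id)
    return out


def top_hubs(g: Interactome, k: int) -> List[Tuple[str, int]]:
    """Top-k gene/anchor nodes by ppi degree (ties by node ID ascending)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if g.n_nodes == 0:
        raise ValueError("empty graph has no hubs")
    nodes = [
        n
        for n, d in g.graph.nodes(data=True)
        if d["kind"] in (GENE, ANCHOR)
    ]
    ranked = sorted(nodes, key=lambda n: (-g.ppi_degree(n), n))
    return [(n, g.ppi_degree(n)) for n in ranked[:k]]


def most_targeted_genes(g: Interactome) -> List[Tuple[str, int]]:
    """Genes ranked by incident miRNA targeting edges, descending.

    All genes tied at the maximum share the head of the list.  Raises if the
    graph carries no targeting edge.
    """
    counts: Dict[str, int] = {}
    for a, b, d in g.graph.edges(data=True):
        if d["kind"] != TARGETING:
            continue
        gene = a if g.graph.nodes[a]["kind"] == GENE else b
        counts[gene] = counts.get(gene, 0) + 1
    if not counts:
        raise ValueError("graph has no targeting edges")
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def motif_components(g: Interactome) -> List[frozenset]:
    """Connected components of the ppi subgraph after anchor removal.

    The curated functional groupings visible in module interactomes are
    approximated here as the components that remain once highly connected
    anchor molecules are taken out.
    """
    sub = nx.Graph()
    for n, d in g.graph.nodes(data=True):
        if d["kind"] == GENE:
            sub.add_node(n)
    for a, b, d in g.graph.edges(data=True):
        if d["kind"] == PPI and sub.has_node(a) and sub.has_node(b):
            sub.add_edge(a, b)
    comps = [frozenset(c) for c in nx.connected_components(sub)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def write_graphml(g: Interactome, path) -> None:
    """GraphML export with kind/direction/degree/mirna_count node attributes."""
    out = g.graph.copy()
    for n in out.nodes:
        out.nodes[n]["degree"] = g.ppi_degree(n)
        out.nodes[n]["mirna_count"] = g.targeting_count(n)
        out.nodes[n].setdefault("direction", "")
    nx.write_graphml(out, path)


def write_node_edge_tables(g: Interactome, nodes_path, edges_path) -> None:
    with open(nodes_path, "w") as fh:
        fh.write("node\tkind\tdirection\tdegree\tmirna_count\n")
        for n in sorted(g.graph.nodes):
            d = g.graph.nodes[n]
            fh.write(
                f"{n}\t{d['kind']}\t{d.get('direction', '')}\t"
                f"{g.ppi_degree(n)}\t{g.targeting_count(n)}\n"
            )
    with open(edges_path, "w") as fh:
        fh.write("node_a\tnode_b\tkind\tsource\n")
        for a, b, d in sorted(g.graph.edges(data=True)):
            x, y = (a, b) if a <= b else (b, a)
            fh.write(f"{x}\t{y}\t{d['kind']}\t{d.get('source', '')}\n")
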