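"""Assembly of the tripartite miRNA-lncRNA-mRNA/TF regulatory network.

Nodes are typed (miRNA, lncRNA, mRNA, TF) and edges carry one of five
classes: miRNA cleavage of an mRNA or of an lncRNA (degradome-supported),
cis or trans lncRNA->gene targeting, and eTM suppression, which runs
lncRNA->miRNA because the mimic sequesters the miRNA.  Edge direction is
regulator->target throughout.  The network is backed by a networkx
MultiDiGraph keyed by edge class, so a pair of nodes may be linked by
several differently-classed edges while same-class duplicates collapse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .etm_finder import EtmRuleReport, PairingAlignment
from .io_formats import Interaction, TargetPair
from .lncrna_targets import CisTarget, TransTarget

__all__ = [
    "NODE_CLASSES",
    "EDGE_CLASSES",
    "RegulatoryNetwork",
    "NetworkSummary",
    "build_network",
    "summarize",
    "export_network",
    "read_edges_tsv",
]

NODE_CLASSES = ("miRNA", "lncRNA", "mRNA", "TF")
EDGE_CLASSES = (
    "mirna_cleaves_mrna",
    "mirna_cleaves_lncrna",
    "lncrna_cis_gene",
    "lncrna_trans_gene",
    "lncrna_etm_mirna",
)


@dataclass
class RegulatoryNetwork:
    """Typed tripartite regulatory graph."""

    graph: nx.MultiDiGraph = field(default_factory=nx.MultiDiGraph)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_class(self, node_id: str) -> str:
        return self.graph.nodes[node_id]["node_class"]

    def add_node(self, node_id: str, node_class: str, **attrs) -> None:
        if node_class not in NODE_CLASSES:
            raise ValueError(f"unknown node class {node_class!r}")
        if node_id in self.graph.nodes:
            existing = self.graph.nodes[node_id]["node_class"]
            if existing != node_class:
                # TF annotation outranks plain mRNA; anything else conflicts
                if {existing, node_class} == {"mRNA", "TF"}:
                    node_class = "TF"
                else:
                    raise ValueError(
                        f"node {node_id!r} classed as both {existing!r} "
                        f"and {node_class!r}"
                    )
        self.graph.add_node(node_id, node_class=node_class, **attrs)

    def add_edge(
        self, source: str, target: str, edge_class: str, **attrs
    ) -> None:
        if edge_class not in EDGE_CLASSES:
            raise ValueError(f"unknown edge class {edge_class!r}")
        for endpoint in (source, target):
            if endpoint not in self.graph.nodes:
                raise ValueError(f"edge endpoint {endpoint!r} not in network")
        # same-class duplicates collapse (attributes of the first kept)
        if not self.graph.has_edge(source, target, key=edge_class):
            self.graph.add_edge(
                source, target, key=edge_class, edge_class=edge_class, **attrs
            )

    def edges(self) -> list[tuple[str, str, str, dict]]:
        return [
            (u, v, k, d) for u, v, k, d in self.graph.edges(keys=True, data=True)
        ]


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes_by_class: dict[str, int]
    n_edges_by_class: dict[str, int]
    n_nodes: int
    n_edges: int
    n_components: int
    max_degree_by_class: dict[str, int]
    top_degree_by_class: dict[str, list[tuple[str, int]]]


def _gene_class(gene_id: str, node_annot: Mapping[str, str]) -> str:
    cls = node_annot.get(gene_id, "mRNA")
    if cls not in NODE_CLASSES:
        raise ValueError(f"unknown annotated class {cls!r} for {gene_id!r}")
    return cls


def build_network(
    mirna_mrna: Iterable[TargetPair] = (),
    mirna_lnc: Iterable[TargetPair] = (),
    cis: Iterable[CisTarget] = (),
    trans: Iterable[TransTarget] = (),
    etms: Iterable[tuple[PairingAlignment, EtmRuleReport]] = (),
    node_annot: Mapping[str, str] | None = None,
) -> RegulatoryNetwork:
    """Assemble the network from per-stage outputs.

    Nodes are created on demand with classes implied by the source table
    (overridable per id through ``node_annot``, used chiefly to mark TF
    genes).  Only verdict-true eTM hits may enter the network.  The result
    is invariant under duplication and reordering of the input rows.
    """
    annot = dict(node_annot or {})
    net = RegulatoryNetwork()

    for p in sorted(mirna_mrna, key=lambda p: (p.regulator_id, p.target_id)):
        if p.interaction is not Interaction.mirna_cleaves_mrna:
            raise ValueError(f"unexpected interaction {p.interaction} in mirna_mrna")
        net.add_node(p.regulator_id, annot.get(p.regulator_id, "miRNA"))
        net.add_node(p.target_id, _gene_class(p.target_id, annot))
        net.add_edge(
            p.regulator_id,
            p.target_id,
            "mirna_cleaves_mrna",
            cleavage_position=p.cleavage_position,
        )

    for p in sorted(mirna_lnc, key=lambda p: (p.regulator_id, p.target_id)):
        if p.interaction is not Interaction.mirna_cleaves_lncrna:
            raise ValueError(f"unexpected interaction {p.interaction} in mirna_lnc")
        net.add_node(p.regulator_id, annot.get(p.regulator_id, "miRNA"))
        net.add_node(p.target_id, annot.get(p.target_id, "lncRNA"))
        net.add_edge(
            p.regulator_id,
            p.target_id,
            "mirna_cleaves_lncrna",
            cleavage_position=p.cleavage_position,
        )

    for c in sorted(cis, key=lambda c: (c.lncrna_id, c.gene_id)):
        net.add_node(c.lncrna_id, annot.get(c.lncrna_id, "lncRNA"))
        net.add_node(c.gene_id, _gene_class(c.gene_id, annot))
        net.add_edge(
            c.lncrna_id,
            c.gene_id,
            "lncrna_cis_gene",
            distance_bp=c.distance_bp,
            side=c.side,
        )

    for t in sorted(trans, key=lambda t: (t.lncrna_id, t.gene_id)):
        net.add_node(t.lncrna_id, annot.get(t.lncrna_id, "lncRNA"))
        net.add_node(t.gene_id, _gene_class(t.gene_id, annot))
        net.add_edge(t.lncrna_id, t.gene_id, "lncrna_trans_gene", r=t.r)

    for aln, rep in sorted(
        etms, key=lambda h: (h[0].lncrna_id, h[0].mirna_id, h[0].site_start)
    ):
        if not rep.verdict:
            raise ValueError(
                f"eTM hit {aln.lncrna_id}->{aln.mirna_id} has verdict=False"
            )
        net.add_node(aln.lncrna_id, annot.get(aln.lncrna_id, "lncRNA"))
        net.add_node(aln.mirna_id, annot.get(aln.mirna_id, "miRNA"))
        net.add_edge(
            aln.lncrna_id,
            aln.mirna_id,
            "lncrna_etm_mirna",
            site_start=aln.site_start,
            site_end=aln.site_end,
            n_mismatch=rep.n_mismatch,
            n_wobble=rep.n_wobble,
        )

    return net


def summarize(net: RegulatoryNetwork, top_k: int = 5) -> NetworkSummary:
    """Direct-enumeration summary: counts, components, degree leaders."""
    g = net.graph
    nodes_by_class = {c: 0 for c in NODE_CLASSES}
    for _, d in g.nodes(data=True):
        nodes_by_class[d["node_class"]] += 1
    edges_by_class = {c: 0 for c in EDGE_CLASSES}
    for _, _, k in g.edges(keys=True):
        edges_by_class[k] += 1
    degrees: dict[str, list[tuple[str, int]]] = {c: [] for c in NODE_CLASSES}
    for node, d in g.nodes(data=True):
        degrees[d["node_class"]].append((node, g.degree(node)))
    top = {
        c: sorted(lst, key=lambda x: (-x[1], x[0]))[:top_k]
        for c, lst in degrees.items()
    }
    max_deg = {c: (max((n for _, n in lst), default=0)) for c, lst in degrees.items()}
    return NetworkSummary(
        n_nodes_by_class=nodes_by_class,
        n_edges_by_class=edges_by_class,
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        n_components=nx.number_weakly_connected_components(g),
        max_degree_by_class=max_deg,
        top_degree_by_class=top,
    )


def export_network(net: RegulatoryNetwork, path: str | Path, format: str) -> None:
    """Write the network as an edges TSV or as GraphML."""
    if format == "edges_tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tedge_class\tsource_class\ttarget_class\tattributes\n")
            for u, v, k, d in sorted(net.edges()):
                attrs = ";".join(
                    f"{key}={value}"
                    for key, value in sorted(d.items())
                    if key != "edge_class" and value is not None
                )
                fh.write(
                    f"{u}\t{v}\t{k}\t{net.node_class(u)}\t{net.node_class(v)}\t{attrs}\n"
                )
    elif format == "graphml":
        g = net.graph.copy()
        for _, _, d in g.edges(data=True):
            for key in [k for k, v in d.items() if v is None]:
                del d[key]
        nx.write_graphml(g, str(path))
    else:
        raise ValueError(f"unknown export format {format!r}")


def read_edges_tsv(path: str | Path) -> RegulatoryNetwork:
    """Re-import an edges TSV written by :func:`export_network`."""
    net = RegulatoryNetwork()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["source", "target", "edge_class"]:
            raise ValueError(f"{path}: unexpected header")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            u, v, k, ucls, vcls, attr_s = line.split("\t")
            net.add_node(u, ucls)
            net.add_node(v, vcls)
            attrs = {}
            if attr_s:
                for item in attr_s.split(";"):
                    key, _, value = item.partition("=")
                    attrs[key] = value
            net.add_edge(u, v, k, **attrs)
    return net
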