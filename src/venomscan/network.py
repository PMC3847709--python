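"""Sequence-similarity networks: build, decompose, classify, export.

Nodes are sequences (tagged by origin: reference panel or query); an
undirected edge joins two sequences when the better of their two directional
E-values passes the chosen ceiling.  Connected components approximate
families; nodes without any passing edge are singletons and, as in the
usual graphical convention, are kept out of the component list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .similarity import SimilarityHit

__all__ = [
    "SimilarityGraph",
    "ComponentPartition",
    "build_graph",
    "connected_components",
    "classify_query_groups",
    "export_graph",
]

#: e-value ceiling used for the panel-wide network
DEFAULT_PANEL_THRESHOLD = 1e-10
#: tighter ceiling used to resolve groups within a family
DEFAULT_FAMILY_THRESHOLD = 1e-20


@dataclass
class SimilarityGraph:
    graph: nx.Graph
    threshold: float

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges


@dataclass
class ComponentPartition:
    components: list[frozenset]     # size-descending, then smallest member id
    singletons: list[str]           # degree-0 nodes, sorted

    def all_nodes(self) -> set:
        out = set(self.singletons)
        for c in self.components:
            out |= c
        return out


def build_graph(
    hits: list[SimilarityHit],
    threshold: float,
    nodes=None,
    origins: dict[str, str] | None = None,
) -> SimilarityGraph:
    """Build the similarity network at an E-value ceiling.

    ``nodes`` optionally names the full sequence universe (so hit-less
    sequences appear as singletons); ``origins`` maps node id to
    ``panel``/``query``.  The edge E-value is the minimum over the two
    directions; self-hits never create edges.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    g = nx.Graph()
    origins = origins or {}
    if nodes is not None:
        for nid in nodes:
            g.add_node(nid, origin=origins.get(nid, "query"))
    for h in hits:
        for nid in (h.query, h.subject):
            if nid not in g:
                g.add_node(nid, origin=origins.get(nid, "query"))
        if h.query == h.subject:
            continue
        u, v = h.query, h.subject
        if g.has_edge(u, v):
            g[u][v]["evalue"] = min(g[u][v]["evalue"], h.evalue)
        elif h.evalue <= threshold:
            g.add_edge(u, v, evalue=h.evalue)
    # drop edges whose min-direction e-value was only later discovered to be
    # above threshold (cannot happen: min only decreases), keep invariant
    return SimilarityGraph(graph=g, threshold=threshold)


def connected_components(graph: SimilarityGraph) -> ComponentPartition:
    """Standard undirected connected components, deterministically ordered
    (size descending, then smallest member id); single nodes are singletons.
    """
    comps = []
    singles = []
    for comp in nx.connected_components(graph.graph):
        if len(comp) >= 2:
            comps.append(frozenset(comp))
        else:
            singles.extend(comp)
    comps.sort(key=lambda c: (-len(c), min(c)))
    return ComponentPartition(components=comps, singletons=sorted(singles))


def classify_query_groups(
    partition: ComponentPartition,
    origins: dict[str, str],
    families: dict[str, str] | None = None,
) -> dict[str, dict]:
    """Label every query node with its similarity group.

    Components are labelled G1, G2, ... in partition order (size descending,
    then smallest member id).  A component containing panel members inherits
    the panel family as annotation (majority family, ties alphabetic).
    Queries in no component are flagged singletons.
    """
    families = families or {}
    out: dict[str, dict] = {}
    for gi, comp in enumerate(partition.components, start=1):
        fams = [families[n] for n in comp
                if origins.get(n) == "panel" and families.get(n)]
        family = None
        if fams:
            counts: dict[str, int] = {}
            for f in fams:
                counts[f] = counts.get(f, 0) + 1
            family = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        for n in comp:
            if origins.get(n, "query") == "query":
                out[n] = {"group": f"G{gi}", "singleton": False, "family": family}
    for n in partition.singletons:
        if origins.get(n, "query") == "query":
            out[n] = {"group": None, "singleton": True, "family": None}
    return out


def export_graph(
    graph: SimilarityGraph,
    partition: ComponentPartition,
    path,
    origins: dict[str, str] | None = None,
    families: dict[str, str] | None = None,
) -> dict[str, Path]:
    """Write GraphML and SIF (plus a TSV membership table) for visualization.

    Node attributes: origin, family, group label; edge attribute:
    -log10(evalue).  Returns the written paths keyed by format.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    origins = origins or {}
    families = families or {}
    group_of: dict[str, str] = {}
    for gi, comp in enumerate(partition.components, start=1):
        for n in comp:
            group_of[n] = f"G{gi}"

    g = nx.Graph()
    for n in graph.graph.nodes:
        g.add_node(
            n,
            origin=origins.get(n, graph.graph.nodes[n].get("origin", "query")),
            family=families.get(n, ""),
            group=group_of.get(n, ""),
        )
    for u, v, data in graph.graph.edges(data=True):
        g.add_edge(u, v, neg_log10_evalue=-math.log10(data["evalue"]))

    graphml = path.with_suffix(".graphml")
    sif = path.with_suffix(".sif")
    tsv = path.with_suffix(".membership.tsv")
    nx.write_graphml(g, graphml)
    with open(sif, "w") as fh:
        written = set()
        for u, v in sorted(g.edges):
            fh.write(f"{u}\tsim\t{v}\n")
            written |= {u, v}
        for n in sorted(g.nodes):
            if n not in written:
                fh.write(f"{n}\n")
    with open(tsv, "w") as fh:
        fh.write("node\torigin\tfamily\tgroup\n")
        for n in sorted(g.nodes):
            d = g.nodes[n]
            fh.write(f"{n}\t{d['origin']}\t{d['family']}\t{d['group']}\n")
    return {"graphml": graphml, "sif": sif, "membership": tsv}
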