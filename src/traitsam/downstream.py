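"""Post-selection utilities: id conversion, chromosome maps, subnetworks.

Significant probes carry RAP-DB locus ids; downstream resources are keyed
either by RAP or by MSU (TIGR) ids, so the stages here convert identifiers
through a user-supplied mapping table, tally genes per chromosome directly
from the id prefix, and induce the subgraph of a protein-interaction edge
list on a gene set, reporting connected components and their hub proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .io_formats import (
    IdMapping,
    InteractionEdges,
    LocusParseError,
    parse_rap_locus,
)

logger = logging.getLogger("traitsam")

N_CHROMOSOMES = 12


@dataclass
class SubnetworkReport:
    """Induced subgraph summary.

    ``components`` (node lists) are sorted by size descending and contain
    only connected sets of >= 2 nodes; input genes with no induced edge are
    listed in ``isolated`` instead.  ``hubs[k]`` is the maximum-degree node
    of ``components[k]`` (ties broken lexicographically).
    """

    nodes: list[str]
    edges: list[tuple[str, str]]
    components: list[list[str]]
    hubs: list[str]
    degrees: dict[str, int]
    isolated: list[str]
    node_attributes: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for a, b in self.edges:
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge ({a!r}, {b!r}) leaves the induced node set")
        if sum(len(c) for c in self.components) + len(self.isolated) != len(node_set):
            raise ValueError("components plus isolated nodes must partition the set")

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        for node, attrs in self.node_attributes.items():
            if node in g:
                g.nodes[node].update(attrs)
        return g


def map_ids(genes: list[str], mapping: IdMapping) -> tuple[list[str], list[str]]:
    """Convert RAP ids to MSU ids, order- and multiplicity-preserving.

    Unmapped input ids are returned separately, never silently dropped.
    """
    mapped: list[str] = []
    unmapped: list[str] = []
    for g in genes:
        msu = mapping.rap_to_msu.get(g)
        if msu is None:
            unmapped.append(g)
        else:
            mapped.append(msu)
    if unmapped:
        logger.info("map_ids: %d id(s) had no MSU mapping", len(unmapped))
    return mapped, unmapped


def chromosome_distribution(genes: list[str]) -> tuple[pd.Series, list[str]]:
    """Count parseable locus ids per chromosome 1-12.

    Returns (counts indexed 1..12, list of unparseable ids); the counts sum
    to the number of parseable inputs, so total + unparseable = input size.
    """
    counts = pd.Series(0, index=pd.RangeIndex(1, N_CHROMOSOMES + 1,
                                              name="chromosome"), name="n_genes")
    unparseable: list[str] = []
    for g in genes:
        try:
            info = parse_rap_locus(g)
        except LocusParseError:
            unparseable.append(g)
        else:
            counts[info.chromosome] += 1
    if unparseable:
        logger.info("chromosome_distribution: %d unparseable id(s)", len(unparseable))
    return counts, unparseable


def induce_subnetwork(
    genes: list[str],
    edges: InteractionEdges,
    node_attributes: dict[str, dict] | None = None,
    hub_metric: str = "degree",
) -> SubnetworkReport:
    """Induce the interaction subgraph on a gene set.

    Edges with either endpoint outside the gene set are excluded; input
    genes with no remaining edge are reported as isolated.  Hubs are the
    maximum-degree node per component by default (``hub_metric=
    "betweenness"`` for the centrality alternative); the result is
    invariant to input gene order and edge orientation.
    """
    if hub_metric not in ("degree", "betweenness"):
        raise ValueError(f"unknown hub metric {hub_metric!r}")
    gene_set = set(genes)
    induced = [e for e in edges.edges if e[0] in gene_set and e[1] in gene_set]
    g = nx.Graph()
    g.add_nodes_from(sorted(gene_set))
    g.add_edges_from(induced)

    isolated = sorted(n for n in g.nodes if g.degree[n] == 0)
    comps = [sorted(c) for c in nx.connected_components(g) if len(c) >= 2]
    comps.sort(key=lambda c: (-len(c), c))
    hubs = []
    for comp in comps:
        if hub_metric == "degree":
            score = {n: g.degree[n] for n in comp}
        else:
            score = nx.betweenness_centrality(g.subgraph(comp))
        hubs.append(min(comp, key=lambda n: (-score[n], n)))
    degrees = {n: int(g.degree[n]) for n in g.nodes}
    return SubnetworkReport(
        nodes=sorted(gene_set),
        edges=sorted(induced),
        components=comps,
        hubs=hubs,
        degrees=degrees,
        isolated=isolated,
        node_attributes=dict(node_attributes or {}),
    )
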