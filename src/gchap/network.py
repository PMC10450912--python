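"""Haplotype networks over a gene's major gcHaps.

Nodes are major haplotypes (frequency and per-population composition
attached); edges connect the most similar haplotypes first, weighted by the
number of mutational differences (Hamming distance between allele strings).
The default construction is a deterministic minimum-spanning tree (Kruskal,
ties broken on the sorted label pair), optionally keeping equal-weight
alternative edges as "ambiguous" links and optionally refusing edges above a
parsimony connection limit, which may leave the network in several
components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from networkx.utils import UnionFind

from .core import GcHapTable, major_gchaps
from .io import InputError, PopulationPartition


def pairwise_hap_distance(haps: Sequence[str]) -> np.ndarray:
    """All-pairs Hamming distance (count of differing positions) between
    equal-length allele strings."""
    n = len(haps)
    length = len(haps[0]) if n else 0
    if any(len(h) != length for h in haps):
        raise InputError("pairwise_hap_distance: unequal allele-string lengths")
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = sum(a != b for a, b in zip(haps[i], haps[j]))
    return d


@dataclass
class HapNetwork:
    """Haplotype network: a networkx graph plus the node order used to
    build it.  Node attributes: ``frequency`` and (after annotation)
    ``composition``; edge attributes: ``mutations`` and ``ambiguous``."""

    gene_id: str
    graph: nx.Graph

    @property
    def n_components(self) -> int:
        return nx.number_connected_components(self.graph)

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            (self.gene_id, a, b, attrs["mutations"], attrs.get("ambiguous", False))
            for a, b, attrs in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["gene", "hapA", "hapB", "mutations", "ambiguous"])

    def write_graphml(self, path) -> None:
        g = self.graph.copy()
        for _, attrs in g.nodes(data=True):
            comp = attrs.pop("composition", None)
            if comp is not None:
                for pop, cnt in comp.items():
                    attrs[f"n_{pop}"] = int(cnt)
        nx.write_graphml(g, path)


def build_network(labels: Sequence[str], freqs: Sequence[float],
                  distances: np.ndarray, gene_id: str = "",
                  keep_ambiguous: bool = False,
                  connection_limit: int | None = None) -> HapNetwork:
    """Minimum-spanning haplotype network (Kruskal).

    Candidate edges are considered in order of increasing mutation count,
    ties broken by the lexicographically smaller sorted label pair; an edge
    is added iff it joins two distinct components.  With ``keep_ambiguous``
    an excluded edge whose weight equals the smallest weight connecting the
    same pair of components at the time of joining is kept, flagged
    ``ambiguous``.  With a ``connection_limit`` edges needing more than that
    many mutations are refused, possibly leaving several components.
    """
    labels = list(labels)
    if not labels:
        raise InputError("build_network: need >= 1 haplotype")
    if len(set(labels)) != len(labels):
        raise InputError("build_network: duplicate labels")
    d = np.asarray(distances)
    g = nx.Graph()
    for lab, f in zip(labels, freqs):
        g.add_node(lab, frequency=float(f))

    candidates = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            w = int(d[i, j])
            if connection_limit is not None and w > connection_limit:
                continue
            a, b = sorted((labels[i], labels[j]))
            candidates.append((w, a, b))
    candidates.sort()

    uf = UnionFind(labels)
    skipped: list[tuple[int, str, str]] = []
    for w, a, b in candidates:
        if uf[a] != uf[b]:
            uf.union(a, b)
            g.add_edge(a, b, mutations=w, ambiguous=False)
        else:
            skipped.append((w, a, b))

    if keep_ambiguous:
        # a skipped edge is an equal-weight alternative iff its weight equals
        # the heaviest edge on the tree path it would close (it belongs to
        # some minimum spanning tree)
        tree_edges = [(a, b, attrs) for a, b, attrs in g.edges(data=True)]
        tree = nx.Graph()
        tree.add_nodes_from(g.nodes)
        for a, b, attrs in tree_edges:
            tree.add_edge(a, b, mutations=attrs["mutations"])
        for w, a, b in skipped:
            path = nx.shortest_path(tree, a, b)
            path_max = max(tree.edges[u, v]["mutations"]
                           for u, v in zip(path, path[1:]))
            if w == path_max:
                g.add_edge(a, b, mutations=w, ambiguous=True)
    return HapNetwork(gene_id=gene_id, graph=g)


def major_hap_network(table: GcHapTable, scope: Sequence[str] | None = None,
                      major_threshold: float = 0.01,
                      keep_ambiguous: bool = False,
                      connection_limit: int | None = None) -> HapNetwork:
    """Build the network over a gene's major haplotypes in a scope."""
    p = table.hap_frequencies(scope)
    majors = major_gchaps(p, threshold=major_threshold)
    if not majors:
        raise InputError(f"gene {table.gene_id}: no major haplotype at "
                         f"threshold {major_threshold}")
    strings = [table.haplotypes[lab] for lab in majors]
    d = pairwise_hap_distance(strings)
    return build_network(majors, [float(p[lab]) for lab in majors], d,
                         gene_id=table.gene_id, keep_ambiguous=keep_ambiguous,
                         connection_limit=connection_limit)


def annotate_composition(network: HapNetwork, table: GcHapTable,
                         partition: PopulationPartition,
                         scope: Sequence[str] | None = None) -> HapNetwork:
    """Attach per-population carrier counts to every node.

    Every population of the partition appears in each node's composition
    mapping (zero when absent); counts sum to the node's carrier count in
    the scope.
    """
    pops = partition.populations
    for lab in network.graph.nodes:
        carriers = table.carriers(lab, scope)
        comp = {p: 0 for p in pops}
        for acc in carriers:
            pop = partition.population.get(acc)
            if pop is not None:
                comp[pop] += 1
        network.graph.nodes[lab]["composition"] = comp
        network.graph.nodes[lab]["n_carriers"] = len(carriers)
    return network
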