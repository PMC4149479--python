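"""Gene-network data model and descriptive statistics.

A :class:`GeneNetwork` is a directed graph over stable integer gene
identifiers (typically Entrez IDs).  Protein–protein interactions without an
obvious direction are stored as the two directed orientations of a reciprocal
pair, flagged undirected; signaling algorithms treat each orientation as an
ordinary directed edge, while summary statistics count the pair once.

With two encoded expression attractors (normal and cancer), nodes split into
*similarity* nodes (the two attractors agree) and *differential* nodes (they
disagree).  Couplings between unlike types transmit no signal, so the network
separates into independent similarity and differential subnetworks; the
:func:`partition_nodes` / :func:`effective_subnetworks` pair exposes that
decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np


class EdgeRecordError(ValueError):
    """A malformed edge record (non-integer ids, wrong arity)."""


@dataclass
class GeneNetwork:
    """Directed gene network with optional undirected (reciprocal) edges.

    Parameters
    ----------
    graph:
        The underlying directed graph; nodes are integer gene ids.
    undirected_pairs:
        Unordered node pairs whose two orientations represent one undirected
        interaction.
    annotations:
        Optional per-node boolean flags (e.g. ``kinase``).
    """

    graph: nx.DiGraph
    undirected_pairs: frozenset[frozenset[int]] = frozenset()
    annotations: dict[int, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.node_ids: np.ndarray = np.array(sorted(self.graph.nodes), dtype=np.int64)
        self.index: dict[int, int] = {int(n): i for i, n in enumerate(self.node_ids)}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_directed_edges(self) -> int:
        """Stored directed edges; each undirected pair contributes two."""
        return self.graph.number_of_edges()

    @property
    def n_undirected_edges(self) -> int:
        return len(self.undirected_pairs)

    @property
    def n_edges(self) -> int:
        """Interactions: directed edges with each reciprocal pair counted once."""
        return self.n_directed_edges - self.n_undirected_edges

    def in_degree(self, node: int) -> int:
        return self.graph.in_degree(node)

    def out_degree(self, node: int) -> int:
        return self.graph.out_degree(node)

    def sources(self) -> set[int]:
        """Nodes with zero indegree (all incoming orientations counted)."""
        return {n for n in self.graph.nodes if self.graph.in_degree(n) == 0}

    def sinks(self) -> set[int]:
        """Nodes with zero outdegree, ignoring self-loops."""
        out = set()
        for n in self.graph.nodes:
            k = self.graph.out_degree(n)
            if self.graph.has_edge(n, n):
                k -= 1
            if k == 0:
                out.add(n)
        return out

    def is_undirected_edge(self, u: int, v: int) -> bool:
        return frozenset((u, v)) in self.undirected_pairs

    def subnetwork(self, nodes: Iterable[int]) -> "GeneNetwork":
        nodes = set(nodes)
        sub = self.graph.subgraph(nodes).copy()
        pairs = frozenset(p for p in self.undirected_pairs if p <= nodes)
        ann = {n: f for n, f in self.annotations.items() if n in nodes}
        return GeneNetwork(sub, pairs, ann)


def build_network(
    edge_records: Sequence[tuple[int, int]],
    undirected_policy: bool = False,
    annotations: Mapping[int, bool] | None = None,
) -> GeneNetwork:
    """Build a :class:`GeneNetwork` from (source, target) id pairs.

    Duplicate records are dropped.  When ``undirected_policy`` is on,
    reciprocal pairs ``(u, v)``/``(v, u)`` with ``u != v`` are flagged as one
    undirected interaction (both orientations are kept in the graph).
    """
    if len(edge_records) == 0:
        raise EdgeRecordError("empty edge list")
    edges: set[tuple[int, int]] = set()
    for lineno, rec in enumerate(edge_records, start=1):
        try:
            s, t = rec
            s, t = int(s), int(t)
        except (TypeError, ValueError) as exc:
            raise EdgeRecordError(f"malformed edge record at entry {lineno}: {rec!r}") from exc
        if (isinstance(rec[0], float) and rec[0] != s) or (isinstance(rec[1], float) and rec[1] != t):
            raise EdgeRecordError(f"malformed edge record at entry {lineno}: {rec!r}")
        edges.add((s, t))
    g = nx.DiGraph()
    g.add_edges_from(edges)
    pairs: set[frozenset[int]] = set()
    if undirected_policy:
        for s, t in edges:
            if s != t and (t, s) in edges:
                pairs.add(frozenset((s, t)))
    return GeneNetwork(g, frozenset(pairs), dict(annotations or {}))


@dataclass
class NodePartition:
    """Similarity/differential split plus the structural node classes."""

    similarity: set[int]
    differential: set[int]
    sources: set[int]
    effective_sources: set[int]
    sinks: set[int]
    islets: set[int]

    @property
    def omega(self) -> set[int]:
        """Source and effective-source nodes (the set forced for full DAG control)."""
        return self.sources | self.effective_sources


def _same_type(partition_diff: set[int], u: int, v: int) -> bool:
    return (u in partition_diff) == (v in partition_diff)


def reduced_graph(net: GeneNetwork, differential: set[int]) -> nx.DiGraph:
    """Graph after deleting every edge joining a similarity and a differential node."""
    g = nx.DiGraph()
    g.add_nodes_from(net.graph.nodes)
    g.add_edges_from(
        (u, v) for u, v in net.graph.edges if _same_type(differential, u, v)
    )
    return g


def partition_nodes(net: GeneNetwork, attractors) -> NodePartition:
    """Classify nodes given a two-attractor (normal, cancer) pair.

    Similarity nodes have equal normal and cancer spins; mixed-type edges are
    effectively deleted, exposing effective sources (indegree becomes zero)
    and islets (differential nodes left with no couplings at all, self-loops
    aside).
    """
    if attractors.p != 2:
        raise ValueError("node partition requires a two-attractor set")
    xi_n, xi_c = attractors.spins("normal"), attractors.spins("cancer")
    differential = {int(n) for n in net.graph.nodes if xi_n[n] != xi_c[n]}
    similarity = set(int(n) for n in net.graph.nodes) - differential
    sources = net.sources()
    red = reduced_graph(net, differential)
    effective_sources = {
        n for n in red.nodes if red.in_degree(n) == 0 and n not in sources
    }
    islets = set()
    for n in differential:
        neighbors = (set(red.predecessors(n)) | set(red.successors(n))) - {n}
        if not neighbors:
            islets.add(n)
    return NodePartition(
        similarity=similarity,
        differential=differential,
        sources=sources,
        effective_sources=effective_sources,
        sinks=net.sinks(),
        islets=islets,
    )


def effective_subnetworks(net: GeneNetwork, attractors) -> list[set[int]]:
    """Weakly connected components of the similarity/differential subnetworks.

    The union of the returned node sets is the full node set; simulating a
    differential component alone reproduces its trajectory in the full
    two-attractor system, because mixed-type couplings vanish.
    Components are sorted by size descending (differential first on ties are
    not distinguished; use :func:`largest_differential_component` for runs).
    """
    part = partition_nodes(net, attractors)
    red = reduced_graph(net, part.differential)
    comps = [set(int(x) for x in c) for c in nx.weakly_connected_components(red)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def largest_differential_component(net: GeneNetwork, attractors) -> set[int]:
    """The largest weakly connected component made of differential nodes."""
    part = partition_nodes(net, attractors)
    best: set[int] = set()
    for comp in effective_subnetworks(net, attractors):
        if comp <= part.differential and len(comp) > len(best):
            best = comp
    return best


@dataclass
class NetworkStats:
    nodes: int
    edges: int
    sources: int
    sinks: int
    avg_outdegree: float
    max_outdegree: int
    max_indegree: int
    self_loops: int
    undirected_edges: int
    diameter_directed: int
    diameter_undirected: int
    max_cycle_cluster: int
    avg_clustering: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def network_stats(net: GeneNetwork) -> NetworkStats:
    """Descriptive statistics of the full network.

    The edge count and average outdegree count a reciprocal undirected pair
    once; diameters are computed on the largest weakly connected component,
    both on directed paths and on the undirected projection; the clustering
    coefficient is the directed-graph generalization (Fagiolo) averaged over
    nodes, with self-loops excluded.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    self_loops = sum(1 for n in g.nodes if g.has_edge(n, n))
    n_edges = net.n_edges
    sccs = [c for c in nx.strongly_connected_components(g)]
    max_scc = max((len(c) for c in sccs), default=0)
    if max_scc == 1:
        # single self-loop nodes are degenerate cycle clusters
        max_scc = 1 if self_loops else 0

    g_plain = g.copy()
    g_plain.remove_edges_from([(n, n) for n in g.nodes if g.has_edge(n, n)])
    clustering = nx.average_clustering(g_plain) if g_plain.number_of_edges() else 0.0

    wcc = max(nx.weakly_connected_components(g), key=len)
    sub = g.subgraph(wcc)
    und = sub.to_undirected()
    diam_und = nx.diameter(und) if und.number_of_nodes() > 1 else 0
    # directed diameter: longest finite directed shortest path on the WCC
    diam_dir = 0
    for _, dists in nx.all_pairs_shortest_path_length(sub):
        m = max(dists.values())
        if m > diam_dir:
            diam_dir = m

    return NetworkStats(
        nodes=net.n_nodes,
        edges=n_edges,
        sources=len(net.sources()),
        sinks=len(net.sinks()),
        avg_outdegree=n_edges / net.n_nodes,
        max_outdegree=max(d for _, d in g.out_degree()),
        max_indegree=max(d for _, d in g.in_degree()),
        self_loops=self_loops,
        undirected_edges=net.n_undirected_edges,
        diameter_directed=diam_dir,
        diameter_undirected=diam_und,
        max_cycle_cluster=max_scc,
        avg_clustering=float(clustering),
    )
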