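"""Deterministic generators of toy networks with planted control structure.

Every algorithm in the package is testable without external data through
three archetypes:

* a layered DAG whose root hub's control set is its entire downstream cone;
* a complete clique (optionally with self-loops, upstream intruder sources
  and a downstream tail chain) whose critical number follows the closed-form
  barrier argument N_c = ceil(n/2) when it has self-loops and no intruders;
* seeded random directed networks with a requested differential fraction,
  plus random strongly connected graphs for bound/oracle comparisons.

Attractor pairs default to all-differential (cancer = -normal) unless a
differential fraction is requested; the ~50% differential fraction default of
``make_random`` mirrors the rough similarity/differential split seen in real
expression data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .coupling import AttractorSet
from .network import GeneNetwork, build_network


@dataclass
class FixtureSpec:
    """Generator name, parameters and planted ground truth of a fixture."""

    generator: str
    params: dict[str, Any]
    seed: int
    truth: dict[str, Any] = field(default_factory=dict)


def _attractors_for(nodes, rng: np.random.Generator,
                    differential_fraction: float = 1.0) -> AttractorSet:
    nodes = sorted(int(n) for n in nodes)
    xi_n = {n: int(rng.choice([-1, 1])) for n in nodes}
    diff = rng.random(len(nodes)) < differential_fraction
    xi_c = {n: (-xi_n[n] if d else xi_n[n]) for n, d in zip(nodes, diff)}
    return AttractorSet({"normal": xi_n, "cancer": xi_c})


def make_dag(
    layers: int,
    fan: int,
    seed: int = 0,
    n_extra_sources: int = 0,
) -> tuple[GeneNetwork, AttractorSet, FixtureSpec]:
    """Layered out-tree: a hub (node 1) fans out ``fan`` children per node for
    ``layers`` levels; optional extra sources feed the hub.

    The hub's control set is the whole tree, so its planted impact is the
    tree size.  All nodes are differential.
    """
    if layers < 2:
        raise ValueError("layers must be >= 2")
    edges = []
    next_id = 2
    frontier = [1]
    for _ in range(layers - 1):
        new_frontier = []
        for parent in frontier:
            for _ in range(fan):
                edges.append((parent, next_id))
                new_frontier.append(next_id)
                next_id += 1
        frontier = new_frontier
    tree_size = next_id - 1
    for _ in range(n_extra_sources):
        edges.append((next_id, 1))
        next_id += 1
    net = build_network(edges)
    rng = np.random.default_rng(seed)
    attractors = _attractors_for(net.graph.nodes, rng, 1.0)
    spec = FixtureSpec(
        "dag", {"layers": layers, "fan": fan, "n_extra_sources": n_extra_sources},
        seed,
        truth={"hub": 1, "hub_impact": tree_size, "n_nodes": net.n_nodes,
               "cycle_clusters": 0},
    )
    return net, attractors, spec


def make_clique_cluster(
    n: int,
    self_loops: bool = True,
    intruders: int = 0,
    tail: int = 0,
    seed: int = 0,
) -> tuple[GeneNetwork, AttractorSet, FixtureSpec]:
    """Complete clique on nodes 1..n plus optional intruder sources and a
    downstream tail chain hanging off node 1.

    For a self-loop clique without intruders the planted critical number is
    ceil(n/2): forcing that many nodes leaves every free node with a field at
    or past the tie point, and tie randomness finishes the flip with
    probability one (even n).
    """
    if n < 2:
        raise ValueError("clique size must be >= 2")
    edges = [(i, j) for i in range(1, n + 1) for j in range(1, n + 1)
             if i != j or self_loops]
    next_id = n + 1
    for k in range(intruders):
        edges.append((next_id, 1 + (k % n)))
        next_id += 1
    prev = 1
    for _ in range(tail):
        edges.append((prev, next_id))
        prev = next_id
        next_id += 1
    net = build_network(edges)
    rng = np.random.default_rng(seed)
    attractors = _attractors_for(net.graph.nodes, rng, 1.0)
    truth: dict[str, Any] = {
        "cluster": list(range(1, n + 1)),
        "cluster_impact": n + tail,
    }
    if self_loops and intruders == 0:
        truth["n_c"] = -(-n // 2)  # ceil(n/2)
    spec = FixtureSpec(
        "clique",
        {"n": n, "self_loops": self_loops, "intruders": intruders, "tail": tail},
        seed,
        truth=truth,
    )
    return net, attractors, spec


def make_random(
    net_size: int,
    density: float,
    differential_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[GeneNetwork, AttractorSet]:
    """Seeded Erdős–Rényi-style directed network with a Bernoulli-sampled
    differential fraction."""
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    if not 0 <= differential_fraction <= 1:
        raise ValueError("differential_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    nodes = list(range(1, net_size + 1))
    edges = [
        (i, j)
        for i in nodes
        for j in nodes
        if i != j and rng.random() < density
    ]
    if not edges:  # guarantee a nonempty edge list
        i, j = rng.choice(nodes, size=2, replace=False)
        edges.append((int(i), int(j)))
    net = build_network(edges)
    attractors = _attractors_for(net.graph.nodes, rng, differential_fraction)
    return net, attractors


def make_random_scc(
    n: int,
    extra_edge_prob: float = 0.3,
    seed: int = 0,
    self_loop_prob: float = 0.0,
) -> tuple[GeneNetwork, AttractorSet]:
    """Random strongly connected digraph: a random Hamiltonian cycle plus
    independent extra edges.  All nodes differential."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(np.arange(1, n + 1))
    edges = [(int(perm[i]), int(perm[(i + 1) % n])) for i in range(n)]
    for i in range(1, n + 1):
        for j in range(1, n + 1):
            if i == j:
                if rng.random() < self_loop_prob:
                    edges.append((i, i))
            elif rng.random() < extra_edge_prob:
                edges.append((i, j))
    net = build_network(edges)
    attractors = _attractors_for(net.graph.nodes, rng, 1.0)
    return net, attractors
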