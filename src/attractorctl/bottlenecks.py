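"""Bottleneck detection, control sets, critical-set bounds and efficiencies.

A *size-1 bottleneck* is a node whose removal drops some other node's
indegree strictly below half of its original value; forcing the bottleneck
away from the cancer pattern then guarantees, in the worst case over tie
resolutions, that a cascade of downstream nodes switches too.  The
*bottleneck control set* B(i) collects that cascade by iterated halving
against original indegrees, and the *impact* I = |B| is the guaranteed flip
count.

Strongly connected subnetworks (*cycle clusters*) act as hysteretic
bottlenecks: their minimum indegree z sets an activation barrier, and the
*critical number* N_c is the smallest number of cluster nodes that must be
forced to guarantee the whole cluster flips.  Exact N_c requires subset
enumeration with simulation-based verification; the bound

    ceil(z/2)  <=  N_c  <=  min(|C|, |R_red ∪ U|)

(with R_red the critical set of the cluster in isolation and U the nodes
receiving intruder connections from outside) prunes that search, and the
clique-barrier overestimate  min(|C|, ceil(|C|/2) + |U|)  replaces the upper
limit when R_red is out of budget.

All computations here are structural/gauge-reduced: by the substitution
s_i = xi^c_i sigma_i the cancer pattern maps to all-(+1) and every coupling
to +1, so no attractor data is needed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from ._rng import tie_spins
from .network import GeneNetwork


# ---------------------------------------------------------------------------
# cycle clusters and size-1 bottlenecks


def cycle_clusters(net: GeneNetwork) -> list[set[int]]:
    """Maximal strongly connected components with >= 2 nodes, plus single
    nodes carrying a self-loop (degenerate clusters), sorted by size desc."""
    out = []
    for comp in nx.strongly_connected_components(net.graph):
        comp = {int(n) for n in comp}
        if len(comp) >= 2:
            out.append(comp)
        else:
            (n,) = comp
            if net.graph.has_edge(n, n):
                out.append(comp)
    out.sort(key=lambda c: (-len(c), min(c)))
    return out


def size1_bottlenecks(net: GeneNetwork) -> list[int]:
    """Nodes whose removal strictly halves some other node's indegree.

    With simple directed edges the test reduces to having a successor whose
    only input is the candidate.
    """
    g = net.graph
    out = []
    for v in g.nodes:
        for w in g.successors(v):
            if w == v:
                continue
            if g.in_degree(w) - 1 < g.in_degree(w) / 2:
                out.append(int(v))
                break
    return sorted(out)


def control_set(net: GeneNetwork, seed_members) -> tuple[set[int], int]:
    """Iterated-halving control set and impact of a node or cluster.

    Starting from the seed members, repeatedly append every node whose
    current indegree (after removing the set) is strictly less than half its
    indegree in the pristine network, until no node qualifies.
    """
    g = net.graph
    B = {int(n) for n in seed_members}
    if not B:
        raise ValueError("seed_members must be nonempty")
    orig = dict(g.in_degree())
    # current indegree = predecessors not yet in B
    changed = True
    while changed:
        changed = False
        for w in g.nodes:
            if w in B:
                continue
            cur = sum(1 for p in g.predecessors(w) if p not in B)
            if cur < orig[w] / 2:
                B.add(int(w))
                changed = True
    return B, len(B)


@dataclass
class BottleneckRecord:
    """A bottleneck (single node or cycle cluster) with its control data."""

    members: tuple[int, ...]
    control: set[int]
    impact: int
    is_bottleneck: bool = True
    nc_lower: int | None = None
    nc_upper: int | None = None
    n_c: int | None = None
    e_crit: float | None = None
    e_crit_interval: tuple[float, float] | None = None
    e_opt: float | None = None
    e_opt_subset: tuple[int, ...] = ()

    @property
    def size(self) -> int:
        return len(self.members)


def size_k_bottlenecks(net: GeneNetwork, clusters: list[set[int]] | None = None) -> list[BottleneckRecord]:
    """One record per cycle cluster; the halving test against nodes outside
    the cluster sets ``is_bottleneck``, and the control set is computed
    regardless (an isolated cluster still flips itself: impact = |C|)."""
    if clusters is None:
        clusters = cycle_clusters(net)
    g = net.graph
    orig = dict(g.in_degree())
    records = []
    for C in clusters:
        is_bn = False
        for w in g.nodes:
            if w in C:
                continue
            cur = sum(1 for p in g.predecessors(w) if p not in C)
            if cur < orig[w] / 2:
                is_bn = True
                break
        B, impact = control_set(net, C)
        records.append(
            BottleneckRecord(
                members=tuple(sorted(C)), control=B, impact=impact, is_bottleneck=is_bn
            )
        )
    records.sort(key=lambda r: (-r.impact, r.members))
    return records


# ---------------------------------------------------------------------------
# gauge-reduced simulation used for verification and flip counting


def _forced_dynamics(
    adj: np.ndarray,
    node_ids: np.ndarray,
    forced: np.ndarray,
    ext: np.ndarray,
    seed: int,
    replicate: int,
    max_steps: int,
) -> tuple[np.ndarray, bool]:
    """Synchronous T=0 run in the cancer gauge (start all +1, couplings +1).

    ``forced`` marks nodes clamped at -1; ``ext`` is a constant field (e.g.
    +1 per intruder connection).  Returns the steady state (element of the
    detected cycle) and a convergence flag.
    """
    n = len(node_ids)
    sigma = np.ones(n, dtype=np.int8)
    sigma[forced] = -1
    # recurrence only counts along tie-free stretches: a zero-field node makes
    # the step stochastic, so a revisited state is not evidence of a cycle
    seen = {sigma.tobytes(): 0}
    for t in range(max_steps):
        h = adj @ sigma.astype(np.float64) + ext
        new = np.sign(h).astype(np.int8)
        zero = (new == 0) & ~forced
        had_tie = bool(zero.any())
        if had_tie:
            new[zero] = tie_spins(node_ids[zero], t, seed, replicate)
        new[forced] = -1
        sigma = new
        key = sigma.tobytes()
        if had_tie:
            seen = {key: t + 1}
            continue
        if key in seen:
            return sigma, True
        seen[key] = t + 1
    return sigma, False


def verify_control(
    net: GeneNetwork,
    cluster: set[int],
    candidate: set[int],
    intruder_field: bool = True,
    replicates: int = 50,
    seed: int = 0,
    max_steps: int = 200,
) -> bool:
    """Does forcing ``candidate`` guarantee the whole cluster flips?

    The cluster is simulated in the cancer gauge with external (intruder)
    inputs held in the cancer direction — the worst case.  Success requires
    every replicate to settle with all cluster nodes flipped; the probability-1
    tie cascades of even cliques are certified empirically this way.
    """
    nodes = sorted(cluster)
    pos = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n))
    ext = np.zeros(n)
    g = net.graph
    for v in nodes:
        for u in g.predecessors(v):
            if u in cluster:
                adj[pos[v], pos[u]] = 1.0
            elif intruder_field:
                ext[pos[v]] += 1.0
    forced = np.zeros(n, dtype=bool)
    for c in candidate:
        forced[pos[c]] = True
    ids = np.array(nodes, dtype=np.int64)
    for r in range(replicates):
        sigma, converged = _forced_dynamics(adj, ids, forced, ext, seed, r, max_steps)
        if not converged or not np.all(sigma == -1):
            return False
    return True


def flipped_count(
    net: GeneNetwork,
    targets: set[int],
    replicates: int = 20,
    seed: int = 0,
    max_steps: int = 200,
) -> float:
    """Replicate-averaged number of nodes flipped away from the cancer
    pattern when ``targets`` are forced, with network sources pinned at the
    cancer state (gauge-reduced full-network simulation)."""
    nodes = sorted(int(n) for n in net.graph.nodes)
    pos = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    g = net.graph
    adj = np.zeros((n, n))
    for v in nodes:
        for u in g.predecessors(v):
            adj[pos[v], pos[u]] = 1.0
    ext = np.zeros(n)
    for s in net.sources():
        if s not in targets:
            ext[pos[s]] += 0.5  # source pin, cancer direction
    forced = np.zeros(n, dtype=bool)
    for t in targets:
        forced[pos[t]] = True
    ids = np.array(nodes, dtype=np.int64)
    counts = []
    for r in range(replicates):
        sigma, _ = _forced_dynamics(adj, ids, forced, ext, seed, r, max_steps)
        counts.append(int(np.sum(sigma == -1)))
    return float(np.mean(counts))


# ---------------------------------------------------------------------------
# theorem inputs, bounds and critical-set search


@dataclass
class TheoremInputs:
    """Quantities entering the critical-number bound for a cycle cluster."""

    cluster: set[int]
    externally_influenced: set[int]  # U: cluster nodes with inbound intruder edges
    intruder_connections: set[tuple[int, int]]  # W: those edges
    z: int  # minimum internal indegree (intruders ignored, self-loops counted)
    reduced_critical_sets: list[set[int]] = field(default_factory=list)
    reduced_nc: int | None = None


@dataclass
class CriticalSetResult:
    sets: list[set[int]]
    n_c: int | None
    tested: int
    replicates: int
    exhausted: bool = False


@dataclass
class BoundsResult:
    lower: int
    upper: int
    eq_overestimate_used: bool
    inputs: TheoremInputs


def theorem_inputs(
    net: GeneNetwork,
    cluster: set[int],
    search_budget: int = 5000,
    replicates: int = 30,
    seed: int = 0,
) -> TheoremInputs:
    """Compute U, W, z and (budget permitting) the reduced critical sets of a
    cluster treated in isolation (intruder connections ignored)."""
    g = net.graph
    U, W = set(), set()
    z = None
    for v in cluster:
        k_int = sum(1 for u in g.predecessors(v) if u in cluster)
        z = k_int if z is None else min(z, k_int)
        for u in g.predecessors(v):
            if u not in cluster:
                U.add(int(v))
                W.add((int(u), int(v)))
    res = critical_set_search(
        net, cluster, budget=search_budget, intruder_field=False,
        replicates=replicates, seed=seed,
    )
    return TheoremInputs(
        cluster=set(cluster),
        externally_influenced=U,
        intruder_connections=W,
        z=int(z or 0),
        reduced_critical_sets=res.sets,
        reduced_nc=res.n_c,
    )


def critical_set_search(
    net: GeneNetwork,
    cluster: set[int],
    budget: int = 5000,
    intruder_field: bool = True,
    replicates: int = 30,
    seed: int = 0,
    size_range: tuple[int, int] | None = None,
) -> CriticalSetResult:
    """Enumerate candidate subsets in increasing cardinality and verify each
    by simulation; returns every minimal controlling subset found at the
    first successful size.

    ``budget`` caps the number of candidate subsets verified; exhaustion
    before a success yields a flagged partial result (n_c unknown).
    """
    nodes = sorted(cluster)
    if size_range is None:
        z = min(
            sum(1 for u in net.graph.predecessors(v) if u in cluster) for v in cluster
        )
        size_range = (max(1, math.ceil(z / 2)), len(nodes))
    tested = 0
    for k in range(size_range[0], size_range[1] + 1):
        winners: list[set[int]] = []
        for cand in itertools.combinations(nodes, k):
            if tested >= budget:
                return CriticalSetResult(winners, k if winners else None, tested,
                                         replicates, exhausted=True)
            tested += 1
            if verify_control(net, cluster, set(cand), intruder_field, replicates, seed):
                winners.append(set(cand))
        if winners:
            return CriticalSetResult(winners, k, tested, replicates)
    return CriticalSetResult([], None, tested, replicates, exhausted=True)


def theorem_bounds(
    net: GeneNetwork,
    cluster: set[int],
    search_budget: int = 5000,
    replicates: int = 30,
    seed: int = 0,
    inputs: TheoremInputs | None = None,
) -> BoundsResult:
    """Interval guaranteed to contain the critical number N_c of a cluster.

    Lower limit: ceil(z/2) — forcing fewer nodes leaves every uncontrolled
    node with a field in the cancer direction.  Upper limit: the reduced
    critical set plus the externally influenced nodes, |R_red ∪ U|, taking
    the R_red with the largest overlap with U; when no reduced critical set
    is available within budget, the clique-barrier overestimate
    ceil(|C|/2) + |U| is used instead (flagged).  Both limits are capped at
    |C|.
    """
    if inputs is None:
        inputs = theorem_inputs(net, cluster, search_budget, replicates, seed)
    nC = len(cluster)
    lower = max(1, math.ceil(inputs.z / 2))
    U = inputs.externally_influenced
    if inputs.reduced_critical_sets:
        upper = min(len(R | U) for R in inputs.reduced_critical_sets)
        upper = min(nC, upper)
        overestimate = False
    else:
        upper = min(nC, math.ceil(nC / 2) + len(U))
        overestimate = True
    upper = max(upper, lower)
    return BoundsResult(lower, upper, overestimate, inputs)


def clique_overestimate(cluster_size: int, n_externally_influenced: int) -> int:
    """Upper limit on N_c assuming the worst-case (clique) barrier."""
    return min(cluster_size, math.ceil(cluster_size / 2) + n_externally_influenced)


# ---------------------------------------------------------------------------
# efficiencies


def internal_size1_bottlenecks(net: GeneNetwork, cluster: set[int]) -> list[int]:
    """Size-1 bottlenecks of the cluster's nodes, ranked by full-network
    impact (descending, ties by id)."""
    inside = [n for n in size1_bottlenecks(net) if n in cluster]
    if not inside:  # fall back to all cluster nodes by impact
        inside = sorted(cluster)
    impacts = {n: control_set(net, {n})[1] for n in inside}
    return sorted(inside, key=lambda n: (-impacts[n], n))


def efficiencies(
    record: BottleneckRecord,
    net: GeneNetwork,
    replicates: int = 20,
    seed: int = 0,
    max_prefix: int | None = None,
    compute_bounds: bool = True,
    bounds_budget: int = 2000,
) -> BottleneckRecord:
    """Attach critical and optimal efficiencies to a bottleneck record.

    Critical efficiency e_crit = impact / N_c (an interval when only bounds
    on N_c are known).  Optimal efficiency e_opt maximizes flipped nodes per
    fixed node over nested prefixes of the cluster's internal size-1
    bottlenecks; for a size-1 bottleneck e_opt equals its impact.
    """
    if record.size == 1:
        record.n_c = 1
        record.nc_lower = record.nc_upper = 1
        record.e_crit = float(record.impact)
        record.e_opt = float(record.impact)
        record.e_opt_subset = record.members
        return record

    cluster = set(record.members)
    if compute_bounds and (record.nc_lower is None or record.nc_upper is None):
        bounds = theorem_bounds(net, cluster, search_budget=bounds_budget,
                                replicates=replicates, seed=seed)
        record.nc_lower, record.nc_upper = bounds.lower, bounds.upper
        if not bounds.eq_overestimate_used and bounds.inputs.reduced_nc is not None and not bounds.inputs.externally_influenced:
            record.n_c = bounds.inputs.reduced_nc
    if record.n_c is not None:
        record.e_crit = record.impact / record.n_c
    if record.nc_lower is not None and record.nc_upper is not None:
        record.e_crit_interval = (
            record.impact / record.nc_upper,
            record.impact / record.nc_lower,
        )

    ranked = internal_size1_bottlenecks(net, cluster)
    if max_prefix is not None:
        ranked = ranked[:max_prefix]
    best, best_j = -math.inf, 0
    for j in range(1, len(ranked) + 1):
        flips = flipped_count(net, set(ranked[:j]), replicates=replicates, seed=seed)
        e = flips / j
        if e > best:
            best, best_j = e, j
    record.e_opt = float(best)
    record.e_opt_subset = tuple(ranked[:best_j])
    return record
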