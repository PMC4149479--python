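"""Bottlenecks, control sets, critical-set search and the N_c bounds.

Independent oracles used here:

* guaranteed flips — simulate the cancer-gauge dynamics with every tie
  resolved *toward* the cancer state.  Because the gauge dynamics are
  monotone, this adversarial trajectory dominates all tie policies, so the
  nodes it flips are exactly the nodes guaranteed to flip.
* critical number — enumerate subsets by increasing size and check control
  with an independently coded replicate simulation.
"""

import itertools

import numpy as np
import pytest

from attractorctl import (
    build_network,
    control_set,
    critical_set_search,
    cycle_clusters,
    efficiencies,
    size1_bottlenecks,
    size_k_bottlenecks,
    theorem_bounds,
    theorem_inputs,
)
from attractorctl.bottlenecks import clique_overestimate
from attractorctl.synth import make_clique_cluster, make_dag, make_random_scc


# --------------------------------------------------------------------------
# oracles


def adversarial_flips(net, forced):
    """Deterministic worst-case simulation: ties resolve to the cancer state.

    Returns the set of nodes that end (and stay) flipped; by monotonicity of
    the ferromagnetic gauge dynamics these are the guaranteed switches.
    """
    nodes = sorted(int(n) for n in net.graph.nodes)
    pos = {n: i for i, n in enumerate(nodes)}
    g = net.graph
    adj = np.zeros((len(nodes), len(nodes)))
    for v in nodes:
        for u in g.predecessors(v):
            adj[pos[v], pos[u]] = 1.0
    ext = np.zeros(len(nodes))
    for s in net.sources():
        if s not in forced:
            ext[pos[s]] += 0.5  # pin at cancer
    sigma = np.ones(len(nodes))
    for f in forced:
        sigma[pos[f]] = -1
    for _ in range(2 * len(nodes) + 5):
        h = adj @ sigma + ext
        new = np.where(h > 0, 1.0, np.where(h < 0, -1.0, 1.0))  # tie -> cancer
        for f in forced:
            new[pos[f]] = -1
        if np.array_equal(new, sigma):
            break
        sigma = new
    return {n for n in nodes if sigma[pos[n]] == -1}


def oracle_controls(net, cluster, candidate, replicates=20, max_steps=80):
    """Replicate-simulation check that forcing ``candidate`` flips all of
    ``cluster`` (independent coding, numpy RNG ties, intruders at cancer)."""
    nodes = sorted(cluster)
    pos = {n: i for i, n in enumerate(nodes)}
    g = net.graph
    adj = np.zeros((len(nodes), len(nodes)))
    ext = np.zeros(len(nodes))
    for v in nodes:
        for u in g.predecessors(v):
            if u in cluster:
                adj[pos[v], pos[u]] = 1.0
            else:
                ext[pos[v]] += 1.0
    forced = np.array([n in candidate for n in nodes])
    for r in range(replicates):
        rng = np.random.default_rng(10_000 + r)
        sigma = np.ones(len(nodes))
        sigma[forced] = -1
        settled = False
        for _ in range(max_steps):
            h = adj @ sigma + ext
            new = np.sign(h)
            zeros = new == 0
            new[zeros] = rng.choice([-1.0, 1.0], size=int(zeros.sum()))
            new[forced] = -1
            if np.array_equal(new, sigma) and not zeros.any():
                settled = True
                break
            sigma = new
        if not (settled and np.all(sigma == -1)):
            return False
    return True


def oracle_nc(net, cluster, replicates=20):
    nodes = sorted(cluster)
    for k in range(1, len(nodes) + 1):
        for cand in itertools.combinations(nodes, k):
            if oracle_controls(net, cluster, set(cand), replicates):
                return k
    return len(nodes)


def random_dag(n, rng):
    """Random DAG on nodes 1..n with edges respecting a random order."""
    order = rng.permutation(np.arange(1, n + 1))
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.4:
                edges.append((int(order[i]), int(order[j])))
    if not edges:
        edges = [(int(order[0]), int(order[1]))]
    return build_network(edges)


# --------------------------------------------------------------------------
# cycle clusters and size-1 bottlenecks


class TestCycleClusters:
    def test_chain_has_none(self, chain_net):
        assert cycle_clusters(chain_net) == []

    def test_four_cycle(self):
        net = build_network([(1, 2), (2, 3), (3, 4), (4, 1)])
        assert cycle_clusters(net) == [{1, 2, 3, 4}]

    def test_self_loop_singleton_is_degenerate_cluster(self):
        net = build_network([(1, 2), (2, 2)])
        assert cycle_clusters(net) == [{2}]


class TestSize1Bottlenecks:
    def test_chain_interior(self, chain_net):
        assert size1_bottlenecks(chain_net) == [1, 2]

    def test_diamond_half_is_not_strict(self, diamond_net):
        # removing node 2 leaves node 4 with exactly half its inputs
        assert 2 not in size1_bottlenecks(diamond_net)
        assert size1_bottlenecks(diamond_net) == [1]

    def test_isolated_sink_is_not_a_bottleneck(self):
        net = build_network([(1, 2)])
        assert 2 not in size1_bottlenecks(net)


class TestControlSet:
    def test_chain_cascade(self, chain_net):
        B, impact = control_set(chain_net, {1})
        assert B == {1, 2, 3}
        assert impact == 3

    def test_diamond_cascade(self, diamond_net):
        B, impact = control_set(diamond_net, {1})
        assert B == {1, 2, 3, 4}
        assert impact == 4

    def test_sink_impact_is_one(self, chain_net):
        _, impact = control_set(chain_net, {3})
        assert impact == 1

    def test_monotone_in_seed(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            net = random_dag(7, rng)
            nodes = sorted(int(n) for n in net.graph.nodes)
            a = set(rng.choice(nodes, size=2, replace=False).tolist())
            b = a | {int(rng.choice(nodes))}
            Ba, _ = control_set(net, a)
            Bb, _ = control_set(net, b)
            assert Ba <= Bb

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_impact_equals_guaranteed_flips_all_small_dags(self, n):
        # every DAG on n labeled nodes in topological order 1..n
        pairs = [(i, j) for i in range(1, n + 1) for j in range(i + 1, n + 1)]
        for mask in range(1, 2 ** len(pairs)):
            edges = [p for b, p in enumerate(pairs) if mask >> b & 1]
            net = build_network(edges)
            for v in net.graph.nodes:
                _, impact = control_set(net, {int(v)})
                assert impact == len(adversarial_flips(net, {int(v)}))

    def test_impact_equals_guaranteed_flips_random_dags(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            net = random_dag(int(rng.integers(5, 9)), rng)
            for v in net.graph.nodes:
                _, impact = control_set(net, {int(v)})
                assert impact == len(adversarial_flips(net, {int(v)}))


class TestSizeKBottlenecks:
    def test_cycle_feeding_chain(self):
        net = build_network(
            [(1, 2), (2, 3), (3, 4), (4, 1), (4, 5), (5, 6), (6, 7)]
        )
        recs = size_k_bottlenecks(net)
        assert len(recs) == 1
        assert recs[0].members == (1, 2, 3, 4)
        assert recs[0].impact == 7
        assert recs[0].is_bottleneck

    def test_isolated_cycle_impact_is_itself(self):
        net = build_network([(1, 2), (2, 3), (3, 4), (4, 1)])
        recs = size_k_bottlenecks(net)
        assert recs[0].impact == 4
        assert not recs[0].is_bottleneck  # nothing downstream to halve

    def test_redundant_inner_bottleneck_is_covered(self, chain_net):
        # node 2 lies in the control set of node 1: fixing 1 fixes 2
        B, _ = control_set(chain_net, {1})
        assert 2 in B


class TestTheorem:
    def test_isolated_clique_inputs(self):
        net, _, _ = make_clique_cluster(5, self_loops=True)
        ti = theorem_inputs(net, set(range(1, 6)), search_budget=50)
        assert ti.externally_influenced == set()
        assert ti.intruder_connections == set()
        assert ti.z == 5

    def test_external_edge_creates_intruder(self):
        net, _, _ = make_clique_cluster(5, self_loops=True, intruders=1)
        ti = theorem_inputs(net, set(range(1, 6)), search_budget=50)
        assert ti.externally_influenced == {1}
        assert len(ti.intruder_connections) == 1
        assert ti.z == 5  # intruder connections ignored for z

    @pytest.mark.parametrize("n,expected", [(5, 3), (4, 2)])
    def test_clique_oracle_critical_number(self, n, expected):
        net, _, spec = make_clique_cluster(n, self_loops=True)
        cluster = set(range(1, n + 1))
        assert spec.truth["n_c"] == expected
        assert oracle_nc(net, cluster) == expected
        res = critical_set_search(net, cluster, replicates=30, seed=1)
        assert res.n_c == expected
        b = theorem_bounds(net, cluster, seed=1)
        assert b.lower <= expected <= b.upper

    def test_four_cycle_single_driver(self):
        net = build_network([(1, 2), (2, 3), (3, 4), (4, 1)])
        res = critical_set_search(net, {1, 2, 3, 4}, replicates=20)
        assert res.n_c == 1

    def test_bridged_triangles_search_matches_oracle(self):
        edges = [(1, 2), (2, 3), (3, 1), (4, 5), (5, 6), (6, 4), (3, 4), (6, 1)]
        net = build_network(edges)
        cluster = set(range(1, 7))
        assert cycle_clusters(net) == [cluster]
        res = critical_set_search(net, cluster, replicates=25, seed=2)
        assert res.n_c == oracle_nc(net, cluster)

    def test_bounds_contain_oracle_on_random_sccs(self):
        hits = 0
        for seed in range(12):
            n = 4 + seed % 4
            net, _ = make_random_scc(n, extra_edge_prob=0.3, seed=seed,
                                     self_loop_prob=0.3)
            cluster = max(cycle_clusters(net), key=len)
            nc = oracle_nc(net, cluster, replicates=15)
            b = theorem_bounds(net, cluster, replicates=25, seed=seed)
            assert b.lower <= nc <= b.upper, (seed, nc, b.lower, b.upper)
            hits += 1
        assert hits == 12

    def test_overestimate_dominates_reduced_upper(self):
        for seed in range(8):
            net, _ = make_random_scc(5 + seed % 3, extra_edge_prob=0.4, seed=seed)
            cluster = max(cycle_clusters(net), key=len)
            b = theorem_bounds(net, cluster, replicates=20, seed=seed)
            over = clique_overestimate(len(cluster),
                                       len(b.inputs.externally_influenced))
            if not b.eq_overestimate_used:
                assert over >= b.upper

    def test_budget_exhaustion_flags_partial(self):
        # restrict the search below the true critical size: no set controls
        net, _, _ = make_clique_cluster(6, self_loops=True)
        res = critical_set_search(net, set(range(1, 7)), budget=100,
                                  replicates=5, size_range=(1, 2))
        assert res.exhausted
        assert res.n_c is None
        assert res.sets == []


class TestEfficiencies:
    def test_size1_optimal_equals_impact(self, chain_net):
        from attractorctl.bottlenecks import BottleneckRecord

        B, impact = control_set(chain_net, {1})
        rec = BottleneckRecord(members=(1,), control=B, impact=impact)
        rec = efficiencies(rec, chain_net)
        assert rec.e_opt == 3.0
        assert rec.e_crit == 3.0
        assert rec.n_c == 1

    def test_cluster_efficiency_interval(self):
        net, _, _ = make_clique_cluster(4, self_loops=True, tail=3)
        rec = size_k_bottlenecks(net)[0]
        rec = efficiencies(rec, net, replicates=10, seed=0)
        assert rec.impact == 7
        lo, hi = rec.e_crit_interval
        assert lo <= rec.impact / 2 <= hi  # true N_c = 2
        assert rec.e_opt is not None and rec.e_opt > 0
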