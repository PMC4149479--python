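# Methods

## Model

Genes are binary spins σ_i ∈ {−1, +1} on a directed network (self-loops
allowed; undirected protein–protein edges are stored as both orientations of
a reciprocal pair). Attractor patterns — binarized expression profiles of a
normal and a cancer cell type — are stored Hopfield-style in couplings
restricted to the edge set. With the 1/p normalization every nonzero
coupling has unit magnitude, which makes degree-based arguments (halving
tests, activation barriers) exact. J_ij denotes the influence of node j on
node i, so an edge-file row (source, target) populates J[target, source];
this orientation is used everywhere.

Dynamics are zero-temperature: σ_i(t+1) = sign(h_i(t)), with h_i the summed
incoming couplings times spins plus any external field, and a fair random
spin when h_i = 0. Only T = 0 is supported; the update scheme is synchronous
by default (asynchronous single-node updates in seeded random order are
available; they terminate at fixed points on the networks treated here).
Source and effective-source nodes are held at their initial spins by a
sub-threshold pin field of half a coupling unit — strong enough to break the
zero-field tie, too weak to overrule any incoming coupling — and lose the
pin when directly targeted. Control (drug) fields have magnitude equal to
the node's total incoming coupling weight plus one unit, so a forced spin
can never be overturned.

In the two-pattern system a coupling is exactly zero when its endpoints are
of unlike similarity/differential type. The network therefore separates into
non-interacting similarity and differential subnetworks, and simulations of
the differential subnetwork alone reproduce the full system's differential
trajectories step for step. This equivalence is exact in this implementation
because tie randomness is keyed per (seed, replicate, node id, time step)
through a counter-based hash (SplitMix64 finalizer), not drawn from a shared
stream whose consumption order would depend on which nodes are simulated.
Derived seeds stay below 2^31.

## Observables

The magnetization along pattern μ is m^μ(t) = (1/N) Σ ξ^μ_i σ_i(t). All
final magnetizations are normalized by the full network size even when only
a subnetwork is simulated; unsimulated nodes are assumed to remain at the
pattern the run started in. Steady values average over the detected limit
cycle (period one for a fixed point). Recurrence of a state only counts as
a fixed point or cycle along tie-free stretches: a zero-field node makes the
step stochastic, so a revisited state is no evidence of periodicity and the
recurrence window is reset. Runs that fail to settle within `max_steps`
(default 500) are flagged and the trailing window is averaged instead.
Replicate averaging (each replicate perturbing the tie hash) handles the
remaining tie-induced variance.

## Bottlenecks and critical numbers

Size-1 bottlenecks, control sets and impacts follow the iterated
strict-halving rule against pristine-network indegrees. Self-loops count
toward indegree, and each orientation of an undirected pair counts as a
directed edge in all degree-based tests (summary statistics, by contrast,
count a reciprocal pair once — the convention under which edge counts and
average outdegree are mutually consistent). Single nodes carrying a
self-loop are reported as degenerate cycle clusters; this affects reporting
only.

For a cycle cluster C, z is the minimum indegree over internal edges only
(intruder connections from outside C are ignored; self-loops counted). The
critical number N_c is bounded below by ⌈z/2⌉ — forcing fewer nodes leaves
every free node with a strictly cancer-directed field — and above by
min(|C|, |R_red ∪ U|), where R_red is a critical set of the isolated cluster
and U the externally influenced nodes; among multiple minimal R_red the one
minimizing |R_red ∪ U| is used. When the reduced search exceeds its budget
the clique-barrier overestimate min(|C|, ⌈|C|/2⌉ + |U|) replaces the upper
limit and is flagged. For a self-loop clique without intruders the closed
form N_c = ⌈n/2⌉ holds (odd n deterministic; even n settles through
probability-1 tie cascades), and the synthetic clique fixtures plant it as
ground truth.

"Guaranteed control" of a candidate set is certified empirically: every one
of R seeded replicates (default 30–50 in the search paths) must settle with
the whole cluster flipped, external inputs held in the cancer direction as
the worst case. This is a probabilistic certificate — exact for the odd
cases, probability-1-in-the-limit for even-clique tie cascades. The test
suite cross-checks it with an independently coded oracle, including a
deterministic adversarial-tie simulation whose monotonicity makes the
guaranteed-flip set exact on DAGs.

Critical efficiency is impact/N_c (an interval when only bounds are known).
Optimal efficiency maximizes simulated flips per fixed node over nested
prefixes of the cluster's internal size-1 bottlenecks ranked by impact; full
subset maximization would be exponential and is out of scope. For a size-1
bottleneck the optimal efficiency equals its impact.

## Strategies

All strategies restrict candidates to differential nodes (similarity nodes
are never deliberately targeted), exclude sinks from the candidate pool
(impact one; they are still simulated), and optionally intersect with an
annotation flag (kinases) and the inhibit-only filter (cancer spin +1).
When a two-pattern run is restricted to the largest weakly connected
differential component, sinks are the effective sinks of that component.

- *Efficiency-ranked*: candidates sorted by optimal efficiency (impact for
  single nodes), fixed in order; a candidate inside an already-fixed
  bottleneck's control set is skipped. The mixed variant lets each cycle
  cluster compete at its optimal efficiency with its achieving prefix.
- *best+1*: greedy; the default seed is the highest-impact size-1
  bottleneck. Candidate evaluations use a reduced replicate count
  (`replicates_search`, default 100); accepted prefixes are re-evaluated at
  `replicates_final` (default 1000; figure-grade runs would use 10,000).
  Stopping is by target budget; a no-improvement stop is available.
- *Monte Carlo*: the evaluation budget is split evenly across target counts
  k; per k, seeded uniform k-subsets without replacement (full enumeration
  when the budget covers the space), keeping the best. The sampling protocol
  is a deliberate design choice — the simplest faithful baseline.
- *Exhaustive*: all k-subsets, refused above a configured budget.

Ties anywhere (equal impact, equal magnetization) break toward the lowest
node id for determinism.

## Synthetic data

The generators emulate the archetypes the method is designed around: layered
DAGs with a hub whose control set is its downstream cone; cliques with
optional self-loops, intruder sources and tail chains, planting the
closed-form N_c; Erdős–Rényi-style directed networks with a Bernoulli
differential fraction (default 0.5, matching the roughly half-similarity
split seen in real expression comparisons); and random strongly connected
graphs (Hamiltonian cycle plus noise edges) for oracle comparisons. Fixture
files are emitted in the same TSV dialect as real inputs so the readers are
exercised by the test suite. The generators do **not** reproduce the degree
distributions, hierarchy or density of real interactomes; passing tests
certify the algorithms' correctness and contracts, not biological
performance on a specific network.

Problem sizes in the shipped tests and acceptance script (12–40 node
networks, 40–100 fixtures, clusters up to 10 nodes for enumeration, 200
replicates for reported curves) are chosen to keep a full run at desk scale
while leaving every code path exercised; all counts are configurable
upward.

## Limitations

- Genes are strictly binary and all edges share one weight and one time
  scale; weighted or delayed signaling is out of scope.
- Finite-temperature dynamics are not implemented (T = 0 only).
- The mapping from magnetization to cell viability is unknown and not
  modeled; results are reported as magnetizations.
- Exact critical sets beyond the enumeration budget are not computed — only
  bounded.
- Simulation-based control verification is probabilistic; pathological
  clusters whose control hinges on very rare tie sequences could in
  principle be misclassified at low replicate counts.
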