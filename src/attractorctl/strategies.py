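"""Target-selection strategies and the magnetization-vs-targets curve.

All strategies pick targets only among *differential* nodes (forcing a
similarity node would damage normal cells too), optionally further restricted
to annotated (e.g. kinase) nodes and to *inhibitable* nodes — those expressed
in the cancer state (cancer spin +1) that a drug can only turn off.  Sinks
are excluded from the candidate pool (their impact is one) but remain part of
every simulation.

Strategies:

* efficiency-ranked (pure / mixed) — fix bottlenecks in order of optimal
  efficiency; *pure* uses size-1 bottlenecks only, *mixed* interleaves cycle
  clusters' optimal prefixes at their efficiency rank.
* best+1 — greedy: repeatedly append the single candidate that most lowers
  the replicate-averaged cancer magnetization.
* Monte Carlo — per target count k, keep the best of a budget of random
  k-subsets.
* exhaustive — evaluate every k-subset (budget permitting).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field as dc_field
from typing import Callable, Iterable, Mapping

import numpy as np

from ._rng import derive_seed
from .bottlenecks import BottleneckRecord, control_set, efficiencies, size_k_bottlenecks
from .coupling import AttractorSet
from .dynamics import ControlEvaluation, SimConfig, evaluate_control_set
from .network import GeneNetwork, NodePartition, partition_nodes


@dataclass
class StrategyConfig:
    """Search protocol shared by all strategies."""

    max_targets: int = 10
    seed: int = 0
    replicates_search: int = 100
    replicates_final: int = 1000
    mc_budget: int = 1000
    exhaustive_budget: int = 1_000_000
    max_steps: int = 200
    annotation_required: bool = False
    inhibit_only: bool = False
    include_sinks: bool = False
    stop_when_no_improvement: bool = False

    def sim(self, replicates: int) -> SimConfig:
        return SimConfig(seed=self.seed, replicates=replicates, max_steps=self.max_steps)


@dataclass
class CurvePoint:
    k: int
    added: tuple[int, ...]
    m_cancer: float
    m_cancer_stderr: float
    m_normal: float
    m_normal_stderr: float


@dataclass
class ControlPlan:
    """Ordered target list with the magnetization curve of its prefixes."""

    strategy: str
    targets: list[int]
    curve: list[CurvePoint]
    config: StrategyConfig
    meta: dict = dc_field(default_factory=dict)

    def final_m_cancer(self) -> float:
        return self.curve[-1].m_cancer if self.curve else 1.0

    def as_records(self) -> list[dict]:
        return [
            {
                "k": pt.k,
                "added": list(pt.added),
                "m_cancer": pt.m_cancer,
                "m_cancer_stderr": pt.m_cancer_stderr,
                "m_normal": pt.m_normal,
                "m_normal_stderr": pt.m_normal_stderr,
            }
            for pt in self.curve
        ]


def n_combinations(n_allowed: int, k: int) -> int:
    """Number of k-subsets an exhaustive search must evaluate."""
    return math.comb(n_allowed, k)


def apply_constraints(
    partition: NodePartition,
    annotations: Mapping[int, bool] | None,
    attractors: AttractorSet,
    config: StrategyConfig,
    candidate_pool: Iterable[int] | None = None,
    sinks: set[int] | None = None,
) -> set[int]:
    """Admissible target set: differential, optionally annotated and
    cancer-expressed (inhibit-only), sinks excluded unless requested.

    ``sinks`` may override the partition's sink set with the effective sinks
    of the simulated subnetwork.
    """
    allowed = set(partition.differential)
    if candidate_pool is not None:
        allowed &= set(int(n) for n in candidate_pool)
    if not config.include_sinks:
        allowed -= partition.sinks if sinks is None else sinks
    if config.annotation_required:
        if not annotations:
            raise ValueError("annotation_required set but no annotations given")
        allowed &= {n for n, flag in annotations.items() if flag}
    if config.inhibit_only:
        xi_c = attractors.spins("cancer")
        allowed &= {n for n in allowed if xi_c.get(n) == 1}
    if not allowed:
        raise ValueError("constraint filtering left no admissible targets")
    return allowed


class _Evaluator:
    """Caches replicate-averaged evaluations of target sets."""

    def __init__(
        self,
        net: GeneNetwork,
        attractors: AttractorSet,
        p: int,
        config: StrategyConfig,
        sim_nodes: Iterable[int] | None = None,
        n_full: int | None = None,
    ) -> None:
        self.net, self.attractors, self.p = net, attractors, p
        self.config = config
        self.sim_nodes = set(sim_nodes) if sim_nodes is not None else None
        self.n_full = n_full
        self._cache: dict[tuple[frozenset[int], int], ControlEvaluation] = {}
        self.n_evaluations = 0

    def __call__(self, targets: Iterable[int], replicates: int) -> ControlEvaluation:
        key = (frozenset(int(t) for t in targets), replicates)
        if key not in self._cache:
            self.n_evaluations += 1
            self._cache[key] = evaluate_control_set(
                self.net,
                self.attractors,
                key[0],
                self.config.sim(replicates),
                p=self.p,
                sim_nodes=self.sim_nodes,
                n_full=self.n_full,
            )
        return self._cache[key]


def _curve_for_prefixes(
    evaluator: _Evaluator, ordered: list[tuple[int, ...]], replicates: int
) -> list[CurvePoint]:
    pts, fixed = [], []
    for group in ordered:
        fixed.extend(group)
        ev = evaluator(fixed, replicates)
        pts.append(
            CurvePoint(len(fixed), tuple(group), ev.m_cancer, ev.m_cancer_stderr,
                       ev.m_normal, ev.m_normal_stderr)
        )
    return pts


def rank_efficiency(
    net: GeneNetwork,
    attractors: AttractorSet,
    p: int,
    config: StrategyConfig,
    mode: str = "pure",
    sim_nodes: Iterable[int] | None = None,
    n_full: int | None = None,
    annotations: Mapping[int, bool] | None = None,
) -> ControlPlan:
    """Efficiency-ranked strategy (pure or mixed).

    Candidates are ranked by optimal efficiency (impact, for size-1
    bottlenecks) and fixed in order; a candidate lying inside the control set
    of an already-fixed bottleneck is skipped (fixing the outer one flips it
    anyway).  In mixed mode each cycle cluster competes at its optimal
    efficiency with the subset of internal bottlenecks that achieves it.
    """
    if mode not in ("pure", "mixed"):
        raise ValueError("mode must be 'pure' or 'mixed'")
    part = partition_nodes(net, attractors)
    work_net = net.subnetwork(sim_nodes) if sim_nodes is not None else net
    allowed = apply_constraints(
        part, annotations or net.annotations, attractors, config,
        candidate_pool=sim_nodes,
        sinks=work_net.sinks() if sim_nodes is not None else None,
    )

    items: list[tuple[float, int, tuple[int, ...], set[int]]] = []
    for n in sorted(allowed):
        B, impact = control_set(work_net, {n})
        items.append((float(impact), n, (n,), B))
    cluster_nodes_used: set[int] = set()
    if mode == "mixed":
        for rec in size_k_bottlenecks(work_net):
            rec = efficiencies(rec, work_net, replicates=min(20, config.replicates_search),
                               seed=config.seed, compute_bounds=False)
            subset = tuple(n for n in rec.e_opt_subset if n in allowed)
            if subset:
                items.append((float(rec.e_opt), min(subset), subset, rec.control))
                cluster_nodes_used |= set(subset)

    items.sort(key=lambda it: (-it[0], it[1]))
    ordered: list[tuple[int, ...]] = []
    covered: set[int] = set()
    fixed: set[int] = set()
    count = 0
    for _, _, members, B in items:
        group = tuple(m for m in members if m not in fixed and m not in covered)
        if not group:
            continue
        take = group[: config.max_targets - count]
        ordered.append(take)
        fixed |= set(take)
        covered |= B
        count += len(take)
        if count >= config.max_targets:
            break

    evaluator = _Evaluator(net, attractors, p, config, sim_nodes, n_full)
    # expand groups into unit steps so the curve has one point per target
    unit = [(t,) for grp in ordered for t in grp]
    curve = _curve_for_prefixes(evaluator, unit, config.replicates_final)
    return ControlPlan(
        strategy=f"efficiency-ranked-{mode}",
        targets=[t for grp in unit for t in grp],
        curve=curve,
        config=config,
        meta={"allowed": sorted(allowed)},
    )


def best_plus_one(
    net: GeneNetwork,
    attractors: AttractorSet,
    p: int,
    config: StrategyConfig,
    seed_set: Iterable[int] | None = None,
    sim_nodes: Iterable[int] | None = None,
    n_full: int | None = None,
    annotations: Mapping[int, bool] | None = None,
) -> ControlPlan:
    """Greedy strategy: grow the target set one node at a time, always adding
    the candidate that minimizes the cancer magnetization.

    The default seed is the single highest-impact size-1 bottleneck among the
    admissible candidates; ties break toward the lowest node id.
    """
    part = partition_nodes(net, attractors)
    work_net = net.subnetwork(sim_nodes) if sim_nodes is not None else net
    allowed = apply_constraints(
        part, annotations or net.annotations, attractors, config,
        candidate_pool=sim_nodes,
        sinks=work_net.sinks() if sim_nodes is not None else None,
    )
    evaluator = _Evaluator(net, attractors, p, config, sim_nodes, n_full)

    if seed_set is None:
        impacts = {n: control_set(work_net, {n})[1] for n in allowed}
        seed_node = min(impacts, key=lambda n: (-impacts[n], n))
        fixed = [seed_node]
    else:
        fixed = [int(n) for n in seed_set]

    curve: list[CurvePoint] = []
    ev = evaluator(fixed, config.replicates_final)
    curve.append(CurvePoint(len(fixed), tuple(fixed), ev.m_cancer, ev.m_cancer_stderr,
                            ev.m_normal, ev.m_normal_stderr))
    current = ev.m_cancer
    while len(fixed) < config.max_targets:
        best_node, best_m = None, math.inf
        for v in sorted(allowed - set(fixed)):
            m = evaluator(fixed + [v], config.replicates_search).m_cancer
            if m < best_m - 1e-12:
                best_node, best_m = v, m
        if best_node is None:
            break
        if config.stop_when_no_improvement and best_m >= current - 1e-12:
            break
        fixed.append(best_node)
        ev = evaluator(fixed, config.replicates_final)
        curve.append(CurvePoint(len(fixed), (best_node,), ev.m_cancer,
                                ev.m_cancer_stderr, ev.m_normal, ev.m_normal_stderr))
        current = ev.m_cancer
    return ControlPlan("best+1", fixed, curve, config,
                       meta={"allowed": sorted(allowed),
                             "evaluations": evaluator.n_evaluations})


def monte_carlo(
    net: GeneNetwork,
    attractors: AttractorSet,
    p: int,
    config: StrategyConfig,
    sim_nodes: Iterable[int] | None = None,
    n_full: int | None = None,
    annotations: Mapping[int, bool] | None = None,
) -> ControlPlan:
    """Random search: for each target count k, sample seeded k-subsets of the
    admissible set and keep the best; the curve reports the best found per k.

    The evaluation budget is split evenly across the k values; if the budget
    covers the whole C(n, k) space the sampling enumerates it instead.
    """
    part = partition_nodes(net, attractors)
    allowed = sorted(
        apply_constraints(
            part, annotations or net.annotations, attractors, config,
            candidate_pool=sim_nodes,
            sinks=net.subnetwork(sim_nodes).sinks() if sim_nodes is not None else None,
        )
    )
    evaluator = _Evaluator(net, attractors, p, config, sim_nodes, n_full)
    per_k = max(1, config.mc_budget // max(1, config.max_targets))
    curve: list[CurvePoint] = []
    best_final: list[int] = []
    for k in range(1, min(config.max_targets, len(allowed)) + 1):
        total = math.comb(len(allowed), k)
        rng = np.random.default_rng(derive_seed(config.seed, 77, k))
        if total <= per_k:
            candidates = [tuple(c) for c in itertools.combinations(allowed, k)]
        else:
            candidates = []
            seen = set()
            while len(candidates) < per_k:
                cand = tuple(sorted(rng.choice(len(allowed), size=k, replace=False)))
                if cand not in seen:
                    seen.add(cand)
                    candidates.append(tuple(allowed[i] for i in cand))
        best_set, best_m = None, math.inf
        for cand in candidates:
            m = evaluator(cand, config.replicates_search).m_cancer
            if m < best_m - 1e-12 or (best_set is None):
                best_set, best_m = cand, m
        ev = evaluator(best_set, config.replicates_final)
        curve.append(CurvePoint(k, tuple(best_set), ev.m_cancer, ev.m_cancer_stderr,
                                ev.m_normal, ev.m_normal_stderr))
        best_final = list(best_set)
    return ControlPlan("monte-carlo", best_final, curve, config,
                       meta={"allowed": allowed, "samples_per_k": per_k})


def exhaustive(
    net: GeneNetwork,
    attractors: AttractorSet,
    p: int,
    k: int,
    config: StrategyConfig,
    sim_nodes: Iterable[int] | None = None,
    n_full: int | None = None,
    annotations: Mapping[int, bool] | None = None,
) -> ControlPlan:
    """Evaluate every k-subset of the admissible set; error if the count
    exceeds the configured budget (use a constrained search instead)."""
    part = partition_nodes(net, attractors)
    allowed = sorted(
        apply_constraints(
            part, annotations or net.annotations, attractors, config,
            candidate_pool=sim_nodes,
            sinks=net.subnetwork(sim_nodes).sinks() if sim_nodes is not None else None,
        )
    )
    total = n_combinations(len(allowed), k)
    if total > config.exhaustive_budget:
        raise ValueError(
            f"exhaustive search over {total} {k}-subsets exceeds the budget "
            f"({config.exhaustive_budget}); constrain the candidate set"
        )
    evaluator = _Evaluator(net, attractors, p, config, sim_nodes, n_full)
    best_set, best_m = None, math.inf
    for cand in itertools.combinations(allowed, k):
        m = evaluator(cand, config.replicates_search).m_cancer
        if m < best_m - 1e-12:
            best_set, best_m = tuple(cand), m
    ev = evaluator(best_set, config.replicates_final)
    curve = [CurvePoint(k, best_set, ev.m_cancer, ev.m_cancer_stderr,
                        ev.m_normal, ev.m_normal_stderr)]
    return ControlPlan("exhaustive", list(best_set), curve, config,
                       meta={"allowed": allowed, "combinations": total})
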