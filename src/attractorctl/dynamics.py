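"""Zero-temperature spin dynamics, control fields and magnetization.

Spins update by the sign of the local field

    h_i(t) = sum_j J_ij sigma_j(t) + h_i^ext,
    sigma_i(t+1) = sign(h_i(t)),  random ±1 when h_i(t) = 0,

either synchronously (all nodes at once; may settle into limit cycles) or
asynchronously (one node at a time in seeded random order; always reaches a
fixed point on the networks treated here).  The magnetization along a stored
pattern xi^mu,  m^mu(t) = (1/N) sum_i xi^mu_i sigma_i(t),  measures overlap
with that cell state; its long-time (cycle-averaged) value is the steady
magnetization.

Two kinds of external field appear: *source pins*, small sub-unit fields that
hold zero-input nodes at their initial spins, and *control fields*, which
exceed the total incoming coupling weight at the target so the forced spin
can never be overturned by neighbors (the drug-dominance condition).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from ._rng import derive_seed, tie_spins
from .coupling import COUPLING_UNIT, AttractorSet, CouplingMatrix, encode_coupling
from .network import GeneNetwork, NodePartition

#: magnitude of a source pin — half a coupling unit, strictly sub-threshold
PIN_FIELD = 0.5 * COUPLING_UNIT


@dataclass
class ExternalFields:
    """Per-node external field values with provenance tags."""

    values: dict[int, float] = field(default_factory=dict)
    provenance: dict[int, str] = field(default_factory=dict)

    def set(self, node: int, value: float, tag: str) -> None:
        self.values[int(node)] = float(value)
        self.provenance[int(node)] = tag

    def merged(self, other: "ExternalFields") -> "ExternalFields":
        """Combine two field sets; entries in ``other`` win on conflict."""
        out = ExternalFields(dict(self.values), dict(self.provenance))
        out.values.update(other.values)
        out.provenance.update(other.provenance)
        return out

    def vector(self, node_ids: np.ndarray) -> np.ndarray:
        v = np.zeros(len(node_ids))
        for n, val in self.values.items():
            pos = np.searchsorted(node_ids, n)
            if pos < len(node_ids) and node_ids[pos] == n:
                v[pos] = val
        return v


@dataclass
class SimConfig:
    """Simulation protocol: update scheme, horizon, seeding, replication."""

    update: str = "synchronous"
    temperature: float = 0.0
    max_steps: int = 500
    seed: int = 0
    replicates: int = 1
    cycle_window: int = 256

    def __post_init__(self) -> None:
        if self.temperature != 0.0:
            raise ValueError("only T = 0 dynamics are supported")
        if self.update not in ("synchronous", "asynchronous"):
            raise ValueError(f"unknown update mode {self.update!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class MagnetizationTrace:
    """Magnetization series per attractor plus steady values and final state."""

    series: dict[str, np.ndarray]
    steady: dict[str, float]
    cyclic: bool
    period: int
    converged: bool
    final_state: np.ndarray
    node_ids: np.ndarray


def local_field(J: CouplingMatrix, sigma: np.ndarray, ext: np.ndarray) -> np.ndarray:
    """Total field at every node: incoming couplings times spins plus external."""
    return J.J @ sigma.astype(np.float64) + ext


def step(
    J: CouplingMatrix,
    sigma: np.ndarray,
    ext: np.ndarray,
    t: int,
    config: SimConfig,
    replicate: int = 0,
) -> np.ndarray:
    """One update of the T=0 dynamics; returns the new spin vector."""
    if config.update == "synchronous":
        h = local_field(J, sigma, ext)
        new = np.sign(h).astype(np.int8)
        zero = new == 0
        if zero.any():
            new[zero] = tie_spins(J.node_ids[zero], t, config.seed, replicate)
        return new
    # asynchronous: seeded random order, one node at a time
    new = sigma.copy()
    order = np.arange(len(sigma))
    rng = np.random.default_rng(derive_seed(config.seed, replicate, t))
    rng.shuffle(order)
    for i in order:
        h = float((J.J.getrow(i) @ new.astype(np.float64)).item()) + ext[i]
        if h > 0:
            new[i] = 1
        elif h < 0:
            new[i] = -1
        else:
            new[i] = tie_spins(J.node_ids[i : i + 1], t, config.seed, replicate)[0]
    return new


def magnetization(
    sigma: np.ndarray,
    xi: np.ndarray,
    n_full: int | None = None,
    rest_at_attractor: bool = False,
) -> float:
    """Overlap (1/N_full) sum_i xi_i sigma_i over the simulated nodes.

    ``n_full`` is the full-network size even when only a subnetwork is
    simulated; with ``rest_at_attractor`` the unsimulated nodes are assumed to
    sit at the reference pattern and contribute +1 each.
    """
    n_sim = len(sigma)
    if n_full is None:
        n_full = n_sim
    if n_full < n_sim:
        raise ValueError("n_full smaller than the number of simulated nodes")
    m = float(np.dot(xi.astype(np.float64), sigma.astype(np.float64))) / n_full
    if rest_at_attractor:
        m += (n_full - n_sim) / n_full
    return m


def pin_sources(
    net: GeneNetwork,
    partition: NodePartition | None,
    initial: Mapping[int, int] | np.ndarray,
    targets: Iterable[int] = (),
) -> ExternalFields:
    """Sub-threshold fields holding source/effective-source nodes at their
    initial spins.  A pinned node that is directly targeted loses its pin (the
    control field replaces it)."""
    targets = set(int(v) for v in targets)
    if partition is not None:
        omega = partition.omega
    else:
        omega = net.sources()
    if isinstance(initial, np.ndarray):
        initial = {int(n): int(s) for n, s in zip(net.node_ids, initial)}
    fields = ExternalFields()
    for n in sorted(omega):
        if n in targets:
            continue
        fields.set(n, PIN_FIELD * initial[n], "source-pin")
    return fields


def control_fields(
    J: CouplingMatrix,
    targets: Iterable[int],
    attractors: AttractorSet,
    net: GeneNetwork,
) -> ExternalFields:
    """Dominant fields driving each target away from the cancer pattern.

    The magnitude strictly exceeds the summed magnitude of incoming couplings
    at the node, so the forced spin holds regardless of the neighbors.
    """
    xi_c = attractors.spins("cancer")
    fields = ExternalFields()
    weights = J.incoming_weights()
    for n in sorted(set(int(v) for v in targets)):
        i = net.index[n]
        mag = weights[i] + COUPLING_UNIT
        fields.set(n, -xi_c[n] * mag, "control")
    return fields


def run(
    net: GeneNetwork,
    J: CouplingMatrix,
    initial: np.ndarray,
    ext: ExternalFields | np.ndarray | None,
    config: SimConfig,
    attractors: AttractorSet | None = None,
    replicate: int = 0,
) -> MagnetizationTrace:
    """Iterate the dynamics until a fixed point or limit cycle, tracking
    magnetization along each stored attractor.

    Steady magnetization is the average over the detected cycle (period 1 for
    a fixed point).  Non-convergence within ``max_steps`` is flagged, and the
    trailing ``cycle_window`` states are averaged instead.
    """
    if ext is None:
        ext_vec = np.zeros(net.n_nodes)
    elif isinstance(ext, ExternalFields):
        ext_vec = ext.vector(net.node_ids)
    else:
        ext_vec = np.asarray(ext, dtype=np.float64)

    labels = list(attractors.labels) if attractors is not None else []
    xi = {lab: attractors.vector(lab, net) for lab in labels}

    sigma = np.asarray(initial, dtype=np.int8).copy()
    # recurrence is only meaningful along tie-free stretches: a zero-field
    # node injects randomness, so a revisited state need not repeat
    seen: dict[bytes, int] = {sigma.tobytes(): 0}
    states = [sigma.copy()]
    cyclic, period, converged = False, 0, False
    t0 = 0
    for t in range(config.max_steps):
        h = local_field(J, sigma, ext_vec)
        had_tie = bool(np.any(h == 0))
        sigma = step(J, sigma, ext_vec, t, config, replicate)
        key = sigma.tobytes()
        if had_tie:
            seen = {key: t + 1}
            states.append(sigma.copy())
            continue
        if key in seen:
            t0 = seen[key]
            period = (t + 1) - t0
            cyclic = period > 1
            converged = True
            break
        seen[key] = t + 1
        states.append(sigma.copy())
    if not converged:
        t0 = max(0, len(states) - config.cycle_window)
        period = len(states) - t0

    series = {
        lab: np.array([magnetization(s, xi[lab]) for s in states]) for lab in labels
    }
    segment = states[t0 : t0 + period]
    steady = {
        lab: float(np.mean([magnetization(s, xi[lab]) for s in segment]))
        for lab in labels
    }
    return MagnetizationTrace(
        series=series,
        steady=steady,
        cyclic=cyclic,
        period=period if converged else 0,
        converged=converged,
        final_state=sigma,
        node_ids=net.node_ids,
    )


@dataclass
class ControlEvaluation:
    """Replicate-averaged steady magnetizations for a fixed target set."""

    m_cancer: float
    m_cancer_stderr: float
    m_normal: float
    m_normal_stderr: float
    replicates: int


def _steady_for(
    net: GeneNetwork,
    J: CouplingMatrix,
    attractors: AttractorSet,
    partition: NodePartition | None,
    init_label: str,
    measure_label: str,
    targets: set[int],
    config: SimConfig,
    n_full: int,
) -> tuple[float, float]:
    xi0 = attractors.vector(init_label, net)
    pins = pin_sources(net, partition, xi0, targets)
    ctrl = control_fields(J, targets, attractors, net)
    ext = pins.merged(ctrl)
    vals = []
    for r in range(config.replicates):
        trace = run(net, J, xi0, ext, config, attractors, replicate=r)
        # complete the subnetwork magnetization: unsimulated nodes stay at the
        # pattern they started in, which matches the measured pattern here
        m = trace.steady[measure_label] * net.n_nodes / n_full + (n_full - net.n_nodes) / n_full
        vals.append(m)
    vals = np.asarray(vals)
    stderr = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return float(vals.mean()), stderr


def evaluate_control_set(
    net: GeneNetwork,
    attractors: AttractorSet,
    targets: Iterable[int],
    config: SimConfig,
    p: int = 2,
    sim_nodes: Iterable[int] | None = None,
    partition: NodePartition | None = None,
    n_full: int | None = None,
) -> ControlEvaluation:
    """Replicate-averaged effect of forcing ``targets`` away from cancer.

    Simulates a cancer cell (initialized at the cancer pattern) and a normal
    cell (at the normal pattern).  For ``p=1`` each cell type carries its own
    single-pattern coupling matrix; for ``p=2`` both share the two-pattern
    matrix.  ``sim_nodes`` restricts the simulation to a subnetwork (e.g. the
    largest differential component); magnetizations are always normalized by
    the full network size ``n_full``.
    """
    targets = set(int(v) for v in targets)
    if n_full is None:
        n_full = net.n_nodes
    if sim_nodes is not None:
        sub = net.subnetwork(sim_nodes)
        attr = attractors.restricted(sub.graph.nodes)
        missing = targets - set(int(n) for n in sub.graph.nodes)
        if missing:
            raise ValueError(f"targets outside the simulated subnetwork: {sorted(missing)}")
    else:
        sub, attr = net, attractors

    from .network import partition_nodes  # local import to avoid cycle

    part = partition_nodes(sub, attr) if attr.p == 2 else None

    if p == 1:
        J_c = encode_coupling(sub, attr, 1, cell_type="cancer")
        J_n = encode_coupling(sub, attr, 1, cell_type="normal")
    else:
        J_c = J_n = encode_coupling(sub, attr, 2)

    m_c, se_c = _steady_for(sub, J_c, attr, part, "cancer", "cancer", targets, config, n_full)
    m_n, se_n = _steady_for(sub, J_n, attr, part, "normal", "normal", targets, config, n_full)
    return ControlEvaluation(m_c, se_c, m_n, se_n, config.replicates)
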