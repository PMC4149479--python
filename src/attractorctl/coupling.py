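"""Attractor patterns and the signed Hopfield coupling matrix.

An attractor is a ±1 spin pattern over all genes: a binarized expression
profile of one cell type.  Couplings are built by the Hopfield outer-product
rule restricted to the network's edges:

    p = 1:  J_ij = A_ij * xi_i * xi_j          (one stored pattern)
    p = 2:  J_ij = A_ij * (xi^n_i xi^n_j + xi^c_i xi^c_j) / 2

With the 1/p normalization every nonzero coupling has unit magnitude, and in
the two-pattern case J_ij is exactly zero when i and j are of unlike
similarity/differential type — the effective edge deletion that decouples
normal-cell from cancer-cell signaling.

Orientation convention: J_ij is the influence of node j on node i, so an edge
file row (source, target) populates J[target, source].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .network import GeneNetwork

#: magnitude of a single nonzero coupling ("one coupling unit")
COUPLING_UNIT = 1.0


class AttractorError(ValueError):
    """Missing or malformed attractor values."""


@dataclass
class AttractorSet:
    """One or two ±1 spin patterns over the network's nodes.

    ``patterns`` maps a label (``"normal"``, ``"cancer"``) to a dict
    node id -> spin in {-1, +1}.
    """

    patterns: dict[str, dict[int, int]]

    def __post_init__(self) -> None:
        for label, spins in self.patterns.items():
            bad = {n: s for n, s in spins.items() if s not in (-1, 1)}
            if bad:
                raise AttractorError(f"attractor {label!r} has non-±1 spins: {bad}")

    @property
    def p(self) -> int:
        return len(self.patterns)

    @property
    def labels(self) -> list[str]:
        return list(self.patterns)

    def spins(self, label: str) -> dict[int, int]:
        return self.patterns[label]

    def vector(self, label: str, net: GeneNetwork) -> np.ndarray:
        """Spin pattern as an int8 vector aligned with ``net.node_ids``."""
        spins = self.patterns[label]
        missing = [int(n) for n in net.node_ids if int(n) not in spins]
        if missing:
            raise AttractorError(
                f"attractor {label!r} missing spins for nodes {missing[:10]}"
                + ("..." if len(missing) > 10 else "")
            )
        return np.array([spins[int(n)] for n in net.node_ids], dtype=np.int8)

    def restricted(self, nodes) -> "AttractorSet":
        nodes = set(int(n) for n in nodes)
        return AttractorSet(
            {lab: {n: s for n, s in spins.items() if n in nodes} for lab, spins in self.patterns.items()}
        )


def two_state(net: GeneNetwork, normal: dict[int, int], cancer: dict[int, int]) -> AttractorSet:
    return AttractorSet({"normal": dict(normal), "cancer": dict(cancer)})


@dataclass
class CouplingMatrix:
    """Sparse signed couplings ``J`` with ``J[i, j]`` = influence of j on i.

    Row/column order follows ``net.node_ids``; ``unit`` records the common
    magnitude of nonzero entries.
    """

    J: sp.csr_matrix
    node_ids: np.ndarray
    p: int
    unit: float = COUPLING_UNIT

    @property
    def n(self) -> int:
        return self.J.shape[0]

    def incoming_weight(self, idx: int) -> float:
        """Sum of |J_ij| over upstream nodes j (row absolute sum)."""
        row = self.J.getrow(idx)
        return float(np.abs(row.data).sum())

    def incoming_weights(self) -> np.ndarray:
        return np.asarray(np.abs(self.J).sum(axis=1)).ravel()


def encode_coupling(net: GeneNetwork, attractors: AttractorSet, p: int,
                    cell_type: str = "cancer") -> CouplingMatrix:
    """Encode attractor patterns into a coupling matrix over the edge set.

    For ``p=1`` the pattern of ``cell_type`` alone is stored; for ``p=2`` the
    normal and cancer patterns are superposed, which zeroes exactly the
    couplings between nodes of unlike similarity/differential type.
    """
    if p not in (1, 2):
        raise ValueError("p must be 1 or 2")
    if p == 2 and attractors.p != 2:
        raise AttractorError("p=2 encoding requires both normal and cancer attractors")
    n = net.n_nodes
    idx = net.index
    rows, cols, vals = [], [], []
    if p == 1:
        xi = attractors.vector(cell_type, net).astype(np.float64)
        for s, t in net.graph.edges:
            i, j = idx[t], idx[s]
            rows.append(i)
            cols.append(j)
            vals.append(xi[i] * xi[j] * COUPLING_UNIT)
    else:
        xi_n = attractors.vector("normal", net).astype(np.float64)
        xi_c = attractors.vector("cancer", net).astype(np.float64)
        for s, t in net.graph.edges:
            i, j = idx[t], idx[s]
            w = (xi_n[i] * xi_n[j] + xi_c[i] * xi_c[j]) / 2.0
            if w != 0.0:
                rows.append(i)
                cols.append(j)
                vals.append(w * COUPLING_UNIT)
    J = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return CouplingMatrix(J=J, node_ids=net.node_ids.copy(), p=p)
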