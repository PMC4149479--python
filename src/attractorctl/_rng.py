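"""Counter-based randomness for tie-breaking spins.

Zero-field nodes draw their spin from a hash of (seed, replicate, node id,
time step) instead of a shared stream.  This makes every draw independent of
which other nodes are being simulated, so a subnetwork simulation reproduces
the full-network trajectory bit for bit, and runs are reproducible from the
seed alone.
"""

from __future__ import annotations

import numpy as np

_M1 = np.uint64(0xBF58476D1CE4E5B9)
_M2 = np.uint64(0x94D049BB133111EB)
_GOLDEN = np.uint64(0x9E3779B97F4A7C15)


def _splitmix64(x: np.ndarray) -> np.ndarray:
    # SplitMix64 finalizer; good avalanche for cheap counter-based hashing.
    x = x.astype(np.uint64, copy=True)
    x ^= x >> np.uint64(30)
    x *= _M1
    x ^= x >> np.uint64(27)
    x *= _M2
    x ^= x >> np.uint64(31)
    return x


def tie_spins(node_ids: np.ndarray, t: int, seed: int, replicate: int = 0) -> np.ndarray:
    """Return ±1 spins for the given node ids at time step ``t``.

    Each (seed, replicate, node, t) tuple maps to an independent fair bit.
    """
    with np.errstate(over="ignore"):
        x = np.asarray(node_ids, dtype=np.uint64) * _GOLDEN
        x += np.uint64(t & 0xFFFFFFFFFFFFFFFF) * _M1
        x += np.uint64(seed & 0xFFFFFFFFFFFFFFFF) * _M2
        x += np.uint64(replicate & 0xFFFFFFFFFFFFFFFF) * _GOLDEN * _GOLDEN
        h = _splitmix64(x)
    return np.where((h >> np.uint64(63)).astype(bool), np.int8(1), np.int8(-1))


def derive_seed(seed: int, *indices: int) -> int:
    """Derive a child seed (< 2**31) from a master seed and stream indices."""
    ss = np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF, spawn_key=tuple(int(i) for i in indices))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
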