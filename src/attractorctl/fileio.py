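"""Readers and writers for the supplementary-style TSV formats.

Edge files: one header line, then two tab-separated integer columns
("Source EzID", "Target EzID").  Attractor files: header, then gene id,
normal spin, cancer spin; spins may be coded {-1, +1} or {0, 1} (0 mapped to
-1, logged).  Annotation files: gene id and a 0/1 flag.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

import pandas as pd

from .coupling import AttractorError, AttractorSet
from .network import EdgeRecordError, GeneNetwork, build_network

log = logging.getLogger("attractorctl")


def _read_tsv(path: str | Path, n_cols: int) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", header=0, dtype=str,
                     skip_blank_lines=True)
    if df.shape[1] < n_cols:
        raise ValueError(f"{path}: expected {n_cols} tab-separated columns, "
                         f"found {df.shape[1]}")
    return df.iloc[:, :n_cols].apply(lambda col: col.str.strip())


def _to_int(value: str, path: Path, lineno: int, what: str) -> int:
    try:
        return int(value)
    except (TypeError, ValueError) as exc:
        raise EdgeRecordError(
            f"{path}, line {lineno}: non-integer {what} {value!r}"
        ) from exc


def read_edges(path: str | Path, undirected_policy: bool = False) -> GeneNetwork:
    """Read an edge TSV into a :class:`GeneNetwork`.

    Logs a parse summary (rows, duplicates, reciprocal pairs); raises on an
    empty file or non-integer ids, naming the offending line.
    """
    path = Path(path)
    df = _read_tsv(path, 2)
    if df.empty:
        raise EdgeRecordError(f"{path}: no edge records")
    records = []
    for lineno, (s, t) in enumerate(df.itertuples(index=False), start=2):
        records.append((_to_int(s, path, lineno, "source id"),
                        _to_int(t, path, lineno, "target id")))
    net = build_network(records, undirected_policy)
    log.info(
        "read %s: %d rows, %d unique directed edges, %d duplicates, "
        "%d undirected pairs, %d nodes",
        path, len(records), net.n_directed_edges,
        len(records) - net.n_directed_edges, net.n_undirected_edges, net.n_nodes,
    )
    return net


_SPIN_MAPS = {
    frozenset({"-1", "1"}): {"-1": -1, "1": 1},
    frozenset({"0", "1"}): {"0": -1, "1": 1},
}


def _decode_spins(values: set[str], path: Path) -> dict[str, int]:
    for alphabet, mapping in _SPIN_MAPS.items():
        if values <= alphabet:
            if "0" in values:
                log.info("%s: spin alphabet {0,1} detected; 0 mapped to -1", path)
            return mapping
    raise AttractorError(f"{path}: unrecognized spin alphabet {sorted(values)}")


def read_attractors(path: str | Path, net: GeneNetwork) -> AttractorSet:
    """Read a (gene id, normal spin, cancer spin) TSV against a network.

    Gene ids absent from the network are dropped with a warning; network
    genes missing from the file are a hard error (their dynamics would be
    undefined).
    """
    path = Path(path)
    df = _read_tsv(path, 3)
    if df.empty:
        raise AttractorError(f"{path}: no attractor records")
    values = set(df.iloc[:, 1]) | set(df.iloc[:, 2])
    mapping = _decode_spins(values, path)
    normal: dict[int, int] = {}
    cancer: dict[int, int] = {}
    extras = []
    known = set(int(n) for n in net.graph.nodes)
    for lineno, (gid, sn, sc) in enumerate(df.itertuples(index=False), start=2):
        g = _to_int(gid, path, lineno, "gene id")
        if sn not in mapping or sc not in mapping:
            raise AttractorError(f"{path}, line {lineno}: malformed spin "
                                 f"({sn!r}, {sc!r})")
        if g not in known:
            extras.append(g)
            continue
        normal[g] = mapping[sn]
        cancer[g] = mapping[sc]
    if extras:
        log.warning("%s: %d gene ids not in the network were ignored", path, len(extras))
    missing = sorted(known - set(normal))
    if missing:
        raise AttractorError(
            f"{path}: network genes missing an attractor value: {missing[:20]}"
            + ("..." if len(missing) > 20 else "")
        )
    return AttractorSet({"normal": normal, "cancer": cancer})


def read_annotations(path: str | Path) -> dict[int, bool]:
    """Read a (gene id, 0/1 flag) TSV of e.g. druggable/kinase marks."""
    path = Path(path)
    df = _read_tsv(path, 2)
    out = {}
    for lineno, (gid, flag) in enumerate(df.itertuples(index=False), start=2):
        out[_to_int(gid, path, lineno, "gene id")] = bool(_to_int(flag, path, lineno, "flag"))
    return out


def write_edges(net: GeneNetwork, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["Source EzID", "Target EzID"])
        for s, t in sorted(net.graph.edges):
            w.writerow([s, t])


def write_attractors(attractors: AttractorSet, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    normal, cancer = attractors.spins("normal"), attractors.spins("cancer")
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["EzID", "Normal", "Cancer"])
        for g in sorted(normal):
            w.writerow([g, normal[g], cancer[g]])


def write_annotations(ann: dict[int, bool], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["EzID", "Flag"])
        for g in sorted(ann):
            w.writerow([g, int(ann[g])])


def write_curve_csv(plan, path: str | Path) -> None:
    """Magnetization curve (k, nodes added, m_cancer, stderr, m_normal)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["k", "added", "m_cancer", "m_cancer_stderr",
                    "m_normal", "m_normal_stderr"])
        for pt in plan.curve:
            w.writerow([pt.k, ";".join(map(str, pt.added)),
                        f"{pt.m_cancer:.6f}", f"{pt.m_cancer_stderr:.6f}",
                        f"{pt.m_normal:.6f}", f"{pt.m_normal_stderr:.6f}"])


def write_plan_json(plan, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "strategy": plan.strategy,
        "targets": [int(t) for t in plan.targets],
        "curve": plan.as_records(),
        "config": {k: v for k, v in vars(plan.config).items()},
        "meta": {k: v for k, v in plan.meta.items()},
    }
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")


def write_json(obj, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=str) + "\n")
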