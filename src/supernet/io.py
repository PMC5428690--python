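"""Readers and writers for the plain-text formats the toolkit touches.

Internal node indices are 0-based; every on-disk artifact uses the
original string identifiers through a :class:`LabelMap`.  Formats:

* edge list — whitespace-separated ``u v [w]`` lines, ``#`` comments;
* GML — via :func:`networkx.read_gml` (real networks circulate as GML);
* constraints — TSV ``u<TAB>v<TAB>ML|CL``;
* partition — TSV ``node<TAB>label``;
* super-network export — weighted edge list plus a membership TSV
  ``node<TAB>super_node``.

Readers reject malformed input with a line-numbered error instead of
silently mangling it; writers produce files their readers round-trip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .core import ConstraintSet, Graph, InputError, Partition, SuperNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "LabelMap",
    "read_edgelist",
    "write_edgelist",
    "read_gml",
    "read_constraints",
    "write_constraints",
    "read_partition",
    "write_partition",
    "write_supernetwork",
]


@dataclass
class LabelMap:
    """Bijection between original node identifiers and 0-based indices."""

    labels: list[str]

    def __post_init__(self) -> None:
        self.to_index = {lab: i for i, lab in enumerate(self.labels)}
        if len(self.to_index) != len(self.labels):
            raise InputError("duplicate node identifiers")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.to_index[label]
        except KeyError:
            raise InputError(f"unknown node identifier {label!r}") from None

    def label(self, index: int) -> str:
        return self.labels[index]


def _parse_edge_line(line: str, lineno: int) -> tuple[str, str, float]:
    parts = line.split()
    if len(parts) not in (2, 3):
        raise InputError(f"line {lineno}: expected 'u v [w]', got {line!r}")
    w = 1.0
    if len(parts) == 3:
        try:
            w = float(parts[2])
        except ValueError:
            raise InputError(f"line {lineno}: bad weight {parts[2]!r}") from None
    return parts[0], parts[1], w


def read_edgelist(path: str | Path) -> tuple[Graph, LabelMap]:
    """Read a whitespace-separated edge list.

    Duplicate edges collapse to the maximum weight; self-loops are
    dropped with a warning.
    """
    labels: list[str] = []
    seen: dict[str, int] = {}
    edges: list[tuple[int, int]] = []
    weights: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            u, v, w = _parse_edge_line(line, lineno)
            for name in (u, v):
                if name not in seen:
                    seen[name] = len(labels)
                    labels.append(name)
            if u == v:
                logger.warning("line %d: dropped self-loop on %r", lineno, u)
                continue
            edges.append((seen[u], seen[v]))
            weights.append(w)
    label_map = LabelMap(labels)
    graph = Graph.from_edges(len(labels), edges, weights, node_labels=list(labels))
    return graph, label_map


def write_edgelist(graph: Graph, label_map: LabelMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, j, w in graph.edge_list():
            wtxt = f"{int(w)}" if float(w).is_integer() else f"{w!r}"
            fh.write(f"{label_map.label(i)} {label_map.label(j)} {wtxt}\n")


def read_gml(path: str | Path) -> tuple[Graph, LabelMap]:
    """Read a GML network as an undirected binary graph.

    Duplicate edges collapse (warning); node ``label`` attributes are
    preserved as identifiers, falling back to the GML id.
    """
    text = Path(path).read_text()
    try:
        g = nx.parse_gml(text, label="label")
    except Exception as exc:
        if "duplicated" in str(exc):
            # re-parse as a multigraph so duplicate edges collapse instead
            # of aborting, then warn
            g = nx.parse_gml(
                text.replace("graph [", "graph [\n  multigraph 1", 1), label="label"
            )
            logger.warning("collapsed duplicate edge(s) in %s", path)
        else:
            raise InputError(f"cannot parse GML file {path}: {exc}") from exc
    g = nx.Graph(g)  # drop direction / parallel edges
    n_loops = nx.number_of_selfloops(g)
    if n_loops:
        logger.warning("dropped %d self-loop(s) from %s", n_loops, path)
        g.remove_edges_from(nx.selfloop_edges(g))
    labels = [str(v) for v in g.nodes()]
    label_map = LabelMap(labels)
    edges = [(label_map.index(str(u)), label_map.index(str(v))) for u, v in g.edges()]
    graph = Graph.from_edges(len(labels), edges, node_labels=list(labels))
    return graph, label_map


def read_constraints(path: str | Path, label_map: LabelMap) -> ConstraintSet:
    """Read TSV constraints ``u<TAB>v<TAB>ML|CL`` against known nodes."""
    ml: set[tuple[int, int]] = set()
    cl: set[tuple[int, int]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 3:
                raise InputError(f"line {lineno}: expected 'u<TAB>v<TAB>ML|CL'")
            u, v, tag = parts
            pair = (label_map.index(u), label_map.index(v))
            if tag == "ML":
                ml.add(pair)
            elif tag == "CL":
                cl.add(pair)
            else:
                raise InputError(f"line {lineno}: unknown constraint tag {tag!r}")
    return ConstraintSet(frozenset(ml), frozenset(cl))


def write_constraints(
    constraints: ConstraintSet, label_map: LabelMap, path: str | Path
) -> None:
    with open(path, "w") as fh:
        for i, j in sorted(constraints.must_links):
            fh.write(f"{label_map.label(i)}\t{label_map.label(j)}\tML\n")
        for i, j in sorted(constraints.cannot_links):
            fh.write(f"{label_map.label(i)}\t{label_map.label(j)}\tCL\n")


def read_partition(path: str | Path, label_map: LabelMap) -> Partition:
    """Read TSV ``node<TAB>label``; every known node must appear once."""
    assigned: dict[int, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise InputError(f"line {lineno}: expected 'node<TAB>label'")
            assigned[label_map.index(parts[0])] = parts[1]
    missing = set(range(len(label_map))) - set(assigned)
    if missing:
        raise InputError(f"partition file misses {len(missing)} node(s)")
    return Partition(np.asarray([assigned[i] for i in range(len(label_map))], dtype=object))


def write_partition(partition: Partition, label_map: LabelMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in range(partition.n_nodes):
            fh.write(f"{label_map.label(i)}\t{partition.labels[i]}\n")


def write_supernetwork(
    sn: SuperNetwork, label_map: LabelMap, prefix: str | Path
) -> tuple[Path, Path]:
    """Export a super-network as ``<prefix>.edges`` (weighted super-edge
    list over SN0..SNk ids) and ``<prefix>.membership.tsv``."""
    prefix = Path(prefix)
    edges_path = prefix.with_name(prefix.name + ".edges")
    members_path = prefix.with_name(prefix.name + ".membership.tsv")
    with open(edges_path, "w") as fh:
        for i, j, w in sn.super_graph.edge_list():
            wtxt = f"{int(w)}" if float(w).is_integer() else f"{w!r}"
            fh.write(f"SN{i} SN{j} {wtxt}\n")
    with open(members_path, "w") as fh:
        for s, members in enumerate(sn.members):
            for v in members:
                fh.write(f"{label_map.label(int(v))}\tSN{s}\n")
    return edges_path, members_path
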