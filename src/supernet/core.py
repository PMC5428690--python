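"""Domain types and the super-network construction pipeline.

A *super-network* is a contraction of an undirected network driven by
pairwise supervision: must-link (ML) pairs assert that two nodes share a
community, cannot-link (CL) pairs assert that they do not.  Nodes joined
by must-links are merged into indivisible *super-nodes* — the connected
components of the must-link graph — so every must-link is satisfied by
construction.  The super-adjacency accumulates original edge weight
between member sets, ``A_s = B^T A B`` with the diagonal zeroed, where
``B`` is the binary node-to-super-node assignment matrix.  Cannot-links
are lifted to super-node level, ``C_s = B^T C B``, and contradicted
super-edges are suppressed elementwise::

    A_s <- max(A_s - alpha * C_s, 0)

with ``alpha`` defaulting to the largest entry of ``A_s`` so suppression
wins regardless of super-edge weight.  Running any community detector on
the contracted graph and projecting labels back to the original nodes
yields a semi-supervised detector; the contraction is linear in the
network size plus the number of constraints.

Inconsistent supervision (a cannot-link inside a must-link component) is
resolved before contraction by giving cannot-links priority: every
must-link of an offending component is demoted to an ordinary weight-1
edge and the cannot-link is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "InputError",
    "ConsistencyError",
    "GenerationError",
    "Graph",
    "ConstraintSet",
    "NodeAssignment",
    "SuperNetwork",
    "Partition",
    "resolve_inconsistency",
    "build_supernodes",
    "init_super_adjacency",
    "lift_constraints",
    "refine_with_cannot_links",
    "construct_supernetwork",
    "project_labels",
    "modtop",
]


class InputError(ValueError):
    """Invalid user-supplied input (bad indices, malformed files, ...)."""


class ConsistencyError(InputError):
    """Constraints violate an operation's precondition (unresolved CL/ML)."""


class GenerationError(RuntimeError):
    """A benchmark generator could not satisfy its parameters."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Graph:
    """Undirected weighted graph as a symmetric sparse adjacency matrix.

    Parameters
    ----------
    weights
        ``n x n`` symmetric nonnegative matrix with zero diagonal.  Input
        networks carry 0/1 weights; super-networks carry nonnegative
        integer-valued weights.
    node_labels
        Optional original (string) identifiers, index-aligned.
    """

    weights: sp.csr_array
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        w = sp.csr_array(self.weights, dtype=float)
        if w.shape[0] != w.shape[1]:
            raise InputError(f"adjacency must be square, got {w.shape}")
        diff = (w - w.T).tocoo()
        if diff.nnz and np.max(np.abs(diff.data)) > 1e-9:
            raise InputError("adjacency must be symmetric")
        if w.nnz and w.data.min() < 0:
            raise InputError("edge weights must be nonnegative")
        if np.any(w.diagonal() != 0):
            raise InputError("self-loops are not supported (nonzero diagonal)")
        w.eliminate_zeros()
        self.weights = w
        if self.node_labels is not None and len(self.node_labels) != w.shape[0]:
            raise InputError("node_labels length does not match node count")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of (undirected) edges with nonzero weight."""
        return int(self.weights.nnz // 2)

    @property
    def total_weight(self) -> float:
        """Sum of weights over undirected edges (each edge counted once)."""
        return float(self.weights.sum() / 2.0)

    def dense(self) -> np.ndarray:
        return self.weights.toarray()

    @classmethod
    def from_edges(
        cls,
        n_nodes: int,
        edges: Iterable[tuple[int, int]],
        weights: Iterable[float] | None = None,
        node_labels: list[str] | None = None,
    ) -> "Graph":
        """Build a graph from an iterable of (i, j) pairs.

        Duplicate pairs collapse to the maximum weight; ordering of the
        endpoints is irrelevant.
        """
        acc: dict[tuple[int, int], float] = {}
        edges = list(edges)
        wlist = list(weights) if weights is not None else [1.0] * len(edges)
        if len(wlist) != len(edges):
            raise InputError("weights length does not match edges length")
        for (i, j), w in zip(edges, wlist):
            i, j = int(i), int(j)
            if not (0 <= i < n_nodes and 0 <= j < n_nodes):
                raise InputError(f"edge ({i},{j}) out of range for {n_nodes} nodes")
            if i == j:
                raise InputError(f"self-loop ({i},{i}) is not supported")
            key = (min(i, j), max(i, j))
            acc[key] = max(acc.get(key, 0.0), float(w))
        if acc:
            rows, cols, data = [], [], []
            for (i, j), w in acc.items():
                rows += [i, j]
                cols += [j, i]
                data += [w, w]
            mat = sp.coo_array((data, (rows, cols)), shape=(n_nodes, n_nodes)).tocsr()
        else:
            mat = sp.csr_array((n_nodes, n_nodes))
        return cls(mat, node_labels=node_labels)

    def edge_list(self) -> list[tuple[int, int, float]]:
        """Undirected edges as (i, j, w) with i < j, sorted."""
        coo = self.weights.tocoo()
        out = [
            (int(i), int(j), float(w))
            for i, j, w in zip(coo.row, coo.col, coo.data)
            if i < j
        ]
        return sorted(out)


def _canon_pairs(pairs: Iterable[tuple[int, int]]) -> frozenset[tuple[int, int]]:
    out = set()
    for i, j in pairs:
        i, j = int(i), int(j)
        if i == j:
            raise InputError(f"constraint pair ({i},{j}) has identical endpoints")
        out.add((min(i, j), max(i, j)))
    return frozenset(out)


@dataclass(frozen=True)
class ConstraintSet:
    """Must-link and cannot-link node pairs (unordered, distinct endpoints)."""

    must_links: frozenset[tuple[int, int]] = frozenset()
    cannot_links: frozenset[tuple[int, int]] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "must_links", _canon_pairs(self.must_links))
        object.__setattr__(self, "cannot_links", _canon_pairs(self.cannot_links))

    def validate_indices(self, n_nodes: int) -> None:
        for i, j in list(self.must_links) + list(self.cannot_links):
            if not (0 <= i < n_nodes and 0 <= j < n_nodes):
                raise InputError(f"constraint ({i},{j}) out of range for {n_nodes} nodes")

    @property
    def n_constraints(self) -> int:
        return len(self.must_links) + len(self.cannot_links)


@dataclass
class NodeAssignment:
    """Node -> super-node assignment (the binary matrix ``B``)."""

    n_nodes: int
    n_super: int
    assign: np.ndarray  # shape (n_nodes,), values in [0, n_super)

    def __post_init__(self) -> None:
        self.assign = np.asarray(self.assign, dtype=np.int64)
        if self.assign.shape != (self.n_nodes,):
            raise InputError("assignment vector has wrong length")
        if self.n_super > self.n_nodes or self.n_super < 1 and self.n_nodes > 0:
            raise InputError("invalid number of super-nodes")
        counts = np.bincount(self.assign, minlength=self.n_super)
        if self.assign.size and (self.assign.min() < 0 or self.assign.max() >= self.n_super):
            raise InputError("assignment refers to an unknown super-node")
        if np.any(counts == 0):
            raise InputError("every super-node must have at least one member")

    @property
    def B(self) -> sp.csr_array:
        """Sparse ``n_nodes x n_super`` indicator matrix, one 1 per row."""
        data = np.ones(self.n_nodes)
        rows = np.arange(self.n_nodes)
        return sp.coo_array(
            (data, (rows, self.assign)), shape=(self.n_nodes, self.n_super)
        ).tocsr()

    def members(self) -> list[np.ndarray]:
        """Original node indices of each super-node."""
        order = np.argsort(self.assign, kind="stable")
        bounds = np.searchsorted(self.assign[order], np.arange(self.n_super + 1))
        return [order[bounds[s] : bounds[s + 1]] for s in range(self.n_super)]

    @classmethod
    def identity(cls, n_nodes: int) -> "NodeAssignment":
        return cls(n_nodes, n_nodes, np.arange(n_nodes))


@dataclass
class SuperNetwork:
    """The full product of the construction pipeline, kept for inspection."""

    assignment: NodeAssignment
    super_graph: Graph  # refined A_s
    super_cl: sp.csr_array  # C_s
    members: list[np.ndarray]
    demoted_links: list[tuple[int, int]]
    unrefined_super_graph: Graph | None = None  # A_s before CL suppression

    @property
    def n_super(self) -> int:
        return self.assignment.n_super


@dataclass
class Partition:
    """Community assignment: one label per node."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1:
            raise InputError("labels must be one-dimensional")

    @property
    def n_nodes(self) -> int:
        return self.labels.shape[0]

    @property
    def k(self) -> int:
        return len(np.unique(self.labels))

    def codes(self) -> np.ndarray:
        """Labels recoded to 0..k-1 in order of first appearance value."""
        _, codes = np.unique(self.labels, return_inverse=True)
        return codes


# ---------------------------------------------------------------------------
# Union-find (must-link components in near-linear time)
# ---------------------------------------------------------------------------


class _DisjointSet:
    __slots__ = ("parent", "rank")

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1


# ---------------------------------------------------------------------------
# Step 0: inconsistency resolution (cannot-link has priority)
# ---------------------------------------------------------------------------


def resolve_inconsistency(
    constraints: ConstraintSet, n_nodes: int | None = None
) -> tuple[ConstraintSet, list[tuple[int, int]]]:
    """Resolve ML/CL contradictions by demoting must-links.

    A cannot-link internal to a must-link connected component proves that
    at least one constraint in that component is wrong, so none of its
    must-links is trusted: *all* must-links of the component are removed
    and returned as ``demoted`` (to be re-added as ordinary weight-1
    edges), while every cannot-link is retained.

    Returns the cleaned constraint set and the demoted pairs (sorted).
    """
    if not constraints.must_links:
        return constraints, []
    if n_nodes is not None:
        constraints.validate_indices(n_nodes)
    nodes = {v for pair in constraints.must_links for v in pair}
    index = {v: i for i, v in enumerate(sorted(nodes))}
    dsu = _DisjointSet(len(index))
    for i, j in constraints.must_links:
        dsu.union(index[i], index[j])
    bad_roots = {
        dsu.find(index[i])
        for i, j in constraints.cannot_links
        if i in index and j in index and dsu.find(index[i]) == dsu.find(index[j])
    }
    if not bad_roots:
        return constraints, []
    demoted = sorted(
        p for p in constraints.must_links if dsu.find(index[p[0]]) in bad_roots
    )
    kept = constraints.must_links - set(demoted)
    logger.info(
        "inconsistent supervision: demoted %d must-link(s) in %d component(s)",
        len(demoted),
        len(bad_roots),
    )
    return ConstraintSet(kept, constraints.cannot_links), demoted


# ---------------------------------------------------------------------------
# Step 1: super-node construction
# ---------------------------------------------------------------------------


def build_supernodes(constraints: ConstraintSet, n_nodes: int) -> NodeAssignment:
    """Merge must-link connected components into super-nodes.

    Nodes untouched by any must-link become singleton super-nodes.
    Super-node indices are ordered by smallest member node index, so the
    result is deterministic.
    """
    constraints.validate_indices(n_nodes)
    if n_nodes == 0:
        return NodeAssignment(0, 0, np.empty(0, dtype=np.int64))
    dsu = _DisjointSet(n_nodes)
    for i, j in constraints.must_links:
        dsu.union(i, j)
    roots = np.fromiter((dsu.find(v) for v in range(n_nodes)), dtype=np.int64, count=n_nodes)
    # first occurrence order of roots == order by smallest member index
    _, first_pos, inverse = np.unique(roots, return_index=True, return_inverse=True)
    order = np.argsort(np.argsort(first_pos))
    assign = order[inverse]
    return NodeAssignment(n_nodes, int(assign.max()) + 1 if n_nodes else 0, assign)


# ---------------------------------------------------------------------------
# Step 2: super-network initialization  (A_s = B^T A B, zero diagonal)
# ---------------------------------------------------------------------------


def init_super_adjacency(graph: Graph, assignment: NodeAssignment) -> Graph:
    """Accumulate original edge weight between super-node member sets.

    The weight between super-nodes ``i != j`` is the total weight of
    original edges spanning their members; the diagonal (intra-super-node
    weight) is forced to zero so the contracted matrix has the same
    structure as an ordinary adjacency matrix.
    """
    if assignment.n_nodes != graph.n_nodes:
        raise InputError(
            f"assignment covers {assignment.n_nodes} nodes, graph has {graph.n_nodes}"
        )
    B = assignment.B
    a_s = (B.T @ graph.weights @ B).tocsr()
    a_s.setdiag(0)
    a_s.eliminate_zeros()
    return Graph(a_s)


# ---------------------------------------------------------------------------
# Step 3a: lift cannot-links  (C_s = B^T C B)
# ---------------------------------------------------------------------------


def lift_constraints(
    cannot_links: Iterable[tuple[int, int]], assignment: NodeAssignment
) -> sp.csr_array:
    """Count cannot-link pairs spanning each pair of super-nodes.

    Raises :class:`ConsistencyError` if a cannot-link falls inside a
    single super-node — a sign that inconsistency resolution was skipped.
    """
    n_s = assignment.n_super
    pairs = _canon_pairs(cannot_links)
    if not pairs:
        return sp.csr_array((n_s, n_s))
    rows, cols = [], []
    for i, j in pairs:
        if not (0 <= i < assignment.n_nodes and 0 <= j < assignment.n_nodes):
            raise InputError(f"cannot-link ({i},{j}) out of range")
        si, sj = int(assignment.assign[i]), int(assignment.assign[j])
        if si == sj:
            raise ConsistencyError(
                f"cannot-link ({i},{j}) is internal to super-node {si}; "
                "run resolve_inconsistency first"
            )
        rows += [si, sj]
        cols += [sj, si]
    data = np.ones(len(rows))
    return sp.coo_array((data, (rows, cols)), shape=(n_s, n_s)).tocsr()


# ---------------------------------------------------------------------------
# Step 3b: refinement  (A_s <- max(A_s - alpha C_s, 0))
# ---------------------------------------------------------------------------


def refine_with_cannot_links(
    super_graph: Graph, super_cl: sp.csr_array, alpha: float | str = "auto"
) -> Graph:
    """Suppress super-edges contradicted by lifted cannot-links.

    With ``alpha="auto"`` the penalty equals the largest super-edge
    weight, which zeroes every cannot-linked entry exactly (``C_s``
    entries are >= 1 wherever nonzero); entries without a cannot-link are
    untouched.
    """
    w = super_graph.weights
    c = sp.csr_array(super_cl, dtype=float)
    if c.shape != w.shape:
        raise InputError(f"shape mismatch: A_s {w.shape} vs C_s {c.shape}")
    if alpha == "auto":
        alpha_val = float(w.data.max()) if w.nnz else 0.0
    else:
        alpha_val = float(alpha)
        if alpha_val < 0:
            raise InputError("alpha must be nonnegative")
    refined = (w - c * alpha_val).maximum(0).tocsr()
    refined.eliminate_zeros()
    return Graph(refined)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def _add_unit_edges(graph: Graph, pairs: Sequence[tuple[int, int]]) -> Graph:
    """Add weight-1 edges where absent; existing edges are left untouched."""
    if not pairs:
        return graph
    w = graph.weights.tolil()
    added = 0
    for i, j in pairs:
        if w[i, j] == 0:
            w[i, j] = 1.0
            w[j, i] = 1.0
            added += 1
    if added:
        logger.info("added %d demoted must-link(s) as weight-1 edges", added)
    return Graph(w.tocsr(), node_labels=graph.node_labels)


def construct_supernetwork(graph: Graph, constraints: ConstraintSet) -> SuperNetwork:
    """Run the three-step contraction: super-nodes, initialization, refinement.

    The pipeline is: resolve inconsistent supervision, add demoted
    must-links as ordinary weight-1 edges, contract must-link components
    into super-nodes, accumulate the super-adjacency, lift cannot-links
    and suppress contradicted super-edges (automatic ``alpha``).  All
    intermediate products are retained on the returned
    :class:`SuperNetwork`.  Total work is proportional to
    ``M + N + |ML| + |CL|``.
    """
    constraints.validate_indices(graph.n_nodes)
    resolved, demoted = resolve_inconsistency(constraints, graph.n_nodes)
    work_graph = _add_unit_edges(graph, demoted)
    assignment = build_supernodes(resolved, graph.n_nodes)
    a_s = init_super_adjacency(work_graph, assignment)
    c_s = lift_constraints(resolved.cannot_links, assignment)
    refined = refine_with_cannot_links(a_s, c_s, alpha="auto")
    logger.info(
        "super-network: %d -> %d nodes, %d -> %d edges (%d CL-suppressed entries)",
        graph.n_nodes,
        assignment.n_super,
        work_graph.n_edges,
        refined.n_edges,
        a_s.n_edges - refined.n_edges,
    )
    return SuperNetwork(
        assignment=assignment,
        super_graph=refined,
        super_cl=c_s,
        members=assignment.members(),
        demoted_links=list(demoted),
        unrefined_super_graph=a_s,
    )


def project_labels(super_partition: Partition, assignment: NodeAssignment) -> Partition:
    """Copy each super-node's community label to its member nodes."""
    if super_partition.n_nodes != assignment.n_super:
        raise InputError(
            f"partition labels {super_partition.n_nodes} super-nodes, "
            f"assignment has {assignment.n_super}"
        )
    labels = super_partition.labels[assignment.assign]
    k_before, k_after = super_partition.k, len(np.unique(labels))
    if k_after < k_before:
        logger.info("projection dropped %d empty label(s)", k_before - k_after)
    return Partition(labels)


# ---------------------------------------------------------------------------
# ModTop baseline (adjacency editing without contraction)
# ---------------------------------------------------------------------------


def modtop(graph: Graph, constraints: ConstraintSet, ml_weight: float = 1.0) -> Graph:
    """Edit the adjacency in place of contracting it.

    Each must-link pair's weight is set to ``ml_weight`` (replacing any
    existing weight) and each cannot-link pair's weight is set to zero.
    This increases the probability that constraints are respected but,
    unlike the super-network, does not guarantee them.
    """
    constraints.validate_indices(graph.n_nodes)
    w = graph.weights.tolil()
    for i, j in constraints.must_links:
        w[i, j] = ml_weight
        w[j, i] = ml_weight
    for i, j in constraints.cannot_links:
        w[i, j] = 0.0
        w[j, i] = 0.0
    return Graph(w.tocsr(), node_labels=graph.node_labels)
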