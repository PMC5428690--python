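"""Planted-partition benchmark generators and the constraint sampler.

Two classic synthetic benchmarks with known ground truth:

* **GN** (Girvan–Newman): 128 nodes in four communities of 32; every
  node has expected degree 16, split into ``z_in`` intra-community and
  ``z_out`` inter-community edges (``z_in + z_out = 16``).  ``z_out``
  controls how blurred the community structure is.
* **LFR** (Lancichinetti–Fortunato–Radicchi): power-law degree and
  community-size distributions; the mixing parameter ``mu`` is the
  fraction of inter-community edges.  Defaults follow the common
  setting: 1000 nodes, community sizes in [10, 50], degree exponent 2,
  community-size exponent 1.

``sample_constraints`` emulates an annotator consulting the planted
truth: a fixed fraction of all node pairs is drawn uniformly without
replacement, each pair labeled must-link if the two nodes share a
planted community and cannot-link otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .core import ConstraintSet, GenerationError, Graph, InputError, Partition

logger = logging.getLogger(__name__)

__all__ = [
    "GNParams",
    "LFRParams",
    "BenchmarkInstance",
    "generate_gn",
    "generate_lfr",
    "sample_constraints",
]


@dataclass
class GNParams:
    """GN benchmark settings: 4 communities of 32 nodes, mean degree 16."""

    z_out: float
    n_communities: int = 4
    community_size: int = 32
    mean_degree: float = 16.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.z_out <= self.mean_degree):
            raise InputError(f"z_out must lie in [0, {self.mean_degree}]")

    @property
    def z_in(self) -> float:
        return self.mean_degree - self.z_out

    @property
    def n_nodes(self) -> int:
        return self.n_communities * self.community_size


@dataclass
class LFRParams:
    """LFR benchmark settings.

    ``mu`` is the requested fraction of inter-community edges; the
    generator retries until the realized fraction is within
    ``mixing_tol`` of it.  ``mean_degree`` and ``max_degree`` default to
    the common 20/50 setting.
    """

    mu: float
    n_nodes: int = 1000
    degree_exponent: float = 2.0
    community_size_exponent: float = 1.0
    min_community: int = 10
    max_community: int = 50
    mean_degree: float = 20.0
    max_degree: int = 50
    seed: int | None = None
    mixing_tol: float = 0.02
    max_attempts: int = 20

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu <= 1.0):
            raise InputError("mu must lie in [0, 1]")
        if not (self.min_community <= self.max_community <= self.n_nodes):
            raise InputError("community size bounds must satisfy min <= max <= N")


@dataclass
class BenchmarkInstance:
    """A generated network with its planted partition."""

    graph: Graph
    truth: Partition
    params: Any
    seed: int | None


# ---------------------------------------------------------------------------
# GN benchmark
# ---------------------------------------------------------------------------


def generate_gn(params: GNParams) -> BenchmarkInstance:
    """Planted 4-block model with exact expected intra/inter degrees.

    Intra-community pairs link with probability ``z_in / (s - 1)`` and
    inter-community pairs with ``z_out / (n - s)`` (``s`` the community
    size), so expected intra and inter degrees equal ``z_in`` and
    ``z_out`` exactly.
    """
    rng = np.random.default_rng(params.seed)
    n, s = params.n_nodes, params.community_size
    labels = np.repeat(np.arange(params.n_communities), s)
    p_in = params.z_in / (s - 1)
    p_out = params.z_out / (n - s)
    same = labels[:, None] == labels[None, :]
    prob = np.where(same, p_in, p_out)
    upper = np.triu(rng.random((n, n)) < prob, k=1)
    adjacency = (upper | upper.T).astype(float)
    graph = Graph.from_edges(n, list(zip(*np.nonzero(np.triu(adjacency, k=1)))))
    return BenchmarkInstance(graph, Partition(labels), params, params.seed)


# ---------------------------------------------------------------------------
# LFR benchmark
# ---------------------------------------------------------------------------


def _powerlaw_probs(exponent: float, lo: int, hi: int) -> np.ndarray:
    support = np.arange(lo, hi + 1, dtype=float)
    probs = support**-exponent
    return probs / probs.sum()


def _degree_lower_bound(params: LFRParams) -> int:
    """Smallest support bound whose truncated power-law mean is closest
    to the requested mean degree."""
    best, best_err = 1, np.inf
    for lo in range(1, params.max_degree):
        support = np.arange(lo, params.max_degree + 1, dtype=float)
        probs = support**-params.degree_exponent
        mean = float((support * probs).sum() / probs.sum())
        err = abs(mean - params.mean_degree)
        if err < best_err:
            best, best_err = lo, err
    return best


def _sample_community_sizes(params: LFRParams, rng: np.random.Generator) -> np.ndarray:
    lo, hi = params.min_community, params.max_community
    probs = _powerlaw_probs(params.community_size_exponent, lo, hi)
    support = np.arange(lo, hi + 1)
    sizes: list[int] = []
    total = 0
    while total < params.n_nodes:
        s = int(rng.choice(support, p=probs))
        if total + s > params.n_nodes:
            remainder = params.n_nodes - total
            if remainder >= lo:
                sizes.append(remainder)
                total += remainder
            else:
                # distribute the remainder over existing communities
                for _ in range(remainder):
                    open_idx = [i for i, sz in enumerate(sizes) if sz < hi]
                    if not open_idx:
                        raise GenerationError("cannot place remaining nodes in size bounds")
                    sizes[int(rng.choice(open_idx))] += 1
                total = params.n_nodes
            break
        sizes.append(s)
        total += s
    return np.asarray(sizes, dtype=np.int64)


def _match_internal(
    stubs: np.ndarray, rng: np.random.Generator, rounds: int = 50
) -> list[tuple[int, int]]:
    """Configuration-model matching within one community; self- and
    multi-edges are rejected and re-matched, leftovers dropped."""
    edges: set[tuple[int, int]] = set()
    pool = stubs.copy()
    for _ in range(rounds):
        if len(pool) < 2:
            break
        rng.shuffle(pool)
        if len(pool) % 2:
            pool = pool[:-1]
        left, right = pool[0::2], pool[1::2]
        bad: list[int] = []
        for u, v in zip(left, right):
            if u == v:
                bad += [u, v]
                continue
            e = (min(u, v), max(u, v))
            if e in edges:
                bad += [u, v]
            else:
                edges.add(e)
        pool = np.asarray(bad, dtype=np.int64)
    return sorted(edges)


def _match_external(
    stubs: np.ndarray,
    community: np.ndarray,
    existing: set[tuple[int, int]],
    rng: np.random.Generator,
    rounds: int = 50,
) -> list[tuple[int, int]]:
    """Global matching of external stubs; pairs within one community are
    rejected alongside self/multi-edges."""
    edges: set[tuple[int, int]] = set()
    pool = stubs.copy()
    for _ in range(rounds):
        if len(pool) < 2:
            break
        rng.shuffle(pool)
        if len(pool) % 2:
            pool = pool[:-1]
        left, right = pool[0::2], pool[1::2]
        bad: list[int] = []
        for u, v in zip(left, right):
            if u == v or community[u] == community[v]:
                bad += [u, v]
                continue
            e = (min(u, v), max(u, v))
            if e in edges or e in existing:
                bad += [u, v]
            else:
                edges.add(e)
        pool = np.asarray(bad, dtype=np.int64)
    return sorted(edges)


def _lfr_attempt(
    params: LFRParams, rng: np.random.Generator
) -> tuple[Graph, np.ndarray, float]:
    n = params.n_nodes
    lo = _degree_lower_bound(params)
    deg_support = np.arange(lo, params.max_degree + 1)
    deg_probs = _powerlaw_probs(params.degree_exponent, lo, params.max_degree)
    degrees = rng.choice(deg_support, size=n, p=deg_probs)

    sizes = _sample_community_sizes(params, rng)
    n_comm = len(sizes)

    internal = np.rint((1.0 - params.mu) * degrees).astype(np.int64)

    # capacity-aware random assignment, hardest (largest internal) first
    community = np.full(n, -1, dtype=np.int64)
    capacity = sizes.copy()
    order = np.argsort(-internal, kind="stable")
    for v in order:
        feasible = np.where((capacity > 0) & (sizes - 1 >= internal[v]))[0]
        if len(feasible):
            c = int(rng.choice(feasible, p=capacity[feasible] / capacity[feasible].sum()))
        else:
            open_comms = np.where(capacity > 0)[0]
            c = int(open_comms[np.argmax(sizes[open_comms])])
            internal[v] = sizes[c] - 1  # clip: excess becomes external stubs
        community[v] = c
        capacity[c] -= 1

    external = degrees - internal
    if params.mu == 0.0:
        external[:] = 0  # no inter-community edges at all

    # per-community internal stub parity: move one stub to external
    for c in range(n_comm):
        members = np.where(community == c)[0]
        if internal[members].sum() % 2:
            v = members[np.argmax(internal[members])]
            internal[v] -= 1
            if params.mu > 0.0:
                external[v] += 1

    edges: list[tuple[int, int]] = []
    for c in range(n_comm):
        members = np.where(community == c)[0]
        stubs = np.repeat(members, internal[members])
        edges.extend(_match_internal(stubs, rng))
    intra_count = len(edges)

    ext_stubs = np.repeat(np.arange(n), external)
    edges.extend(_match_external(ext_stubs, community, set(edges), rng))
    inter_count = len(edges) - intra_count

    total = intra_count + inter_count
    mixing = inter_count / total if total else 0.0
    return Graph.from_edges(n, edges), community, mixing


def generate_lfr(params: LFRParams) -> BenchmarkInstance:
    """Generate an LFR network, retrying until the realized mixing
    fraction is within ``mixing_tol`` of the requested ``mu``.

    Raises :class:`GenerationError` with the attempted mixing values if
    no attempt lands inside the tolerance.
    """
    rng = np.random.default_rng(params.seed)
    attempts: list[float] = []
    for _ in range(params.max_attempts):
        graph, community, mixing = _lfr_attempt(params, rng)
        attempts.append(mixing)
        if abs(mixing - params.mu) <= params.mixing_tol:
            logger.info(
                "LFR: N=%d, %d communities, realized mixing %.3f (target %.3f)",
                params.n_nodes,
                len(np.unique(community)),
                mixing,
                params.mu,
            )
            return BenchmarkInstance(graph, Partition(community), params, params.seed)
    raise GenerationError(
        f"LFR mixing never reached {params.mu}+/-{params.mixing_tol} in "
        f"{params.max_attempts} attempts (got {attempts})"
    )


# ---------------------------------------------------------------------------
# Ground-truth constraint sampling
# ---------------------------------------------------------------------------


def _decode_pair_indices(idx: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Map linear indices of the strict upper triangle to (i, j) pairs."""
    # row i occupies indices [i(2n-1-i)/2, (i+1)(2n-2-i)/2); invert the
    # quadratic, then fix float rounding at row boundaries
    idx = idx.astype(np.int64)
    b = 2 * n - 1
    i = np.floor((b - np.sqrt(b * b - 8.0 * idx)) / 2.0).astype(np.int64)
    row_start = (i * (b - i)) // 2
    i[row_start > idx] -= 1
    next_start = ((i + 1) * (b - i - 1)) // 2
    i[next_start <= idx] += 1
    row_start = (i * (b - i)) // 2
    j = (idx - row_start) + i + 1
    return i, j


def sample_constraints(
    truth: Partition, fraction: float, seed: int | None = None
) -> ConstraintSet:
    """Draw a fraction of all node pairs and label them from the truth.

    ``round(fraction * N(N-1)/2)`` unordered pairs are sampled uniformly
    without replacement; same-community pairs become must-links, the
    rest cannot-links.
    """
    if not (0.0 <= fraction <= 1.0):
        raise InputError("fraction must lie in [0, 1]")
    n = truth.n_nodes
    total = n * (n - 1) // 2
    m = int(round(fraction * total))
    if m == 0:
        return ConstraintSet()
    rng = np.random.default_rng(seed)
    chosen = rng.choice(total, size=m, replace=False)
    i, j = _decode_pair_indices(chosen.astype(np.float64), n)
    same = truth.labels[i] == truth.labels[j]
    ml = frozenset(zip(i[same].tolist(), j[same].tolist()))
    cl = frozenset(zip(i[~same].tolist(), j[~same].tolist()))
    return ConstraintSet(ml, cl)
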