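"""Community detection back-ends for (weighted) graphs.

Two detectors are provided, both operating directly on a weighted
adjacency matrix so they apply unchanged to contracted super-networks:

* **Symmetric NMF** — find a nonnegative factor ``H`` (n x k)
  approximately minimizing ``||A - H H^T||_F^2`` with a damped
  multiplicative update; node ``i`` joins the community of its largest
  membership, ``argmax_j H[i, j]``.
* **Spectral modularity maximization** — Newman's leading-eigenvector
  method: recursive bisection of the (group-restricted) modularity
  matrix, with optional single-node fine-tuning, forced median splits
  when exactly ``k`` communities are required but no split has positive
  modularity gain.

``semi_supervised_detect`` wires either detector into the super-network
or ModTop pipelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .core import (
    ConstraintSet,
    Graph,
    InputError,
    Partition,
    construct_supernetwork,
    modtop,
    project_labels,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SnmfConfig",
    "SpectralConfig",
    "snmf_detect",
    "snmf_factorize",
    "spectral_modularity_detect",
    "modularity",
    "semi_supervised_detect",
]

_EPS = 1e-12


@dataclass
class SnmfConfig:
    """Settings for symmetric NMF detection.

    ``restarts`` independent random initializations are run and the
    factorization with the lowest objective is kept; ``tol`` is the
    relative objective-change stopping threshold.
    """

    k: int
    max_iters: int = 500
    tol: float = 1e-6
    seed: int | None = None
    restarts: int = 5

    def __post_init__(self) -> None:
        if self.k < 1 or self.max_iters < 1 or self.tol <= 0 or self.restarts < 1:
            raise InputError("invalid SNMF configuration")


@dataclass
class SpectralConfig:
    """Settings for spectral modularity maximization."""

    k: int
    refine: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise InputError("k must be >= 1")


# ---------------------------------------------------------------------------
# Symmetric NMF
# ---------------------------------------------------------------------------


def _snmf_run(
    a: np.ndarray, h: np.ndarray, max_iters: int, tol: float
) -> tuple[np.ndarray, float, list[float]]:
    """Damped multiplicative updates H <- H * (1/2 + 1/2 (AH)/(HH^T H)).

    The 1/2 damping guarantees a non-increasing objective for the
    symmetric factorization.  Returns the factor, the final objective
    ``||A - HH^T||_F^2`` and the per-iteration objective trace.
    """
    a_norm2 = float(np.sum(a * a))

    def objective(h: np.ndarray, ah: np.ndarray | None = None) -> float:
        if ah is None:
            ah = a @ h
        g = h.T @ h
        # ||A - HH^T||^2 = ||A||^2 - 2 tr(H^T A H) + ||H^T H||^2
        return a_norm2 - 2.0 * float(np.sum(h * ah)) + float(np.sum(g * g))

    trace = [objective(h)]
    for _ in range(max_iters):
        ah = a @ h
        hhh = h @ (h.T @ h)
        h = h * (0.5 + 0.5 * ah / np.maximum(hhh, _EPS))
        obj = objective(h)
        trace.append(obj)
        prev = trace[-2]
        if abs(prev - obj) <= tol * max(abs(prev), _EPS):
            break
    return h, trace[-1], trace


def snmf_factorize(
    graph: Graph, config: SnmfConfig, init: np.ndarray | None = None
) -> tuple[np.ndarray, float, list[float]]:
    """Best-of-restarts symmetric NMF; returns (H, objective, trace).

    ``init`` optionally fixes the initial factor of a single run
    (restarts are then ignored) — useful for reproducibility studies.
    """
    n = graph.n_nodes
    if config.k > n:
        raise InputError(f"k={config.k} exceeds the {n} available nodes")
    a = graph.dense()
    if init is not None:
        h0 = np.asarray(init, dtype=float)
        if h0.shape != (n, config.k):
            raise InputError("init factor has wrong shape")
        return _snmf_run(a, h0, config.max_iters, config.tol)
    rng = np.random.default_rng(config.seed)
    scale = np.sqrt(max(a.mean(), _EPS) / config.k)
    best: tuple[np.ndarray, float, list[float]] | None = None
    for _ in range(config.restarts):
        h0 = rng.random((n, config.k)) * scale
        result = _snmf_run(a, h0, config.max_iters, config.tol)
        if best is None or result[1] < best[1]:
            best = result
    assert best is not None
    return best


def snmf_detect(
    graph: Graph, config: SnmfConfig, init: np.ndarray | None = None
) -> tuple[Partition, float]:
    """Partition a graph by symmetric NMF membership argmax.

    Ties in a node's membership row resolve to the lowest community
    index.  An edgeless graph yields a single community with a warning.
    """
    if graph.weights.nnz == 0:
        if config.k > graph.n_nodes:
            raise InputError(f"k={config.k} exceeds the {graph.n_nodes} available nodes")
        logger.warning("graph has no edges; assigning all nodes to one community")
        return Partition(np.zeros(graph.n_nodes, dtype=np.int64)), 0.0
    h, obj, _ = snmf_factorize(graph, config, init=init)
    labels = np.argmax(h, axis=1)  # argmax takes the lowest index on ties
    return Partition(labels), obj


# ---------------------------------------------------------------------------
# Spectral modularity maximization
# ---------------------------------------------------------------------------


def modularity(graph: Graph, partition: Partition) -> float:
    """Weighted Newman modularity Q of a partition."""
    if partition.n_nodes != graph.n_nodes:
        raise InputError("partition does not match graph")
    w = graph.weights
    two_m = float(w.sum())
    if two_m <= 0:
        raise InputError("modularity requires positive total weight")
    d = np.asarray(w.sum(axis=1)).ravel()
    codes = partition.codes()
    q = 0.0
    for c in range(codes.max() + 1):
        idx = np.where(codes == c)[0]
        internal = float(w[idx][:, idx].sum())
        dc = float(d[idx].sum())
        q += internal / two_m - (dc / two_m) ** 2
    return q


def _leading_eigvec(m: np.ndarray) -> tuple[float, np.ndarray]:
    vals, vecs = scipy.linalg.eigh(m, subset_by_index=[m.shape[0] - 1, m.shape[0] - 1])
    return float(vals[0]), vecs[:, 0]


def _group_matrix(b: np.ndarray, group: np.ndarray) -> np.ndarray:
    """Group-restricted modularity matrix B^(g) (row sums subtracted)."""
    sub = b[np.ix_(group, group)]
    return sub - np.diag(sub.sum(axis=1))

def _fine_tune(bg: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Greedy single-node sweeps: flip the node that most increases
    s^T B^(g) s while an improving flip exists and both sides stay
    nonempty."""
    s = s.copy()
    ms = bg @ s
    for _ in range(len(s) * 4):  # hard bound; usually exits much earlier
        gains = -4.0 * s * ms + 4.0 * np.diag(bg)
        # forbid emptying either side
        for sign in (1, -1):
            side = s == sign
            if side.sum() == 1:
                gains[side] = -np.inf
        best = int(np.argmax(gains))
        if gains[best] <= 1e-12:
            break
        ms = ms - 2.0 * s[best] * bg[:, best]
        s[best] = -s[best]
    return s


def _bisect(
    b: np.ndarray, group: np.ndarray, refine: bool
) -> tuple[float, np.ndarray, np.ndarray]:
    """Best sign-split of a group; returns (gain, part_a, part_b).

    Gain is ``s^T B^(g) s`` (un-normalized modularity change times 4m).
    A group that the leading eigenvector cannot split gets gain -inf.
    """
    if len(group) < 2:
        return -np.inf, group, group[:0]
    bg = _group_matrix(b, group)
    _, v = _leading_eigvec(bg)
    s = np.where(v >= 0, 1.0, -1.0)
    if np.all(s == s[0]):
        return -np.inf, group, group[:0]
    if refine:
        s = _fine_tune(bg, s)
    gain = float(s @ bg @ s)
    return gain, group[s > 0], group[s < 0]


def _median_split(b: np.ndarray, group: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forced split at the median of the leading eigenvector (ties by index)."""
    bg = _group_matrix(b, group)
    _, v = _leading_eigvec(bg)
    order = np.argsort(v, kind="stable")
    half = len(group) // 2
    return group[np.sort(order[half:])], group[np.sort(order[:half])]


def spectral_modularity_detect(
    graph: Graph, config: SpectralConfig
) -> tuple[Partition, float]:
    """Newman leading-eigenvector bisection into exactly ``k`` communities.

    The group whose best sign-split yields the largest positive
    modularity gain is divided next.  When ``k`` communities are required
    but no positive-gain split remains, the largest group is split at the
    median of its leading eigenvector (logged) so the community count is
    honored.  Returns the partition and its weighted modularity.
    """
    n = graph.n_nodes
    if config.k > n:
        raise InputError(f"k={config.k} exceeds the {n} available nodes")
    a = graph.dense()
    d = a.sum(axis=1)
    two_m = float(d.sum())
    if two_m <= 0:
        raise InputError("spectral detection requires positive total weight")
    b = a - np.outer(d, d) / two_m

    groups: list[np.ndarray] = [np.arange(n)]
    # cached candidate split per group
    candidates = [_bisect(b, groups[0], config.refine)]
    while len(groups) < config.k:
        gains = [c[0] for c in candidates]
        best = int(np.argmax(gains))
        if np.isfinite(gains[best]) and gains[best] > 1e-12:
            _, part_a, part_b = candidates[best]
        else:
            sizes = [len(g) for g in groups]
            best = int(np.argmax(sizes))
            if sizes[best] < 2:
                raise InputError("cannot split singleton groups further")
            logger.info(
                "no positive-gain split; forcing median split of group of size %d",
                sizes[best],
            )
            part_a, part_b = _median_split(b, groups[best])
        groups[best] = part_a
        groups.append(part_b)
        candidates[best] = _bisect(b, part_a, config.refine)
        candidates.append(_bisect(b, part_b, config.refine))

    # deterministic labeling: groups ordered by smallest member index
    groups.sort(key=lambda g: int(g.min()))
    labels = np.empty(n, dtype=np.int64)
    for c, g in enumerate(groups):
        labels[g] = c
    partition = Partition(labels)
    return partition, modularity(graph, partition)


# ---------------------------------------------------------------------------
# Semi-supervised wrapper
# ---------------------------------------------------------------------------


def _detect(graph: Graph, method: str, k: int, seed: int | None, **kwargs):
    if method == "snmf":
        cfg = SnmfConfig(
            k=k,
            max_iters=kwargs.get("max_iters", 500),
            tol=kwargs.get("tol", 1e-6),
            seed=seed,
            restarts=kwargs.get("restarts", 5),
        )
        return snmf_detect(graph, cfg)
    if method == "spectral":
        cfg = SpectralConfig(k=k, refine=kwargs.get("refine", True))
        return spectral_modularity_detect(graph, cfg)
    raise InputError(f"unknown detection method {method!r}")


def semi_supervised_detect(
    graph: Graph,
    constraints: ConstraintSet,
    method: str = "snmf",
    k: int = 2,
    mode: str = "supernet",
    seed: int | None = None,
    **detector_kwargs,
) -> Partition:
    """Turn an unsupervised detector into a constraint-aware one.

    ``mode="supernet"`` contracts the network, detects on the
    super-network and projects labels back (must-links guaranteed);
    ``mode="modtop"`` edits the adjacency per the ModTop baseline and
    detects on the edited network; ``mode="none"`` ignores the
    constraints entirely.
    """
    if mode == "supernet":
        sn = construct_supernetwork(graph, constraints)
        super_partition, _ = _detect(sn.super_graph, method, k, seed, **detector_kwargs)
        return project_labels(super_partition, sn.assignment)
    if mode == "modtop":
        edited = modtop(graph, constraints)
        partition, _ = _detect(edited, method, k, seed, **detector_kwargs)
        return partition
    if mode == "none":
        partition, _ = _detect(graph, method, k, seed, **detector_kwargs)
        return partition
    raise InputError(f"unknown mode {mode!r}")
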