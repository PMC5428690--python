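import numpy as np
import pytest

from supernet import ConstraintSet, Graph

# Node layout of the 13-node walkthrough instance: letters a-f then
# digits 1-7.  Must-links f-d, d-a merge {a,d,f}; b-c merges {b,c};
# a cannot-link 6-b contradicts the two edges 6-b, 6-c.
LETTERS = list("abcdef") + [str(i) for i in range(1, 8)]
IDX = {name: i for i, name in enumerate(LETTERS)}


@pytest.fixture
def walkthrough():
    """Small hand-built instance with known contraction results.

    Expected: super-node {a,d,f} (weight 3 to {b,c} via edges a-b, b-d,
    c-d); singleton {6} connected to {b,c} with weight 2 but suppressed
    by the cannot-link (6, b); singletons 1 and 7 joined by a weight-1
    super-edge.
    """
    edges = [
        (IDX["a"], IDX["b"]),
        (IDX["b"], IDX["d"]),
        (IDX["c"], IDX["d"]),
        (IDX["6"], IDX["b"]),
        (IDX["6"], IDX["c"]),
        (IDX["1"], IDX["7"]),
        (IDX["e"], IDX["f"]),
        (IDX["2"], IDX["3"]),
    ]
    graph = Graph.from_edges(len(LETTERS), edges, node_labels=list(LETTERS))
    constraints = ConstraintSet(
        must_links=frozenset(
            {(IDX["f"], IDX["d"]), (IDX["d"], IDX["a"]), (IDX["b"], IDX["c"])}
        ),
        cannot_links=frozenset({(IDX["6"], IDX["b"])}),
    )
    return graph, constraints


def random_graph(rng: np.random.Generator, n: int, p: float = 0.2,
                 weighted: bool = False) -> Graph:
    """Erdos-Renyi helper used by the brute-force comparison tests."""
    upper = np.triu(rng.random((n, n)) < p, k=1)
    edges = list(zip(*np.nonzero(upper)))
    weights = rng.integers(1, 5, size=len(edges)).astype(float) if weighted else None
    return Graph.from_edges(n, edges, weights)
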