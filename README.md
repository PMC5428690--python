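# supernet

Semi-supervised community detection via constraint-induced
super-networks.

Community detection degrades as the planted structure blurs, and extra
knowledge often exists as *pairwise* supervision: must-link (ML) pairs
known to share a community and cannot-link (CL) pairs known not to.
`supernet` encodes that supervision by **contracting the network**
instead of tweaking an objective: must-link connected components are
merged into indivisible super-nodes (`B` the node-to-super-node
indicator), the super-adjacency accumulates original edge weight,

```
A_s = B^T A B          (diagonal zeroed)
C_s = B^T C B          (lifted cannot-links)
A_s <- max(A_s - alpha * C_s, 0),   alpha = max(A_s)
```

and any community detector runs on the smaller weighted graph, its
labels projected back to the original nodes. Must-links are satisfied
by construction, cannot-links suppress contradicted super-edges, the
contraction is parameter-free and linear in network size plus
constraint count — and detection gets *faster* as supervision grows,
because the graph shrinks.

The package ships:

- the construction pipeline (`construct_supernetwork`,
  `project_labels`) with cannot-link-priority resolution of
  inconsistent supervision, and the **ModTop** baseline (`modtop`: ML
  pairs -> weight-1 edges, CL pairs -> edge removal, no contraction);
- two detectors that accept weighted graphs: symmetric NMF with damped
  multiplicative updates (`snmf_detect`) and Newman spectral modularity
  maximization (`spectral_modularity_detect`), plus the one-call
  wrapper `semi_supervised_detect`;
- GN and LFR planted-partition generators and a ground-truth constraint
  sampler (`generate_gn`, `generate_lfr`, `sample_constraints`);
- an NMI scorer and the constraint-group averaging protocol
  (`nmi`, `run_experiment`), and a `supernet` CLI over edge-list/GML
  networks and TSV constraint files.

## Worked example

Generate a hard GN network (four planted 32-node communities, expected
degree 16, `z_out = 8`), sample 5% of all node pairs as constraints
from the planted truth, and compare encodings:

```python
from supernet import (GNParams, generate_gn, sample_constraints,
                      construct_supernetwork, semi_supervised_detect, nmi)

inst = generate_gn(GNParams(z_out=8.0, seed=42))
constraints = sample_constraints(inst.truth, 0.05, seed=7)
print("constraints:", len(constraints.must_links), "ML,",
      len(constraints.cannot_links), "CL")

sn = construct_supernetwork(inst.graph, constraints)
print(f"contraction: {inst.graph.n_nodes} -> {sn.n_super} nodes, "
      f"{inst.graph.n_edges} -> {sn.super_graph.n_edges} edges")

for mode in ("none", "modtop", "supernet"):
    p = semi_supervised_detect(inst.graph, constraints, method="snmf",
                               k=4, mode=mode, seed=0)
    print(f"{mode:9s} NMI = {nmi(p, inst.truth):.3f}")
```

prints

```
constraints: 97 ML, 309 CL
contraction: 128 -> 41 nodes, 1053 -> 222 edges
none      NMI = 0.668
modtop    NMI = 0.924
supernet  NMI = 0.975
```

The 97 must-links collapse 128 nodes into 41 super-nodes and the
cannot-links strip contradicted super-edges, so symmetric NMF runs on a
graph a third the size and recovers the planted partition almost
perfectly (NMI 0.975), while unsupervised detection stalls at 0.668 and
the edit-in-place baseline reaches 0.924.

The same flow from the shell:

```sh
supernet benchmark gn --zout 8 --seed 42 --out gn
supernet constraints sample --network gn.edges --truth gn.truth.tsv \
         --fraction 0.05 --seed 7 --out gn.constraints.tsv
supernet detect gn.edges --constraints gn.constraints.tsv \
         --k 4 --mode supernet --out gn.partition.tsv
supernet nmi gn.edges gn.partition.tsv gn.truth.tsv
```

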