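# Methods

## The super-network construction

Given an undirected network `G = (V, E)` with adjacency `A` (binary for
input networks) and pairwise supervision in the form of must-link (ML)
and cannot-link (CL) node pairs, the toolkit contracts `G` into a
weighted super-network in three steps:

1. **Super-node construction.** Super-nodes are the connected components
   of the graph whose edges are the must-links; an unconstrained node is
   its own singleton super-node. Components are found by union-find with
   path compression, `O(N + |ML|)`. Because a super-node is indivisible
   in all later steps, every must-link is satisfied by construction.
   Super-nodes are numbered by their smallest member index, which makes
   every downstream artifact deterministic.
2. **Initialization.** With `B` the binary node-to-super-node indicator,
   the super-adjacency is `A_s = B^T A B` — entry `(i, j)` is the total
   original edge weight between the member sets of super-nodes `i` and
   `j`. The diagonal (internal edge weight) is zeroed so `A_s` has the
   shape of an ordinary adjacency matrix. Implemented as a sparse
   triple product, `O(M + N)`.
3. **Refinement.** Cannot-links lift to super-node level as
   `C_s = B^T C B` (`C` the symmetric 0/1 cannot-link indicator;
   `C_s[i, j]` counts CL pairs spanning the two member sets), and the
   topology is overridden by the supervision:

   `A_s <- max(A_s - alpha * C_s, 0)`.

   `alpha` defaults to the largest entry of `A_s` ("auto"); since every
   nonzero `C_s` entry is >= 1, each cannot-linked super-edge is zeroed
   exactly, however heavy it was, and all other entries are untouched.
   The step is idempotent under auto `alpha`.

Detection on the contracted graph plus projection of each super-node's
label onto its members yields a semi-supervised detector out of any
unsupervised one. The whole construction is parameter-free and costs
`O(M + N + |ML| + |CL|)`.

**Inconsistent supervision.** A cannot-link whose endpoints fall in the
same must-link component proves at least one constraint in that
component wrong. Cannot-links are given priority: *all* must-links of
the offending component are demoted to ordinary weight-1 edges (added
only where no edge exists; existing binary edges are left at weight 1)
and the cannot-link is kept. Demotion is per component, not per pair,
because none of a contradicted component's must-links remains credible.

**ModTop baseline.** The comparison baseline edits the adjacency
without contraction: each ML pair's weight is set to exactly 1
(replacing, not augmenting — input weights are binary anyway) and each
CL pair's weight to 0. It biases detection toward the constraints but
guarantees neither.

## Detectors

Both detectors consume the weighted adjacency as-is — no rescaling is
applied to super-edge weights, so the same code runs on original and
contracted networks.

**Symmetric NMF.** Minimizes `||A - H H^T||_F^2` over nonnegative
`H (n x k)` with the damped multiplicative update
`H <- H ∘ (1/2 + 1/2 (A H) / (H H^T H))`; the 1/2 damping makes the
objective provably non-increasing for the symmetric problem (asserted
to 1e-10 in the tests). `H` is initialized uniform-random in (0, 1)
scaled by `sqrt(mean(A)/k)` so `H H^T` starts at the right magnitude.
Defaults: `max_iters=500`, relative-change tolerance `tol=1e-6`,
`restarts=5` (best objective kept). Node label = argmax over the k
membership columns, ties to the lowest index. An edgeless graph returns
one community with a warning.

**Spectral modularity.** Newman's leading-eigenvector method on the
weighted modularity matrix `M = A - d d^T / 2m`: recursive bisection by
the sign of the leading eigenvector of the group-restricted matrix,
splitting next whichever group offers the largest positive modularity
gain, with an optional (default on) single-node hill-climbing
fine-tune of each bisection. The protocol assumes the community count
`K` is known, so when `K` groups are required but no split has positive
gain, the largest group is split at the median of its leading
eigenvector (logged) — modularity alone would stop early. Ties break to
the lowest index throughout.

## Benchmark generators

**GN.** 128 nodes, four planted communities of 32; intra-community
pairs link with probability `z_in/31` and inter-community pairs with
`z_out/96`, so expected intra/inter degrees are exactly `z_in`/`z_out`
with `z_in + z_out = 16`. `z_out` dials the difficulty.

**LFR.** `N=1000` nodes; degrees from a truncated power law with
exponent 2 (lower cutoff chosen so the mean matches `mean_degree`),
community sizes from a truncated power law with exponent 1 on [10, 50]
(the final size adjusted so sizes sum to `N`); each node's internal
degree is `round((1-mu) * degree)`, clipped to community size - 1 when
needed; internal and external stubs are matched configuration-model
style with rejection of self/multi-edges and same-community external
pairs (leftover stubs dropped). The realized fraction of
inter-community edges is censused and the network regenerated (<= 20
attempts) until it is within ±0.02 of `mu`. `mean_degree=20` and
`max_degree=50` are the common LFR settings; both are exposed as
parameters. At `mu=0` external stubs are suppressed outright so all
edges are intra-community.

**Constraint sampler.** Emulates an annotator consulting ground truth:
`round(fraction * N(N-1)/2)` unordered node pairs are drawn uniformly
without replacement from *all* pairs (the standard convention in the
constrained-clustering literature — a "5% constraint budget" means 5%
of all pairs), labeled ML if the planted labels agree and CL otherwise.
Constraint sets from equal seeds are identical, from different seeds
differ.

What the generators deliberately do not emulate: degree correlations,
overlapping communities, weighted or directed input, noisy (wrong)
constraints. Passing benchmark tests therefore demonstrates correctness
of the machinery and the relative supernet-vs-ModTop ordering under
clean planted structure, not performance on real networks with noisy
supervision.

## Evaluation protocol

Accuracy is normalized mutual information with the sum-of-entropies
normalization,

`NMI = -2 Σ_ij n_ij log(n_ij n / n_i n_j) / (Σ_i n_i log(n_i/n) + Σ_j n_j log(n_j/n))`,

with `0·log 0 = 0` and NMI = 1 when both partitions are the single
trivial community. This equals scikit-learn's arithmetic-mean variant,
which the tests use as an independent cross-check. `run_experiment`
draws, per constraint fraction, `n_groups=10` (default) independent
constraint sets — different constraint draws of equal size can help
very differently — runs every (detector, mode) combination and reports
mean/SD NMI and mean wall-clock seconds. Timing wraps construction plus
detection, excluding generation, scoring and file I/O; absolute times
are reported for information only (they are hardware-bound), whereas
the supernet/ModTop time *ratio* is a meaningful, hardware-free claim.

## Numerical choices and degenerate inputs

- Multiplicative-update denominators are floored at 1e-12; SNMF stops
  on relative objective change < `tol` or at `max_iters`.
- `refine_with_cannot_links` with an empty graph resolves auto `alpha`
  to 0 (no-op).
- Eigenvectors come from dense symmetric `eigh` restricted to the top
  index; group matrices are small after contraction.
- All randomness flows through `numpy.random.default_rng` seeds;
  experiment sweeps derive per-network/per-group/per-detector seeds
  from one master seed.
- Problem sizes in the shipped tests and the reproduction script —
  3–5 GN realizations x 10 constraint groups, and LFR comparisons run
  with `restarts=2`, `max_iters=200` on 3 groups — were chosen as the
  smallest sweeps whose means are stable against the documented
  tolerances; larger sweeps only shrink the error bars.

## Known limitations

- Cannot-links are encoded, not guaranteed: after refinement two
  cannot-linked super-nodes can still land in one community.
- Heavy, inconsistent supervision degrades gracefully (demotion) but
  no attempt is made to identify *which* constraint was wrong.
- The LFR generator targets the mixing fraction by rejection; extreme
  parameter combinations (e.g. mean degree near the max degree) can
  exhaust the attempt budget and raise a generation error.
- `K` is assumed known everywhere; no model selection is provided.
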