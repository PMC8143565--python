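# Methods

## Scope and model

The package detects non-overlapping communities in simple, undirected,
unweighted graphs.  A partition's quality is measured by Newman–Girvan
modularity

    Q = (1/2m) Σ_ij [A_ij − k_i k_j / 2m] δ(C_i, C_j)
      = Σ_c [ l_c/m − (d_c / 2m)² ]

with `m` edges, degrees `k_i`, `l_c` edges internal to community `c`, and
`d_c` the total degree of its members.  All computations are unweighted:
edge weights, if present in an input file, are ignored.  (This matters for
the karate-club fixture, whose classic datafile carries conversation
counts; the weighted and unweighted modularity of the same partition differ
by ~0.03.)

## LPA-MNI

Classical label propagation draws three kinds of random numbers: initial
conditions do not matter (labels start unique), but the node visit order
and the majority tie-breaks do.  LPA-MNI replaces each with a
deterministic rule.

**Node importance.**  Degree centrality `DC(i) = k_i/(n−1)`; an isolated
node scores 0, and for `n = 1` the score is defined as 0.  The processing
order sorts by descending `DC`, breaking ties by ascending node id.  Node
ids read from a file are parsed as integers when every token is numeric
(so `10` sorts after `2`); otherwise ids are compared as strings, and
mixed-type id sets fall back to first-seen order.  The order is computed
once and reused by both phases — it is not re-sorted after moves.

**Phase 1 — rough communities (modularity-gain local moving).**  Start
from singletons.  For each node in order: detach it, evaluate the gain of
inserting it into each distinct neighbor community and back into its
former one, and insert it where the gain is maximal and strictly positive;
otherwise restore it.  The gain of inserting a detached node `i` into
community `C` is

    ΔQ = k_{i,in}/m − Σ_tot(C) · k_i / (2 m²)

where `k_{i,in}` counts edges from `i` into `C` and `Σ_tot(C)` is the
total degree of `C`'s members.  The baseline state is `i` as a singleton,
so "strictly positive" means "better than staying alone"; the formula is
held to the contract `ΔQ = Q(after) − Q(before)` against the global
definition, verified to 1e−12 by an independent brute-force oracle in the
tests.  Gain ties prefer the former community, then the smallest community
id.  Sweeps repeat until one completes with no move; monotone ascent on a
finite lattice guarantees termination.  This is single-level local moving
only — no Louvain-style graph aggregation or recursion, since the seeding
phase only needs a coarse, deterministic starting partition.

**Phase 2 — importance-ordered propagation.**  All members of a rough
community share one label.  Sweeps visit nodes in the fixed order;
updates are asynchronous (already-updated neighbors contribute their new
label, the rest their previous one).  A node adopts the label held by the
most of its neighbors; the node's own label is not added to the tally.
When several labels tie for the majority, each tied label scores the
maximum `DC` over the neighbors currently holding it and the
highest-scoring label wins; residual ties go to the smallest label token.
An alternative reading — summing importance over all holders instead of
taking the maximum — is plausible; the choice is isolated in one function
(`lpa_mni._tie_break`) and the max rule is used because it also satisfies
the "single most important neighbor" reading.  Propagation stops when a
full sweep changes no label, with a `max_sweeps` cap (default 100, far
above observed convergence: 3 sweeps on karate) surfaced in diagnostics.

No RNG exists anywhere in the pipeline, so repeated runs are identical and
every run-to-run entropy statistic is exactly zero by construction.

## LPA baseline

Asynchronous label propagation with unique initial labels: each sweep
visits all nodes in a fresh uniformly-random order; majority ties are
broken uniformly at random; the node's own label is not counted.  The
literal stop rule "no label changed" rarely triggers under random
tie-flipping, so the conventional criterion is used instead: stop when
every node's label is among its neighbors' most frequent labels (plus the
same `max_sweeps = 100` cap).  A single seeded generator drives the
shuffles and the tie-breaks, making each run reproducible bit-for-bit
given its seed.  Repeated-run experiments use consecutive seeds
`base_seed .. base_seed + runs − 1`.

## Metrics

* **Modularity** uses the per-community form; an edgeless graph is an
  error (undefined), and the all-in-one partition is exactly 0.
* **NMI** normalizes mutual information by the arithmetic mean of the two
  partition entropies, `2·MI/(H(A)+H(B))`; logs are natural (the base
  cancels).  When both partitions are single-community over the same node
  set they are identical, hence NMI = 1.
* **AMI** subtracts the expected MI under the hypergeometric permutation
  model (computed in log space via `gammaln`) and normalizes by
  `mean(H(A), H(B)) − E[MI]`.  This matches scikit-learn's
  `adjusted_mutual_info_score(average_method="arithmetic")` to 1e−9,
  verified in the tests; the package implementation is used at run time,
  scikit-learn only as the cross-check.
* **Stability entropy** of a metric sequence: round each value to
  `precision` decimals (default 3, the precision at which Q/NMI values are
  conventionally reported), form the empirical distribution over distinct
  rounded values, return its Shannon entropy in bits.  Zero iff the
  sequence is constant; the maximum for `r` runs is `log2(r)` ≈ 6.64 bits
  at `r = 100`.  The default precision affects only how much of LPA's
  run-to-run jitter collapses into one bin; the LPA-MNI value of 0 is
  binning-independent.

## Benchmark generators

**GN planted partition.**  128 nodes in four blocks of 32; each node's
expected degree is 16, a fraction `f` of it external.  Independent edge
sampling with `p_in = (1−f)·16/31` and `p_out = f·16/96`.  The swept
parameter is the external *fraction* `f ∈ [0, 1]` (an external expected
degree of `16·f`), so `f = 0.5` means half of each node's links leave its
block.  Realized mean degree concentrates within 16 ± 1 and the realized
external edge fraction within ±0.05 of `f`.

**LFR-style generator.**  Heterogeneous benchmark with power-law degree
(exponent `τ1`, default 2) and community-size (exponent `τ2`, default 1)
distributions, defaults `N = 1000`, `⟨k⟩ = 15`, `Max(k) = 50`, sizes in
[10, 50], mixing `μ`.  Construction:

* Degrees are drawn from a continuous power law truncated at `Max(k)`,
  with the *lower* cutoff tuned by bisection (on a fixed uniform sample)
  so the realized mean hits `⟨k⟩`.  Rescaling draws toward the mean and
  clipping at the cap was tried first and rejected: it piles several
  percent of nodes at `Max(k)`, which makes the internal degree sequences
  of large communities non-graphical and silently loses edges.
* Community sizes are power-law draws in `[Min(c), Max(c)]`, adjusted to
  sum exactly to `N` while respecting the bounds.
* Each node's external degree is `μ·k_i` with stochastic rounding, so the
  average mixing is unbiased (deterministic rounding of `μ·k` would bias
  the realized mixing by up to several points at small degrees).
* Nodes are assigned to communities in descending internal-degree order,
  each into the community with the most free slots that can host its
  internal degree (`size − 1 ≥ k_i^int`); when none can, a free slot is
  reallocated to the largest community, within the size bounds.
  Infeasible parameter combinations (`(1−μ)·Max(k) > Max(c) − 1`) are
  rejected before generation.
* Internal stubs (per community) and external stubs (globally, with the
  same-community constraint) are paired by a configuration model;
  rejected stubs are re-shuffled, and irreducible leftovers are resolved
  by degree-preserving double-edge swaps against already-placed edges of
  the same class.  This keeps the realized mean degree within ±1 and the
  realized mixing within ±0.02 of `μ` at the default scale.

Realized statistics (mean degree, per-node external fraction, community
sizes) are reported with every instance so experiments can condition on
them.  What the generators do *not* emulate: degree–degree correlations,
clustering beyond what the planted structure induces, overlapping or
nested communities, and weighted/directed edges.  Passing benchmark tests
therefore demonstrates recovery of planted block structure under the
stated degree and mixing laws, not performance on real networks with
richer dependence.

**Sweep harness.**  For each parameter bundle and replicate a fresh
instance is generated (replicate seeds derived from the master seed) and
each algorithm scored against the planted truth (NMI, AMI, community
count, modularity) into a tidy DataFrame; generation failures flag the row
and the sweep continues.  Default replicates: 10 (5 in the bundled
experiment scripts); the stochastic baseline gets one seed per replicate.

## Numerical choices and degenerate inputs

* Gain comparisons use an absolute guard of 1e−12 ("strictly positive"
  and tie detection); modularity gains are rational with denominator
  `4m²`, so real ties are exact and the guard only absorbs float noise.
* NMI is clamped to [0, 1] and AMI to [−1, 1] against 1-ulp overshoot.
* Self-loops and duplicate edges in input files are dropped with a logged
  warning (strict mode turns self-loops into errors); a file whose only
  content is a self-loop yields a single-node, zero-edge graph.
* Isolated nodes keep their initial label in both algorithms and score
  `DC = 0`.
* Edgeless graphs are rejected wherever modularity is involved.

## Problem sizes

The default experiment scale is chosen to keep the full reproduction
desk-sized: 100 repeats for stability entropy, 200 random graphs (n ≤ 8)
for the gain-formula oracle, 5 replicates per GN grid point, and one
`N = 1000` LFR instance per setting.  All complete in seconds; larger-scale
sweeps (8 LFR groups × 8 mixing values × 100 LPA repeats) are a matter of
raising `--replicates`/`--runs`.

## Known limitations

* Weighted, directed, dynamic and overlapping-community settings are out
  of scope.
* Degree centrality is a deliberately simple importance measure; on
  networks whose hubs straddle community boundaries the fixed
  hub-first order can entrench a poor early label.
* Single-level local moving inherits modularity's resolution limit for
  the seeding phase; very small modules may be merged into their
  neighbors before propagation starts.
* The stochastic baseline's summary statistics (e.g., mean modularity
  over 100 karate runs ≈ 0.35) depend mildly on tie-handling conventions;
  alternative published implementations differ by a few hundredths.
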