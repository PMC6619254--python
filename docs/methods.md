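# Methods

## Problem and model

Given per-subject symmetric `N x N` connectivity matrices and a binary
group label per subject, the package tests every unique edge (i < j)
for a group difference while controlling the family-wise error (FWE)
rate across the whole connectome.  The raw statistic at each edge is
the one-way two-group GLM F statistic with degrees of freedom
`(1, S - 2)`, identical to the square of the pooled-variance two-sample
t statistic.  The diagonal carries no connection and is excluded from
all computation; with a fully connected matrix there are `N(N-1)/2`
unique tests.

### Threshold-free enhancement

Instead of choosing a single cluster-forming threshold, every edge's
statistic is enhanced by integrating component support over a ladder of
thresholds:

    score(i,j) = sum over rungs h of  e_h(i,j)^E * h^H

where `e_h(i,j)` is the extent (edge count) of the connected component
containing edge (i,j) among the edges at or above height h (0 if the
edge is below h), and `E`, `H` are the extension and height enhancement
exponents.  Edges that are both strong and embedded in strong
neighbourhoods accumulate the largest scores; isolated strong effects
still accumulate through the `h^H` term.

The ladder interval is `dh = max(Mstat)/n_intervals` with
`n_intervals = 100` by default, so the observed matrix is thresholded at
101 rungs (`h = 0, dh, ..., max`).  `dh` is computed once from the
observed statistic matrix and reused for every permuted matrix, whose
ladder is truncated or extended to its own maximum — this keeps the
rung heights comparable between observed and null scores.

Numerical conventions:

- An edge contributes at every rung `h <= its height`, inclusive with a
  relative tolerance of 1e-12, so the matrix maximum contributes at the
  top rung and a single edge of height `x` scores exactly
  `sum_{k=1..n} (k dh)^H` with `n = round(x/dh)`.  This matches the
  inclusive thresholding used by threshold-free enhancement in the
  voxel-wise setting.  The standalone component query
  (`suprathreshold_components`) uses the strict comparison `stat > h`,
  which matters only on exact ties.
- The `h = 0` rung contributes nothing because `h^H = 0` for `H > 0`.
- Scores are plain per-rung sums by default.  Multiplying by `dh`
  (`multiply_dh=True`) recovers the literal discretised integral, but
  since `dh` is a constant shared by the observed and all permuted
  matrices the factor cancels from every p value; the default keeps
  scores on the same scale regardless of the statistic maximum.
- The sweep is implemented incrementally: edges are inserted into a
  union-find forest while walking the ladder from the top down, with
  per-component edge counts maintained on the roots, so the cost is
  about one find() per (suprathreshold edge, rung) pair and the
  `N x N x t` stack is never materialised.  The tests verify the sweep
  against a naive oracle that does materialise the stack.
- Degenerate inputs: an all-zero statistic matrix yields `dh = 0` (with
  a warning) and all-zero scores with p = 1 everywhere.  An edge with
  zero within-group variance gets F = 0 when the group means agree and
  the largest finite float (with a warning) when they differ, keeping
  the ladder finite.

### Permutation inference

Group labels are shuffled across subjects; the full F matrix is
recomputed from the relabeled cohort at every permutation (preserving
the dependence structure among edges) and re-enhanced with the same
`dh`.  Edge-wise p values are

- FWE-corrected: each observed edge score against the null distribution
  of the connectome-wide maximum score, and
- uncorrected: each edge against its own null score distribution,

both with the convention `p = (1 + r)/(1 + n_perm)` counting the
observed statistic into the null, which guarantees p > 0 and test
validity for any number of random permutations.  Default
`n_perm = 3000`.  Every permutation's labels are a pure function of
`(seed, perm_index)`, so runs are bit-reproducible and independent of
execution order.  For small cohorts an exhaustive mode enumerates all
`C(S, n1)` distinct relabelings and reports exact counts instead.

### NBS baseline

The classic network-based statistic applies one hard component-defining
F threshold, identifies suprathreshold components, and assigns each a
FWE-corrected p value by comparing its measure against the permutation
null of the maximum measure.  Two measures are provided: *extent* (edge
count) and *intensity*, measured as the sum of statistic excesses above
the threshold (`sum F - extent * threshold`).  The excess form is used
deliberately: with the plain F sum, the null maximum at liberal
thresholds is dominated by chains of barely-suprathreshold noise edges
(each contributing the full threshold value), and a genuinely strong
isolated effect can be swamped — measured sensitivity to a
contrast-to-noise ratio (CNR) 1 single edge drops to ~0.44 at threshold
8.5, which contradicts the near-certain detection this design is known
to achieve.  The excess measure restores it (~1.0) and is what standard
NBS implementations compute.  NBS and the threshold-free engine share
the same permutation label stream for a given seed, so method
comparisons are paired.

## Synthetic study conditions

The generator emulates a two-group functional-connectivity comparison:

- 82 nodes, fully connected, 100 subjects per group by default;
- healthy subjects: iid standard normal edge values (mean 0, sd 1);
- disrupted subjects: identical except at planted edges, drawn with
  mean `-cnr` and sd 1, so the planted CNR equals Cohen's d;
- planted effects organised in node-disjoint components.  The reference
  pattern is five components of 20/7/3/1/1 edges (32 edges); the
  mixed-CNR regime assigns them CNRs 0.75/1/0.5/1/0.5.

Component topologies: *tree* components are uniformly random labeled
trees on `extent + 1` nodes (the 20-edge component therefore spans 21
nodes; enhancement depends only on extent and height, not on the
specific tree shape); *cyclic* components pack edges onto the minimum
node count n with `n(n-1)/2 >= extent`, dropping surplus clique edges
in seeded order; the growing-component regime's *linear* topology is a
path graph.  The growing design enumerates 14 sizes (4-30 edges, step
2) x 2 CNRs (0.5, 0.75) x 2 topologies x 75 groups = 4,200 comparisons.

What the generator does **not** emulate: real connectivity matrices are
not iid Gaussian — they have transitivity, modular structure and
heavy-tailed, spatially correlated noise.  Passing benchmarks on these
cohorts therefore demonstrates the statistical machinery (calibration
under exchangeable noise, sensitivity to planted extent/height), not
performance on organised noise.

## Evaluation

Detections are scored over unique edges: TP/FP/FN/TN with
`TP + FP + FN + TN = N(N-1)/2`, sensitivity `TP/(TP+FN)`, specificity
`TN/(TN+FP)`, false-positive rate `1 - specificity`, and a per-
comparison FWE indicator `[FP >= 1]`; rates are means over replicate
comparisons.  Per-component sensitivity is the detected fraction of
each planted component's edges; its extent-weighted mean equals overall
sensitivity.  A helper quantifies the spurious-neighbour risk of a
planted component: given the per-edge probability of an isolated noise
effect and the number of candidate edges adjacent to the component, it
returns the linear expected-count approximation (which grows with the
component's node count) alongside the exact complement probability.

## Default scales and runtime choices

Batch experiments in `tfnbs.experiments` default to 100 noise cohorts /
50 mixed-CNR replicates with 500 permutations and a handful of (E, H)
combinations spanning the conservative grid (E 0.25-1, H 2.25-4.75;
44 combinations in full).  These sizes give binomial standard errors of
about 0.02 on rate estimates while keeping a full run in the
one-to-two-minute range on a single core; the published-scale design
(up to 1,000 groups, 3,000 permutations, all 44 combinations) is a
strict scaling of the same code paths.

Known behaviour worth noting: under the global null the max-statistic
procedure is essentially exact, so the measured FWE on noise-only
cohorts fluctuates around the nominal 0.05 rather than sitting below
it; conservative (E, H) choices do not change this, because the
corrected p value of the best-scoring edge is uniform under
exchangeability regardless of the enhancement.

## Limitations

- Only the two-group comparison is implemented: no covariates,
  exchangeability blocks or repeated measures.
- Gaussian iid noise only; no organised-noise backgrounds (small-world,
  modular, scale-free).
- Inputs start at connectivity matrices; no imaging-format ingestion.
- Permutations are simple random draws (not guaranteed unique) except
  in the explicit exhaustive mode.
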