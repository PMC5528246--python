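# Methods

## The pairwise overlap model

For a node pair (i, j) the package compares the observed number of shared
partners O with its expectation under the hypergeometric sampling
distribution.  The shareable set A_ij contains every node that is a
*permitted* partner of both i and j; its size n is the hypergeometric
population.  With d_i, d_j the realized partner counts of i and j *inside*
A_ij, the expectation and the attainable bounds are

    E = d_i d_j / n,  s_min = max(0, d_i + d_j − n),  s_max = min(d_i, d_j).

That E is exactly the mean of the shared-partner distribution is verified in
the test suite by exhaustive enumeration of subset placements for all
n ≤ 12.  The standardized value divides the deviation O − E by the maximum
deviation achievable on its side,

    value = (O − E)/(s_max − E) if O ≥ E, else (O − E)/(E − s_min),

the unique piecewise-linear map sending {s_min, E, s_max} to {−1, 0, +1}.
The published description of the index is verbal (a hypergeometric-based
measure running from overlap to segregation); the two-branch form used here
is a reconstruction from that description and is pinned down by the
saturation requirements (value = +1 exactly when O = s_max > E, −1 exactly
when O = s_min < E) together with the canonical fixtures (a perfectly nested
web must score +1 on every defined pair).  N̄ is the arithmetic mean of the
defined pairwise values over the candidate pairs of a scope (one guild, both
guilds, or all unimode pairs under a partner direction).

### Branch decisions in exact arithmetic

O, d_i, d_j, n are integers, so O ≥ E is evaluated as O·n ≥ d_i·d_j and the
value itself as a ratio of integers ((O·n − d_i·d_j) over the corresponding
bound difference times n); no floating-point comparison can flip a branch.

### Degenerate pairs

Three situations carry no information about overlap tendency and are
excluded from N̄ but counted and reported per summary: an empty shareable
set (n = 0), a zero realized degree within A_ij, and a forced outcome
(s_min = s_max, which includes every pair where one node's degree equals n).
`degenerate_policy="zero"` optionally scores forced pairs as 0 for
sensitivity analysis.  Whether the original analyses excluded or zeroed such
pairs is not documented anywhere we know of; exclusion is the default
because a forced outcome has no room to deviate from expectation.

### Null behaviour — a known, exact property

Under independent Bernoulli(c) links the conditional distribution of O given
the degrees is exactly hypergeometric, so E[O] = E; but the two branches are
normalized by different constants, so E[value] ≠ 0 unless the degree
distribution makes the branches cancel.  Exact enumeration (tests) gives,
for 15×15 webs, E[value] = 0 at c = 0.5 (the d ↔ n − d symmetry of the
binomial at p = 1/2) and E[value] ≈ −0.355 at c = 0.2 = b(0.2); the bias
curve b(c) is symmetric about c = 0.5 and negative on both flanks (−0.64 at
c = 0.9).  Sparse or very dense random webs therefore read as segregated on
average.  This is a property of the index itself, not of the
implementation; the Monte-Carlo tests assert agreement with the exact
enumeration rather than an unconditional zero.  Interpreting N̄ for a real
web should always be done against this connectance-dependent baseline.

## Constraints

**Trophic rule.**  Edges are stored resource→consumer.  Basal species have
no prey (in-degree zero after removing cannibalistic loops) and take level
0; other levels are minimum path distances from the basal set (multi-source
BFS).  Nodes unreachable from any basal species (e.g. isolated cycles) get
an undefined level and participate in no permitted interaction.  A link is
permitted iff both levels are defined and the resource's level is strictly
lower, which makes the permitted relation antisymmetric, loop-free and
acyclic by construction.  Partner direction defaults to `out` = shared
resource (prey) sets; `in` (shared consumers) and `undirected` are options
because published analyses rarely state which was used.

**Loops.**  Cannibalism is handled solely through the permitted relation's
`loops_allowed` flag.  With loops forbidden the diagonal is false, so both
focal nodes drop out of every A_ij — reproducing the n − 2 correction in the
fully permissive unimode case with one mechanism instead of two.

**Realized-but-forbidden links.**  Real food webs contain same-level feeding
that the trophic rule forbids.  Degrees and O are computed strictly within
A_ij (the hypergeometric support), so such links are simply invisible to the
pair in question; a validation helper reports them as warnings, never
errors.  This keeps s_min ≤ O ≤ s_max provable for arbitrary inputs.

**Task matching.**  A host–parasite link is permitted iff the two trait
(task) sets intersect; the indicator depends only on the unordered pair of
sets, so one symmetric relation serves both guilds.  Empty repertoires are
legal for hosts (unparasitizable), not for parasites.

**Reduction ratios.**  For each node, the constrained potential-partner
count divided by the unconstrained one (all other nodes, or the full
opposite guild); reported per node and as a mean.  The ratio is
reduced/complete, in [0, 1] — the orientation that makes reported means
below one meaningful.

## Synthetic generators

All generators draw from one `numpy.random.Generator` seeded per call;
identical configuration and seed give byte-identical written outputs.

* `gen_bipartite_bernoulli` — independent links, the null benchmark.
* `gen_bipartite_nested` — a Young-diagram incidence at a target fill
  (cell (i, j) filled iff i/rows + j/cols < t, t found by bisection), so row
  partner sets are nested prefixes; optional independent cell-flip noise.
* `gen_bipartite_modular` — block-diagonal, the archetypal segregation
  regime.
* `gen_layered_foodweb` — L levels of s species; consumers draw prey from
  the level below with probability `down_link_prob` (re-drawn until
  non-empty, which guarantees BFS recovers the generator's levels when
  `skip_link_prob` = 0) plus skip links to deeper levels.  With skip = 0 the
  mean out-direction reduction ratio is exactly s(L−1)/(2(Ls−1)), increasing
  with depth toward 1/2 — deeper webs do *not* shrink the average permitted
  set, because high-level consumers gain access to everything below them.
* `gen_task_world` — a phenomenological emulator of digital host–parasite
  co-evolution experiments.  Task repertoires are per-token Bernoulli
  (`task_prob`); the permitted matrix follows from task matching; each
  parasite realizes a Binomial(m, `realization`) subset of its m permitted
  hosts, selected uniformly (`structure` = 0), preferentially toward
  globally high-permitted-degree hosts (structure > 0, nested realization),
  or preferentially within a random resource partition orthogonal to task
  matching (structure < 0, segregated realization standing in for resource
  competition).  Nodes with no realized link are dropped, as in empirical
  networks of realized interactions.

### Generator defaults and the two repertoire regimes

`task_prob` defaults to 0.45 with 6 tasks: the closed form
P(two repertoires intersect) = 1 − (1 − p²)^T then puts the mean
permitted/complete ratio near 0.73, the value reported for the digital
host–parasite benchmark this generator emulates.  The
constrained-vs-unconstrained *contrast* experiment instead uses
`task_prob = 0.2` (mean ratio ≈ 0.46): with independent Bernoulli
repertoires, permitted sets covering ~75% of partners barely restrict
anything, and the contrast only emerges when the constraint genuinely bites
— the regime of the real food webs, whose trophic reductions are ~0.33–0.37.
Both values are fixed design choices, not fitted quantities.

### Problem sizes

The shipped experiments use 50 layered webs (4 levels × 8 species), 50 task
worlds (20 hosts × 20 parasites), 200 null replicates (15 × 15) and a
60-world diversity gradient (6–40 per guild) — sizes chosen to sit inside
the empirical envelopes being emulated while keeping every experiment
re-runnable in seconds.

## Batch statistics

Group summaries report the mean N̄ with a t-based 95% CI
(t(0.975, k−1)·sd/√k; undefined for singleton groups) plus the paired
difference constrained − unconstrained.  The diversity relationship is
Spearman's rank correlation between total species count and per-network N̄,
with average ranks for ties and a two-sided t-approximation p-value; an
exact permutation p-value is available for n ≤ 8.  Both are cross-checked in
the tests against hand-rolled rank arithmetic and high-precision t
quantiles.

## Known limitations

* The two-branch standardization is a reconstruction (see above); any
  implementation detail of the original not derivable from its verbal
  description (degenerate handling, food-web direction) is exposed as an
  option with the documented default.
* The null expectation of N̄ is zero only at half connectance; comparisons
  across webs of very different connectance should use the exact baseline
  b(c), which the test suite computes by enumeration.
* The task-world emulator preserves the single formal rule of its target
  system (task matching) plus one free structure parameter.  It reproduces
  the headline contrast (constrained N̄ > unconstrained N̄ under restrictive,
  structured realization) but *not* the reported diversity-correlation
  contrast (a more negative species-diversity correlation under the
  constrained metric): with realized links a subset of permitted ones, O is
  identical under both specifications of n, so within-permitted segregation
  saturates pairs at −1 under both metrics, and the two channels that do
  distinguish them (exclusion of incompatible pairs; the b(c) support bias)
  both move the constrained value upward as selectivity grows.  Reproducing
  that contrast appears to require co-evolved repertoire structure outside
  this independent-Bernoulli family.  The acceptance script reports both
  correlations as computed.
* Presence–absence networks only; no weighted interactions, no alternative
  trophic-level definitions (flow-based, prey-averaged), no nestedness
  indices of the NODF family and no null-model matrix randomization.
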