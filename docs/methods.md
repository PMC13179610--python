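# Methods

## The probing model

`regprobe` models the choice of influential transcription factors (TFs) in
a gene regulatory network as stochastic probing on a weighted, complete
bipartite graph. One side holds `n_A` *regulators* (TFs), the other `n_B`
*positions* (genes). Each edge `(a, b)` carries a discrete weight
distribution `D_{a,b}` over the integer value set `{0, ..., V_max}`; a
weight of 0 means no influence. Weights are drawn independently. A policy
may *probe* up to `k` regulators; probing reveals the realized weights of
all edges incident to that regulator. After probing, at most `l <= k`
probed regulators are selected and scored by an objective `f` on the
realization:

* coverage `f_cov(S) = sum_b max_{a in S} w_{a,b}` (weighted maximum
  coverage — each gene is credited to its single best selected TF),
* `f_max(S) = sum_{a in S} max_b w_{a,b}`,
* `f_sum(S) = sum_{a in S} sum_b w_{a,b}`.

The parent function `f*(S') = max_{S ⊆ S', |S| <= l} f(S)` scores a probed
set by its best feasible sub-selection. `f_cov` is monotone submodular,
but its parent is *not* submodular once `k > l + 1`; the package ships the
4×4 deterministic counterexample (`counterexample_fixture`) whose parent values
2, 2, 3, 4 on the nested sets {1,2} ⊂ {1,2,3} ⊂ {1,2,4} ⊂ {1,2,3,4}
exhibit a growing marginal (2 > 1). For monotone submodular parent
functions the adaptivity gap — optimal adaptive over optimal non-adaptive
expected value — is bounded by `e/(e-1) ≈ 1.58`
(`ADAPTIVITY_GAP_BOUND`); because the optimal adaptive policy itself is
prohibitively costly, the package only brackets policy quality through
offline references (below), never computes the gap directly.

## Policies

All policies are myopic greedies; the coverage variants switch rule once
the guaranteed-selectable prefix is exhausted.

* **amp** (adaptive, `f_max`/`f_sum`): each regulator is reduced to a
  scalar score variable — the row sum (exact pmf by iterated convolution)
  or the row maximum (pmf from the product of edge CDFs). At each step the
  policy probes the regulator maximizing `E[(X_a − t)+]`, where `t` is the
  current l-th best realized score among probes (0 while fewer than `l`
  are probed). Near-ties in the expected gain are broken by expected
  score, then by lowest index; on deterministic instances this makes the
  probe order the descending score order, which is the behaviour one
  wants when no uncertainty is present. When the convolution support
  would exceed `CONVOLUTION_SUPPORT_CAP` (10^4) the score switches to a
  normal approximation with the exact mean and variance; the error of
  `E[(X−t)+]` is then that of a CLT approximation over `n_B` independent
  summands.
* **namp** (non-adaptive): probe the top-`k` regulators by expected row
  sum (`f_sum`) or exact expected row maximum (`f_max`).
* **ampcov** (adaptive, `f_cov`): for the first `l` probes the expected
  marginal gain `sum_b E[(w_{a,b} − m_b)+]` is exact (`m_b` = best
  realized weight seen at `b`), because every early probe is guaranteed
  selectable. Afterwards each candidate row is substituted by its
  expected values and scored by the greedy selection value of
  {probed rows} ∪ {substituted row} minus the greedy value of the probed
  rows alone — the "uncovered subgraph" is handled as residual gains
  inside the greedy on the union matrix, which needs no graph mutation.
  The final selection runs the submodular greedy on the `k` realized rows.
* **nampcov** (non-adaptive, `f_cov`): the first `l` picks greedily
  maximize the exact increment of the expected coverage of the growing
  prefix, maintained as a per-position product of CDFs; the remaining
  `k − l` picks are the unchosen regulators with the highest expected row
  sums.
* **off**: submodular greedy on the fully revealed matrix, the scalable
  stand-in for the offline optimum.

Exact selection for `f_cov` is NP-hard, so selections use the
`(1 − 1/e)`-greedy everywhere; an exact enumeration mode exists below a
cap of 2×10^5 subsets and raises rather than silently degrading. All
tie-breaks default to the lowest index; a seeded random tie-break mode
(relative tolerance 1e-9) exists for the network application and is off
in simulations.

## Offline references

The optimum of the revealed instance is bracketed per realization by

    Off (greedy)  <=  optimum (= IP)  <=  LP bound.

`offline_ip` is the standard weighted max-coverage integer program
(select variables `x_a`, assignment variables `y_{a,b} <= x_a`, one unit
of coverage per position) solved with HiGHS through `scipy.optimize.milp`;
it is used in tests and for small instances. `offline_lp_bound` solves
the LP relaxation in an equivalent *layered* form: per position the
fractional-knapsack value of capacities `x` equals the sum over distinct
weight levels of `min(1, sum_{w >= level} x_a)`, so one bounded variable
per (position, level) replaces the per-edge `y` variables. The two
relaxations have identical optima (the layered program is the level
decomposition of the per-position fractional knapsack); the layered one is
several times smaller on 10-valued weights and is solved with HiGHS
interior point at its default ~1e-8 tolerance. Solver choice is
configuration, not contract; any LP/MIP backend within 1e-6 relative
optimality would do.

## Simulation study

Two regimes, scaled by an integer multiplier `z`:

* **Uniform**: `n_A = n_B = 16 z`, value set of size `16 z`; each edge
  pmf is an independent vector of uniform[0,1] weights normalized to 1.
* **Network**: `n_A = 16 z`, `n_B = 400 z`, 10 weight values; each edge
  is Poisson with rate drawn uniformly from [0.5, 2.5], with the tail
  mass `P(X >= 9)` lumped onto the top value so the support stays
  `{0..9}` and total mass is conserved. Lumping (rather than
  renormalizing) preserves the stochastic ordering in the rate and was
  chosen as the simplest capping convention.

For every `z`, instances are generated, realizations sampled, and each
policy is run over the grid `k ∈ {n_A/4, n_A/2, 3n_A/4}` ×
`l ∈ {k/4, k/2, 3k/4, k}` (fractions floored, minimum 1). Each achieved
value is divided by the offline reference: the LP bound for
`n_A <= 160` ("auto" mode), the greedy Off beyond that, or the exact
top-`l` optimum for the additive-separable objectives. One realization is
shared by all algorithms within a run, which removes between-algorithm
sampling noise from the comparison; realizations whose offline reference
is zero are resampled under an incremented sub-seed and logged. Wall time
is recorded per run but never asserted — it is hardware-dependent.

The package default is a desk-scale spec — `z ∈ {1, 2, 3}`, 20 instances
× 5 runs — chosen so a full coverage study completes in minutes on one
core; the larger published-style protocol (`z` up to 20, 100 × 10) is
expressible through the same `ExperimentSpec`. The acceptance check uses
`z ∈ {1, 2}`, 20 × 5: at that size the mean NampCov/AmpCov ratio against
the LP bound is ≈ 0.95, and the spread across (k, l) cells spans ≈
0.91–0.99, rising with `k` at fixed `l/k` ("probing more, taking less").

Reproducibility: a single master seed feeds named substreams
(`regprobe.rng.substream`) for instance generation, realization sampling
and tie-breaking, so any record can be regenerated from its logged
coordinates alone, and each layer is reproducible in isolation.

## TF-gene network construction

Edges are weighted by the fraction of a gene's regulatory elements (REs)
that carry a predicted binding site for the TF, `w = |c_TF|/|C_G|`, gated
by a one-sided Fisher exact test (alternative = greater): the TF's hits
must be enriched among the gene's REs relative to the RE universe at
`p <= alpha` (inclusive; default 0.05, no multiple-testing correction —
`alpha` is exposed as a flag). Pairs failing the gate get weight zero and
are omitted, so every emitted edge weight lies in (0, 1] and is a
multiple of `1/|C_G|`. Numerically the inclusive comparison uses a 1e-12
guard because the exact tail can equal `alpha` (e.g. 1/20) while floating
point lands a few ulp above it.

The RE universe is taken from the links table itself (all REs appearing
there, after whatever upstream filtering produced the table). Whether the
published background should instead be genome-wide REs is not derivable
from the inputs; users holding a different universe can encode it in the
links file, since the universe is exactly the set of REs the file
mentions. Motif hits are binarized (any hit count >= 1); TF dimers are
opaque identifiers at this layer and only matter for co-expression, where
constituent expressions are averaged first. BED inputs are treated as
0-based half-open and unstranded, reduced to `chrom:start-end` ids.

Upstream steps — peak calling, enhancer–gene prediction, motif scanning,
promoter-based TF filtering — are out of scope; the builder consumes
their tabular outputs.

## Network application

Built networks are deterministic, so the greedy policies would always
return the same TF set. To obtain selection *frequencies* over repeated
iterations, `run_triplet_search` enables seeded random tie-breaking among
candidates whose marginal scores agree within a relative tolerance of
1e-9 (a configurable "soft" tolerance widens the tie pool). This is the
minimal mechanism that yields a frequency distribution on a fixed
network; it is this package's own reconstruction of repeated-run
variability, can be disabled (`randomize_ties=False`, which provably
yields a single modal set with frequency 1), and its effect is visible in
the tally. Defaults follow the triplet protocol: `l = 3`,
`k ∈ {30, 40, 50}` capped at `n_A`, 500 iterations per `k`; an `l`-sweep
3–10 at fixed `k` is supported by the same entry point.

Co-expression of a TF set is the mean of pairwise Pearson correlations
(zero-variance vectors are warned about and their pairs skipped); the
selected sets are compared against uniformly drawn random sets (default
baseline 1000 draws) with a two-sided Mann–Whitney U test. When the two
groups are identical point masses the tie-corrected normal approximation
is undefined and the test conventionally reports p = 1.

## Synthetic fixtures and what they show

`synth_regulatory_fixture` emulates the input tables of a network build
with a planted signal: every gene owns 6 private REs; the first 12 of 24
genes are partitioned round-robin among 3 planted TFs, each of which hits
(by default) all REs of its own gene block; all 12 TFs additionally hit
background REs independently at density 0.02. Expected surviving edges
are recomputed by an exact-rational hypergeometric oracle
(`exact_fisher_greater`), never hand-typed. Expression over 40 samples
gives the planted TFs a shared standard-normal latent factor plus noise
of sd 0.5, so their pairwise correlation has the closed form
`1/(1 + 0.5^2) = 0.8`; background TFs are independent noise. Defaults
were set so the planted triplet is the brute-force coverage optimum on at
least 95 of 100 generator seeds.

What passing tests on this fixture do **not** show: real RE-gene links
are shared between genes and spatially correlated, motif hits are highly
redundant between TF families, expression is heteroskedastic and
confounded — none of which the generator emulates. The fixture
establishes correctness of the pipeline's logic (gating, weighting,
probing, tallying, testing), not performance on epigenomic data.

## Numerical choices and limitations

* Edge pmfs must sum to 1 within 1e-9; CDF-product computations keep full
  float64 precision.
* Exact parent/brute-force enumeration is capped at 2×10^5 subsets and
  raises beyond it.
* `l = 0` or an empty row set yields value 0 and an empty selection, not
  an error.
* Degenerate all-zero realizations (possible in principle under the
  Uniform regime) are resampled and logged rather than producing
  undefined ratios.
* Only independent edge weights are supported; correlated weights and
  continuous weight distributions are out of scope. Gene weighting
  (importance-scaled positions) is not implemented but is expressible by
  pre-scaling the weight matrix.
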