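# Methods

## The index

For mother *m* in a group of *N* ≥ 2 parturient mothers with relative
birth dates *t* (first birth anchored at *t* = 1),

PSI_m = 1 / (mean_{i≠m} |t_i − t_m| + 1).

The "+1" in the denominator makes complete synchrony (all pairwise
differences zero) evaluate to exactly 1 and keeps the index strictly
positive. The index is a function of pairwise differences only, so it is
invariant to translating all dates, and the multiset of values is
invariant to reflecting the season (t → max+min − t). It is *not*
scale-free: stretching a season by a factor k strictly lowers every
PSI value below 1, which is exactly the season-duration sensitivity the
robustness study quantifies. The group-level index PSĪ is the arithmetic
mean of the individual values; the inter-individual variability measure
is the CV of the individual values, reported in percent
(100·SD/mean, sample SD with n−1 denominator).

A single-mother group is rejected: the defining mean runs over zero
terms. Dates are normally integer day numbers; fractional dates are
accepted with a warning since the formula does not require integers
(field data occasionally carry half-day estimates), but the simulator
only emits integers.

### Computation

`psi_all_fast` sorts the dates and uses prefix sums: with k values ≤ x
and prefix sum S_k, Σ_i |t_i − x| = x·k − S_k + (S_N − S_k) − x·(N−k).
The self-term |x − x| is zero, so no correction is needed. This is
O(N log N) and agrees with the O(N²) double loop `psi_all_naive` to
≤ 1e-12 relative error (the tolerance asserted in the tests; exhaustive
random small cases plus one 5000-mother case).

## The simulator

The simulator emulates a season of parturitions as integer dates in
[1, D] for a season of D days, under five distribution families. For
each (family, duration) combination a preliminary pool of 100,000 dates
is generated, and each group is a simple random subsample of that pool —
a two-stage design retained deliberately even though direct sampling
would be statistically equivalent. Continuous draws are rounded to the
nearest integer and then clipped to [1, D], in that order.

Family parameterizations (D = season duration in days):

| family      | construction                                         | rationale |
|-------------|------------------------------------------------------|-----------|
| synchronous | every birth on day 1 (D = 1)                         | degenerate anchor: PSI ≡ 1, CV ≡ 0 |
| lognormal   | log-scale SD 0.4, median 0.15·D                      | right-skewed early-season pulse typical of capital breeders |
| normal      | mean (D+1)/2, SD D/6                                 | symmetric season-filling bell; ≈99.7% of mass in-season before clipping |
| bimodal     | equal mixture of normals at 0.3·D and 0.7·D, SD D/12 | two separated birth pulses (e.g. days 60 and 140 of a 200-day season) |
| uniform     | discrete uniform on {1,…,D}                          | no temporal structure; least synchronous reference |

The lognormal/normal/bimodal shape constants are package defaults chosen
once so that the simulated family-level means of PSĪ and of the CV fall
inside the published 95% confidence intervals for those quantities; all
are exposed as configurable `DistributionSpec` parameters.

**Span enforcement.** Every simulated group is constrained to span its
full season — a birth on day 1 and on day D. The default mechanism is
endpoint injection: if day 1 is missing, the group's earliest birth is
moved to day 1; if day D is missing, the latest birth is moved to D. At
most two dates change and group size is preserved. A rejection-resampling
mode (`span_mode="reject"`) redraws until the sample spans naturally, but
is computationally infeasible for small groups under peaked
distributions (the probability that a 5-mother lognormal sample contains
day 365 is vanishing), hence injection as the default. Injection is a
real distortion for small groups — it plants one early and one late
outlier — and is part of the study conditions, not a nuisance: it is why
small peaked-distribution groups show depressed PSĪ.

**Study design.** The default `default_design()` crosses the four
non-degenerate families with five durations {10, 50, 100, 200, 365} days
and eight sizes {5, 10, 25, 50, 100, 500, 1000, 5000} mothers, one group
per cell, plus one synchronous group (D = 1) per size: 168 groups and
140,490 mothers (6,690 synchronous, 33,450 per other family). An
optional replicate count extends the grid for users who want within-cell
replication.

**RNG policy.** One root seed (default 777) generates keyed substreams
via `SeedSequence(seed, spawn_key=(family, duration[, size, replicate]))`:
the pool stream depends only on (family, duration) and each group's
subsampling stream on its full cell key, so stream identity never depends
on the order cells are iterated. Identical seed + design reproduce the
output tables byte-for-byte. RNG streams from other statistical
platforms are not reproducible bit-for-bit here, so agreement with
published reference estimates is distributional (CI containment), not
numerical identity.

## Inference

Two fixed-effects OLS models are fitted on the per-group table, always
excluding the degenerate synchronous family (160 groups in the default
design), for each response (mean PSI, CV of PSI):

1. one-way: `response ~ family`, F with df (L−1, N−L) — (3, 156) on the
   default design;
2. nested: `response ~ family + duration(family) + size(family)`, with
   the nested effects tested against the residual mean square — df
   (16, 112) and (28, 112) on the default design.

OLS replaces a maximum-likelihood GLM fit: for balanced fixed-effects
models the two give identical F statistics and means, and the default
design is balanced (unbalanced input is rejected rather than silently
re-weighted, which also sidesteps the sequential-vs-marginal
sum-of-squares distinction — they coincide here). LS-means are computed
as arithmetic level means — equal to the model-based marginal means on a
balanced design (asserted to 1e-10 in the tests) — with 95% CIs
mean ± t(0.975, df_resid)·√(MSE/n_level) using the pooled residual mean
square. Family LS-means come from the one-way model (whose df accompany
them), duration- and size-within-family LS-means from the nested model.

Degenerate responses (constant, or exactly explained) would make the F
statistic a ratio of rounding errors; terms whose sum of squares is
negligible relative to the response scale (≤ 1e-20·n·mean(y²)) are
reported as F = 0, p = 1, and a negligible residual with a real effect
as F = ∞, p = 0.

`residual_summary` provides programmatic residual diagnostics (skewness,
excess kurtosis, per-family residual variance) in place of visual
inspection; it is advisory and gates nothing. Zero-variance residual
vectors report shape statistics of 0.

## What the simulation does and does not emulate

The generator produces idealized groups: independent mothers, a single
pulse (or two) per season, no year-to-year carryover, no observation
error in dates, and exact season endpoints by construction. Passing the
robustness study therefore demonstrates the index's behaviour under
controlled distributional shapes — not that real populations meet those
assumptions. In field data, birth-date uncertainty, detection bias
toward surviving litters, and non-independence among related mothers all
propagate into PSI and should be handled upstream. The published global
minimum PSI (0.003) is an extreme order statistic of one RNG stream and
is not treated as reproducible.

## Problem sizes and numerical choices

The full study (168 groups, 140,490 mothers, pools of 100,000) runs in a
few seconds; the test suite exercises the naive O(N²) kernel only up to
N = 5000. Tolerances: fast-vs-naive 1e-12 relative; LS-mean vs
arithmetic mean 1e-10 absolute; uniform-family large-group means within
15% of the continuous-uniform limit 1/(D/3 + 1) (mean pairwise distance
of a uniform season is D/3). Medians of even-length vectors are the
midpoint of the central order statistics. CSV output prints 6
significant digits by default (full precision via `--full-precision`).
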