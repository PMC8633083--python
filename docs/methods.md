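# Methods

## Model

We describe the genealogy of `n` lineages sampled at a neutral locus `d`
bases from the site of a hard selective sweep that fixed `Ta` units of
`2·Ne` generations before sampling.  Time runs pastward from sampling.
More recently than the sweep the sample follows the neutral Kingman
coalescent (pairwise mergers at rate 1 per pair).  At `Ta` the sweep acts
as an instantaneous event that partitions the extant lineages; the history
then continues neutrally.  This instantaneous treatment is justified when
selection is strong: the sweep's duration, `t_fix = 2·ln(2·Ne·s)/s`
generations, is short on the coalescent time scale (`t_fix/(2Ne) ≈ 0.03`
for `s = 0.05, Ne = 10^4`).

Two partition laws are implemented.

* **Star-like.**  Each lineage independently escapes the sweep with
  probability `Pe = 1 − e^(−α)`, `α = (r·d/s)·ln(2·Ne·s)`; the
  non-escapers coalesce simultaneously into the sweep's founder.  Counts
  of escapers are binomial, `P_{m,n} = C(n,m)·Pe^m·(1−Pe)^(n−m)`.

* **Instantaneous marked Yule.**  The beneficial allele's genealogy is a
  pure-birth tree with per-lineage split rate `2·Ne·s` (time in `2Ne`
  generations), stopped at `⌈4·Ne·s⌉` lineages (each has chance `≈ 2s` of
  an infinite line of descent), and marked by recombination at rate
  `2·Ne·r·d` per lineage.  Tracing each sampled tip pastward through the
  spanning tree, the first marked edge on its path classifies it: a marked
  pendant edge yields a late recombinant singleton (L), a marked internal
  edge releases an early-recombinant family (E), and unmarked tips descend
  from the founder (N).  No closed-form sampling law is used: the
  partition-shape distribution is estimated by Monte Carlo, for every
  subset size 2..n, and plugged into the GF exactly as the star-like
  probabilities are.  The process can produce more than one marked family,
  which the three-family description does not represent; such shapes are
  kept as extra blocks (the GF handles arbitrary partitions) and their
  frequency is reported as a diagnostic (`extra_family_freq`).  Size-1
  escape families are counted as late singletons.

## The generating function

The GF is the joint Laplace transform of branch lengths, one dummy
variable per branch class.  It is built by recursion over coalescent
histories: a state with `k` lineages contributes a factor
`1/(C(k,2) + δ + Σ ω)` where the sum runs over extant branch variables and
`δ` is the rate of a competing exponential process standing in for the
sweep.  When the sweep wins, the partition is applied and the continuation
is neutral (no further `δ`: the sweep happens at most once).  Dividing by
`δ` and inverting the Laplace transform in `δ` converts the competing-rate
form to the discrete sweep age `Ta`.

The engine is a small term algebra, not a general computer-algebra system:
every expression is a finite sum of terms

    c · w(pkey) · Ta^p · exp(−Ta·(b + Σ eᵥ ωᵥ)) · Π 1/(λⱼ + Σ cⱼᵥ ωᵥ)^{pⱼ}

closed under differentiation, substitution, per-variable limits, variable
merging (i-Ton collapse, total-time substitution), inverse transforms and
Taylor expansion.  Design points:

* **Symbolic partition weights.**  Terms carry a weight key (e.g. "m of k
  escaped") resolved at evaluation time, so one GF structure serves every
  `α` — essential for fitting, where thousands of (α, Ta, θ) tables are
  needed.
* **δ-inversion by partial fractions.**  Along any history the pre-sweep
  waiting rates `C(k,2)` strictly decrease, so the poles in `δ` are always
  simple; the partial-fraction coefficients are rational in the ω's
  (differences of pole locations), which is why the term language allows
  negative constants and mixed-sign ω coefficients in denominators.
* **Sample-size cap.**  Full GF construction is capped at n = 6 (the
  history count grows super-exponentially); the expected SFS for larger
  samples (n ≤ 10) uses a marginal-moments path instead (below).
* **Taylor tables.**  bSFS probabilities need mixed partial derivatives up
  to order `3·k_max`.  Rather than repeated term-wise differentiation, each
  term's factors have closed-form multivariate Taylor coefficients, and a
  precompiled, vectorized truncated-convolution plan produces the whole
  derivative array at once (~milliseconds per table; a `(θ, Ta)` grid is
  tabulated in seconds).

Exactness checks: every constructed GF evaluates to 1 at ω = 0 (to 1e−12);
the n = 2 sweep GF matches the printed closed forms term by term; the
`δ → 0`, `Ta → ∞` and `Pe → 1` limits all reduce to the neutral GF.

## Observables

* **Pairwise diversity.**  `E[t_mrca] = 1 − e^(−Ta−2α)`, verified both
  from the closed form and by GF differentiation.  The t_mrca distribution
  is `e^(−t)` below `Ta`, an atom `e^(−Ta−2α)` at `Ta`, and
  `(1 − e^(−2α))·e^(−t)` beyond.
* **Expected SFS (n ≤ 10).**  The marginal-moments path decomposes
  `E[t_i]` into (i) neutral accumulation before the sweep, using the exact
  lineage-count distribution of the Kingman death process and its
  closed-form time-integrals, with the classical subtending probability
  `P(i of n | k lineages) = C(n−i−1,k−2)/C(n−1,k−1)`; and (ii) the neutral
  continuation after the partition, where survivor family sizes are
  uniform over compositions and post-sweep branches subtend uniformly
  chosen subsets of the surviving blocks (a subset-sum count handles the
  block multiset).  For n = 4 this path agrees with full-GF derivatives to
  1e−10 across (α, Ta), which cross-validates both.
* **Topology classes (n = 4, star-like).**  Root classes are symmetric
  {2,2}, asymmetric {3,1}, and the four-way star
  `Pstar = e^(−6Ta)·P_{0,4}`.  A trifurcating root (three lineages at the
  sweep, none escaping, probability `2(e^(−3Ta) − e^(−6Ta))·P_{0,3}`) is
  counted with the *symmetric* class — the convention under which the
  closed forms sum to one exactly; it was confirmed by exact enumeration
  and by Monte-Carlo classification of simulated root nodes.
* **i-Ton marginal distributions (n = 4).**  Obtained by single-variable
  inverse Laplace transform of the GF (partial fractions with repeated
  roots supported via the logarithmic-derivative recursion).  Components
  are shifted pieces `(t − τ)^k e^(−a(t−τ))` with shifts `τ = c·Ta` set by
  the number of i-Ton branches extant at the sweep; atoms are kept
  explicit and never smeared into densities (they are contracted in the
  CDF).  Pieces with non-decaying rates are legitimate on interior
  intervals and must cancel beyond the last breakpoint, which is asserted
  numerically.  `discontinuities()` counts atoms plus breakpoints where
  the piecewise representation changes — this includes *removable*
  discontinuities where only derivatives jump (e.g. the doubleton form
  change at `2·Ta`), matching the expected counts `n−1` for singletons and
  `⌊n/i⌋+1` for i > 1.
* **bSFS (n = 4).**  With block mutation rate `θ = 4·Ne·μ·l` and
  per-class rate `θ/2` per unit branch length,
  `P[k] = Π_i ((θ/2)^{k_i}/k_i!) · (−1)^{Σk} · ∂^k φ` at `ω = θ/2`;
  `>k_max` bins follow by inclusion–exclusion over partially marginalized
  evaluations, so the `(k_max+2)^3` table sums to one by construction.
  The convention is anchored by two neutral identities: `E[π] = θ` for a
  pair, and the geometric block law `P[k] = (1/(1+θ))(θ/(1+θ))^k`.

## Simulators

* **Hybrid sampler** — an *exact* sampler of the analytic model (Kingman /
  instantaneous partition / Kingman), in two forms: a vectorized
  array implementation (per-replicate α and Ta, used for 10^5-replicate
  oracle comparisons and dataset generation) and a labeled per-replicate
  implementation producing full genealogies (any partition model,
  per-branch mutation placement, root classification).
* **Trajectory simulator** — the structured coalescent along the
  beneficial-allele frequency path: beneficial-background pairs coalesce
  at rate `1/X`, escape at `2·Ne·r·d·(1−X)` per coalescent unit, escaped
  lineages coalesce at `1/(1−X)`, and the sweep's origin forces the
  remaining beneficial lineages into the founder.  The default path is the
  deterministic logistic `X(u) = 1/(1 + e^{s(u − t_fix/2)})` over
  `u ∈ [0, t_fix]` generations (1-generation steps, midpoint frequencies,
  competing-risk event sampling within a step).  Its symmetry makes the
  integrated escape exposure exactly `α` per lineage, so the single-lineage
  escape probability reproduces `1 − e^(−α)`; stochastic conditioned
  trajectories are deliberately out of scope for this desk-scale oracle.

A measured property of the full model worth stating: the pair
"fails-to-escape" probability exceeds the star-like `e^(−2α)` by
`≈ 0.28·α·e^(−2α)` at moderate α.  Coalescence clusters near the sweep's
origin (mean position ≈ 0.93·t_fix pastward), truncating part of the
escape window that the star-like approximation integrates in full.  The
two agree in the small-α / strong-selection limit, which is where the
package tests that agreement; the late burst is also why observables
expose the optional duration correction `Ta → Ta + t_fix/(2Ne)` (default
off, matching the closed forms).

Mutations are dropped on i-Ton class totals (the bSFS depends on nothing
else); per-branch placement is used when subsampling `x` of `n > x`
lineages.

## Inference

Two-step grid fit.  (1) θ̂ maximizes the neutral composite likelihood over
blocks far from the target; a block qualifies if its α at a reference `s`
exceeds 0.5.  The reference defaults to the *largest* s on the grid — the
most conservative choice, since α decreases in s over the grid's range, so
qualifying blocks are distant under every candidate.  (2) `(T̂a, ŝ)`
maximize `lnCL_s` conditional on θ̂; ties break toward the neutral-most
cell (largest Ta, then smallest s) by scan order.  Subsample terms are
summed as defined despite overlap — a composite likelihood, no variance
correction.  Zero-probability configurations are floored at `log(1e−300)`
(the analytic tables are strictly positive, so the guard is inert in
practice).

Exact memoized tables are the reference path.  For batch power studies,
tables are computed at log-spaced α nodes and interpolated per
configuration (cubic in log α); because α enters only as the composite
`f(d, s)`, one node set serves every grid `s`.  Interpolated and exact
fits agree to well under one lnCL unit on test datasets.

## Study conditions for recovery and power

B = 2000 blocks of l = 500 bases (μ = 2.5e−8, so θ = 0.5 per block;
500 kb of flank per side), `Ne = 10^4`, `r = 1e−7`, n = x = 4,
`k_max = 2`; grid θ ∈ {0.3..0.7}, Ta ∈ {0.1, 0.5, 1.0, 2.0},
s ∈ {0.005, 0.015, 0.05, 0.15}; 200 sweep replicates per condition
against a shared pool of 2000 neutral replicates.  The 500-bp block
length keeps θ at 0.5 while giving the conservative distant-block rule
~1600 qualifying blocks; 200/2000 replicates resolve the AUC ordering
and the modal recovery cell clearly at desk scale.  Typical outcomes
(seed-dependent at the third decimal): recovery of the generating cell in
~98% of replicates at (s = 0.05, Ta = 0.1); AUC ≈ 1.00 / 0.97 / 0.76 for
(0.05, 0.1) / (0.05, 1.0) / (0.005, 1.0); constraining Ta = 0 drops the
old-sweep AUC to ≈ 0.79; neutral median ΔlnCL ≈ 0.1.

## What the synthetic data do and do not show

The generator draws independent genealogies per block from the same
instantaneous-partition model the likelihood assumes, with no intra-block
recombination, no linkage between blocks, constant `Ne`, a single
completed hard sweep, and free mutation rate homogeneity.  Passing tests
therefore demonstrate internal consistency (estimator correctness,
calibration of ΔlnCL, power ordering) — not robustness to demography,
background selection, θ heterogeneity, soft/partial sweeps, or intra-block
recombination.  The trajectory simulator relaxes exactly one assumption
(the instantaneous sweep) and quantifies the resulting bias; relaxing the
others requires external forward or ancestral-recombination-graph
simulators, for which the dataset TSV format is the exchange point.

## Numerical choices

* Algebraic-identity tests at 1e−10 relative; GF normalization at 1e−12.
* Density assembly merges per-(power, rate) coefficients with `fsum`;
  rates are keyed at 1e−10 rounding; total mass checked to 1e−8 (the
  δ-inversion's partial fractions cancel to ~1e−12 in practice).
* Tavaré lineage-count coefficients are computed in exact rational
  arithmetic before float evaluation (alternating sums).
* The marked-Yule sampler thins the pure-birth pastward scan to
  sampled-pair mergers (`C(c,2)/C(j,2)` per step) and draws marks as
  Bernoulli per spanning-tree edge; time units `2Ne` generations.
* Degenerate inputs: `α = 0 ∧ Ta = 0` (zero-length tree) raises for the
  SFS rather than returning NaN; `2·Ne·s ≤ 1` raises wherever `t_fix`
  or α is needed.
* Grid argmax uses strict improvement (`> best + 1e−12`) over a
  neutral-most-first scan, making the conservative tie-break explicit.

## Limitations

Full GFs stop at n = 6; i-Ton marginals and bSFS at n = 4 (subsampling
covers larger n); topology closed forms assume the star-like law
(Monte-Carlo fallback otherwise).  Recurrent and soft sweeps, demography,
migration and intra-block recombination are out of scope.  The composite
likelihood's ΔlnCL has no calibrated null distribution here — power is
assessed by ROC against simulated neutrality, and significance thresholds
via asymptotic theory are not provided.
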