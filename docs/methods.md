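# Methods

## Model and design criterion

A two-arm cluster randomized crossover trial assigns K/2 clusters to a
treatment sequence over T periods and K/2 clusters to its mirror (A and B
swapped in every period). The trial is cross-sectional: each cluster-period
enrols m fresh subjects, measured once at the end of the period. The outcome
model is a linear mixed model with fixed period effects (the first period is
the reference, β₁ = 0), a fixed treatment effect θ, a random cluster-period
effect with variance σ²_CP, and subject error with variance σ²_ε. The
cluster-period effects of one cluster are correlated across periods with
exponential decay, corr = r^|t−t′|: subjects measured closer in time are more
alike. r = 1 recovers the classical exchangeable (constant cluster effect)
model; r = 0 makes cluster-periods independent.

All computations work on cluster-period means, whose per-cluster covariance
is V = (σ²_ε/m)I + σ²_CP R. This is an exact reduction for balanced designs,
not an approximation: the package's test suite verifies that the resulting
GLS variance equals the one computed from the full mT×mT subject-level
covariance matrix. The design criterion is var(θ̂), the last diagonal entry
of the inverted information matrix; designs are compared by relative
efficiency RE = var(θ̂)_best / var(θ̂)_alt, so 100·(1/RE − 1)% extra
replication of the alternative matches the best design.

## Design spaces

* **Fixed-K**: every candidate uses the same, user-chosen number of
  clusters. RE values in this space are invariant to K (information is
  linear in K), which the tests assert.
* **Budget**: a candidate with T periods, S switches and cluster-period size
  m affords the largest even K with c_c·K + c_s·K·T·m + c_x·K·S ≤ B.
  The cost equation generalises the switch-every-period case (S = T−1) to
  arbitrary switch counts: each of the K clusters performs S switches.
  K is always rounded *down* to an even integer so both arms stay equal;
  the resulting spend can sit slightly below the budget. Money is held as
  exact rationals (`fractions.Fraction`) so feasibility comparisons never
  depend on floating-point rounding.

Candidate sequences are mirror pairs: of the 2^T label strings, each design
appears once via the lexicographically smaller member of each
complement pair (it always starts with A), giving 2^(T−1) candidates,
ordered by switch count and then binary value. For T = 4 a reference
ordering option reproduces the conventional eight-row presentation used in
the crossover-design literature, including its arm orientation (RE is
invariant to which arm of a pair is displayed).

## Parameters and defaults

| parameter | meaning | default | why |
|---|---|---|---|
| ρ | intraclass correlation σ²_CP/(σ²_CP+σ²_ε) | 0.1 | reference worksite scenario |
| r | cluster autocorrelation per period of lag | 0.95 | 5% decay between adjacent periods |
| σ² | total outcome variance | 1 | RE, K and cost are scale-invariant |
| m | subjects per cluster-period | 25 | reference scenario |
| c_c, c_s, c_x | costs per cluster / subject / switch | 2500 / 25 / 250 | reference scenario |
| B | budget | 250,000 | reference scenario |
| T cap | maximum periods searched | 12 | ~a year of monthly, or a quarter of weekly, periods (overridable) |

Boundary handling: ρ = 1 with r < 1 and r = 1 with ρ < 1 are valid (V stays
positive definite); the joint boundary ρ = r = 1 is rejected because V
becomes singular. Designs with fewer than 20 clusters trigger a warning —
random cluster effects are not advisable with so few clusters — but are not
refused, since the variance formula itself remains valid.

## Numerical choices

* V and the information matrix are factorised by Cholesky; factorisation
  failure raises a singularity error. The final (T+1)×(T+1) covariance is
  materialised explicitly (it is the deliverable) and symmetrised.
* Symmetry and positive-definiteness checks use a 1e-10 relative tolerance:
  matrices are at most 13×13 and well-conditioned away from parameter
  boundaries.
* Tie-breaking in `find_optimal` (ties within 1e-12 relative): fewer
  periods, then fewer switches, then canonical sequence order. Ties occur,
  e.g., between a sequence and its time reversal, which are exactly equally
  efficient (centrosymmetry).
* Treatment coding A→0, B→1. With mirrored equal allocation var(θ̂) is
  invariant to relabelling, so the choice only fixes reproducible design
  matrices.

## Simulator

`simulate_trial` draws data from exactly the model above: per cluster, a
length-T cluster-period effect vector L·z with L the Cholesky factor of
σ²_CP R, plus independent subject noise. Each cluster owns a random
substream keyed by (seed, arm, cluster index), so enlarging a trial never
perturbs previously drawn clusters and identical seeds give bit-identical
trials. The simulator emulates balanced, complete, normally distributed
trials — it deliberately reproduces the design assumptions. It does not
emulate attrition, unequal cluster-period sizes, non-normal outcomes or
cohort (repeated-subject) participation, so the Monte-Carlo agreement shown
by the tests validates the algebra under the model, not robustness to
violations of it.

Estimation works on cluster-period means:

* `gls_estimate` takes the variance components as known (the design-stage
  assumption) and reproduces the analytic covariance exactly; across
  replicated trials the empirical variance of θ̂ is checked against the
  analytic value with a 99% chi-square interval at 2000 replicates.
* `ml_fit` maximises the multivariate-normal likelihood over
  (log σ²_CP, log σ²_eff, logit r), where σ²_eff = σ²_ε/m is the means-level
  residual variance, profiling the fixed effects out by GLS at every
  evaluation. Optimisation uses Nelder-Mead from two starting points — an
  even variance split and a method-of-moments start from the pooled residual
  autocovariances — keeping the better optimum; the log/logit scales make
  the positivity and range constraints implicit, and estimates that land on
  a boundary are flagged rather than rejected. REML is not provided; the
  design-stage theory is ML-based. With 200 clusters the fit recovers
  ρ and r to within a few hundredths (median over 50 replicates in the
  acceptance suite).

The design-stage engine treats (ρ, r) as known. Uncertainty in these
planning inputs is not propagated into var(θ̂); sensitivity is explored by
re-running sweeps at alternative values (the `--rho/--r` flags or config
overrides).

## Problem sizes in the test suite

The Monte-Carlo validation uses three scenarios spanning T ∈ {2, 4, 6},
ρ ∈ {0.05, 0.1} and r ∈ {0.8, 0.95} at K = 20 clusters and m = 25 subjects
per cluster-period with 2000 replicates each, and ML parameter recovery runs
50 replicates at K = 200, T = 4, m = 25 — cluster counts and replicate
numbers at which the asymptotic and Monte-Carlo approximations quoted above
are comfortably accurate while the whole suite stays desk-scale.

## Known limitations

* Only two-arm, mirror-pair designs with equal allocation and a common m;
  no cohort designs, washout periods, attrition or unequal cluster-period
  sizes.
* Budget-mode cluster counts always round down to even; no option to round
  up on negligible overshoot.
* The budget-mode RE of a design depends on integer rounding of K, so RE
  curves over T are slightly jagged by construction.
* Optimisation is over T and the switch pattern only; m is an input, not a
  decision variable, and no cost-power frontier is computed.
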