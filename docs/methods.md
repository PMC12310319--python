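# Methods

This note documents the statistical procedures implemented in
`symptomnet`, the choices made where the design was genuinely open, and
what the synthetic test bed does and does not establish.

## Data model and recoding

Input is a two-wave panel of CESD-10 responses on the 0–3 frequency
scale. The two positively worded items ("felt hopeful", "felt happy")
are reverse-coded (r → 3 − r) and every item is then binarised as
0 = rarely vs 1 = at least sometimes. For the positive items the two
steps collapse to "1 iff raw ≤ 2"; the code uses this closed form and
the test suite checks it against the explicit two-step transformation.
Rows with any missing or out-of-range cell in either wave are dropped
listwise and counted (network estimation does not accommodate missing
data; no imputation is attempted). Items are fixed in D1..D10 order and
every matrix in the package is indexed in that order.

## Cross-sectional estimation (eLasso)

Each node j is regressed on the remaining p−1 nodes by ℓ1-penalised
logistic regression over a log-spaced descending grid of 100 penalties
from λ_max (the smallest penalty with an all-zero slope vector, computed
from the score at the intercept-only fit) down to λ_max/100. The
intercept is never penalised. Per node, EBIC with γ = 0.5 selects the
penalty; k counts nonzero slopes only and the candidate count is p−1.
Ties in EBIC resolve toward the larger penalty (sparser model).
Symmetrisation uses the AND rule by default — an edge exists only if
both directed coefficients are nonzero, with weight equal to their
average — matching the established eLasso convention; the OR rule is a
flag. Predictors enter unstandardised: they are binary, so raw
coefficients are log-odds per endorsement (`standardize=True` is
available and returns coefficients on the original scale).

The optimiser is an IRLS outer loop around cyclic coordinate descent on
the weighted least-squares subproblem, warm-started along the grid,
with an active-set strategy (full Karush–Kuhn–Tucker sweeps activate
coordinates; cheap sweeps over the active set do the work). Convergence
is declared when the largest coefficient change in an outer iteration
falls below 1e-7. IRLS weights are clipped at 1e-5, the usual guard
against degenerate fitted probabilities. λ_max is inflated by a factor
1 + 1e-9 so the boundary coordinate stays exactly zero at the first
grid point regardless of summation order. The unit tests verify the
KKT conditions along the path to 1e-4 and agreement with an
independent solver (scikit-learn's penalised logistic regression).

A node with a constant column cannot be regressed; it is isolated
(all-zero row/column) with a warning and a ±30 threshold stands in for
the infinite intercept.

## Longitudinal estimation (CLPN)

For each Wave-2 item, all ten Wave-1 items enter an ℓ1-penalised
logistic regression. Tenfold cross-validation on the held-out binomial
deviance (mean per-observation deviance per fold; SE = SD of fold
deviances/√10) selects λ_min, and the one-standard-error rule reports
the largest penalty whose mean deviance is within one SE of the
minimum. Folds are stratified by outcome prevalence — binary outcomes
near 20% endorsement with ten folds otherwise risk folds whose training
outcome is constant; if that still happens the assignment is redrawn
from a spawned sub-seed and logged. Reported weights are the raw
log-odds coefficients at λ_1SE (λ_min selectable). Autoregressive
effects sit on the diagonal of B and are retained in the network object
but excluded from expected-influence sums.

## Centrality

Strength uses absolute weights (all-positive printed networks make the
absolute and signed versions coincide; absolute is the default),
expected influence uses signed weights, and the directed network gets
out-EI (row sums of B minus the loop) and in-EI (column sums minus the
loop); a flag can re-include loops. Standardised values are z-scores
with the population SD (divisor n); a zero-SD metric is reported as
all-zero z with a degeneracy flag. Closeness and betweenness are
computed on distances 1/|w| via networkx, flagged exploratory
throughout — they are unstable in cross-sectional symptom networks —
and closeness falls back to the harmonic form (flagged) on disconnected
graphs.

## Resampling

Edge and centrality accuracy use the nonparametric bootstrap (default
B = 1000): rows resampled with replacement, networks re-estimated,
empirical 2.5/97.5% quantiles as CIs, and difference tests that flag a
pair when the bootstrap CI of the difference excludes zero. The CS
coefficient uses case-dropping subsampling **without** replacement (the
established convention) over drop proportions 0.05–0.75 in steps of
0.05, correlating subset strength with full-sample strength (Pearson by
default, Spearman optional); CS is the largest drop proportion at which
at least 95% of subsamples correlate ≥ 0.7, and 0.75 is the reportable
ceiling. Replicates draw independent streams from a SeedSequence
hierarchy, so results are reproducible and independent of execution
order; degenerate replicates (constant columns after resampling) are
counted, never silently dropped.

## Network comparison

Replicability between two same-node networks: φ = Pearson correlation
of the 45 edge-presence indicators (presence means exactly nonzero
after estimation — LASSO and the AND rule produce exact zeros, so no
epsilon is needed; all-present or all-absent networks make φ undefined
and it is reported as NaN) and ρ = Spearman correlation of the 45
weights. Invariance: the maximum absolute edge difference M and the
global-strength difference ΔS are recomputed under permutation with the
add-one convention p = (1 + #{perm ≥ obs})/(1 + n_perm), so p ∈
[1/(n_perm+1), 1]. Two permutation schemes are provided: the standard
independent-groups shuffle of pooled rows, and — the default for
two-wave comparisons of the *same* subjects, where the groups are
dependent — a paired scheme that swaps each subject's two rows with
probability ½. The independent-groups test applied to dependent waves
reproduces the conventional procedure but is anti-conservative in
principle; the paired mode is the statistically appropriate one, and
both are exposed.

## Synthetic generator

Wave 1 is an Ising model on {0,1}^p — the {0,1} coding (not ±1) makes
its full conditionals exactly the nodewise logistic regressions the
estimator fits, so parameter recovery is a like-for-like test. Sampling
is full-sweep Gibbs with P(x_j = 1 | rest) = logistic(τ_j + Σ W_ij x_i).
By default each row is an independent chain run for `burn_in = 1000`
sweeps from a uniform start, giving i.i.d. rows (what the estimators
assume); a single-chain mode with thinning exists for completeness.
Wave-2 items are conditionally independent Bernoulli draws given
Wave 1 through logistic(α_j + Σ_i B_ij x1_i) — exactly the CLPN
likelihood's implicit assumption; contemporaneous Wave-2 dependence is
deliberately absent from the preset.

`cohort_preset` fixes p = 10 with 12 edges, |W| ∈ [0.5, 1.5], one
negative edge, anchored on the strongest empirically reported symptom
pairs (hopelessness–lack of happiness 1.4, lonely–cannot-get-going
1.3). Thresholds are calibrated by a deterministic fixed-point
iteration against **exact** 2^10-state marginals so the endorsement
rates equal the empirical Wave-1 rates (0.20–0.67 band); Wave-2
intercepts are solved by bisection against the exact Wave-1
distribution the same way. Autoregressive effects lie in [0.5, 1.2]
(restless sleep highest at 1.2) and five cross-lagged effects of
0.5–0.6 exist, four leaving the "lack of happiness" driver node, which
therefore has the largest true out-EI by construction. The construction
is deterministic; the `seed` argument is recorded for provenance.

What the preset does **not** emulate: item-level measurement error,
covariate-driven heterogeneity, panel attrition, ordinal response
structure, or contemporaneous Wave-2 dependence. Passing recovery tests
therefore shows the estimators work when their model is true — a
necessary check, not evidence about any particular cohort.

## Problem sizes and numerical settings

Defaults used by the library: B = 1000 bootstraps, 1000 permutations,
10 folds, 100-point λ grid with ratio 0.01, coordinate-descent
tolerance 1e-7, burn-in 1000 sweeps. The statistical test suite and the
acceptance script scale the *replication* dimensions down to keep a
single-core run tractable while leaving the generator and all
acceptance bands untouched: recovery studies use n = 5000 with 20 seeds
(tests) or 5 seeds (script); the type-I calibration of the M-test uses
80 simulations × 60 permutations with 500 subjects per group and a
20-point grid at tolerance 1e-5 (the permutation null only requires the
estimator to be applied identically to observed and permuted data, so
the coarser estimator settings do not affect validity); CS coefficients
use B = 25 over the coarse grid {0.1, 0.25, 0.5, 0.75} at n = 3000 for
structured data and n = 200 for noise. The CLPN recovery runs use a
50-point grid with ratio 0.05, which leaves the 1SE selection
unchanged on these problems at half the cost.

## Known limitations

* The AND-rule edge weight averages two shrunken coefficients; weights
  are biased toward zero relative to the generating W (visible in the
  worked example), as expected for LASSO-regularised estimates.
* The λ_1SE rule is deliberately conservative; true cross-lagged
  effects below ≈0.3 log-odds at n ≈ 5000 are routinely shrunk to zero.
* The CS coefficient is reported on the package's fixed grid; values
  are grid-resolution-limited (a CS of 0.75 means "the ceiling", not a
  continuum estimate).
* φ is undefined (NaN) when either network is edge-complete or empty;
  callers must handle that case.
* p > 14 has no exact pmf oracle (enumeration bound); sampler checks at
  larger p rely on moment comparisons only.
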