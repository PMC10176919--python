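# Methods

## Model

p values from a directional DE experiment are split by fold-change sign into
a *signal* half (the direction where direct, primary effects can occur) and a
*background* half.  Both halves are modelled with one shared bi-beta-uniform
mixture:

* signal:      `f(p) = θ·ar·p^(ar−1) + (1−θ)(1−λ)·a·p^(a−1) + (1−θ)λ`
* background:  the same with θ = 0, r = 1, i.e. `(1−λ)·a·p^(a−1) + λ`

with CDF `F(p) = θ·p^(ar) + (1−θ)(1−λ)·p^a + (1−θ)λ·p`.  Assumptions: primary
effects occur in exactly one known direction; secondary effects have the same
`Beta(a,1)` p-value shape in both directions; the primary peak is steeper than
the secondary peak (`ar < a`, i.e. r < 1); p values are independent draws.
The background half is what identifies the secondary-effect shape — without
it θ and λ would be badly confounded.

### Parameters

| parameter | meaning | domain |
|---|---|---|
| λ | null fraction of the non-primary density | (0, 1) |
| a | secondary-effect beta shape | (0, 1) |
| θ | primary-effect mixing weight | (0, 1 − 2α) |
| r | primary/secondary shape ratio; primary shape = a·r | (0, 1) final; (0, 10) preliminary |

θ's upper bound 1 − 2α removes the degenerate optimum where the entire signal
half is labelled primary when true signal is weak.  α (default 0.05) is the
intended significance level of the downstream calls.

## Fitting

The total log-likelihood — the sum over both halves — is maximised with BFGS
(scipy, analytic gradients, at most 200 iterations per start) in
logit-transformed coordinates `z = log((x − lb)/(ub − x))`, which keeps every
parameter strictly inside its bounds.  Six fixed starting vectors crossing
λ ∈ {0.25, 0.75}, a ∈ {0.2, 0.6}, r ∈ {0.05, 0.3}, with θ at 10/50/90 % of its
bounded range, are tried; the converged solution with the highest likelihood
wins (ties to the earliest start, for determinism).  scipy's "precision loss"
stop is accepted as convergence alongside a clean success — it routinely fires
at a perfectly usable optimum of this surface — while iteration-capped runs
are not.  Non-finite likelihood evaluations return a large penalty so line
searches retreat from degenerate corners.

The gradient is computed in component-weight form (each component's share of
the density at each point), which stays bounded even at p values near the
underflow floor where `p^(a−1)` approaches the overflow threshold.  A test
validates it against finite differences, and a separate test cross-checks the
whole optimum against an independent R `optim()` implementation of the same
likelihood.

**Underflow.**  Upstream software reports p values that underflow to 0.  Any
p below 10× the smallest positive normalised double (≈ 2.23e-307) is raised
to that floor before fitting; the likelihood is then finite everywhere since
all density exponents exceed −1.

## Outlier trimming (the "modified" procedure)

A preliminary fit with r bounded to (0, 10) is run first.  Fitted r ≥ 1
contradicts the model's premise (primary steeper than secondary) and flags
unexpectedly strong background signal, i.e. outliers.  The smallest
background p values are then removed one at a time — refitting with the wide
bound after each removal — until r < 1, stopping at
`min(floor(0.05·n_background), 10)` removals.  The reported fit is always
re-done with r bounded to (0, 1) on the (possibly) trimmed data, so the final
model satisfies r < 1 structurally even when the cap is hit.  Signal-half
points are never trimmed.  Unit steps and the conservative `floor` reading of
the 5 % cap were chosen where the procedure leaves the batch size open.

## Significance

`p_BBUM(p) = 1 − θ·p^(ar)/F(p)` is the model's expected FDR among
signal-direction features with raw p at or below p; features with
`p_BBUM < α` (strict) are called.  For r < 1 the quantity is monotone
non-decreasing in p.  Comparators:

* **BH** — standard step-up adjustment (statsmodels), computed over the
  combined two-direction feature set, matching how DE engines report `padj`.
* **Extreme-value rule** — the BH threshold is lowered through the canonical
  sequence 0.05, 0.01, 0.001, … to the most permissive value strictly below
  every background-direction adjusted p value.  One extreme background
  outlier therefore collapses the threshold and can silence the analysis —
  the failure mode the mixture model is designed to avoid.

Features are classified four ways for reporting: significant by both BBUM
and BH, by BBUM only, by BH only (the only category background features can
reach, since p_BBUM is undefined for them), or trimmed as an outlier
(which takes precedence).

## Synthetic data and benchmark

The generator emulates an experiment drawn from the model itself: total
feature count N ~ U(200, 1000); signal-half size Binomial(N, 0.5); per half,
component counts cascade through binomials (primary ~ B(n, θ) in the signal
half, outlier ~ B(n, θ′) in the background half when enabled,
null ~ B(remaining, λ), secondary the rest); component draws are inverse-CDF
(`Beta(s,1) = U^(1/s)`).  Per-dataset parameters come from λ, a ~ U(0.1, 0.9),
log10 θ, log10 r ~ U(−1.5, −0.5), log10 θ′ ~ U(−2.5, −1.5),
log10 r′ ~ U(−2, −1).  Whole simulations are redrawn until they hold ≥ 3
primary points (and ≥ 1 outlier when the outlier component is enabled), so
confusion statistics are always defined.

Each dataset is scored per method: positives are called signal-half
features, truth is the generating component label, `FDR = FP/(FP+TP)`
(0 when nothing is called — this makes the statistic total and produces the
spike of zero-FDR datasets visible in the benchmark histograms) and
`sensitivity = TP/(FN+TP)`.  Aggregates (mean FDR, CV of FDR, mean
sensitivity) carry 95 % basic-bootstrap CIs (scipy, 3000 resamples),
reported as the mean deviation of the interval ends from the point estimate.
BBUM variants are refit at every α examined because θ's bound depends on α.

What the generator does **not** emulate: dependence between features (shared
samples, correlated genes), discreteness of count-based p values,
non-beta-shaped alternatives, and asymmetric secondary effects.  Passing
benchmarks therefore demonstrate correctness of the procedure under its own
model, not robustness to real-data violations of it.

### Problem sizes and numerical choices

Benchmark runs in the test suite and the acceptance script use 500
simulations per scenario, and 250 per point of the six-value α grid
{0.2, 0.1, 0.05, 0.02, 0.01, 0.005} used for the calibration curve — sizes
at which bootstrap CIs on the headline statistics are a few thousandths wide
while a full run stays in the minutes range on one CPU.  Statistical
assertions in tests use the CIs the benchmark itself computes; the α-grid
check allows for the multiplicity of six simultaneous intervals (at most one
mild 95 % excursion, all points within 3.5 standard errors).  Ties among
equal background p values during trimming are broken by input order; ties in
log-likelihood across starts by start index.  All randomness flows from
explicit seeds (numpy `SeedSequence` spawning per simulation), so every
result in the package is bit-reproducible under a fixed seed.

## Known limitations

* The canonical-threshold comparator loops to arbitrarily small powers of
  ten; a background feature with adjusted p of exactly 0 (possible after
  underflow) yields a zero threshold and an empty call set for that dataset.
* With very large datasets (thousands of background points), a handful of
  extreme outliers may no longer push the preliminary r above 1 — their
  likelihood share shrinks with n — so trimming is less sensitive at scales
  far above the few-hundred-feature experiments the procedure targets.
* Parameter uncertainty is not propagated into p_BBUM; no standard errors or
  CIs are reported for (λ, a, θ, r).
* Model selection against the plain two-component beta-uniform mixture is
  out of scope.
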