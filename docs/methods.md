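# Methods

## Profile space and state construction

A cognitive profile assigns levels to seven function indicators: four
binary functions (ATT, VF, CF, PS) and ordinal episodic memory with
levels 0–3, expanded for reporting into the monotone indicator triple
EM1 ≥ EM2 ≥ EM3 (capability at level k implies capability below it; a
battery entry demanding EM2 therefore also demands EM1, and
non-contiguous memory requirements are rejected at parse time).  The
full space holds 2·4·2·2·2 = 64 profiles.

Each profile's ideal response vector over the battery is computed under
the conjunctive rule: entry 1 iff the profile holds every function the
test requires at a high level.  Profiles are grouped by identical ideal
vector; each group is one classification state.  This construction is
identifiable by design: two profiles land in the same state exactly when
no test in the battery can separate them.  Functions on which a state's
member profiles disagree are *undetermined* (confounded); in the bundled
9-test panel CF is undetermined in the four non-bottom states whose
member profiles hold VF and PS low, because CF is only ever probed
jointly with VF (category fluency) or PS (a timed trail-making task).

States are partially ordered by entrywise dominance of ideal vectors —
well-defined on equivalence classes, and equivalent to profile dominance
for conjunctive requirements.  The Hasse diagram is the transitive
reduction (networkx), verified in tests against a brute-force
reachability oracle.

**State numbering.**  Indices 1..n are assigned by sorting the states'
seven-function high-indicator vectors (ATT, EM1, EM2, EM3, VF, CF, PS;
undetermined treated as low) in descending lexicographic order, ties
broken by descending ideal vector.  This is a linear extension of the
partial order (asserted in tests), puts the all-high state at index 1
and the bottom class last, and reproduces the published 29- and 33-state
tables index-for-index, including the confounded states at 7, 14, 21 and
28.  A published tie-break rule is not available; lexicographic order is
the simplest rule consistent with both published tables.

**Bottom-state convention.**  In the bundled panels every test requires
attention, so all 32 ATT-low profiles collapse into one bottom state in
which every other function is undetermined.  That state is reported with
all functions low — the conservative convention — and correspondingly
contributes nothing to any function-high probability.

## Response distributions

Raw scores are aligned so higher is better (timed scores negated), then
categorized by the sample 25/50/75 percentiles (linear-interpolation
definition).  A value's category is the number of cutpoints strictly
below it, so ties always share a category and the categorization is
invariant under strictly monotone transforms.  Fewer than four
non-missing scores is an error; an all-constant score column degenerates
to a single category with a warning.

Per test, capable and non-capable multinomials over the four categories
are estimated by Gibbs sampling with Dirichlet(α = 1) priors:

1. given current θs, draw each subject's latent state from its
   conditional posterior (uniform prior over states; likelihood in log
   space with missing responses contributing nothing);
2. given states, draw each test's θ_capable and θ_noncapable from
   Dirichlet(α + category counts), a subject counting toward capable iff
   the ideal response of its current state is 1 for that test.

Defaults: 2000 sweeps, 500 burn-in, posterior means reported.  The
chain is initialized from a dominance-seeded tilt (capable mass
increasing in category, non-capable decreasing) with each subject at
its MAP state under that tilt, which pins the capable/non-capable role
labels and prevents label switching.  The sampler is vectorized over
subjects × states and runs in roughly two seconds at n = 500 with 29
states on one CPU.  Identical seeds give bit-identical output.

A fitted test is flagged when its posterior-mean capable distribution
fails to stochastically dominate the non-capable one (CDF crossing) —
the model-fit criterion that estimated distributions should reflect the
specified order structure.  On well-specified synthetic cohorts the
flag rate is at most 5%; generating both groups from the same
distribution reliably raises it.

Timed scores can alternatively be modelled continuously with a finite
Gaussian mixture, components 1..5 fitted by maximum likelihood and
selected by BIC.  The discrete quartile path is the default for all
tests; the mixture is an option, not a second code path through the
classifier.

**Estimation accuracy and its floor.**  At n = 500 a group's empirical
category frequency carries standard error ≈ √(0.7·0.3/250) ≈ 0.03 even
under a perfectly balanced design, so the max-norm error of *any*
estimator against the generating θs across all tests and categories is
typically 0.05–0.09.  The recovery tests therefore check two things
separately: agreement of the Gibbs posterior means with the oracle
estimates computed from the true latent memberships (≤ 0.05 — the
algorithmic content), and agreement with the generating values at the
noise-consistent 0.10.  On the full 9-test panel under a uniform state
distribution the attention-only test's non-capable group is a single
state (~n/29 subjects), and the calibrated tolerance there is 0.2.  A
single-test design is avoided entirely: with one response per subject
the two-group mixture is identified only through its marginal, so
recovery batteries replicate tests that probe the same latent split.

## Classification

Posterior over states by Bayes rule with the conditional-independence
likelihood, computed in log space; an observed category with zero
probability under both distributions of a test is reported as an error
naming the test.  Uniform priors (1/29, 1/33) are the default and the
no-data posterior equals the prior.  Updating one test at a time in any
order equals the joint update.  P(function high) sums posterior mass
over states that determine the function high; undetermined functions
contribute zero ("not demonstrably high") — the same pessimistic
convention as the bottom state.  Consequently P(EM1) ≥ P(EM2) ≥ P(EM3)
for every posterior, since the EM-high state sets are nested.  The MAP
state breaks exact ties toward the lower index.

## Cohort analysis

Ages are stratified <70, 70–80, 81–90 (inclusive bounds, fractional
ages floored; accepted study range 55–90).  Within-age-group z-scores
use the group mean and sample SD after orientation alignment; groups
with fewer than two scores or zero spread are errors.

Mann-Whitney U is two-sided, delegated to scipy: the exact null
distribution whenever the pooled sample is tie-free and n₁+n₂ ≤ 40
(covering the published strata sizes), otherwise the tie-corrected
normal approximation with continuity correction.  Tests verify
agreement with an independent exact-enumeration oracle (the classic
partition recurrence for the U distribution) to 10⁻³ and with a 10⁶-draw
Monte-Carlo permutation oracle.

The amyloid comparison emits one row per stratum × function with U, p,
arm sizes, a Bonferroni flag at 0.05/7 ≈ 0.007 (the divisor is the
number of cognitive functions, not the number of strata) and a nominal
0.05 flag for the exploratory cognitive-status-stratified mode.  Strata
with fewer than two subjects in either arm are flagged not-computable
but kept.  The APOE4-by-age table reports, per cell, the amyloid
negative/positive counts, the majority class and the accuracy of always
predicting it, max(n₊, n₋)/(n₊+n₋) as a percentage with one decimal;
empty cells report NA.

## Random forest

Each of `ntree` (default 1000) CART trees (scikit-learn, Gini splits,
`mtry` = 4 candidate variables per split, leaves down to one sample) is
grown on an n-draw bootstrap; bootstrap sampling, OOB vote tallying and
permutation importance are computed in this package so the OOB/MDA
semantics are independent of backend defaults.  OOB error is the
misclassification rate of the majority vote over the trees for which
each subject was out of bag (~e⁻¹ ≈ 0.37 of trees each).  MDA permutes
one predictor within a tree's OOB rows, averages the accuracy drop over
trees and reports percentage points; a permutation that leaves the
column unchanged (constant predictor) contributes exactly zero, and
negative values for uninformative predictors are expected.  Categorical
predictors are integer-encoded (APOE4 0/1/2 ordinal, gender and
education binary); rows with missing predictors are dropped
(complete-record analysis).

## Synthetic cohorts

The generator draws, per subject: an age uniform within its stratum, a
gender (1:1), an education flag (P = 0.8), an APOE4 count from a
status-specific distribution (more alleles under MCI), an amyloid
status whose probability rises with APOE4 count and age (defaults
patterned on the observed cell proportions of the screening analysis —
configuration values, not assertions about any study), a latent state,
and per-test quartile categories from θ_capable or θ_noncapable
according to the state's ideal response (defaults 0.7 mass on the best
and worst category respectively).  Default stratum sizes total 437
across three age bands × two cognitive statuses, the scale of a
mid-sized two-arm screening study.

Latent-state weights concentrate toward high states for cognitively
normal subjects and away from them for MCI (`state_sharpness`, default
0.5), or can be given explicitly.  The episodic-memory depression
`delta` moves a fraction δ of every EM2-high state's weight, in amyloid
positives only, to the state with the same non-memory signature and EM
demoted to level 1; δ = 0 makes the arms exchangeable exactly — the null
used for calibration.  Categories can be emitted as continuous scores
drawn within the matching quartile band of a standard normal (negated
for lower-is-better tests), so quartile categorization recovers the
generating category up to cutpoint estimation error; 2% missingness by
default.

What the generator does *not* emulate: real score distributions (shapes,
floors/ceilings, practice effects), correlated residuals beyond the
latent state, informative missingness, longitudinal follow-up, or
site/cohort effects.  Passing tests therefore demonstrate correctness of
the machinery and calibration under the assumed model, not performance
on restricted clinical data; published p-values, demographics and
forest importance magnitudes are deliberately out of reach and only the
table *shapes* are reproduced.

## Problem sizes and numerical choices

Test-suite simulations use cohorts of 200–500 subjects, Gibbs chains of
200–2000 sweeps and forests of 50–500 trees; power and calibration
checks use 25–50 seeded replicates with thresholds frozen from a single
calibration run (null rate within [0.02, 0.08] at the nominal 0.05
level; ≥ 80% detection of δ = 0.5 at ~100 subjects per arm; signal
variables outranking noise covariates in ≥ 90% of forest replicates).
Probability vectors are validated to 10⁻⁹; likelihoods accumulate in
log space with −∞ guarded; all randomness flows through
`numpy.random.default_rng` seeds recorded in the run manifest, and
re-runs with identical manifests are byte-identical.
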