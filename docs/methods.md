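# Methods

## The problem

Verbal autopsy (VA) infers a cause of death from a structured interview
with caregivers, in settings without medical certification.  Validation
studies compare a VA method's assignments with gold-standard causes and
must summarize performance in two distinct dimensions: how often
individual deaths receive the correct cause, and how accurately the
population-level cause-specific mortality fractions (CSMFs) are
estimated.  Most legacy metrics — specificity, overall concordance,
Cohen's kappa, absolute and relative CSMF errors — are functions of the
cause composition of the particular test dataset, so values from
different studies are not comparable and a worse method can look better
on a single test set.  This package implements composition-robust
metrics and the resampling protocol that makes any remaining
composition sensitivity visible.

## Metrics

**Chance-corrected concordance (CCC).**  For cause *j* with per-cause
sensitivity *s_j* (diagonal count over row total of the N×N
classification table) and *N* causes,

    CCC_j = (s_j − 1/N) / (1 − 1/N).

Uniform random assignment gets a death right with probability 1/N, so
CCC is 0 at chance, 1 at perfection, and negative (bounded by
−1/(N−1)) below chance.  Because *s_j* conditions on the true cause,
CCC is exactly invariant to the test-set composition whenever the
method's misclassification probabilities are.  The overall CCC is a
weighted mean of the per-cause values; equal weights are the default
(and the recommended choice) because test-set weights reintroduce
composition sensitivity and standardized global weights behave badly
when a study's cause list is partial.  Test-set weights and
user-supplied weight vectors remain available.

**Partial chance-corrected concordance PCCC(k).**  For methods that
rank several candidate causes per death, C(k) is the fraction of deaths
whose true cause is among the k highest-ranked causes (non-decreasing
in k by construction).  Chance correction uses the partial chance
concordance PC(k), the probability that a random method places the true
cause in its top k.  We model the random method as producing a uniform
random ranking without duplicates, giving PC(k) = k/N; this satisfies
both boundary conditions PC(1) = 1/N and PC(N) = 1, and matches
brute-force enumeration over random rankings.  An alternative
"replacement" convention, PC(k) = 1 − ((N−1)/N)^k (k independent
guesses, duplicates allowed), is available as a configuration switch
for sensitivity analysis; it does not reach 1 at k = N, which is why it
is not the default.  PCCC(k) = (C(k) − PC(k))/(1 − PC(k)) and is
undefined at k = N, where any method scores 1.

**Cohen's kappa** is included as the legacy comparator.  Its expected
agreement is built from the dataset's own marginals
(Σ row_i·col_i/total²), which ties it to the test composition — the
instability the simulation study demonstrates.

**CSMF accuracy.**  With true fractions *t* and predicted fractions
*p*, the total absolute error Σ_j |p_j − t_j| is bounded by
2·(1 − min_j t_j), attained by predicting 100% of deaths from the cause
with the smallest true fraction.  CSMF accuracy is

    1 − Σ_j |p_j − t_j| / (2·(1 − min_j t_j)),

which runs from 0 (worst possible method) to 1 (no error) regardless of
N.  Per-cause CSMF behaviour across many compositions is summarized by
OLS of the predicted fraction on the true fraction: the intercept α
measures mass assigned to a cause even when absent, the slope β < 1 for
any imperfect method (small causes over-, large causes under-estimated),
and the residual SD (RMSE) the noise at fixed truth.  RMSE uses
denominator n by default (residual SD as a descriptive quantity); the
n−2 regression convention is available.

## The resampling protocol

Compositions are drawn from an uninformative Dirichlet — all
concentration parameters 1, i.e. the uniform distribution on the
simplex, whose mean is equal cause fractions.  For each drawn
composition, cause counts are multinomial and records are resampled
with replacement within each true cause, preserving the method's
conditional prediction behaviour.  A metric is summarized as the median
across draws (robust to the extreme values CSMF accuracy takes at
extreme compositions).  The running median is monitored every 10 draws;
it counts as stabilized when its relative change falls below 0.5%.  The
default run is a fixed 500 draws with stabilization reported; stopping
at stabilization is opt-in, so default results are exactly reproducible
from the seed alone.  Randomness is a single root seed that spawns one
independent substream per draw, making per-draw results independent of
execution order.

## The simulation study

A hypothetical VA method is abstracted as its misclassification matrix
— the row-stochastic matrix p_ij = P(predicted j | true i).  Two
built-in three-cause methods are provided; method 2 dominates method 1,
differing only in a higher diagonal entry for cause A.  The experiment
draws compositions, simulates test datasets, applies both methods, and
computes every metric per draw, demonstrating that (a) all legacy
metrics except sensitivity/CCC swing widely with composition, and
(b) on a substantial fraction of single test sets the inferior method
shows the smaller absolute CSMF error — the central argument for
median-across-compositions reporting.

Two evaluation modes exist:

* **analytic** — the expected classification table diag(p)·M is used
  directly (the infinite-sample limit).  Composition-invariant metrics
  are constant across draws up to float re-summation (~1e-16), and
  paired comparisons have no sampling ties.  Paired win counts are
  computed in this mode by default in the acceptance workflow because
  expected errors are deterministic functions of the drawn composition.
* **finite-sample** — true-cause counts are multinomial at
  `deaths_per_dataset` (default 1000; the realistic scale of a VA
  validation study), and predictions are sampled from the matrix rows.
  When several methods are evaluated, predictions are coupled across
  methods by common random numbers: one uniform variate per death,
  inverted through each method's row CDF.  Marginals per method are
  exactly multinomial, while a method that differs only by a better
  diagonal entry reclassifies *the same* deaths rather than redrawing
  them — the paired analogue of applying every method to one test
  dataset, and the design that makes per-draw win counts meaningful.

The benchmark (`vametrics reproduce`, and `scripts/acceptance.py`) uses
500 draws.  At that size the Monte-Carlo standard error is ≈0.02 on the
regression slope/intercept diagnostics and ≈2 percentage points on win
percentages; published values for such experiments carry the same
order of uncertainty.

## Numerical and design choices

* Probability and fraction sums are validated to 1e-9 and never
  silently renormalized; malformed inputs raise labeled errors naming
  the offending record or cause.
* Undefined metrics (sensitivity/CCC of a cause with no true deaths,
  specificity with no off-cause deaths, relative error at a zero true
  fraction, kappa with expected agreement 1) return NaN with a logged
  warning and are excluded — with weight renormalization — from
  aggregates.  Dirichlet draws can make a cause vanish at small n;
  propagating NaN would poison medians across draws.  Reports serialize
  undefined values as JSON null, never 0.
* Ranked predictions are stored sorted by descending probability, ties
  broken by cause order in the cause list, so top-k sets are
  deterministic.
* Confusion counts are floats so that tallied integer tables and
  analytic expected tables share one type; `grand_total` must be
  positive.
* Win-count ties are reported in their own column rather than assigned
  to either method; under continuous (analytic) errors they have
  probability zero, under finite sampling they are real and visible.
* Specificity is computed as (off-cause deaths not assigned to the
  cause)/(off-cause deaths) in one division, so it agrees exactly with
  per-record counting.

## What the simulator does and does not emulate

The generator reproduces the structure of a validation study in which a
method's misclassification probabilities are fixed attributes: it
varies only composition and sampling noise.  Real VA methods can have
misclassification probabilities that themselves drift with the cause
composition (empirically trained methods especially), real studies have
imperfect gold standards, and real ranked outputs have correlated
probabilities across causes.  Passing tests therefore certify the
metrics and the protocol, not any claim that a particular real VA
method is composition-robust — establishing that requires running this
protocol on that method's own validation data.

## Known limitations

* Proper scoring rules (Brier, log score) for probabilistic
  assignments are out of scope; top-k concordance is used for
  simplicity and comparability.
* Nominal-association measures (phi, Cramér's V, Matthews correlation,
  …) are deliberately not implemented: they mix individual-assignment
  and CSMF performance into one number, which is the confusion the
  two-metric design avoids.
* With very small datasets or extreme compositions, many per-cause
  metrics are undefined; aggregates then rest on few causes and the
  logged exclusion counts should be inspected.
* Kappa can be low only where expected CSMF errors are moderate for the
  built-in method 1 (given kappa < 0.1, the total absolute error is at
  least ≈0.06 in expectation); joint "low kappa, near-zero error"
  draws are therefore rare borderline sampling events at 1000 deaths
  per dataset rather than a typical occurrence.
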