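# Methods

This note documents the statistical model behind `diabrisk`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate.

## Evidence model

The unit of evidence is a *from-to record*: one published finding stating
that when a risk factor moved from one value to another, the risk of a
complication moved from one percentage to another. Records are flattened to
two scatter points, one per endpoint, with no interpolation between them:
the record format preserves the provenance of paired observations, but the
curve-fitting stage consumes plain (factor, risk) points. Findings from
different sources at the same factor value are both kept, unweighted —
study sizes for the underlying trials are generally unavailable, so no
meta-analytic weighting is attempted.

Risks are percentages but are *not* capped at 100 on ingestion: several
source studies report rates per 100 patient-years, which can legitimately
exceed 100; ingestion warns above 100 and otherwise keeps the value.
"Prevents" relationships are stored with their risks untransformed — a
protective factor simply yields a downward-sloping curve.

## The seven-pattern fit

Each factor-complication dataset is fitted with seven shapes: linear,
logarithmic, quadratic and cubic by OLS on the raw risk, and power, S and
exponential by OLS after log-transforming the risk (the classic linearised
scheme). Diagnostics are reported on the fitting scale, which is why the
log-scale patterns show standard errors of estimate near 0.5 while the
polynomial fits on the same data show 8–10: the numbers are ln-risk units
versus percent units. Comparing R² across these two scales is not strictly
kosher — R² on ln y measures explained variance of a different response —
but it is how this model family is conventionally ranked, and the package
follows that convention rather than re-scaling.

**Selection** uses Wherry's adjusted R², not raw R². Raw R² can only grow
with polynomial order, so a cubic would routinely beat simpler shapes on
16-point tables by fitting noise; the adjustment
1 − (1−R²)(n−1)/(n−k−1) removes exactly that advantage. On the packaged
reference table the cubic has the highest raw R² (0.569 vs 0.542) yet the
linear fit wins on the adjusted scale (0.509 vs 0.461), matching the
published model choice for that dataset. Exact ties (e.g. a quadratic
fitted to perfectly linear data) resolve toward fewer coefficients, then
toward the canonical pattern order; adjusted values are rounded at 1e-12
before comparison so floating-point dust cannot override parsimony.

**Diagnostics.** R² is computed as SS_M/SS_T with SS_M the explained sum of
squares about the observed mean (identical to 1 − SS_R/SS_T for OLS fits
with intercept). F = (R²/k)/((1−R²)/(n−k−1)) with p from F(k, n−k−1).
Stein's formula estimates cross-validated fit and is always ≤ Wherry's for
n > k+2. The Durbin–Watson statistic Σ(eₜ−eₜ₋₁)²/Σeₜ² is computed on
residuals in ascending factor order — serial correlation is only defined
relative to an ordering, and ascending factor value is the order the
datasets are stored and printed in. A perfect fit has no residual sequence
and is reported as DW = 0. Degenerate inputs are rejected rather than
silently patched: constant responses (SS_T = 0), all-zero residual vectors,
rank-deficient designs, and non-positive values where a pattern needs a
logarithm.

The ANN baseline is deliberately minimal: one tanh hidden layer, linear
output, full-batch gradient descent, inputs and targets standardised
internally, all randomness from one seed. It exists as a comparison arm for
the regression patterns, not as a serious competitor; no regularisation or
early stopping is provided.

## Naïve-Bayes combination

A fitted curve evaluated at an observed factor value is read as
q_k = P(C=yes | f_k) after dividing by 100. Class-conditional independence
turns the inverted conditionals P(f_k|C) = P(f_k)P(C|f_k)/P(C) into a
product; writing the chain for both classes and normalising, the factor
marginals P(f_k) cancel, leaving

    P(yes | X) = σ( log s_yes − log s_no ),
    log s_yes = (1−n)·log p + Σ log q_k,
    log s_no  = (1−n)·log(1−p) + Σ log(1−q_k),

with p the complication's population prior. The published formulation
computes only the unnormalised "yes" product; the two-class normalisation
is this package's addition, required for the output to be a probability
(and for the n=1 case to reduce exactly to q₁). Log-space evaluation keeps
the chain finite for at least 50 factors.

Two clips guard the curve-to-probability boundary: raw predictions outside
(0, 100)% — possible for polynomials — are clipped to [1e−4, 100−1e−4]
percent with a warning, and q values are clipped into [1e−6, 1−1e−6] before
the logs. Bayes inversion similarly clips ratios above 1 (inconsistent
inputs) with a warning.

## Network compilation and inference

Continuous factors are discretised into half-open bins ]lo, hi] (right
boundary included, matching the convention that a measured 8.0 falls in
]7, 8]). Each bin carries a representative value — the midpoint by default,
overridable per bin, and deliberately *required* to be explicit where a
midpoint would be a poor summary (wide top bins). CPT rows are the
combiner's posterior evaluated at the parents' representative values, one
row per element of the Cartesian product of parent state sets.

Complication-to-complication edges (e.g. albuminuria stages feeding
retinopathy) are quantified through a `parent_value_map` that places each
parent state on the measured scale of the factor the 1-1 curve was fitted
on — "micro = yes" maps to a configured representative albumin excretion
rate — so the same curve machinery supplies the conditional. No separate
complication-to-complication dose-response data exists, and this mapping
makes the assumption explicit and configurable.

Inference enumerates the joint distribution exactly: observed factors are
fixed to their discretised state, everything else (unobserved factors over
their population bin frequencies, complications over yes/no) is summed out,
and each complication's yes-mass is normalised by the total. Networks here
have a handful of nodes and at most dozens of states, so enumeration is
exact, dependency-correct (complications sharing unobserved factor parents
are handled by the joint sum, not by an independence shortcut), and fast.
Acyclicity, CPT completeness and prior normalisation are validated at
compile time via `networkx`.

## Evaluation

Probabilities are dichotomised at a percentage cut-off with an *inclusive*
threshold (prediction ≥ cutoff/100 → "yes"); at cut-off 100 only an exact
probability of 1 classifies positive. Sensitivity, specificity, precision
and accuracy follow the standard confusion-count formulas; a ratio with a
zero denominator is reported as missing (NaN), never as zero, so an empty
positive-prediction set does not masquerade as zero precision. The default
sweep is 60/70/80/90/100 percent.

## Synthetic cohorts

The generator emulates the kind of longitudinal diabetes cohort such
models are validated against. Default marginals (configuration choices, not
literature claims): HbA1c ~ truncated normal(8, 1.5²) on [5, 14] percent;
duration ~ uniform(0.5, 30) years; mean arterial pressure ~ truncated
normal(100, 12²) on [70, 135] mmHg; albumin excretion rate ~ truncated
lognormal(median 20, σ 0.9) on [2, 300] mg/day — plausible for a mixed
type-2 population. Factors are sampled independently by default, matching
the combiner's own independence assumption; an equicorrelation Gaussian
copula knob exists for violation studies but is off by default. Outcomes
are Bernoulli draws from the naïve-Bayes combination of the configured
*truth curves*, so the generative process matches the model class exactly.
Default truth curves use the pattern shapes typical for each pair (linear
HbA1c→retinopathy, power duration→retinopathy, logarithmic
AER→retinopathy, quadratic HbA1c→microalbuminuria, exponential
MAP→microalbuminuria) with coefficients keeping risks inside (0, 100)% over
the truncation ranges; a configuration whose curves leave that range is
rejected, not clipped.

Prior estimation uses relative bin frequencies with add-one counts for
empty bins only (occupied bins keep their exact counts, then the vector is
renormalised), so every marginal is strictly positive without distorting
well-populated bins. Empirical dose-response tables take, per bin with at
least 20 patients (configurable), the representative value against
100 × the outcome proportion.

**Parameter recovery.** The identifiability check generates a
50,000-patient cohort per pattern, bins it into 45 equal bins, refits the
generating pattern, and requires every coefficient within 10% relative
error. The study conditions (`cohort.RECOVERY_STUDY`: per-pattern domains
and generating coefficients) were set by an a-priori power analysis — exact
OLS coefficient covariance under binomial bin noise — such that 10% of each
coefficient is at least ~4 standard errors; for the log-scale patterns this
also means keeping minimum risks near or above 10%, where log-scale
binomial noise is modest. Binning at midpoints introduces a small
discretisation bias for curved patterns; at 45 bins it is well below the
sampling noise.

**What passing these tests shows — and does not.** The synthetic cohort is
generated under the model's own assumptions: independent factors, exactly
pattern-shaped dose-response, naïve-Bayes outcome combination. Recovery and
end-to-end results therefore demonstrate the *correctness* of the pipeline
(no systematic bias, correct formulas, correct plumbing), not its accuracy
on real patients, where factors correlate, curves are misspecified, and
independence fails. The end-to-end check accordingly asserts only
better-than-chance discrimination (sensitivity and specificity both above
0.5 at the balanced operating point): with realistic low prevalences and
modest true risk gradients, even the generating probabilities themselves
have an AUC near 0.66 on these cohorts, so a well-implemented learner
cannot do much better and should not be asked to.

## Problem sizes

The test suite and the reproduction script use cohorts of 1,500–6,000
patients for the end-to-end runs and 50,000 per pattern for recovery, 100
randomised toy joints for the combiner oracle and 10 randomised networks ×
3 evidence patterns for the inference oracle — sizes at which every check
is decisive (oracle agreement is exact to ≤1e−12; recovery errors sit at a
few percent against a 10% bound) while the whole suite runs in seconds.

## Known limitations

- Evidence ingestion trusts the published numbers; no bias assessment or
  study weighting is modelled.
- Extrapolating a fitted curve outside its training factor range is allowed
  but unguarded beyond the stored domain metadata.
- R² comparison across raw and log fitting scales is conventional, not
  principled (see above).
- Exact enumeration scales exponentially in the number of unobserved
  nodes; fine for these clinical networks, wrong tool past a few dozen
  nodes.
- Only binary complications are supported, and categorical factors (e.g.
  smoking) are representable as named-category bins but ship without
  default risk data.
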