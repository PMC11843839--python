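# Methods

This note documents the statistical procedures implemented in `demnorms`,
the design of the synthetic-cohort generator, the numerical conventions,
and the limits of what the test suite can establish.

## 1. The norming model

Each DEM raw score y (VT, AHT, Ratio, errors) is modelled as a linear
function of transformed demographics,

    y = β₀ + Σᵢ βᵢ tᵢ(xᵢ) + ε,

with xᵢ ∈ {age, education, sex}.  Transforms come from a configurable menu
{identity, square, cube, log, sqrt, inverse} for the continuous predictors
(sex is a 0/1 indicator, female = 0, male = 1).  Two nested searches are
run per score:

- **Transform search.** For each continuous predictor, every candidate
  transform is screened by a bivariate OLS regression; the candidate with
  the lowest BIC wins.  Transforms undefined on the data (log/inverse of a
  non-positive value) or degenerate (zero variance) are skipped with a
  warning.
- **Subset selection.** All seven non-empty predictor subsets, each in its
  best transform, are fitted by OLS (statsmodels).  The lowest-BIC model is
  retained only if its omnibus F test against the intercept-only model has
  p < 0.05; otherwise the score is normed without demographic correction.

**BIC convention.** BIC = K·ln(n) − 2·LL with K counting the slopes, the
intercept *and* the residual variance (a two-predictor model has K = 4).
This is the convention under which the published model-comparison table's
BIC column is reproduced from its printed log-likelihoods to within the
table's integer rounding (±1).  BIC weights are exp(−ΔBIC/2), normalised
over the comparison set.

**Correction equations.** The selected model is refitted on mean-centered
transformed predictors (slopes are unchanged; the refit doubles as a
numerical cross-check) and its coefficients are reversed:

    c(d) = − Σᵢ βᵢ ( tᵢ(d) − t̄ᵢ ),    adjusted = raw + c(d).

A participant at the normative-sample means receives zero correction.  The
shipped published equations are additive in the centered terms; the
printed captions are typographically ambiguous about parenthesisation, and
only the additive reading reproduces every printed grid cell, so that
reading is used throughout.  Grids are emitted at ages 20–75 (step 5) and
educations {8, 13, 16, 18, 21}, rounded half-away-from-zero to 2 decimals
(1 decimal for errors).  Exact-equation scoring is the default; the
nearest-anchor grid mode mirrors hand scoring and may differ from the
equations by up to ~0.26 score units between anchors.

## 2. Tolerance limits, equivalent scores, percentiles

Adjusted scores are screened with sample skewness (flag at |g₁| > 1) and
*excess* (Fisher) kurtosis (flag at |g₂| > 3); either flag marks the
distribution non-normal and motivates the non-parametric limits.  The
kurtosis threshold is interpreted on the excess scale and is configurable,
since the raw-vs-excess reading of the conventional |3| rule is ambiguous.

With observations ordered best-to-worst (lower adjusted score is better
for all four subtests; the worse tail is the upper tail), coverage p and
confidence γ, and B(k) = P(Bin(n, p) ≤ k−1):

- OTL rank = smallest k with B(k) ≥ γ;
- ITL rank = smallest k with B(k) > 1 − γ.

These inequality conventions reproduce ranks (488, 504) at n = 521,
p = γ = 0.95.  The OTL exists only when 1 − pⁿ ≥ γ (n ≥ 59 at 95/95); the
error raised below that reports the minimal usable n.  Ties are handled by
stable sort; the limit is the value at the rank position regardless of
ties.  Because ranks are discrete the OTL is conservative: its exact
confidence at n = 521 is B(503) = 0.963, not 0.950, which matters when
interpreting empirical coverage over simulated cohorts.

**Equivalent scores.** ES 0 is worse than the OTL, ES 4 better than the
median order statistic (rank ⌊(n+1)/2⌋).  The intermediate ES 1–3 bounds
sit at the ranks one and two thirds of the way from the median rank to the
OTL rank ("rank-thirds" policy).  The cited rank-based ES literature does
not pin the intermediate rule exactly, so the policy is a named,
configurable choice.  Percentile level q is the adjusted score with q% of
the normative sample performing worse — the (1 − q/100) quantile under
lower-is-better, linearly interpolated between order statistics — at the
printed levels 99, 95, 90, …, 5, 4, 3, 2, 1.

**Published cutoffs.** The shipped asset stores the published ES bands and
percentile rows verbatim.  Two print anomalies are preserved rather than
repaired: the Ratio and errors ITL/OTL columns appear swapped relative to
the VT/AHT ordering (the ES-band table's cutoffs, 1.33 and 2.2, are taken
as authoritative for ES 0), and the errors ES 2 and ES 3 bands are printed
identically (0.8–0.2), so assignments in that band carry an
`es_ambiguous` flag.

## 3. Power analysis

The a-priori sample size for the omnibus test of a u-predictor regression
uses the noncentral F with numerator df u, denominator df N − u − 1,
noncentrality λ = f²·N and critical value from the central F at α.  The
λ = f²·N (total-N) convention is the default because it reproduces the
design's published N = 368 at u = 3, f² = 0.03, α = 0.05, power 0.80; the
λ = f²·(N − u − 1) convention is available as an option.  The smallest N
is located by doubling plus bisection (power is monotone in N), with a
final downward walk as a guard.

## 4. The synthetic-cohort generator

No participant-level data are deposited, so the generator emulates the
study conditions and is itself first-class, tested code.

- **Demographics.** Cells of an age-decade × education-band × sex margin
  table are drawn multinomially with probability proportional to the
  published counts (n = 521; 258 male).  Ages are uniform integers within
  the decade; education is a uniform integer within the band, except that
  the lowest band is pinned at exactly 5 years so the generated range
  matches the normative sample's 5–27 years.  The margins induce the
  negative age–education correlation (≈ −0.42) seen in the sample.
- **Timed scores.** Linear means use the published reversed coefficients
  (VT: 0.000012·age³ + 48.074/edu; AHT: 0.000017·age³ + 57.49/edu; Ratio:
  0.00000016·age³) with intercepts anchored so grand means land near the
  published descriptives.  Residuals are standardised log-normals
  (shape 0.5: skew 1.75, excess kurtosis 5.9), matching the reported right
  skew and heavy tails; a Student-t family is available.  Residual SDs
  (4.71, 5.59, 0.118 s) are fixed so the *marginal* SDs match the
  published 5.68, 6.87 and 0.12.  The published marginal SDs and R² values
  cannot both be matched under these margins (the deterministic part alone
  has variance 10.1 for VT); matching the SDs was chosen because the
  downstream cutoffs depend on score spread, and the implied R² (≈ 0.31,
  0.33, 0.04) remain close to the published 0.25, 0.29, 0.03.
- **Shared naming-speed factor.** VT and AHT residuals are drawn from a
  Gaussian copula with residual Pearson correlation 0.74, chosen so the
  marginal VT–AHT correlation lands near the published 0.84; independent
  residuals would give ≈ 0.34.  Ratio is generated as its own dependent
  variable by default (the pipeline treats it as such), with a
  compositional AHT/VT option.
- **Errors.** Zero-inflated Poisson with structural-zero mass 0.70 and
  conditional mean equal to the linear predictor
  0.38 + 3.02·(1/edu − 0.0854) + 0.307·(male − 0.495), clipped at zero; OLS
  on raw errors therefore recovers the generative coefficients in
  expectation, and the marginal mean/SD (≈ 0.40/0.94) sit near the
  published 0.38/0.86 with a large point mass at zero.
- **Determinism.** All randomness flows from one seed through named
  substreams; identical (n, params, seed) reproduce the cohort bit for bit.

What the generator does *not* emulate: card-level timing and error events
(raw-score fixtures cover those), practice/administration effects,
measurement rounding of stopwatch times, and any residual dependence of
Ratio on VT/AHT beyond the optional compositional mode.  Tests that pass
on synthetic cohorts therefore establish that the pipeline recovers the
structure it assumes, not that the published coefficient values are the
truth about the population.

## 5. Known statistical limitations

- **Cubic-vs-quadratic age transforms are near-indistinguishable at this
  design.** Over ages 20–79, corr(age², age³) ≈ 0.992; at n = 521 and
  R² ≈ 0.3 the BIC gap between the cubic and quadratic bivariate fits has
  expectation ≈ 1.5 with SD ≈ 2.5, so the cubic transform wins the
  bivariate search only ~60–65% of the time on cohorts generated *with* a
  cubic truth.  Structure recovery of the full {age(cube),
  education(inverse)} specification on 100 replicates therefore plateaus
  around 60–65, and the corresponding end-to-end check is expected to
  flag this; the education-inverse transform, by contrast, is recovered
  essentially always.  This is a property of the design, not of the
  implementation.
- **Tolerance-limit coverage is conservative by construction** (exact
  confidence 0.963 at 95/95, n = 521), so empirical coverage over
  replicates concentrates near 0.963, at the edge of a 95% Wilson interval
  around 0.95.
- **Real-sample quantities** (the published decade means, correlation
  matrix, ANOVA effect sizes, tolerance-limit values and percentile rows)
  depend on the restricted cohort and cannot be recomputed here; they are
  covered by property checks (monotone grids, ES/percentile consistency,
  sign and magnitude recovery on synthetic cohorts) and the verbatim
  published asset.
- The problem sizes used by the simulation-based checks (100 replicates
  for recovery, 500 for coverage, cohorts of n = 521) were chosen to keep
  the full suite in the minutes range while leaving Monte-Carlo error well
  below the tolerances asserted.
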