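# Methods

## Model and procedure

The package treats a corpus of systematic reviews (SRs), one random-effects
meta-analysis per review, as the unit of analysis.  Three layers:

**1. Prediction intervals from reported summaries.**  Each record carries a
pooled estimate, its 95% CI, the effect measure (MD, SMD, RR, OR), the number
of trials k and, when reported, τ².  Ratio measures are moved to the natural
log scale before any arithmetic and back-transformed only at interval
boundaries; MD and SMD are identical on the identity scale with null 0.  The
standard error is back-calculated from the CI width, SE = (u − l)/(2·z₀.₉₇₅)
on the analysis scale, and the 95% prediction interval is
M ± t_{k−2,0.975}·√(τ² + SE²).  The k − 2 degrees of freedom follow the
convention that both M and τ² are estimated; `df_rule="k-1"` is exposed for
sensitivity analysis only.  A PI requires k ≥ 3 (df ≥ 1) and a reported τ²;
τ² = 0 is a legitimate value (the PI becomes a t-interval around M), whereas
a missing τ² makes the record "not computable" — it is never imputed as zero,
since a review that omits τ² gives no information about heterogeneity.

**2. Agreement classification.**  For each computable record the CI and PI
are compared against the measure's null.  Because t_{k−2,0.975} ≥ z₀.₉₇₅ and
τ² ≥ 0, the PI contains the CI, so exactly three categories exist:
corroborated-significant (both exclude the null), both-non-significant, and
CI-significant-but-PI-not.  A "PI significant, CI not" input is rejected as
corrupted rather than silently categorized.  By default the *reported* CI
determines CI significance (what the review's readers saw); a recomputed CI
from the back-calculated SE is available via `use_reported_ci=False`.

**3. Exact inference on SR-level covariates.**  Corpora of ~100 reviews
yield small, sometimes zero-celled tables, so all association analyses are
exact rather than asymptotic.  The engine is the conditional distribution of
the sufficient statistic: for a 2×2 table, the (1,1) cell given all margins
(noncentral hypergeometric); for a continuous covariate, T = Σxᵢ over the
events given the event count, with subset counts computed by dynamic
programming over the multiset of covariate values.  Weights are exact Python
integers up to normalization; probabilities at any odds ratio ψ are formed in
log space, so estimates are stable even when the support spans hundreds of
units (121 observations × 10 year values).  Point estimates are conditional
MLEs (root of E_ψ[T] = t_obs, solved by bracketed Brent iteration on log ψ to
1e−12); when t_obs sits on the support boundary the conditional MLE is 0 or
∞, so the median-unbiased estimate (ψ with half the mass on the observed
tail) is reported instead, matching the behaviour of the exact-logistic
software family used in this literature.  Confidence intervals invert the
exact tails at α/2, with 0 / ∞ at the respective boundaries.  Two-sided
p-values use probability-mass ordering with a (1 + 1e−7) tie tolerance, the
dominant convention in exact-test implementations; r×2 tables use the
Freeman–Halton generalization by full enumeration, guarded at 10⁷ candidate
tables.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| z₀.₉₇₅ | 1.959964 | normal quantile in SE back-calculation; set 1.96 to match hand calculations |
| df_rule | k−2 | df of the PI t-quantile |
| level | 0.95 | exact-CI coverage |
| MIN_TRIALS | 3 | eligibility and PI-definedness threshold |
| tie tolerance | 1e−7 (relative) | probability-ordering ties in exact p-values |
| root tolerance | 1e−12 on log ψ | CMLE/MUE/CI solver |

## Synthetic corpus generator

`synthetic_data` emulates the corpus the pipeline expects: per review it
draws k, μ, τ² and within-study variances, simulates θᵢ ~ N(μ, τ²),
yᵢ ~ N(θᵢ, vᵢ), DL-fits the studies, and writes the fit into the record the
way a published review would (estimate + 95% CI on the reported scale, τ²
possibly withheld).  SR covariates act on the probability of PI reporting
through a logistic model.  Defaults describe a realistic reviews corpus:
121 SRs; effect-measure mix 64.5/19.0/9.1/7.4% (MD/SMD/RR/OR); τ² withheld
with probability 0.215; PROSPERO prevalence 0.51 with log-odds ln 3.3 on
reporting; Cochrane 0.05 / ln 0.5; Americas 0.16 / ln 0.17 and Asia-or-other
0.42 / −3 relative to Europe; publication year effect ln 0.85 per year;
baseline reporting rate 0.19 at the reference levels.  Quantities no corpus
publishes were fixed once at field-plausible values: k from a small-count
discrete distribution (mode 3–5, 12% at k = 2 to exercise the eligibility
filter), μ ~ N(0.2, 0.3), τ² ~ U(0, 0.15), vᵢ ~ U(0.01, 0.1).  One seeded
`numpy` Generator threads through all draws; a fixed spec + seed yields a
byte-identical corpus CSV.

What the generator does **not** emulate: publication bias and small-study
effects, non-normal random-effects distributions, rounding of reported CIs
to two digits, correlated covariates, or multiple meta-analyses per review.
Passing tests therefore establish internal correctness of the pipeline under
the normal random-effects model, not robustness of real extracted corpora to
those features.

## Numerical choices and degenerate inputs

- Exact integer weights until normalization; log-space pmfs; `logsumexp`
  throughout — no overflow for any table the enumeration guard admits.
- Root brackets on log ψ start at [−30, 30] and double on demand.
- DL τ² is truncated at 0 explicitly; with τ̂² = 0 the random-effects fit
  reduces exactly to the fixed-effect fit.
- Degenerate tables (an empty row/column, all outcomes identical) yield a
  flagged single-point support; estimation on them raises instead of
  returning a number.
- Missing values in corpus CSVs are empty cells or "NA"; validation errors
  are collected per row (field name + reason) and only `strict` mode raises.
- Forest plots draw the PI as a hatched rectangle on its own row beneath the
  summary diamond so the two interval types cannot be conflated; SVG output
  pins `svg.hashsalt` so renders are byte-reproducible.

## Design choices where the design was open

- The agreement analysis recomputes PIs even when a review reported one, so
  all 95-type cohorts are internally consistent; reported PIs still count for
  prevalence.
- Reviews whose result-significance field is "not reported" form their own
  level in the characteristics table and are excluded from the 2×2 exact
  contrast, mirroring how "not estimable" rows are handled.
- Continent collapses to Europe / Americas / Asia-or-other; mapping raw
  country strings to these levels is the caller's job.
- The printed odds ratios this package is validated against could in
  principle be conditional MLEs or median-unbiased estimates; we use CMLE for
  interior tables and MUE at boundaries, which reproduces all of them to the
  printed two decimals.  Exact-CI conventions differ more across software:
  our tail-inversion interval reproduces the reference values for the
  registration and Cochrane tables exactly, but for the Americas-vs-Europe
  table the published lower bound (0.04) differs from tail inversion (0.02) —
  a known convention gap (e.g. score-inverted or mid-p intervals), documented
  rather than special-cased.
- Plot regression tests compare two renders of the same input for byte
  identity rather than freezing a golden image, which would pin a matplotlib
  version rather than any scientific property.

## Known limitations

- The t_{k−2} prediction interval ignores the sampling error of τ̂²: its
  empirical coverage approaches 0.95 from below as k and I² grow.  The test
  suite measures ≈0.94 at k = 20 under substantial heterogeneity (I² ≈ 0.8,
  5000 replicates) and demonstrates under-coverage (< 0.93) at k = 5; at low
  I² the zero-truncation of τ̂² makes small-k coverage worse still.
  Hartung–Knapp-type PIs would mitigate this but are out of scope.
- Exact logistic regression is single-covariate only (no multi-covariate
  conditioning, no mid-p variants).
- The Freeman–Halton test enumerates; tables beyond the 10⁷-candidate guard
  need a Monte-Carlo approach not provided here.
- Simulation sizes in the test suite (2000 replicates for DL recovery, 5000
  for PI coverage, exhaustive 2×2 scans to n = 30) were chosen to make
  Monte-Carlo error small relative to the asserted tolerances.
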