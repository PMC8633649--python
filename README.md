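# metapi

Meta-epidemiological analysis of **prediction-interval reporting** in
random-effects meta-analyses: compute 95% prediction intervals (PIs) from the
summary statistics a published review reports, classify how often a
statistically significant 95% confidence interval (CI) is actually
corroborated by its PI, and test which review-level characteristics
(registration, review type, continent, publication year, result significance)
are associated with PI reporting — using **exact** conditional inference
throughout, because the contingency tables such corpora produce are small and
sparse.

The intended users are evidence-synthesis methodologists auditing a corpus of
systematic reviews, and meta-analysts who want a correct, tested PI
implementation for a single meta-analysis.

## The statistics at the core

For a random-effects meta-analysis of *k* trials with pooled estimate *M*
(on the log scale for ratio measures), standard error SE(*M*) and
between-study variance τ², the 95% prediction interval for the true effect of
a new trial drawn from the same population of trials is

```
M ± t_{k−2, 0.975} · sqrt(τ² + SE(M)²)
```

defined for k ≥ 3.  Because t ≥ z and τ² ≥ 0, the PI always contains the 95%
CI `M ± z_{0.975}·SE(M)`: a significant PI implies a significant CI, never
the converse.  SE(*M*) is back-calculated from the reported CI as
`(upper − lower) / (2·z_{0.975})` (log-transformed bounds for RR/OR).
τ² comes from the DerSimonian–Laird moment estimator
`max(0, (Q − (k−1))/C)`, with Q Cochran's heterogeneity statistic.

Covariate associations with PI reporting are estimated by **exact
conditional logistic regression**: for a 2×2 table the sufficient statistic
given all margins follows the noncentral hypergeometric distribution
`P_ψ(t) ∝ C(r₁,t)·C(r₂,c₁−t)·ψᵗ`; the conditional MLE solves `E_ψ[T] = t_obs`,
boundary tables (a zero cell) get the median-unbiased estimate
(`P_ψ(observed tail) = 0.5`), and CIs come from exact tail inversion.  For a
continuous covariate (e.g. publication year) the conditional distribution of
`T = Σ xᵢ` over event subsets is built by exact integer dynamic programming.
Fisher's exact test (probability-mass ordering; Freeman–Halton for r×2
tables) gives the p-values.

## Worked example

The classic illustration: a meta-analysis of bracket bond failures reported
OR 1.35 with 95% CI 0.99–1.83 — "verging on significance".

```python
import math
from metapi import back_calculate_se, wald_p, prediction_interval, AnalysisScaleSummary

se = back_calculate_se(0.99, 1.83, "OR")          # 0.15673 on the log scale
p = wald_p(math.log(1.35), se)                    # 0.056
s = AnalysisScaleSummary(M=math.log(1.35), se_M=se, tau2=0.045, k=6, measure="OR")
pi = prediction_interval(s)                        # (0.65, 2.81)
```

prints `SE(log OR) = 0.15673`, `two-sided Wald p = 0.056` and
`95% PI = (0.65, 2.81), significant = False`: although the CI only just
includes the null, the PI comfortably contains 1 — a future trial in a
similar setting may well show no effect, or one in the opposite direction.

Exact analysis of a 2×2 table from the shell (registered vs unregistered
reviews; counts not-reported/reported 53/6 and 45/17):

```
$ metapi exact --table 53,6,45,17
3.3048	1.1237	11.1358	0.0202	conditional_mle
```

i.e. OR 3.30, exact 95% CI (1.12, 11.14), Fisher p 0.020 — registered
reviews report prediction intervals substantially more often.

A full synthetic-corpus round trip:

```
$ metapi simulate --seed 5 --out corpus.csv --truth truth.csv
$ metapi run --input corpus.csv --out-dir results/
{"corroborated": 15.5, "both_nonsignificant": 44.0, "ci_sig_pi_not": 40.5}
```

`results/` then holds `per_record.csv` (input schema plus back-calculated SE,
PI bounds and agreement category), `table1.tsv` / `table2.tsv` (covariate
associations and frequency tables) and `agreement.json`.  The percentages
above say: among meta-analyses where a PI could be computed, only ~16% of
significant CIs were corroborated by the PI, and ~40% of significant CIs were
*not* — the phenomenon the pipeline is built to quantify.

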