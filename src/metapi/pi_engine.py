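"""Prediction intervals for random-effects meta-analyses.

Implements standard-error back-calculation from reported confidence
intervals, the t-based 95% prediction interval

    M +/- t_{k-2, 0.975} * sqrt(tau^2 + SE(M)^2)

(with k the number of trials, tau^2 the between-study variance and M the
pooled estimate on the analysis scale), two-sided Wald p-values, and the
classification of agreement between a meta-analysis' confidence interval and
its prediction interval.

Ratio measures (RR, OR) are handled entirely on the natural-log scale and
exponentiated only at the interval boundaries; mean differences (MD, SMD) use
the identity scale.  The prediction interval is defined for k >= 3 trials
(degrees of freedom k - 2 >= 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from scipy.stats import norm, t as t_dist

__all__ = [
    "Z975",
    "EffectMeasure",
    "AgreementCategory",
    "AnalysisScaleSummary",
    "IntervalResult",
    "AgreementRecord",
    "is_ratio_measure",
    "null_value_for",
    "back_calculate_se",
    "wald_p",
    "prediction_interval",
    "confidence_interval",
    "classify_agreement",
]

#: 97.5th percentile of the standard normal, to six decimals.  Using the full
#: quantile rather than the textbook 1.96 keeps back-calculation reproducible
#: in closed form; pass z=1.96 to reproduce hand-calculated literature values.
Z975 = 1.959964


class EffectMeasure(str, Enum):
    MD = "MD"
    SMD = "SMD"
    RR = "RR"
    OR = "OR"


class AgreementCategory(str, Enum):
    CORROBORATED_SIGNIFICANT = "corroborated_significant"
    BOTH_NONSIGNIFICANT = "both_nonsignificant"
    CI_SIG_PI_NOT = "ci_sig_pi_not"
    NOT_COMPUTABLE = "not_computable"


def is_ratio_measure(measure: EffectMeasure | str) -> bool:
    return EffectMeasure(measure) in (EffectMeasure.RR, EffectMeasure.OR)


def null_value_for(measure: EffectMeasure | str) -> float:
    """Null effect on the reported scale: 1 for ratio measures, 0 otherwise."""
    return 1.0 if is_ratio_measure(measure) else 0.0


@dataclass(frozen=True)
class AnalysisScaleSummary:
    """Pooled summary on the analysis scale (log scale for RR/OR).

    M: pooled estimate; se_M: its standard error; tau2: between-study
    variance; k: number of trials (>= 3 for a prediction interval).
    """

    M: float
    se_M: float
    tau2: float
    k: int
    measure: EffectMeasure

    def __post_init__(self) -> None:
        if self.se_M <= 0:
            raise ValueError("se_M must be positive")
        if self.tau2 < 0:
            raise ValueError("tau2 must be nonnegative")
        if self.k < 3:
            raise ValueError("prediction interval undefined below three trials")
        object.__setattr__(self, "measure", EffectMeasure(self.measure))


@dataclass(frozen=True)
class IntervalResult:
    """A CI or PI on the reported scale with its significance verdict."""

    lower: float
    upper: float
    kind: str  # "CI95" or "PI95"
    null_value: float
    significant: bool

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("interval bounds out of order")
        excludes_null = not (self.lower <= self.null_value <= self.upper)
        if self.significant != excludes_null:
            raise ValueError("significance flag inconsistent with interval vs null")


@dataclass(frozen=True)
class AgreementRecord:
    sr_id: str
    category: AgreementCategory


def _interval(lower: float, upper: float, kind: str, null_value: float) -> IntervalResult:
    significant = not (lower <= null_value <= upper)
    return IntervalResult(lower, upper, kind, null_value, significant)


def back_calculate_se(
    ci_lower: float, ci_upper: float, measure: EffectMeasure | str, z: float = Z975
) -> float:
    """Standard error of the pooled estimate from its reported 95% CI.

    MD/SMD: (upper - lower) / (2 z); RR/OR: (ln upper - ln lower) / (2 z),
    i.e. the SE on the log scale.
    """
    measure = EffectMeasure(measure)
    if is_ratio_measure(measure):
        if ci_lower <= 0 or ci_upper <= 0:
            raise ValueError("ratio CI must be positive")
        lo, hi = math.log(ci_lower), math.log(ci_upper)
    else:
        lo, hi = ci_lower, ci_upper
    if not lo < hi:
        raise ValueError("ci_lower must be strictly below ci_upper")
    return (hi - lo) / (2.0 * z)


def wald_p(M: float, se_M: float) -> float:
    """Two-sided normal-theory p-value for M against 0 on the analysis scale."""
    if se_M <= 0:
        raise ValueError("se_M must be positive")
    return float(2.0 * norm.sf(abs(M) / se_M))


def prediction_interval(
    summary: AnalysisScaleSummary, df_rule: str = "k-2"
) -> IntervalResult:
    """95% prediction interval for the true effect of a new study.

    Half-width t_{df, 0.975} * sqrt(tau2 + se_M^2) around M on the analysis
    scale, exponentiated back to the reported scale for ratio measures.
    ``df_rule`` defaults to "k-2"; "k-1" is exposed for sensitivity analysis.
    """
    if df_rule == "k-2":
        df = summary.k - 2
    elif df_rule == "k-1":
        df = summary.k - 1
    else:
        raise ValueError("df_rule must be 'k-2' or 'k-1'")
    tq = float(t_dist.ppf(0.975, df))
    h = tq * math.sqrt(summary.tau2 + summary.se_M**2)
    lo, hi = summary.M - h, summary.M + h
    if is_ratio_measure(summary.measure):
        lo, hi = math.exp(lo), math.exp(hi)
    return _interval(lo, hi, "PI95", null_value_for(summary.measure))


def confidence_interval(summary: AnalysisScaleSummary, z: float = Z975) -> IntervalResult:
    """Recomputed 95% CI, M +/- z*se_M, back-transformed for ratio measures."""
    lo, hi = summary.M - z * summary.se_M, summary.M + z * summary.se_M
    if is_ratio_measure(summary.measure):
        lo, hi = math.exp(lo), math.exp(hi)
    return _interval(lo, hi, "CI95", null_value_for(summary.measure))


def reported_ci_interval(
    ci_lower: float, ci_upper: float, measure: EffectMeasure | str
) -> IntervalResult:
    """Wrap an author-reported 95% CI with its significance verdict."""
    return _interval(ci_lower, ci_upper, "CI95", null_value_for(measure))


def classify_agreement(
    sr_id: str, ci: IntervalResult, pi: Optional[IntervalResult]
) -> AgreementRecord:
    """CI/PI corroboration category for one meta-analysis.

    A missing PI (tau^2 unreported or k < 3) is not computable.  A PI can
    never be significant while the CI is not — the PI contains the CI by
    construction — so that configuration raises, flagging corrupted input.
    """
    if pi is None:
        return AgreementRecord(sr_id, AgreementCategory.NOT_COMPUTABLE)
    if ci.null_value != pi.null_value:
        raise ValueError("CI and PI must share a null value")
    if pi.significant and not ci.significant:
        raise ValueError(
            "PI significant while CI non-significant violates interval nesting; "
            "input is inconsistent"
        )
    if ci.significant and pi.significant:
        cat = AgreementCategory.CORROBORATED_SIGNIFICANT
    elif ci.significant:
        cat = AgreementCategory.CI_SIG_PI_NOT
    else:
        cat = AgreementCategory.BOTH_NONSIGNIFICANT
    return AgreementRecord(sr_id, cat)
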