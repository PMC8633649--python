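"""Random-effects meta-analysis from study-level effects and variances.

Inverse-variance pooling with the DerSimonian–Laird moment estimator of the
between-study variance tau^2, plus Cochran's Q and I^2.  This is the
historical default estimator of the software era the analysed corpora span;
REML and small-sample corrections are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StudySet", "REFit", "dl_fit", "fixed_fit"]


@dataclass(frozen=True)
class StudySet:
    """Per-study effect estimates y_i and within-study variances v_i."""

    effects: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.effects, dtype=float)
        v = np.asarray(self.variances, dtype=float)
        if y.ndim != 1 or v.ndim != 1 or y.shape != v.shape:
            raise ValueError("effects and variances must be equal-length 1-d arrays")
        if y.size < 1:
            raise ValueError("need at least one study")
        if not np.all(v > 0):
            raise ValueError("all within-study variances must be positive")
        object.__setattr__(self, "effects", y)
        object.__setattr__(self, "variances", v)

    @property
    def k(self) -> int:
        return int(self.effects.size)


@dataclass(frozen=True)
class REFit:
    """Random-effects pooled summary.

    M is the pooled estimate, se_M its standard error, tau2_DL the truncated
    DerSimonian–Laird between-study variance, Q Cochran's heterogeneity
    statistic and I2 = max(0, (Q - (k-1))/Q).
    """

    M: float
    se_M: float
    tau2_DL: float
    Q: float
    I2: float
    k: int


def fixed_fit(studies: StudySet) -> tuple[float, float]:
    """Fixed-effect (common-effect) inverse-variance pooled estimate and SE."""
    w = 1.0 / studies.variances
    m = float(np.sum(w * studies.effects) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    return m, se


def dl_fit(studies: StudySet) -> REFit:
    """DerSimonian–Laird random-effects fit.

    Q is the inverse-variance weighted sum of squared deviations from the
    fixed-effect mean; tau2_DL = max(0, (Q - (k-1)) / C) with
    C = sum(w) - sum(w^2)/sum(w); the pooled estimate then uses weights
    1/(v_i + tau2_DL).  Negative moment estimates of tau^2 are truncated at
    zero and never propagate.
    """
    k = studies.k
    if k < 2:
        raise ValueError("Q and tau^2 require at least two studies")
    y, v = studies.effects, studies.variances
    w = 1.0 / v
    sw = np.sum(w)
    y_fixed = np.sum(w * y) / sw
    Q = float(np.sum(w * (y - y_fixed) ** 2))
    C = float(sw - np.sum(w**2) / sw)
    tau2 = max(0.0, (Q - (k - 1)) / C) if C > 0 else 0.0
    w_star = 1.0 / (v + tau2)
    M = float(np.sum(w_star * y) / np.sum(w_star))
    se_M = float(1.0 / np.sqrt(np.sum(w_star)))
    I2 = max(0.0, (Q - (k - 1)) / Q) if Q > 0 else 0.0
    return REFit(M=M, se_M=se_M, tau2_DL=tau2, Q=Q, I2=I2, k=k)
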