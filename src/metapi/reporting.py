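"""Pipeline orchestration and report generation.

Wires a validated corpus of extracted meta-analyses through eligibility
filtering, standard-error back-calculation, prediction-interval computation,
CI/PI agreement classification, and the covariate association analyses
(exact conditional odds ratios and Fisher exact tests), producing:

* an agreement summary (how often a significant 95% CI is corroborated by
  the 95% prediction interval);
* a study-characteristics table with exact odds ratios, exact CIs, and
  Fisher p-values per covariate (the "Table 1" analog);
* an effect-measure / tau^2-reporting frequency table (the "Table 2" analog);
* a per-record CSV with the computed SE, PI bounds and agreement category
  appended to the input schema;
* descriptive statistics (author-count median and IQR, reporting prevalence);
* a forest plot in which the prediction interval is drawn as a rectangle on
  its own row beneath the summary diamond, keeping it visually distinct from
  the confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import pi_engine
from .exact_inference import (
    Table2x2,
    exact_logistic_2x2,
    exact_logistic_continuous,
    fisher_exact_rxc,
)
from .pi_engine import (
    AgreementCategory,
    AnalysisScaleSummary,
    IntervalResult,
    classify_agreement,
    is_ratio_measure,
    prediction_interval,
    reported_ci_interval,
)
from .re_meta import REFit, StudySet
from .records import MetaRecord, filter_eligible, records_to_frame

__all__ = ["PipelineConfig", "AgreementSummary", "PipelineResult", "run_pipeline", "render_forest"]


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs for the analysis conventions.

    z: normal quantile used in SE back-calculation (1.959964 by default;
    1.96 reproduces hand calculations).  df_rule: degrees of freedom of the
    prediction-interval t quantile ("k-2" or "k-1").  use_reported_ci:
    whether the agreement verdicts use the authors' reported CI (default) or
    a CI recomputed from the back-calculated SE.
    """

    z: float = pi_engine.Z975
    df_rule: str = "k-2"
    use_reported_ci: bool = True


@dataclass(frozen=True)
class AgreementSummary:
    """Counts of CI/PI corroboration categories over the computable subset."""

    n_total: int
    n_corroborated: int
    n_both_nonsig: int
    n_ci_sig_pi_not: int

    def __post_init__(self) -> None:
        if self.n_corroborated + self.n_both_nonsig + self.n_ci_sig_pi_not != self.n_total:
            raise ValueError("agreement counts must partition the computable subset")

    def percentages(self) -> dict[str, float]:
        if self.n_total == 0:
            return {"corroborated": 0.0, "both_nonsignificant": 0.0, "ci_sig_pi_not": 0.0}
        return {
            "corroborated": 100.0 * self.n_corroborated / self.n_total,
            "both_nonsignificant": 100.0 * self.n_both_nonsig / self.n_total,
            "ci_sig_pi_not": 100.0 * self.n_ci_sig_pi_not / self.n_total,
        }


@dataclass
class PipelineResult:
    agreement: AgreementSummary
    table1: pd.DataFrame
    table2: pd.DataFrame
    per_record: pd.DataFrame
    descriptives: dict
    exclusions: list = field(default_factory=list)


def _summarize_record(
    r: MetaRecord, config: PipelineConfig
) -> tuple[Optional[AnalysisScaleSummary], Optional[str]]:
    """Build the analysis-scale summary for one record, or a reason it cannot be."""
    if r.tau2 is None:
        return None, "tau2 not reported"
    if r.ci_lower is None or r.ci_upper is None or r.pooled_estimate is None:
        return None, "estimate or CI not reported"
    if r.k_trials < 3:
        return None, "fewer than three trials"
    se = pi_engine.back_calculate_se(r.ci_lower, r.ci_upper, r.effect_measure, z=config.z)
    M = (
        math.log(r.pooled_estimate)
        if is_ratio_measure(r.effect_measure)
        else r.pooled_estimate
    )
    return AnalysisScaleSummary(M=M, se_M=se, tau2=r.tau2, k=r.k_trials, measure=r.effect_measure), None


def _fmt_or(fit) -> tuple[str, str, str]:
    hi = "inf" if math.isinf(fit.ci_upper) else f"{fit.ci_upper:.2f}"
    return f"{fit.or_estimate:.2f}", f"{fit.ci_lower:.2f}, {hi}", f"{fit.p_value:.3f}"


def _table1(records: Sequence[MetaRecord]) -> pd.DataFrame:
    """Covariate associations with prediction-interval reporting.

    Binary covariates get a 2x2 exact analysis (reference level first row);
    continent additionally gets a Freeman–Halton exact p over all levels and
    a 2x2 Americas-vs-Europe contrast; year enters as a continuous covariate
    through exact conditional logistic regression.  Levels with no events
    at all are reported as not estimable, as an exact CI for them is
    unbounded below.
    """
    rows = []

    def counts(pred) -> tuple[int, int]:
        sel = [r for r in records if pred(r)]
        rep = sum(r.pi_reported for r in sel)
        return len(sel) - rep, rep

    def add_2x2(variable: str, ref_label: str, idx_label: str, ref, idx):
        a, b = counts(ref)
        c, d = counts(idx)
        rows.append({"variable": variable, "level": ref_label, "not_reported": a,
                     "reported": b, "odds_ratio": "Reference", "ci_95": "", "p_value": ""})
        row = {"variable": variable, "level": idx_label, "not_reported": c, "reported": d}
        if (b == 0 and d == 0) or (a == 0 and c == 0) or (c == 0 and d == 0):
            row.update({"odds_ratio": "Not estimable", "ci_95": "Not estimable", "p_value": ""})
        else:
            fit = exact_logistic_2x2(Table2x2(a, b, c, d))
            orr, ci, p = _fmt_or(fit)
            row.update({"odds_ratio": orr, "ci_95": ci, "p_value": p})
        rows.append(row)

    # year, continuous
    years = [r.year for r in records]
    outcomes = [r.pi_reported for r in records]
    if 0 < sum(outcomes) < len(outcomes) and len(set(years)) > 1:
        fit = exact_logistic_continuous(years, outcomes)
        orr, ci, p = _fmt_or(fit)
    else:
        orr = ci = p = "Not estimable"
    rows.append({"variable": "year (per year)", "level": "continuous",
                 "not_reported": sum(not o for o in outcomes), "reported": sum(outcomes),
                 "odds_ratio": orr, "ci_95": ci, "p_value": p})

    # continent: Europe reference, Americas contrast, Asia/other listed
    add_2x2("continent", "Europe", "Americas",
            lambda r: r.continent.value == "Europe", lambda r: r.continent.value == "Americas")
    asia_nr, asia_r = counts(lambda r: r.continent.value == "AsiaOther")
    rows.append({"variable": "continent", "level": "AsiaOther", "not_reported": asia_nr,
                 "reported": asia_r,
                 "odds_ratio": "Not estimable" if asia_r == 0 else "",
                 "ci_95": "Not estimable" if asia_r == 0 else "", "p_value": ""})
    cont_table = [
        list(counts(lambda r, lv=lv: r.continent.value == lv))
        for lv in ("Europe", "Americas", "AsiaOther")
    ]
    cont_table = [row for row in cont_table if sum(row) > 0]
    if len(cont_table) >= 2:
        p_fh = fisher_exact_rxc(cont_table)
        rows.append({"variable": "continent", "level": "all levels (Freeman-Halton)",
                     "not_reported": sum(r[0] for r in cont_table),
                     "reported": sum(r[1] for r in cont_table),
                     "odds_ratio": "", "ci_95": "",
                     "p_value": "<0.001" if p_fh < 0.001 else f"{p_fh:.3f}"})

    add_2x2("prospero", "no", "yes", lambda r: not r.prospero, lambda r: r.prospero)
    add_2x2("cochrane", "non-Cochrane", "Cochrane",
            lambda r: not r.cochrane, lambda r: r.cochrane)
    # reported significance: keep "not_reported" as its own level, excluded
    # from the 2x2 exact contrast
    add_2x2("reported_significant", "no", "yes",
            lambda r: r.reported_significant.value == "no",
            lambda r: r.reported_significant.value == "yes")
    nr_nr, nr_r = counts(lambda r: r.reported_significant.value == "not_reported")
    if nr_nr + nr_r:
        rows.append({"variable": "reported_significant", "level": "not_reported",
                     "not_reported": nr_nr, "reported": nr_r,
                     "odds_ratio": "Not estimable", "ci_95": "Not estimable", "p_value": ""})
    return pd.DataFrame(rows)


def _table2(records: Sequence[MetaRecord]) -> pd.DataFrame:
    n = len(records)
    rows = []
    for m in ("MD", "SMD", "RR", "OR"):
        cnt = sum(r.effect_measure.value == m for r in records)
        rows.append({"variable": "effect_measure", "level": m, "n": cnt,
                     "percent": round(100.0 * cnt / n, 1) if n else 0.0})
    rep = sum(r.tau2 is not None for r in records)
    for label, cnt in (("reported", rep), ("not_reported", n - rep)):
        rows.append({"variable": "tau2", "level": label, "n": cnt,
                     "percent": round(100.0 * cnt / n, 1) if n else 0.0})
    return pd.DataFrame(rows)


def run_pipeline(
    records: Sequence[MetaRecord], config: Optional[PipelineConfig] = None
) -> PipelineResult:
    """Run the full meta-epidemiological analysis over a validated corpus."""
    config = config or PipelineConfig()
    eligible, excluded = filter_eligible(records)
    exclusions = [(r.sr_id, reason) for r, reason in excluded]

    per_rows = []
    n_corr = n_both = n_disc = 0
    n_computable = 0
    for r in eligible:
        summary, reason = _summarize_record(r, config)
        row = {"sr_id": r.sr_id, "se_backcalc": "", "pi_lower": "", "pi_upper": "",
               "ci_significant": "", "pi_significant": "", "agreement": ""}
        if summary is None:
            row["agreement"] = AgreementCategory.NOT_COMPUTABLE.value
            exclusions.append((r.sr_id, f"not computable: {reason}"))
            per_rows.append(row)
            continue
        if config.use_reported_ci:
            ci = reported_ci_interval(r.ci_lower, r.ci_upper, r.effect_measure)
        else:
            ci = pi_engine.confidence_interval(summary, z=config.z)
        pi = prediction_interval(summary, df_rule=config.df_rule)
        rec = classify_agreement(r.sr_id, ci, pi)
        n_computable += 1
        if rec.category is AgreementCategory.CORROBORATED_SIGNIFICANT:
            n_corr += 1
        elif rec.category is AgreementCategory.BOTH_NONSIGNIFICANT:
            n_both += 1
        else:
            n_disc += 1
        row.update({
            "se_backcalc": f"{summary.se_M:.6g}",
            "pi_lower": f"{pi.lower:.6g}", "pi_upper": f"{pi.upper:.6g}",
            "ci_significant": str(ci.significant).lower(),
            "pi_significant": str(pi.significant).lower(),
            "agreement": rec.category.value,
        })
        per_rows.append(row)

    agreement = AgreementSummary(
        n_total=n_computable, n_corroborated=n_corr,
        n_both_nonsig=n_both, n_ci_sig_pi_not=n_disc,
    )

    base = records_to_frame(eligible)
    computed_cols = ["sr_id", "se_backcalc", "pi_lower", "pi_upper",
                     "ci_significant", "pi_significant", "agreement"]
    computed = pd.DataFrame(per_rows, columns=computed_cols)
    per_record = base.merge(computed, on="sr_id", how="left")

    n_authors = np.array([r.n_authors for r in eligible])
    n_rep = sum(r.pi_reported for r in eligible)
    descriptives = {
        "n_records": len(records),
        "n_eligible": len(eligible),
        "n_computable": n_computable,
        "pi_reported_n": int(n_rep),
        "pi_reported_percent": round(100.0 * n_rep / len(eligible), 1) if eligible else 0.0,
        "authors_median": float(np.median(n_authors)) if eligible else float("nan"),
        "authors_iqr": (
            [float(np.percentile(n_authors, 25)), float(np.percentile(n_authors, 75))]
            if len(eligible) else [float("nan")] * 2
        ),
    }

    table1 = _table1(eligible) if eligible else pd.DataFrame()
    table2 = _table2(eligible) if eligible else pd.DataFrame()
    return PipelineResult(agreement, table1, table2, per_record, descriptives, exclusions)


def render_forest(
    studies: StudySet,
    fit: REFit,
    pi: IntervalResult,
    out: str | Path,
    labels: Optional[Sequence[str]] = None,
    z: float = pi_engine.Z975,
) -> Path:
    """Forest plot with the prediction interval as a separate-row rectangle.

    Per-study markers with CI whiskers, the pooled estimate as a diamond, and
    the 95% prediction interval drawn as a rectangle on its own bottom row so
    it cannot be mistaken for the confidence-interval diamond.  Layout is
    deterministic for fixed inputs.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    # fixed hash salt so SVG element ids (and hence bytes) are reproducible
    matplotlib.rcParams["svg.hashsalt"] = "metapi"
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon, Rectangle

    k = studies.k
    labels = list(labels) if labels is not None else [f"Study {i + 1}" for i in range(k)]
    fig, ax = plt.subplots(figsize=(6.5, 0.45 * (k + 3) + 1.2))
    ys = np.arange(k, 0, -1)
    se_i = np.sqrt(studies.variances)
    ax.errorbar(
        studies.effects, ys, xerr=z * se_i, fmt="s", color="black",
        markersize=4, capsize=2, lw=1,
    )
    for yv, lab in zip(ys, labels):
        ax.text(-0.02, yv, lab, transform=ax.get_yaxis_transform(),
                ha="right", va="center", fontsize=8)

    d_lo, d_hi = fit.M - z * fit.se_M, fit.M + z * fit.se_M
    y_sum = 0.0
    ax.add_patch(Polygon(
        [(d_lo, y_sum), (fit.M, y_sum + 0.3), (d_hi, y_sum), (fit.M, y_sum - 0.3)],
        closed=True, facecolor="0.3", edgecolor="black",
    ))
    ax.text(-0.02, y_sum, "Pooled (95% CI)", transform=ax.get_yaxis_transform(),
            ha="right", va="center", fontsize=8)

    # the plot lives on the analysis scale; a ratio-scale PI (null at 1) is
    # mapped back to the log scale before drawing
    pi_lo, pi_hi = pi.lower, pi.upper
    if pi.null_value == 1.0:
        pi_lo, pi_hi = math.log(pi_lo), math.log(pi_hi)
    y_pi = -1.0
    ax.add_patch(Rectangle(
        (pi_lo, y_pi - 0.18), pi_hi - pi_lo, 0.36,
        facecolor="0.75", edgecolor="black", hatch="//",
    ))
    ax.text(-0.02, y_pi, "95% prediction interval", transform=ax.get_yaxis_transform(),
            ha="right", va="center", fontsize=8)

    ax.axvline(0.0, color="gray", lw=0.8, ls="--")
    ax.set_ylim(y_pi - 0.8, k + 0.8)
    ax.set_yticks([])
    ax.set_xlabel("Effect size")
    fig.subplots_adjust(left=0.28)
    out = Path(out)
    fig.savefig(out, format=out.suffix.lstrip(".") or "svg", metadata={"Date": None})
    plt.close(fig)
    return out
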