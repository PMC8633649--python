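"""Data model and CSV I/O for an extracted meta-analysis corpus.

One row per systematic review (SR): the characteristics a reviewer extracts
from a published random-effects meta-analysis — publication year, authorship,
registration, review type, whether a prediction interval was reported and
discussed, the number of trials, the effect measure, the pooled estimate with
its 95% CI, and tau^2 where given.

Missing values are encoded as an empty cell or "NA" (both accepted on read);
a missing tau^2 stays missing and is never imputed as zero.  Validation
failures are collected per row with the offending field, so a single bad row
does not abort a corpus load unless strict mode is requested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .pi_engine import EffectMeasure

__all__ = [
    "Continent",
    "PiDiscussed",
    "ReportedSignificant",
    "MetaRecord",
    "RowError",
    "CorpusValidationError",
    "read_corpus",
    "write_corpus",
    "filter_eligible",
    "MIN_TRIALS",
]

#: prediction intervals require at least this many trials (df = k - 2 >= 1)
MIN_TRIALS = 3


class Continent(str, Enum):
    EUROPE = "Europe"
    AMERICAS = "Americas"
    ASIA_OTHER = "AsiaOther"


class PiDiscussed(str, Enum):
    NO = "no"
    YES = "yes"
    NOT_APPLICABLE = "not_applicable"


class ReportedSignificant(str, Enum):
    NO = "no"
    YES = "yes"
    NOT_REPORTED = "not_reported"


@dataclass(frozen=True)
class MetaRecord:
    """One extracted meta-analysis summary and its SR-level covariates."""

    sr_id: str
    year: int
    n_authors: int
    continent: Continent
    prospero: bool
    cochrane: bool
    pi_reported: bool
    pi_discussed: PiDiscussed
    k_trials: int
    effect_measure: EffectMeasure
    pooled_estimate: Optional[float]
    ci_lower: Optional[float]
    ci_upper: Optional[float]
    tau2: Optional[float]
    reported_significant: ReportedSignificant

    def __post_init__(self) -> None:
        object.__setattr__(self, "continent", Continent(self.continent))
        object.__setattr__(self, "pi_discussed", PiDiscussed(self.pi_discussed))
        object.__setattr__(self, "effect_measure", EffectMeasure(self.effect_measure))
        object.__setattr__(
            self, "reported_significant", ReportedSignificant(self.reported_significant)
        )
        if self.n_authors < 1:
            raise ValueError("n_authors must be positive")
        if self.k_trials < 1:
            raise ValueError("k_trials must be at least 1")
        if self.tau2 is not None and self.tau2 < 0:
            raise ValueError("tau2 must be nonnegative when present")
        lo, hi = self.ci_lower, self.ci_upper
        if lo is not None and hi is not None:
            if not lo < hi:
                raise ValueError("ci_lower < ci_upper violated")
            est = self.pooled_estimate
            if est is not None and not (lo <= est <= hi):
                raise ValueError("pooled_estimate outside its confidence interval")
        if self.effect_measure in (EffectMeasure.RR, EffectMeasure.OR):
            for name in ("pooled_estimate", "ci_lower", "ci_upper"):
                v = getattr(self, name)
                if v is not None and v <= 0:
                    raise ValueError(f"{name} must be positive for a ratio measure")

    @property
    def recomputable(self) -> bool:
        """Whether a prediction interval can be recomputed for this record."""
        return (
            self.tau2 is not None
            and self.ci_lower is not None
            and self.ci_upper is not None
            and self.pooled_estimate is not None
            and self.k_trials >= MIN_TRIALS
        )


@dataclass(frozen=True)
class RowError:
    row: int  # 1-based data-row number (excluding the header)
    field: str
    message: str

    def __str__(self) -> str:
        return f"row {self.row}, field {self.field!r}: {self.message}"


class CorpusValidationError(ValueError):
    def __init__(self, errors: Sequence[RowError]):
        self.errors = list(errors)
        super().__init__(
            f"{len(self.errors)} invalid row(s): " + "; ".join(map(str, self.errors[:5]))
        )


_FIELDS = [f.name for f in fields(MetaRecord)]
_MISSING_TOKENS = {"", "na", "nan", "none"}


def _is_missing(cell: object) -> bool:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return True
    return str(cell).strip().lower() in _MISSING_TOKENS


def _parse_bool(cell: str) -> bool:
    s = str(cell).strip().lower()
    if s in {"true", "yes", "1"}:
        return True
    if s in {"false", "no", "0"}:
        return False
    raise ValueError(f"expected a boolean (true/false/yes/no/1/0), got {cell!r}")


def _parse_enum(cell: str, enum_cls) -> object:
    try:
        return enum_cls(str(cell).strip())
    except ValueError:
        allowed = ", ".join(e.value for e in enum_cls)
        raise ValueError(f"unknown label {cell!r}; allowed: {allowed}") from None


def _parse_row(row: pd.Series) -> MetaRecord:
    def num(name, kind=float, optional=False):
        cell = row[name]
        if _is_missing(cell):
            if optional:
                return None
            raise ValueError(f"missing required value in field {name!r}")
        try:
            return kind(str(cell).strip())
        except (TypeError, ValueError):
            raise ValueError(f"unparseable numeric cell {cell!r} in field {name!r}") from None

    return MetaRecord(
        sr_id=str(row["sr_id"]).strip(),
        year=num("year", int),
        n_authors=num("n_authors", int),
        continent=_parse_enum(row["continent"], Continent),
        prospero=_parse_bool(row["prospero"]),
        cochrane=_parse_bool(row["cochrane"]),
        pi_reported=_parse_bool(row["pi_reported"]),
        pi_discussed=_parse_enum(row["pi_discussed"], PiDiscussed),
        k_trials=num("k_trials", int),
        effect_measure=_parse_enum(row["effect_measure"], EffectMeasure),
        pooled_estimate=num("pooled_estimate", optional=True),
        ci_lower=num("ci_lower", optional=True),
        ci_upper=num("ci_upper", optional=True),
        tau2=num("tau2", optional=True),
        reported_significant=_parse_enum(row["reported_significant"], ReportedSignificant),
    )


def read_corpus(
    path: str | Path, strict: bool = False
) -> tuple[list[MetaRecord], list[RowError]]:
    """Read a corpus CSV, validating every row.

    Returns the parsed records and a list of per-row validation errors
    (1-based data-row numbers).  With ``strict=True`` any error raises
    :class:`CorpusValidationError` instead.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in _FIELDS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"corpus is missing required columns: {missing_cols}")
    records: list[MetaRecord] = []
    errors: list[RowError] = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            records.append(_parse_row(row))
        except ValueError as exc:
            msg = str(exc)
            fld = next((f for f in _FIELDS if f"'{f}'" in msg or f in msg.split()), "row")
            errors.append(RowError(i, fld, msg))
    if strict and errors:
        raise CorpusValidationError(errors)
    return records, errors


def _cell(v: object) -> str:
    if v is None:
        return ""
    if isinstance(v, Enum):
        return v.value
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def records_to_frame(records: Sequence[MetaRecord]) -> pd.DataFrame:
    rows = [{f: _cell(getattr(r, f)) for f in _FIELDS} for r in records]
    return pd.DataFrame(rows, columns=_FIELDS)


def write_corpus(records: Sequence[MetaRecord], path: str | Path) -> None:
    """Write records to CSV in the canonical schema (missing values as empty cells)."""
    records_to_frame(records).to_csv(path, index=False)


def filter_eligible(
    records: Sequence[MetaRecord],
) -> tuple[list[MetaRecord], list[tuple[MetaRecord, str]]]:
    """Partition records by the minimum-trials eligibility rule.

    A meta-analysis enters the analysis set only with at least three trials;
    every input record lands in exactly one of the two outputs.
    """
    eligible: list[MetaRecord] = []
    excluded: list[tuple[MetaRecord, str]] = []
    for r in records:
        if r.k_trials >= MIN_TRIALS:
            eligible.append(r)
        else:
            excluded.append((r, "fewer than three trials"))
    return eligible, excluded
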