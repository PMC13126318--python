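"""Chart-review audit structures and data-quality summaries.

Audits are kept in long format (one row per patient encounter per variable)
with a reviewed value filled in by the auditor.  Every reviewed data point
gets exactly one of five mutually exclusive findings: for values that were
*non-missing* in the extraction — ``extracted_correct``,
``extracted_incorrect``, or ``extracted_not_found`` (the auditor could not
locate the value in the chart at all); for values that were *missing* —
``aux_found`` (auxiliary information located) or ``aux_not_found``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FINDINGS",
    "NOT_FOUND",
    "AuditEntry",
    "Proportion",
    "QualitySummary",
    "to_long",
    "to_wide",
    "classify_finding",
    "classify_entries",
    "quality_summary",
    "component_quality",
    "fleiss_kappa",
]

FINDINGS = (
    "extracted_correct",
    "extracted_incorrect",
    "extracted_not_found",
    "aux_found",
    "aux_not_found",
)

#: Sentinel the auditor records when an extracted value cannot be located.
NOT_FOUND = "not_found"

_NONMISSING_FINDINGS = frozenset(FINDINGS[:3])
_MISSING_FINDINGS = frozenset(FINDINGS[3:])


def _is_missing(x: object) -> bool:
    if x is None:
        return True
    if isinstance(x, float) and math.isnan(x):
        return True
    if isinstance(x, str) and not x.strip():
        return True
    return False


@dataclass
class AuditEntry:
    """One reviewed data point."""

    patient_id: object
    encounter_id: object
    variable: str
    extracted_value: float | None = None
    reviewed_value: object = None
    finding: str | None = None
    notes: str = ""
    variable_class: str = ""        # e.g. "labs" / "vitals"

    def __post_init__(self) -> None:
        if self.finding is not None:
            self.validate_finding()

    def validate_finding(self) -> None:
        if self.finding not in FINDINGS:
            raise ValueError(f"unknown finding {self.finding!r}")
        extracted_missing = _is_missing(self.extracted_value)
        if extracted_missing and self.finding in _NONMISSING_FINDINGS:
            raise ValueError(
                f"finding {self.finding!r} requires a non-missing extracted "
                "value")
        if not extracted_missing and self.finding in _MISSING_FINDINGS:
            raise ValueError(
                f"finding {self.finding!r} requires a missing extracted value")


def to_long(wide: pd.DataFrame,
            id_cols: tuple[str, str] = ("patient_id", "encounter_id"),
            variable_classes: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Wide (one row per encounter) to long (one row per encounter per
    variable), with empty reviewed-value and finding columns for auditors.

    Raises
    ------
    ValueError
        On duplicate (patient, encounter) rows — they would create duplicate
        (patient, encounter, variable) entries.
    """
    for col in id_cols:
        if col not in wide.columns:
            raise ValueError(f"missing id column {col!r}")
    if wide.duplicated(subset=list(id_cols)).any():
        raise ValueError("duplicate (patient, encounter) rows in wide table")
    value_cols = [c for c in wide.columns if c not in id_cols]
    long = wide.melt(id_vars=list(id_cols), value_vars=value_cols,
                     var_name="variable", value_name="extracted_value")
    long["reviewed_value"] = pd.NA
    long["finding"] = pd.NA
    long["notes"] = ""
    classes = variable_classes or {}
    long["variable_class"] = long["variable"].map(lambda v: classes.get(v, ""))
    return long.sort_values(list(id_cols) + ["variable"]).reset_index(drop=True)


def to_wide(long: pd.DataFrame,
            id_cols: tuple[str, str] = ("patient_id", "encounter_id")
            ) -> pd.DataFrame:
    """Inverse of :func:`to_long` (drops review columns)."""
    wide = long.pivot(index=list(id_cols), columns="variable",
                      values="extracted_value").reset_index()
    wide.columns.name = None
    return wide


def classify_finding(extracted_value: object, reviewed_value: object,
                     tol: float = 0.0) -> str:
    """Assign the audit finding for one data point.

    For a non-missing extracted value the reviewed value is either the value
    seen in the chart (compared within ``tol``; default exact, so a
    transposed 5.6 vs 6.5 registers as incorrect) or the ``NOT_FOUND``
    sentinel.  For a missing extracted value the reviewed value is the
    auxiliary information found (any non-empty content) or empty.
    """
    if _is_missing(extracted_value):
        if isinstance(reviewed_value, str) and \
                reviewed_value.strip() == NOT_FOUND:
            raise ValueError(
                "'not found' review is inconsistent with a missing "
                "extracted value")
        return "aux_found" if not _is_missing(reviewed_value) else "aux_not_found"
    if _is_missing(reviewed_value):
        raise ValueError("non-missing extracted value needs a reviewed value "
                         f"or the {NOT_FOUND!r} sentinel")
    if isinstance(reviewed_value, str):
        if reviewed_value.strip() == NOT_FOUND:
            return "extracted_not_found"
        reviewed_value = float(reviewed_value)
    if abs(float(extracted_value) - float(reviewed_value)) <= tol:
        return "extracted_correct"
    return "extracted_incorrect"


def classify_entries(long: pd.DataFrame, tol: float = 0.0) -> pd.DataFrame:
    """Fill the ``finding`` column of a reviewed long-format table."""
    out = long.copy()
    out["finding"] = [
        classify_finding(e, r, tol)
        for e, r in zip(out["extracted_value"], out["reviewed_value"])
    ]
    return out


@dataclass(frozen=True)
class Proportion:
    """A proportion with its explicit numerator and denominator; ``value``
    is ``None`` when the denominator is empty (undefined, never 0/0)."""

    numerator: int
    denominator: int

    @property
    def value(self) -> float | None:
        if self.denominator == 0:
            return None
        return self.numerator / self.denominator

    @property
    def percent(self) -> float | None:
        v = self.value
        return None if v is None else 100.0 * v


@dataclass
class QualitySummary:
    """Audit-quality metrics with explicit counts."""

    finding_counts: dict = field(default_factory=dict)
    finding_counts_by_class: dict = field(default_factory=dict)
    recovery: Proportion = Proportion(0, 0)
    recovery_by_variable: dict = field(default_factory=dict)
    tpr: Proportion | None = None
    fpr: Proportion | None = None
    n_entries: int = 0


def quality_summary(entries: pd.DataFrame,
                    components: pd.DataFrame | None = None) -> QualitySummary:
    """Summaries over classified audit entries.

    ``entries`` is a long-format table with ``finding`` filled.  The
    recovery rate is ``aux_found / (aux_found + aux_not_found)`` (overall
    and per variable).  When ``components`` is given — one row per validated
    (patient, component) with 0/1/NaN columns ``ehr_component`` and
    ``validated_component`` — the true/false-positive rates of the
    error-prone indicators are computed over pairs where both are
    non-missing; ``extracted_not_found`` points have no validated value and
    therefore never enter those denominators.
    """
    if entries["finding"].isna().any():
        raise ValueError("entries must be classified first")
    bad = set(entries["finding"]) - set(FINDINGS)
    if bad:
        raise ValueError(f"unknown findings: {sorted(bad)}")
    counts = entries["finding"].value_counts().to_dict()
    counts = {f: int(counts.get(f, 0)) for f in FINDINGS}
    by_class: dict = {}
    if "variable_class" in entries.columns:
        for cls, sub in entries.groupby("variable_class"):
            sub_counts = sub["finding"].value_counts().to_dict()
            by_class[cls] = {f: int(sub_counts.get(f, 0)) for f in FINDINGS}

    recovery = Proportion(counts["aux_found"],
                          counts["aux_found"] + counts["aux_not_found"])
    per_var: dict = {}
    for var, sub in entries.groupby("variable"):
        found = int((sub["finding"] == "aux_found").sum())
        miss = int((sub["finding"] == "aux_not_found").sum())
        per_var[var] = Proportion(found, found + miss)

    tpr = fpr = None
    if components is not None:
        both = components.dropna(subset=["ehr_component",
                                         "validated_component"])
        pos = both[both["validated_component"] == 1]
        neg = both[both["validated_component"] == 0]
        tpr = Proportion(int((pos["ehr_component"] == 1).sum()), len(pos))
        fpr = Proportion(int((neg["ehr_component"] == 1).sum()), len(neg))

    return QualitySummary(
        finding_counts=counts,
        finding_counts_by_class=by_class,
        recovery=recovery,
        recovery_by_variable=per_var,
        tpr=tpr,
        fpr=fpr,
        n_entries=int(len(entries)),
    )


def component_quality(cohort: pd.DataFrame,
                      names: Iterable[str]) -> pd.DataFrame:
    """Long (patient, component) table of error-prone vs validated
    indicators for validated patients, suitable for :func:`quality_summary`.
    """
    from .synthetic_cohort import ehr_column, validated_column

    validated = cohort[cohort["v"] == 1]
    frames = []
    for name in names:
        frames.append(pd.DataFrame({
            "patient_id": validated["patient_id"].to_numpy(),
            "variable": name,
            "ehr_component": validated[ehr_column(name)].to_numpy(),
            "validated_component": validated[validated_column(name)].to_numpy(),
        }))
    return pd.concat(frames, ignore_index=True)


def fleiss_kappa(ratings: np.ndarray | pd.DataFrame,
                 n_raters: int | None = None) -> float:
    """Fleiss' kappa from an items-by-categories count table.

    Every item must be rated by the same number of raters.  Raises on a
    degenerate table where chance agreement is one (kappa undefined).
    """
    table = np.asarray(ratings, dtype=float)
    if table.ndim != 2:
        raise ValueError("ratings must be a 2-D items x categories table")
    row_sums = table.sum(axis=1)
    if n_raters is None:
        n_raters = int(row_sums[0])
    if not np.all(row_sums == n_raters):
        raise ValueError("every item must be rated by exactly "
                         f"{n_raters} raters")
    if n_raters < 2:
        raise ValueError("kappa needs at least two raters")
    n_items = table.shape[0]
    p_cat = table.sum(axis=0) / (n_items * n_raters)
    p_item = (np.sum(table * (table - 1.0), axis=1)
              / (n_raters * (n_raters - 1.0)))
    p_bar = float(np.mean(p_item))
    p_e = float(np.sum(p_cat**2))
    if p_e >= 1.0:
        raise ValueError("all ratings in a single category; kappa undefined")
    return (p_bar - p_e) / (1.0 - p_e)
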