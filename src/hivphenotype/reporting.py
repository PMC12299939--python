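"""Cohort accounting tables, evidence-source breakdown, display formatting.

Counts below a governance threshold are masked at *display* time only
("<20" by default); machine-readable outputs keep exact integers behind an
explicit opt-in.  Percentages round half-up to one decimal, with a
two-decimal fallback so nonzero counts never display as "0.0".
"""

from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import pandas as pd

from .phenotyper import EvidenceProfile, CohortAssignment, Label

#: display order of the 7 nonempty evidence-source intersections
VENN_CELLS: tuple[str, ...] = (
    "conditions_only",
    "labs_only",
    "drugs_only",
    "conditions_labs",
    "conditions_drugs",
    "labs_drugs",
    "conditions_labs_drugs",
)


def obfuscate_count(n: int, threshold: int = 20) -> str:
    """Mask small counts for display: n < threshold -> "<threshold"."""
    if n < 0:
        raise ValueError("count must be nonnegative")
    if n < threshold:
        return f"<{threshold}"
    return f"{n:,}"


def format_percent(numerator: int, denominator: int, decimals: int = 1) -> str:
    """Percentage display string, rounded half-up.

    Trailing ".0" is stripped ("71", not "71.0").  If the value would round
    to 0 at the requested precision but the numerator is nonzero, precision
    is extended to two decimals so small nonzero shares stay visible
    ("0.03" rather than "0").
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = Decimal(100 * numerator) / Decimal(denominator)

    def _round(p: Decimal, d: int) -> Decimal:
        q = Decimal(1).scaleb(-d) if d > 0 else Decimal(1)
        return p.quantize(q, rounding=ROUND_HALF_UP)

    shown = _round(pct, decimals)
    if shown == 0 and numerator > 0:
        shown = _round(pct, max(decimals + 1, 2))
    text = str(shown.normalize()) if shown != 0 else "0"
    # normalize() can produce exponent notation for e.g. 7E+1
    if "E" in text:
        text = str(int(shown))
    return text


def _evidence_cell(profile: EvidenceProfile) -> str:
    has_cond = profile.n_hiv_conditions >= 1
    has_lab = profile.lab.any_lab_order
    has_drug = profile.any_hiv_drug
    parts = [
        name
        for name, flag in (
            ("conditions", has_cond), ("labs", has_lab), ("drugs", has_drug)
        )
        if flag
    ]
    if not parts:
        raise ValueError(
            f"person {profile.person_id} labeled PLWH with no evidence class"
        )
    return parts[0] + "_only" if len(parts) == 1 else "_".join(parts)


@dataclasses.dataclass(frozen=True)
class VennBreakdown:
    """Disjoint counts over the 7 evidence-source intersections among PLWH."""

    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def venn_breakdown(
    profiles: Mapping[str, EvidenceProfile],
    assignments: Mapping[str, CohortAssignment],
) -> VennBreakdown:
    """Partition the final PLWH cohort by which evidence classes are present."""
    counts = {cell: 0 for cell in VENN_CELLS}
    for pid, a in assignments.items():
        if a.label is not Label.plwh:
            continue
        counts[_evidence_cell(profiles[pid])] += 1
    return VennBreakdown(counts)


def cohort_summary(
    assignments: Mapping[str, CohortAssignment],
    persons: Mapping[str, object],
    stratify_by: str = "sex",
    threshold: int = 20,
    unsafe_exact: bool = False,
) -> pd.DataFrame:
    """Per-(cohort, stratum) accounting with display-safe counts.

    One row per (cohort, stratum) with the exact count (only when
    ``unsafe_exact``), the obfuscated display count, and the within-cohort
    percentage.  ``persons`` maps person_id -> PersonRecord (or any object
    exposing the stratification attribute).
    """
    rows = []
    cohorts: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {}
    for pid, a in assignments.items():
        label = a.label.value
        totals[label] = totals.get(label, 0) + 1
        person = persons.get(pid)
        stratum = str(getattr(person, stratify_by, "unknown")) if person else "unknown"
        cohorts.setdefault(label, {})
        cohorts[label][stratum] = cohorts[label].get(stratum, 0) + 1

    for label in sorted(cohorts):
        for stratum in sorted(cohorts[label]):
            n = cohorts[label][stratum]
            row = {
                "cohort": label,
                "stratum": stratum,
                "count_display": obfuscate_count(n, threshold),
                "percent": format_percent(n, totals[label]) if totals[label] else "0",
            }
            if unsafe_exact:
                row["count_exact"] = n
            rows.append(row)
    cols = ["cohort", "stratum", "count_display", "percent"]
    if unsafe_exact:
        cols.append("count_exact")
    return pd.DataFrame(rows, columns=cols)
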