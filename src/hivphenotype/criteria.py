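"""Confidence-level criterion registry for the PLWH cohort.

A person surviving every carve-out is assigned a confidence level (1 is
strongest) by the first matching rule in an ordered registry of 12 criteria.
Level semantics:

* level 1 — positive HIV laboratory results (detectable viral load, positive
  antigen/antibody, low CD4, or viral suppression on treatment);
* level 2 — no usable lab results but corroborated evidence (conditions plus
  drugs and/or resultless lab orders, or repeated diagnosis dates);
* level 3 — weak evidence: HIV drug exposures alone or a single diagnosis.

The published source of this phenotype states only the level semantics and
per-criterion cohort counts; the 12 default predicates here are this
package's reconstruction and are fully overridable via a JSON registry
(``{id, level, predicate, parameters, description}`` entries evaluated in
ascending id order, first match wins).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Callable

from .labs import CD4Category, VLCategory

Predicate = Callable[..., bool]


def _vl_detectable(p) -> bool:
    return p.lab.vl_worst is VLCategory.ge50


def _qual_positive_with_condition(p) -> bool:
    return p.lab.any_qual_positive and p.n_hiv_conditions >= 1


def _cd4_low(p) -> bool:
    return p.lab.cd4_worst is CD4Category.le200


def _qual_positive_with_art(p) -> bool:
    return p.lab.any_qual_positive and p.art_drug_rows >= 1


def _vl_suppressed_with_art(p) -> bool:
    # virally suppressed on treatment: strong indirect positive
    return p.lab.vl_worst is VLCategory.lt50 and p.art_drug_rows >= 1


def _qual_positive(p) -> bool:
    return p.lab.any_qual_positive


def _condition_art_resultless(p) -> bool:
    return p.n_hiv_conditions >= 1 and p.art_drug_rows >= 1 and p.lab.any_resultless


def _repeat_condition_with_art(p, min_dates: int = 2) -> bool:
    return p.hiv_condition_dates >= min_dates and p.art_drug_rows >= 1


def _repeat_condition(p, min_dates: int = 2) -> bool:
    return p.hiv_condition_dates >= min_dates


def _art_repeat(p, min_rows: int = 2) -> bool:
    return p.art_drug_rows >= min_rows


def _hiv_drug_any(p) -> bool:
    # residual drug evidence: a single treatment row, or ritonavir exposures
    # that were not resolved as COVID-19 therapy
    return p.art_drug_rows >= 1 or p.ritonavir_rows >= 1


def _single_condition(p) -> bool:
    return p.hiv_condition_dates >= 1


PREDICATES: dict[str, Predicate] = {
    "vl_detectable": _vl_detectable,
    "qual_positive_with_condition": _qual_positive_with_condition,
    "cd4_low": _cd4_low,
    "qual_positive_with_art": _qual_positive_with_art,
    "vl_suppressed_with_art": _vl_suppressed_with_art,
    "qual_positive": _qual_positive,
    "condition_art_resultless": _condition_art_resultless,
    "repeat_condition_with_art": _repeat_condition_with_art,
    "repeat_condition": _repeat_condition,
    "art_repeat": _art_repeat,
    "hiv_drug_any": _hiv_drug_any,
    "single_condition": _single_condition,
}


@dataclasses.dataclass(frozen=True)
class CriterionRule:
    """One confidence-level rule; matched in ascending ``id`` order."""

    id: int
    level: int
    predicate: str
    description: str = ""
    parameters: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= self.level <= 3:
            raise ValueError(f"criterion {self.id}: level must be 1-3")
        if self.predicate not in PREDICATES:
            raise ValueError(f"criterion {self.id}: unknown predicate {self.predicate!r}")

    def matches(self, profile) -> bool:
        return PREDICATES[self.predicate](profile, **self.parameters)


class CriterionRegistry(list):
    """Ordered list of :class:`CriterionRule` with unique ids, sorted by id."""

    def __init__(self, rules):
        rules = sorted(rules, key=lambda r: r.id)
        ids = [r.id for r in rules]
        if len(set(ids)) != len(ids):
            raise ValueError("criterion ids must be unique")
        levels = {r.level for r in rules}
        if rules and levels != {1, 2, 3}:
            raise ValueError("every confidence level 1-3 needs at least one rule")
        super().__init__(rules)

    def first_match(self, profile) -> CriterionRule | None:
        for rule in self:
            if rule.matches(profile):
                return rule
        return None


def load_criteria(path: str | Path) -> CriterionRegistry:
    raw = json.loads(Path(path).read_text())
    return CriterionRegistry(CriterionRule(**obj) for obj in raw)


def default_criteria() -> CriterionRegistry:
    """The 12-rule default registry shipped with the package."""
    return load_criteria(Path(__file__).parent / "data" / "criteria_default.json")
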