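"""The phenotyping cascade.

Every person in the population ends up with exactly one label:

``plwh``      person living with HIV, with a confidence level 1-3 and the
              id of the criterion that fired;
``prep``      pre-exposure prophylaxis user, with a confidence level 1-3;
``pep``       post-exposure prophylaxis user (no confidence tiering: a PEP
              course is a single short regimen, too little signal to tier);
``uncertain`` evidence compatible with both HIV care and something else
              (repeat resultless viral-load orders; ritonavir of unknown
              indication in the COVID-19 era);
``not_hiv``   everyone else, including carve-out exclusions (hepatitis-B
              monoinfection on tenofovir, Paxlovid-only ritonavir) and
              condition codes contradicted by negative tests.

The cascade runs: candidate identification -> PrEP carve-out -> PEP
carve-out -> ritonavir-only resolution -> uncertain flag -> confidence
typing.  All predicates use distinct-date / membership semantics, so the
outcome is invariant to row order and row duplication.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import enum
from collections import Counter
from typing import Iterable, Mapping

import pandas as pd

from .config import DEFAULT_CONFIG, PipelineConfig
from .criteria import CriterionRegistry, default_criteria
from .labs import CD4Category, LabProfile, VLCategory, build_lab_profile
from .omop_model import ConceptSetRegistry, DrugExposureRecord, Tables

_PAXLOVID_TEXT = ("paxlovid", "nirmatrelvir")


class Label(str, enum.Enum):
    plwh = "plwh"
    prep = "prep"
    pep = "pep"
    uncertain = "uncertain"
    not_hiv = "not_hiv"


class ExclusionReason(str, enum.Enum):
    none = "none"
    hbv_monoinfection = "hbv_monoinfection"
    paxlovid_only = "paxlovid_only"


class RitonavirResolution(str, enum.Enum):
    not_hiv_paxlovid = "not_hiv_paxlovid"
    uncertain_ritonavir = "uncertain_ritonavir"
    not_applicable = "not_applicable"


@dataclasses.dataclass(frozen=True)
class DrugRow:
    """One HIV-relevant drug exposure, tagged by concept-set membership."""

    start_date: dt.date
    days_supply: int | None
    is_prep: bool
    is_pep_companion: bool
    is_art: bool
    is_ritonavir: bool
    is_paxlovid: bool


@dataclasses.dataclass(frozen=True)
class EvidenceProfile:
    """Per-person evidence summary — the sole input to classification."""

    person_id: str
    n_hiv_conditions: int
    hiv_condition_dates: int
    lab: LabProfile
    art_drug_rows: int
    ritonavir_rows: int
    prep_drug_rows: int
    prep_drug_dates: int
    drug_rows: tuple[DrugRow, ...]
    hbv_condition: bool
    paxlovid_flag: bool
    ritonavir_after_cutoff: bool

    @property
    def any_hiv_drug(self) -> bool:
        return (self.art_drug_rows + self.ritonavir_rows + self.prep_drug_rows) > 0


@dataclasses.dataclass(frozen=True)
class CohortAssignment:
    person_id: str
    label: Label
    confidence: int | None = None
    criterion_id: int | None = None
    exclusion_reason: ExclusionReason = ExclusionReason.none

    def __post_init__(self) -> None:
        needs_conf = self.label in (Label.plwh, Label.prep)
        if needs_conf != (self.confidence is not None):
            raise ValueError(f"confidence present iff label is plwh/prep (got {self.label})")


# ---------------------------------------------------------------------------
# evidence assembly
# ---------------------------------------------------------------------------

def _classify_drug_row(d: DrugExposureRecord, sets: ConceptSetRegistry) -> DrugRow | None:
    cid = d.drug_concept_id
    is_prep = cid in sets["prep_drugs"]
    is_pep = cid in sets["pep_drugs"]
    is_art = cid in sets["art_drugs"]
    in_rtv = cid in sets["ritonavir"]
    in_pax = cid in sets["paxlovid"]
    src = (d.drug_source_value or "").lower()
    is_pax = in_pax or ((in_rtv or in_pax) and any(t in src for t in _PAXLOVID_TEXT))
    is_rtv = in_rtv or in_pax  # a Paxlovid combination row is a ritonavir exposure
    if not (is_prep or is_pep or is_art or is_rtv):
        return None
    return DrugRow(
        start_date=d.start_date,
        days_supply=d.days_supply,
        is_prep=is_prep,
        is_pep_companion=is_pep,
        is_art=is_art,
        is_ritonavir=is_rtv,
        is_paxlovid=is_pax,
    )


def build_evidence_profile(
    person_id: str,
    tables: Tables,
    sets: ConceptSetRegistry,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> EvidenceProfile:
    """Aggregate one person's rows into an :class:`EvidenceProfile`.

    Drug rows are partitioned by concept-set membership into PrEP backbone
    (emtricitabine/tenofovir products), PEP companion integrase inhibitors,
    HIV-treatment antiretrovirals (excluding ritonavir) and ritonavir; a
    ritonavir row also matching the Paxlovid combination concepts or a
    nirmatrelvir/ritonavir source-value pattern is Paxlovid-flagged.
    A person absent from every table yields an all-zero profile.
    """
    hiv_cond = sets["hiv_conditions"]
    hbv_cond = sets["hbv_conditions"]

    # exact duplicate rows carry no information (there is no visit structure
    # here to distinguish them) and are collapsed so that duplicated input
    # yields identical assignments
    conditions = dict.fromkeys(c for c in tables.conditions if c.person_id == person_id)
    measurements = list(
        dict.fromkeys(m for m in tables.measurements if m.person_id == person_id)
    )
    drug_records = dict.fromkeys(d for d in tables.drugs if d.person_id == person_id)

    n_conditions = 0
    condition_dates: set[dt.date] = set()
    hbv = False
    for c in conditions:
        if c.condition_concept_id in hiv_cond:
            n_conditions += 1
            condition_dates.add(c.start_date)
        if c.condition_concept_id in hbv_cond:
            hbv = True

    lab = build_lab_profile(person_id, measurements, sets, config)

    rows: list[DrugRow] = []
    for d in drug_records:
        row = _classify_drug_row(d, sets)
        if row is not None:
            rows.append(row)
    rows.sort(key=lambda r: (r.start_date, r.days_supply is None, r.days_supply or 0))

    rtv_rows = [r for r in rows if r.is_ritonavir]
    return EvidenceProfile(
        person_id=person_id,
        n_hiv_conditions=n_conditions,
        hiv_condition_dates=len(condition_dates),
        lab=lab,
        art_drug_rows=sum(1 for r in rows if r.is_art),
        ritonavir_rows=len(rtv_rows),
        prep_drug_rows=sum(1 for r in rows if r.is_prep),
        prep_drug_dates=len({r.start_date for r in rows if r.is_prep}),
        drug_rows=tuple(rows),
        hbv_condition=hbv,
        paxlovid_flag=any(r.is_paxlovid for r in rtv_rows),
        ritonavir_after_cutoff=all(r.start_date >= config.ritonavir_cutoff for r in rtv_rows),
    )


# ---------------------------------------------------------------------------
# cascade predicates
# ---------------------------------------------------------------------------

def identify_candidates(
    profiles: Iterable[EvidenceProfile],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> set[str]:
    """Persons with any HIV-related evidence: conditions, labs or drugs.

    CD4 orders alone do not create candidacy by default (CD4 counts are
    ordered for many non-HIV indications); set ``cd4_alone_candidacy`` to
    include them.
    """
    out = set()
    for p in profiles:
        lab_evidence = p.lab.n_hiv_qual_tests > 0 or p.lab.n_vl_tests > 0
        if config.cd4_alone_candidacy:
            lab_evidence = lab_evidence or p.lab.n_cd4_tests > 0
        if p.n_hiv_conditions >= 1 or lab_evidence or p.any_hiv_drug:
            out.add(p.person_id)
    return out


def _is_drug_only_candidate(p: EvidenceProfile) -> bool:
    """Candidate without an HIV condition or any positive lab evidence."""
    return (
        p.n_hiv_conditions == 0
        and not p.lab.any_qual_positive
        and p.lab.vl_worst is not VLCategory.ge50
        and p.lab.cd4_worst is not CD4Category.le200
        and p.any_hiv_drug
    )


def _pep_regimen_instance(p: EvidenceProfile, config: PipelineConfig) -> bool:
    """True iff the person's HIV-drug history is exactly one PEP regimen.

    One distinct start date across *all* HIV drug rows, combining an
    emtricitabine/tenofovir backbone with dolutegravir or raltegravir, every
    component supplied for under ``pep_max_days_supply`` days (or with a
    null supply).
    """
    if not p.drug_rows:
        return False
    dates = {r.start_date for r in p.drug_rows}
    if len(dates) != 1:
        return False
    has_backbone = any(r.is_prep for r in p.drug_rows)
    has_companion = any(r.is_pep_companion for r in p.drug_rows)
    if not (has_backbone and has_companion):
        return False
    return all(
        r.days_supply is None or r.days_supply < config.pep_max_days_supply
        for r in p.drug_rows
    )


def classify_prep(
    profile: EvidenceProfile,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[bool, ExclusionReason]:
    """PrEP carve-out for a drug-exposure-only candidate.

    Requires an emtricitabine/tenofovir exposure with no HIV condition and no
    positive lab; a lone PEP regimen instance does not count as PrEP (it
    falls through to the PEP rule).  An otherwise-PrEP person with a chronic
    hepatitis B condition is excluded as probable HBV monotherapy (tenofovir
    treats HBV) and ends up ``not_hiv`` with reason ``hbv_monoinfection``.
    """
    if profile.n_hiv_conditions > 0:
        raise ValueError("classify_prep called on a person with an HIV condition")
    if profile.prep_drug_rows < 1 or _pep_regimen_instance(profile, config):
        return False, ExclusionReason.none
    if profile.hbv_condition:
        return False, ExclusionReason.hbv_monoinfection
    return True, ExclusionReason.none


def assign_prep_confidence(profile: EvidenceProfile) -> int:
    """Confidence tier for a PrEP user.

    Default reconstruction (the published source defers PrEP tier details to
    its appendix): level 1 = repeat dispensing (>=2 distinct dates) with a
    documented negative HIV test; level 2 = repeat dispensing without one;
    level 3 = a single dispensing record.
    """
    if profile.prep_drug_dates >= 2:
        return 1 if profile.lab.any_qual_negative else 2
    return 3


def classify_pep(profile: EvidenceProfile, config: PipelineConfig = DEFAULT_CONFIG) -> bool:
    """PEP carve-out: exactly one short same-date combination regimen."""
    return _pep_regimen_instance(profile, config)


def resolve_ritonavir_only(
    profile: EvidenceProfile,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> RitonavirResolution:
    """Resolve candidates whose only evidence is ritonavir in the COVID era.

    Applies to persons with no HIV conditions, no HIV lab orders at all, no
    treatment or PrEP drugs, and every ritonavir exposure on/after the
    cutoff.  If every such row is Paxlovid-flagged the person is not living
    with HIV; otherwise the indication is unknowable and they are classified
    uncertain.  Ritonavir next to other antiretrovirals is a pharmacokinetic
    booster and leaves the person in the PLWH pathway (``not_applicable``).
    """
    applies = (
        profile.ritonavir_rows >= 1
        and profile.art_drug_rows == 0
        and profile.prep_drug_rows == 0
        and profile.n_hiv_conditions == 0
        and not profile.lab.any_lab_order
        and profile.ritonavir_after_cutoff
    )
    if not applies:
        return RitonavirResolution.not_applicable
    rtv = [r for r in profile.drug_rows if r.is_ritonavir]
    if all(r.is_paxlovid for r in rtv):
        return RitonavirResolution.not_hiv_paxlovid
    return RitonavirResolution.uncertain_ritonavir


def flag_uncertain(profile: EvidenceProfile) -> bool:
    """Repeat viral-load orders, none with a result, and nothing else.

    Repeat resultless VL orders could be treatment monitoring or screening;
    the distinction is unknowable, so these persons are set aside rather
    than forced into a cohort.  A single resultless order does not qualify
    ("repeat" means at least two) and resolves to ``not_hiv`` downstream.
    """
    lab = profile.lab
    return (
        lab.n_vl_tests >= 2
        and lab.n_vl_resultless == lab.n_vl_tests
        and profile.n_hiv_conditions == 0
        and profile.art_drug_rows == 0
        and profile.prep_drug_rows == 0
        and not lab.any_qual_positive
        and lab.cd4_worst in (CD4Category.null, CD4Category.unknown)
    )


def assign_plwh_confidence(
    profile: EvidenceProfile,
    rules: CriterionRegistry,
) -> tuple[int, int] | None:
    """Assign (level, criterion_id) to a surviving candidate, or None.

    ``None`` means the person is not living with HIV despite candidacy.  Two
    adjudication triggers run before the rule registry:

    * miscoded condition: condition codes contradicted by exclusively
      negative antigen/antibody tests, with no treatment exposure, no VL
      orders and no low CD4 to corroborate them;
    * no positive evidence: lab orders only (negative, suppressed-without-
      treatment, or a single resultless order) with no conditions and no
      HIV drugs.

    A surviving candidate that matches neither a trigger nor any rule is a
    registry-exhaustiveness bug and raises.
    """
    lab = profile.lab
    miscoded = (
        profile.n_hiv_conditions >= 1
        and lab.any_qual_negative
        and not lab.any_qual_positive
        and profile.art_drug_rows == 0
        and profile.ritonavir_rows == 0
        and lab.n_vl_tests == 0
        and lab.cd4_worst is not CD4Category.le200
    )
    if miscoded:
        return None
    no_positive_evidence = (
        profile.n_hiv_conditions == 0
        and not lab.any_qual_positive
        and lab.vl_worst is not VLCategory.ge50
        and lab.cd4_worst is not CD4Category.le200
        and not profile.any_hiv_drug
    )
    if no_positive_evidence:
        return None
    rule = rules.first_match(profile)
    if rule is None:
        raise RuntimeError(
            f"criterion registry is not exhaustive: no rule fired for {profile.person_id}"
        )
    return rule.level, rule.id


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PipelineResult:
    """Assignments plus run accounting."""

    assignments: dict[str, CohortAssignment]
    profiles: dict[str, EvidenceProfile]
    summary: dict

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "person_id": a.person_id,
                "label": a.label.value,
                "confidence": a.confidence,
                "criterion_id": a.criterion_id,
                "exclusion_reason": a.exclusion_reason.value,
            }
            for a in self.assignments.values()
        ]
        return pd.DataFrame(
            rows,
            columns=["person_id", "label", "confidence", "criterion_id", "exclusion_reason"],
        ).sort_values("person_id", kind="stable").reset_index(drop=True)


def _summarize(assignments: Mapping[str, CohortAssignment]) -> dict:
    labels = Counter(a.label.value for a in assignments.values())
    criteria = Counter(
        a.criterion_id for a in assignments.values() if a.label is Label.plwh
    )
    plwh_levels = Counter(
        a.confidence for a in assignments.values() if a.label is Label.plwh
    )
    prep_levels = Counter(
        a.confidence for a in assignments.values() if a.label is Label.prep
    )
    exclusions = Counter(
        a.exclusion_reason.value
        for a in assignments.values()
        if a.exclusion_reason is not ExclusionReason.none
    )
    return {
        "n_persons": len(assignments),
        "labels": {lbl.value: labels.get(lbl.value, 0) for lbl in Label},
        "plwh_levels": {lvl: plwh_levels.get(lvl, 0) for lvl in (1, 2, 3)},
        "plwh_criteria": {str(k): v for k, v in sorted(criteria.items())},
        "prep_levels": {lvl: prep_levels.get(lvl, 0) for lvl in (1, 2, 3)},
        "exclusions": dict(exclusions),
    }


def _classify_one(
    profile: EvidenceProfile,
    candidates: set[str],
    rules: CriterionRegistry,
    config: PipelineConfig,
) -> CohortAssignment:
    pid = profile.person_id
    if pid not in candidates:
        return CohortAssignment(pid, Label.not_hiv)

    if _is_drug_only_candidate(profile):
        is_prep, reason = classify_prep(profile, config)
        if is_prep:
            return CohortAssignment(pid, Label.prep, confidence=assign_prep_confidence(profile))
        if reason is ExclusionReason.hbv_monoinfection:
            return CohortAssignment(pid, Label.not_hiv, exclusion_reason=reason)
        if classify_pep(profile, config):
            return CohortAssignment(pid, Label.pep)
        resolution = resolve_ritonavir_only(profile, config)
        if resolution is RitonavirResolution.not_hiv_paxlovid:
            return CohortAssignment(
                pid, Label.not_hiv, exclusion_reason=ExclusionReason.paxlovid_only
            )
        if resolution is RitonavirResolution.uncertain_ritonavir:
            return CohortAssignment(pid, Label.uncertain)

    if flag_uncertain(profile):
        return CohortAssignment(pid, Label.uncertain)

    assigned = assign_plwh_confidence(profile, rules)
    if assigned is None:
        return CohortAssignment(pid, Label.not_hiv)
    level, criterion_id = assigned
    return CohortAssignment(pid, Label.plwh, confidence=level, criterion_id=criterion_id)


def run_pipeline(
    tables: Tables,
    sets: ConceptSetRegistry,
    config: PipelineConfig = DEFAULT_CONFIG,
    rules: CriterionRegistry | None = None,
) -> PipelineResult:
    """Run the full cascade over the population.

    Deterministic and order-independent: persons are processed in sorted
    person_id order and every predicate uses set/distinct-date semantics.
    No person is ever dropped — everyone appearing in any table receives
    exactly one label.
    """
    if rules is None:
        rules = default_criteria()
    # group rows once so profile building is linear in table size
    grouped: dict[str, Tables] = {
        pid: Tables([], [], [], []) for pid in tables.person_ids()
    }
    for c in tables.conditions:
        grouped[c.person_id].conditions.append(c)
    for m in tables.measurements:
        grouped[m.person_id].measurements.append(m)
    for d in tables.drugs:
        grouped[d.person_id].drugs.append(d)
    profiles = {
        pid: build_evidence_profile(pid, sub, sets, config)
        for pid, sub in grouped.items()
    }
    candidates = identify_candidates(profiles.values(), config)
    assignments = {
        pid: _classify_one(profile, candidates, rules, config)
        for pid, profile in profiles.items()
    }
    return PipelineResult(assignments, profiles, _summarize(assignments))
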