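"""HIV laboratory interpretation: qualitative tests, viral load, CD4 count.

Each measurement row resolves into a category, and a person's rows roll up
into a :class:`LabProfile` with "ever" semantics: the per-person category is
the worst observed one under a fixed dominance order.  Two non-result states
matter clinically and are kept distinct throughout:

* ``unknown`` — the test was ordered but no interpretable result is present
  (a pervasive artifact of multi-site EHR harmonization);
* ``null`` — the test was never ordered at all.

Thresholds: a viral load (VL) >=50 copies/mL is *detectable* (``ge50``),
below that *suppressed* (``lt50``); a CD4 count <=200 cells/uL marks
advanced immunosuppression (``le200``).
"""

from __future__ import annotations

import dataclasses
import enum
import logging
import re
from typing import Iterable

from .config import DEFAULT_CONFIG, PipelineConfig
from .omop_model import ConceptSetRegistry, MeasurementRecord, QualResult

log = logging.getLogger(__name__)


class VLCategory(enum.IntEnum):
    """Viral-load category; integer value encodes dominance (higher wins)."""

    null = 0
    unknown = 1
    lt50 = 2
    ge50 = 3


class CD4Category(enum.IntEnum):
    """CD4 category; integer value encodes dominance (higher wins)."""

    null = 0
    unknown = 1
    gt200 = 2
    le200 = 3


class QualInterpretation(str, enum.Enum):
    positive = "positive"
    negative = "negative"
    unknown = "unknown"


@dataclasses.dataclass(frozen=True)
class LabProfile:
    """Per-person summary of HIV lab evidence."""

    person_id: str
    n_vl_tests: int = 0
    n_cd4_tests: int = 0
    n_hiv_qual_tests: int = 0
    any_qual_positive: bool = False
    any_qual_negative: bool = False
    vl_worst: VLCategory = VLCategory.null
    cd4_worst: CD4Category = CD4Category.null
    n_vl_resultless: int = 0

    def __post_init__(self) -> None:
        if self.n_vl_resultless > self.n_vl_tests:
            raise ValueError("n_vl_resultless cannot exceed n_vl_tests")
        if (self.vl_worst is VLCategory.null) != (self.n_vl_tests == 0):
            raise ValueError("vl_worst must be null iff no VL tests")
        if (self.cd4_worst is CD4Category.null) != (self.n_cd4_tests == 0):
            raise ValueError("cd4_worst must be null iff no CD4 tests")

    @property
    def any_lab_order(self) -> bool:
        return (self.n_vl_tests + self.n_cd4_tests + self.n_hiv_qual_tests) > 0

    @property
    def any_resultless(self) -> bool:
        """Some HIV lab was ordered but yielded no interpretable result."""
        qual_unresolved = (
            self.n_hiv_qual_tests > 0
            and not self.any_qual_positive
            and not self.any_qual_negative
        )
        return (
            self.n_vl_resultless > 0
            or self.cd4_worst is CD4Category.unknown
            or qual_unresolved
        )


def interpret_qual_result(m: MeasurementRecord) -> QualInterpretation:
    """Interpret a qualitative HIV test (antigen/antibody) row."""
    if m.value_as_concept is QualResult.positive:
        return QualInterpretation.positive
    if m.value_as_concept is QualResult.negative:
        return QualInterpretation.negative
    return QualInterpretation.unknown


# assay-floor text like "<20 copies/mL"; group 1 is the floor
_LT_PATTERN = re.compile(r"^<\s*(\d+(?:\.\d+)?)")
_UNDETECTABLE = re.compile(r"undetect|not\s+detect|target\s+not", re.IGNORECASE)


def categorize_vl(m: MeasurementRecord, config: PipelineConfig = DEFAULT_CONFIG) -> VLCategory:
    """Categorize one viral-load measurement.

    Numeric values compare against the detectability threshold (inclusive:
    exactly 50 copies/mL is detectable).  Censored text results like
    "<20 copies/mL" count as suppressed when the assay floor sits at or below
    the threshold; a floor above it (e.g. "<400") is uninterpretable for this
    rule and maps to ``unknown``, as does any row with no usable result.
    """
    v = m.value_as_number
    if v is not None:
        if v < 0:
            log.warning("negative viral load %s for person %s; treated as unknown", v, m.person_id)
            return VLCategory.unknown
        return VLCategory.ge50 if v >= config.vl_threshold else VLCategory.lt50
    if m.value_source_text:
        text = m.value_source_text.strip()
        if _UNDETECTABLE.search(text):
            return VLCategory.lt50
        match = _LT_PATTERN.match(text)
        if match:
            floor = float(match.group(1))
            return VLCategory.lt50 if floor <= config.vl_threshold else VLCategory.unknown
    return VLCategory.unknown


def categorize_cd4(m: MeasurementRecord, config: PipelineConfig = DEFAULT_CONFIG) -> CD4Category:
    """Categorize one absolute CD4 count measurement.

    With ``strict_units`` on, a value whose unit is missing is treated as
    uninterpretable; by default the value is accepted as cells/uL.
    """
    v = m.value_as_number
    if v is None:
        return CD4Category.unknown
    if config.strict_units and not m.unit:
        return CD4Category.unknown
    return CD4Category.le200 if v <= config.cd4_threshold else CD4Category.gt200


def build_lab_profile(
    person_id: str,
    measurements: Iterable[MeasurementRecord],
    sets: ConceptSetRegistry,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> LabProfile:
    """Roll one person's measurement rows up into a :class:`LabProfile`.

    ``measurements`` must already be filtered to this person.  Rows whose
    concept ID belongs to none of the HIV lab concept sets are ignored.
    Worst categories follow the dominance order declared on the enums
    (detectable > suppressed > unknown > null; low CD4 > normal > unknown >
    null), encoding "any-time" evidence.
    """
    vl_set = sets["hiv_viral_load"]
    cd4_set = sets["cd4_count_absolute"]
    qual_set = sets["hiv_qualitative_tests"]

    n_vl = n_cd4 = n_qual = n_vl_resultless = 0
    any_pos = any_neg = False
    vl_worst = VLCategory.null
    cd4_worst = CD4Category.null

    for m in measurements:
        if m.person_id != person_id:
            continue
        cid = m.measurement_concept_id
        if cid in vl_set:
            n_vl += 1
            cat = categorize_vl(m, config)
            if cat is VLCategory.unknown:
                n_vl_resultless += 1
                vl_worst = max(vl_worst, VLCategory.unknown)
            else:
                vl_worst = max(vl_worst, cat)
        elif cid in cd4_set:
            n_cd4 += 1
            cd4_worst = max(cd4_worst, categorize_cd4(m, config))
        elif cid in qual_set:
            n_qual += 1
            interp = interpret_qual_result(m)
            any_pos = any_pos or interp is QualInterpretation.positive
            any_neg = any_neg or interp is QualInterpretation.negative

    return LabProfile(
        person_id=person_id,
        n_vl_tests=n_vl,
        n_cd4_tests=n_cd4,
        n_hiv_qual_tests=n_qual,
        any_qual_positive=any_pos,
        any_qual_negative=any_neg,
        vl_worst=vl_worst,
        cd4_worst=cd4_worst,
        n_vl_resultless=n_vl_resultless,
    )
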