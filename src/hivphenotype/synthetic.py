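"""Synthetic OMOP-shaped cohorts with known ground truth.

The generator emits archetype persons whose rows satisfy, by construction,
the defining predicate of exactly one cohort label (and confidence tier,
where applicable), then optionally perturbs them with the noise mechanisms
that drive real-world misclassification:

* ``miscode_condition_rate`` — an HIV condition code landing on a person who
  is not living with HIV (codes applied during screening or PrEP visits);
* ``resultless_lab_rate`` — a lab order whose result is lost in ingestion /
  harmonization;
* ``cd4_unit_drop_rate`` — a CD4 value arriving without its unit.

All randomness flows through one ``numpy`` generator and dates are integer
offsets from the study window start (2018-01-01 .. 2023-11-02), so output
is reproducible bit-for-bit given a seed.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .omop_model import (
    ConditionRecord,
    DrugExposureRecord,
    MeasurementRecord,
    PersonRecord,
    QualResult,
    Tables,
)

WINDOW_START = dt.date(2018, 1, 1)
WINDOW_END = dt.date(2023, 11, 2)
COVID_ERA_START = dt.date(2020, 1, 1)

# toy concept IDs, matching the shipped concept-set JSONs
HIV_CONDITION = 1001
HBV_CONDITION = 1101
QUAL_TEST = 2001
VL_TEST = 2101
CD4_TEST = 2201
FTC_TDF = 3001          # emtricitabine/tenofovir backbone (PrEP set)
DOLUTEGRAVIR = 3101
RALTEGRAVIR = 3102
DARUNAVIR = 3201
EFAVIRENZ = 3202
RITONAVIR = 3301
PAXLOVID = 3401

ARCHETYPES: tuple[str, ...] = (
    "plwh_L1", "plwh_L2", "plwh_L3",
    "prep_L1", "prep_L2", "prep_L3",
    "pep", "paxlovid_only", "uncertain_vl", "hbv_tdf", "negative",
)

#: Balanced-ish default mix: every archetype well represented at modest n.
#: (The study population itself is ~99% HIV-negative; reproduce that with a
#: custom mix if population-scale prevalence matters for an experiment.)
DEFAULT_CLASS_MIX: dict[str, float] = {
    "plwh_L1": 0.12, "plwh_L2": 0.08, "plwh_L3": 0.08,
    "prep_L1": 0.08, "prep_L2": 0.06, "prep_L3": 0.06,
    "pep": 0.06, "paxlovid_only": 0.08, "uncertain_vl": 0.08,
    "hbv_tdf": 0.06, "negative": 0.24,
}

_RACE_ETHNICITY = (
    "Hispanic or Latinx", "Non-Hispanic Black or African American",
    "Non-Hispanic White", "Non-Hispanic Asian", "Unknown",
)
_RACE_P = (0.14, 0.20, 0.47, 0.04, 0.15)
_SEX = ("female", "male", "other_unknown")
_SEX_P = (0.50, 0.49, 0.01)


@dataclasses.dataclass(frozen=True)
class NoiseSpec:
    miscode_condition_rate: float = 0.0
    resultless_lab_rate: float = 0.0
    cd4_unit_drop_rate: float = 0.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f.name} must be in [0, 1]")

    @property
    def any(self) -> bool:
        return any(getattr(self, f.name) > 0 for f in dataclasses.fields(self))


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    n_persons: int = 500
    class_mix: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX)
    )
    noise: NoiseSpec = NoiseSpec()
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.class_mix) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetype(s) in class_mix: {sorted(unknown)}")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1 (got {total})")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticSpec":
        raw = json.loads(Path(path).read_text())
        if "noise" in raw:
            raw["noise"] = NoiseSpec(**raw["noise"])
        return cls(**raw)


@dataclasses.dataclass(frozen=True)
class GroundTruthRecord:
    person_id: str
    true_label: str
    true_confidence: int | None
    archetype: str


# ---------------------------------------------------------------------------
# date helpers (pure integer arithmetic on day offsets)
# ---------------------------------------------------------------------------

def _rand_date(rng: np.random.Generator, start: dt.date = WINDOW_START,
               end: dt.date = WINDOW_END) -> dt.date:
    span = (end - start).days
    return start + dt.timedelta(days=int(rng.integers(0, span + 1)))


def _distinct_dates(rng: np.random.Generator, k: int, start: dt.date = WINDOW_START,
                    end: dt.date = WINDOW_END) -> list[dt.date]:
    span = (end - start).days
    offsets = rng.choice(span + 1, size=k, replace=False)
    return sorted(start + dt.timedelta(days=int(o)) for o in offsets)


# ---------------------------------------------------------------------------
# per-archetype templates
# ---------------------------------------------------------------------------

def _vl(pid: str, date: dt.date, value: float | None) -> MeasurementRecord:
    return MeasurementRecord(pid, VL_TEST, date, value_as_number=value,
                             unit=None if value is None else "copies/mL")


def _cd4(pid: str, date: dt.date, value: float | None) -> MeasurementRecord:
    return MeasurementRecord(pid, CD4_TEST, date, value_as_number=value,
                             unit=None if value is None else "cells/uL")


def _qual(pid: str, date: dt.date, result: QualResult) -> MeasurementRecord:
    return MeasurementRecord(pid, QUAL_TEST, date, value_as_concept=result)


def _drug(pid: str, concept: int, date: dt.date, supply: int | None = None,
          source: str | None = None) -> DrugExposureRecord:
    return DrugExposureRecord(pid, concept, date, days_supply=supply,
                              drug_source_value=source)


def generate_person(
    archetype: str,
    rng: np.random.Generator,
    person_id: str = "P1",
) -> tuple[PersonRecord, list[ConditionRecord], list[MeasurementRecord],
           list[DrugExposureRecord], GroundTruthRecord]:
    """Generate one synthetic person of the given archetype.

    Pre-noise, the emitted rows satisfy the target label's defining
    predicate exactly; several archetypes draw among sub-variants so that
    different criteria of the same confidence level are exercised.
    """
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype: {archetype!r}")
    pid = person_id
    person = PersonRecord(
        person_id=pid,
        age_years=float(rng.integers(18, 81)),
        sex=str(rng.choice(_SEX, p=_SEX_P)),
        race_ethnicity=str(rng.choice(_RACE_ETHNICITY, p=_RACE_P)),
    )
    conds: list[ConditionRecord] = []
    meas: list[MeasurementRecord] = []
    drugs: list[DrugExposureRecord] = []
    label, conf = "not_hiv", None

    if archetype == "plwh_L1":
        label, conf = "plwh", 1
        variant = int(rng.integers(0, 6))
        d = _distinct_dates(rng, 4)
        if variant == 0:      # detectable VL + condition + treatment
            conds.append(ConditionRecord(pid, HIV_CONDITION, d[0]))
            meas.append(_vl(pid, d[1], float(rng.integers(50, 200_000))))
            meas.append(_cd4(pid, d[1], float(rng.integers(50, 900))))
            drugs.append(_drug(pid, DOLUTEGRAVIR, d[2], 90))
        elif variant == 1:    # positive antigen/antibody + condition
            conds.append(ConditionRecord(pid, HIV_CONDITION, d[0]))
            meas.append(_qual(pid, d[1], QualResult.positive))
        elif variant == 2:    # low CD4 + condition
            conds.append(ConditionRecord(pid, HIV_CONDITION, d[0]))
            meas.append(_cd4(pid, d[1], float(rng.integers(5, 201))))
        elif variant == 3:    # positive antigen/antibody + treatment
            meas.append(_qual(pid, d[0], QualResult.positive))
            drugs.append(_drug(pid, DARUNAVIR, d[1], 30))
            drugs.append(_drug(pid, RITONAVIR, d[1], 30))  # booster
        elif variant == 4:    # suppressed VL on treatment
            meas.append(_vl(pid, d[0], float(rng.integers(0, 50))))
            drugs.append(_drug(pid, DOLUTEGRAVIR, d[1], 90))
            drugs.append(_drug(pid, DOLUTEGRAVIR, d[2], 90))
        else:                 # positive antigen/antibody alone
            meas.append(_qual(pid, d[0], QualResult.positive))

    elif archetype == "plwh_L2":
        label, conf = "plwh", 2
        variant = int(rng.integers(0, 3))
        d = _distinct_dates(rng, 4)
        if variant == 0:      # condition + treatment + resultless VL order
            conds.append(ConditionRecord(pid, HIV_CONDITION, d[0]))
            meas.append(_vl(pid, d[1], None))
            drugs.append(_drug(pid, EFAVIRENZ, d[2], 90))
        elif variant == 1:    # repeat condition dates + treatment, no labs
            conds.append(ConditionRecord(pid, HIV_CONDITION, d[0]))
            conds.append(ConditionRecord(pid, HIV_CONDITION, d[1]))
            drugs.append(_drug(pid, DARUNAVIR, d[2], 90))
        else:                 # repeat condition dates + resultless VL order
            conds.append(ConditionRecord(pid, HIV_CONDITION, d[0]))
            conds.append(ConditionRecord(pid, HIV_CONDITION, d[1]))
            meas.append(_vl(pid, d[2], None))

    elif archetype == "plwh_L3":
        label, conf = "plwh", 3
        variant = int(rng.integers(0, 4))
        if variant == 0:      # repeat treatment exposure alone
            for date in _distinct_dates(rng, int(rng.integers(2, 4))):
                drugs.append(_drug(pid, DARUNAVIR, date, 90))
        elif variant == 1:    # a single treatment row alone
            drugs.append(_drug(pid, EFAVIRENZ, _rand_date(rng), 30))
        elif variant == 2:    # ritonavir alone, entirely pre-COVID era
            drugs.append(_drug(
                pid, RITONAVIR,
                _rand_date(rng, WINDOW_START, COVID_ERA_START - dt.timedelta(days=1)),
                30,
            ))
        else:                 # a single condition date, nothing else
            conds.append(ConditionRecord(pid, HIV_CONDITION, _rand_date(rng)))

    elif archetype in ("prep_L1", "prep_L2", "prep_L3"):
        label = "prep"
        conf = int(archetype[-1])
        if conf == 1:         # repeat dispensing + documented negative test
            dates = _distinct_dates(rng, int(rng.integers(2, 5)) + 1)
            meas.append(_qual(pid, dates[0], QualResult.negative))
            for date in dates[1:]:
                drugs.append(_drug(pid, FTC_TDF, date, 90))
        elif conf == 2:       # repeat dispensing, no documented test
            for date in _distinct_dates(rng, int(rng.integers(2, 5))):
                drugs.append(_drug(pid, FTC_TDF, date, 90))
        else:                 # a single dispensing record
            drugs.append(_drug(pid, FTC_TDF, _rand_date(rng), int(rng.integers(30, 91))))

    elif archetype == "pep":
        label = "pep"
        date = _rand_date(rng)
        supply_choices = (28, 14, 29, None)
        supply = supply_choices[int(rng.integers(0, len(supply_choices)))]
        companion = DOLUTEGRAVIR if rng.integers(0, 2) == 0 else RALTEGRAVIR
        drugs.append(_drug(pid, FTC_TDF, date, supply))
        drugs.append(_drug(pid, companion, date, supply))

    elif archetype == "paxlovid_only":
        date = _rand_date(rng, COVID_ERA_START, WINDOW_END)
        if rng.integers(0, 2) == 0:
            drugs.append(_drug(pid, PAXLOVID, date, 5, "nirmatrelvir/ritonavir 300-100mg"))
        else:
            drugs.append(_drug(pid, RITONAVIR, date, 5, "PAXLOVID"))

    elif archetype == "uncertain_vl":
        label = "uncertain"
        for date in _distinct_dates(rng, int(rng.integers(2, 5))):
            meas.append(_vl(pid, date, None))

    elif archetype == "hbv_tdf":
        d = _distinct_dates(rng, 4)
        conds.append(ConditionRecord(pid, HBV_CONDITION, d[0]))
        for date in d[1 : 1 + int(rng.integers(2, 4))]:
            drugs.append(_drug(pid, FTC_TDF, date, 90))

    else:  # negative
        variant = int(rng.integers(0, 3))
        if variant == 1:      # CD4 ordered for a non-HIV indication
            meas.append(_cd4(pid, _rand_date(rng), float(rng.integers(300, 1200))))
        elif variant == 2:    # screened negative
            meas.append(_qual(pid, _rand_date(rng), QualResult.negative))
        # variant 0: no rows at all

    truth = GroundTruthRecord(pid, label, conf, archetype)
    return person, conds, meas, drugs, truth


# ---------------------------------------------------------------------------
# noise injection
# ---------------------------------------------------------------------------

def inject_noise(
    tables: Tables,
    noise: NoiseSpec,
    rng: np.random.Generator,
) -> tuple[Tables, list[dict]]:
    """Apply the three noise mechanisms; returns perturbed tables and a log.

    Miscoding targets persons with no HIV evidence rows at all (no HIV
    conditions, no HIV drugs, no VL orders, no positive qualitative test):
    each such person gains exactly one HIV condition code with probability
    ``miscode_condition_rate``.  Result loss applies per measurement row
    carrying a result; unit loss applies per CD4 row with a unit.  All
    rates 0 is the identity transform.
    """
    log: list[dict] = []
    if not noise.any:
        return tables, log

    hiv_drug_concepts = {FTC_TDF, DOLUTEGRAVIR, RALTEGRAVIR, DARUNAVIR,
                         EFAVIRENZ, RITONAVIR, PAXLOVID}
    measurements = list(tables.measurements)
    conditions = list(tables.conditions)

    if noise.resultless_lab_rate > 0:
        for i, m in enumerate(measurements):
            has_result = m.value_as_number is not None or m.value_as_concept is not QualResult.none
            if has_result and rng.random() < noise.resultless_lab_rate:
                measurements[i] = dataclasses.replace(
                    m, value_as_number=None, value_as_concept=QualResult.none,
                    value_source_text=None,
                )
                log.append({"mechanism": "resultless_lab", "person_id": m.person_id,
                            "concept_id": m.measurement_concept_id})

    if noise.cd4_unit_drop_rate > 0:
        for i, m in enumerate(measurements):
            if m.measurement_concept_id == CD4_TEST and m.unit is not None:
                if rng.random() < noise.cd4_unit_drop_rate:
                    measurements[i] = dataclasses.replace(m, unit=None)
                    log.append({"mechanism": "cd4_unit_drop", "person_id": m.person_id})

    if noise.miscode_condition_rate > 0:
        evident = {c.person_id for c in conditions if c.condition_concept_id == HIV_CONDITION}
        evident |= {d.person_id for d in tables.drugs if d.drug_concept_id in hiv_drug_concepts}
        evident |= {m.person_id for m in measurements if m.measurement_concept_id == VL_TEST}
        evident |= {
            m.person_id for m in measurements
            if m.measurement_concept_id == QUAL_TEST and m.value_as_concept is QualResult.positive
        }
        for p in tables.persons:
            if p.person_id in evident:
                continue
            if rng.random() < noise.miscode_condition_rate:
                conditions.append(
                    ConditionRecord(p.person_id, HIV_CONDITION, _rand_date(rng))
                )
                log.append({"mechanism": "miscode_condition", "person_id": p.person_id})

    perturbed = Tables(tables.persons, conditions, measurements, tables.drugs,
                       dict(tables.dropped))
    return perturbed, log


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(spec: SyntheticSpec) -> tuple[Tables, list[GroundTruthRecord], list[dict]]:
    """Generate a full synthetic population per ``spec``.

    Class counts are drawn multinomially from ``class_mix``; noise is applied
    after template generation.  Output is reproducible given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    names = [a for a in ARCHETYPES if spec.class_mix.get(a, 0.0) > 0]
    probs = np.array([spec.class_mix[a] for a in names])
    counts = rng.multinomial(spec.n_persons, probs / probs.sum())

    width = max(6, len(str(spec.n_persons)))
    persons: list[PersonRecord] = []
    conds: list[ConditionRecord] = []
    meas: list[MeasurementRecord] = []
    drugs: list[DrugExposureRecord] = []
    truth: list[GroundTruthRecord] = []
    idx = 0
    for name, k in zip(names, counts):
        for _ in range(int(k)):
            idx += 1
            pid = f"P{idx:0{width}d}"
            person, c, m, d, t = generate_person(name, rng, pid)
            persons.append(person)
            conds.extend(c)
            meas.extend(m)
            drugs.extend(d)
            truth.append(t)

    tables = Tables(persons, conds, meas, drugs)
    tables, log = inject_noise(tables, spec.noise, rng)
    return tables, truth, log


def truth_frame(truth: Sequence[GroundTruthRecord]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "person_id": t.person_id,
                "true_label": t.true_label,
                "true_confidence": "" if t.true_confidence is None else t.true_confidence,
                "archetype": t.archetype,
            }
            for t in truth
        ],
        columns=["person_id", "true_label", "true_confidence", "archetype"],
    )
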