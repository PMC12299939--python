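import datetime as dt

import pytest

from hivphenotype import builtin_concept_sets
from hivphenotype.omop_model import (
    ConditionRecord,
    DrugExposureRecord,
    MeasurementRecord,
    PersonRecord,
    QualResult,
    Tables,
)
from hivphenotype.synthetic import (
    CD4_TEST,
    DOLUTEGRAVIR,
    FTC_TDF,
    HIV_CONDITION,
    QUAL_TEST,
    RITONAVIR,
    VL_TEST,
)

D = dt.date


def cond(pid, date, concept=HIV_CONDITION):
    return ConditionRecord(pid, concept, date)


def vl(pid, date, value=None, text=None):
    return MeasurementRecord(pid, VL_TEST, date, value_as_number=value,
                             value_source_text=text,
                             unit=None if value is None else "copies/mL")


def cd4(pid, date, value=None, unit="cells/uL"):
    return MeasurementRecord(pid, CD4_TEST, date, value_as_number=value, unit=unit)


def qual(pid, date, result):
    return MeasurementRecord(pid, QUAL_TEST, date,
                             value_as_concept=QualResult(result))


def drug(pid, concept, date, supply=None, source=None):
    return DrugExposureRecord(pid, concept, date, days_supply=supply,
                              drug_source_value=source)


@pytest.fixture(scope="session")
def sets():
    return builtin_concept_sets()


@pytest.fixture()
def eight_person_tables():
    """One archetype per cohort class, each hand-traceable through the cascade.

    Expected outcome per person is returned alongside the tables as
    (label, confidence) pairs.
    """
    persons = [PersonRecord(f"A{i}") for i in range(1, 9)]
    conditions = [
        # A1: level-1 PLWH — condition + detectable VL + treatment
        cond("A1", D(2020, 3, 1)),
        # A2: level-2 PLWH — two condition dates + treatment + resultless VL
        cond("A2", D(2020, 5, 1)),
        cond("A2", D(2021, 2, 10)),
        # A3: level-3 PLWH — one condition date, nothing else
        cond("A3", D(2022, 7, 4)),
    ]
    measurements = [
        vl("A1", D(2020, 3, 15), value=1000.0),
        vl("A2", D(2020, 6, 1)),                      # ordered, no result
        qual("A4", D(2021, 1, 5), "negative"),         # PrEP user's screening
        vl("A7", D(2021, 4, 1)),                       # repeat resultless orders
        vl("A7", D(2021, 8, 1)),
        vl("A7", D(2022, 1, 1)),
    ]
    drugs = [
        drug("A1", DOLUTEGRAVIR, D(2020, 4, 1), 90),
        drug("A2", DOLUTEGRAVIR, D(2020, 7, 1), 90),
        # A4: PrEP — repeat FTC/TDF dispensing + documented negative test
        drug("A4", FTC_TDF, D(2021, 1, 10), 90),
        drug("A4", FTC_TDF, D(2021, 4, 10), 90),
        drug("A4", FTC_TDF, D(2021, 7, 10), 90),
        # A5: PEP — backbone + integrase inhibitor, same date, 28-day supply
        drug("A5", FTC_TDF, D(2021, 3, 1), 28),
        drug("A5", DOLUTEGRAVIR, D(2021, 3, 1), 28),
        # A6: Paxlovid-only ritonavir
        drug("A6", RITONAVIR, D(2022, 1, 10), 5, source="PAXLOVID"),
    ]
    tables = Tables(persons, conditions, measurements, drugs)
    expected = {
        "A1": ("plwh", 1),
        "A2": ("plwh", 2),
        "A3": ("plwh", 3),
        "A4": ("prep", 1),
        "A5": ("pep", None),
        "A6": ("not_hiv", None),
        "A7": ("uncertain", None),
        "A8": ("not_hiv", None),
    }
    return tables, expected
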