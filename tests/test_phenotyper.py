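import random

import pytest

from hivphenotype.config import PipelineConfig
from hivphenotype.criteria import default_criteria
from hivphenotype.omop_model import PersonRecord, Tables
from hivphenotype.phenotyper import (
    ExclusionReason,
    Label,
    RitonavirResolution,
    assign_plwh_confidence,
    assign_prep_confidence,
    build_evidence_profile,
    classify_pep,
    classify_prep,
    flag_uncertain,
    identify_candidates,
    resolve_ritonavir_only,
    run_pipeline,
)
from hivphenotype.synthetic import (
    DARUNAVIR,
    DOLUTEGRAVIR,
    FTC_TDF,
    HBV_CONDITION,
    RALTEGRAVIR,
    RITONAVIR,
)

from conftest import D, cd4, cond, drug, qual, vl

RULES = default_criteria()


def profile_for(sets, pid="p", conditions=(), measurements=(), drugs=()):
    tables = Tables([PersonRecord(pid)], list(conditions), list(measurements), list(drugs))
    return build_evidence_profile(pid, tables, sets)


class TestEvidenceProfile:
    def test_direct_aggregation(self, sets):
        p = profile_for(
            sets,
            conditions=[cond("p", D(2020, 1, 1)), cond("p", D(2020, 1, 1)),
                        cond("p", D(2021, 1, 1))],
            measurements=[vl("p", D(2020, 2, 1), value=1000.0)],
            drugs=[drug("p", DOLUTEGRAVIR, D(2020, 3, 1), 90)],
        )
        assert p.n_hiv_conditions == 2  # the exact-duplicate row collapses
        assert p.hiv_condition_dates == 2  # distinct dates
        assert p.lab.vl_worst.name == "ge50"
        assert p.art_drug_rows == 1

    def test_paxlovid_recognized_via_source_value(self, sets):
        p = profile_for(sets, drugs=[drug("p", RITONAVIR, D(2021, 6, 1), 5, "PAXLOVID")])
        assert p.ritonavir_rows == 1
        assert p.paxlovid_flag is True
        assert p.ritonavir_after_cutoff is True

    def test_empty_person_gives_all_zero_profile(self, sets):
        p = profile_for(sets)
        assert p.n_hiv_conditions == 0 and not p.any_hiv_drug
        assert not p.lab.any_lab_order


class TestCandidacy:
    def test_condition_only_person_is_candidate(self, sets):
        p = profile_for(sets, conditions=[cond("p", D(2020, 1, 1))])
        assert identify_candidates([p]) == {"p"}

    def test_negative_test_only_person_is_candidate_at_this_step(self, sets):
        p = profile_for(sets, measurements=[qual("p", D(2020, 1, 1), "negative")])
        assert identify_candidates([p]) == {"p"}

    def test_all_zero_profile_is_not_candidate(self, sets):
        assert identify_candidates([profile_for(sets)]) == set()

    def test_cd4_order_alone_does_not_create_candidacy_by_default(self, sets):
        p = profile_for(sets, measurements=[cd4("p", D(2020, 1, 1), 350.0)])
        assert identify_candidates([p]) == set()
        assert identify_candidates([p], PipelineConfig(cd4_alone_candidacy=True)) == {"p"}


class TestPrEP:
    def test_repeat_dispensing_with_negative_screen_is_prep(self, sets):
        p = profile_for(
            sets,
            measurements=[qual("p", D(2021, 1, 1), "negative")],
            drugs=[drug("p", FTC_TDF, D(2021, 1, 5), 90),
                   drug("p", FTC_TDF, D(2021, 4, 5), 90),
                   drug("p", FTC_TDF, D(2021, 7, 5), 90)],
        )
        assert classify_prep(p) == (True, ExclusionReason.none)
        assert assign_prep_confidence(p) == 1

    def test_hbv_condition_excludes_as_monoinfection(self, sets):
        p = profile_for(
            sets,
            conditions=[cond("p", D(2020, 1, 1), HBV_CONDITION)],
            drugs=[drug("p", FTC_TDF, D(2021, 1, 5), 90),
                   drug("p", FTC_TDF, D(2021, 4, 5), 90)],
        )
        assert classify_prep(p) == (False, ExclusionReason.hbv_monoinfection)

    def test_hiv_condition_violates_contract(self, sets):
        p = profile_for(sets, conditions=[cond("p", D(2020, 1, 1))],
                        drugs=[drug("p", FTC_TDF, D(2021, 1, 5), 90)])
        with pytest.raises(ValueError, match="HIV condition"):
            classify_prep(p)

    @pytest.mark.parametrize("dates,has_negative,expected", [
        (3, True, 1), (2, False, 2), (1, False, 3),
    ])
    def test_confidence_tiers(self, sets, dates, has_negative, expected):
        measurements = [qual("p", D(2021, 1, 1), "negative")] if has_negative else []
        drugs_ = [drug("p", FTC_TDF, D(2021, m, 5), 90) for m in range(2, 2 + dates)]
        p = profile_for(sets, measurements=measurements, drugs=drugs_)
        assert classify_prep(p)[0] is True
        assert assign_prep_confidence(p) == expected


class TestPEP:
    def test_same_date_combination_with_short_supply_is_pep(self, sets):
        p = profile_for(sets, drugs=[drug("p", FTC_TDF, D(2021, 3, 1), 28),
                                     drug("p", DOLUTEGRAVIR, D(2021, 3, 1), 28)])
        assert classify_pep(p) is True
        # the same person must not be captured by the PrEP rule
        assert classify_prep(p)[0] is False

    def test_null_supply_counts_as_short(self, sets):
        p = profile_for(sets, drugs=[drug("p", FTC_TDF, D(2021, 3, 1)),
                                     drug("p", RALTEGRAVIR, D(2021, 3, 1))])
        assert classify_pep(p) is True

    @pytest.mark.parametrize("supply,expected", [(29, True), (30, False), (90, False)])
    def test_supply_boundary_strictly_below_30(self, sets, supply, expected):
        p = profile_for(sets, drugs=[drug("p", FTC_TDF, D(2021, 3, 1), supply),
                                     drug("p", DOLUTEGRAVIR, D(2021, 3, 1), supply)])
        assert classify_pep(p) is expected

    def test_components_on_different_dates_are_not_pep(self, sets):
        p = profile_for(sets, drugs=[drug("p", FTC_TDF, D(2021, 3, 1), 28),
                                     drug("p", DOLUTEGRAVIR, D(2021, 3, 5), 28)])
        assert classify_pep(p) is False

    def test_other_hiv_drug_rows_on_other_dates_disqualify(self, sets):
        p = profile_for(sets, drugs=[drug("p", FTC_TDF, D(2021, 3, 1), 28),
                                     drug("p", DOLUTEGRAVIR, D(2021, 3, 1), 28),
                                     drug("p", DARUNAVIR, D(2022, 1, 1), 90)])
        assert classify_pep(p) is False


class TestRitonavirOnly:
    def test_paxlovid_flagged_rows_resolve_to_not_hiv(self, sets):
        p = profile_for(sets, drugs=[drug("p", RITONAVIR, D(2022, 1, 10), 5, "PAXLOVID")])
        assert resolve_ritonavir_only(p) is RitonavirResolution.not_hiv_paxlovid

    def test_plain_ritonavir_in_covid_era_is_uncertain(self, sets):
        p = profile_for(sets, drugs=[drug("p", RITONAVIR, D(2021, 5, 1), 30)])
        assert resolve_ritonavir_only(p) is RitonavirResolution.uncertain_ritonavir

    def test_ritonavir_boosting_other_art_is_not_applicable(self, sets):
        p = profile_for(sets, drugs=[drug("p", RITONAVIR, D(2021, 5, 1), 30),
                                     drug("p", DARUNAVIR, D(2021, 5, 1), 30)])
        assert resolve_ritonavir_only(p) is RitonavirResolution.not_applicable

    def test_pre_covid_ritonavir_is_not_applicable(self, sets):
        p = profile_for(sets, drugs=[drug("p", RITONAVIR, D(2019, 5, 1), 30)])
        assert resolve_ritonavir_only(p) is RitonavirResolution.not_applicable


class TestUncertainFlag:
    def test_repeat_resultless_vl_orders_flag_uncertain(self, sets):
        p = profile_for(sets, measurements=[vl("p", D(2021, m, 1)) for m in (1, 4, 8)])
        assert flag_uncertain(p) is True

    def test_condition_routes_to_confidence_typing_instead(self, sets):
        p = profile_for(sets, conditions=[cond("p", D(2021, 1, 1))],
                        measurements=[vl("p", D(2021, m, 1)) for m in (1, 4, 8)])
        assert flag_uncertain(p) is False
        assert assign_plwh_confidence(p, RULES) is not None

    def test_single_resultless_order_is_not_uncertain(self, sets):
        p = profile_for(sets, measurements=[vl("p", D(2021, 1, 1))])
        assert flag_uncertain(p) is False
        assert assign_plwh_confidence(p, RULES) is None  # resolves not_hiv


class TestConfidenceAssignment:
    def test_detectable_vl_is_level_1(self, sets):
        p = profile_for(sets, measurements=[vl("p", D(2021, 1, 1), value=1000.0)])
        assert assign_plwh_confidence(p, RULES) == (1, 1)

    def test_conditions_art_and_resultless_orders_is_level_2(self, sets):
        p = profile_for(
            sets,
            conditions=[cond("p", D(2020, 1, 1)), cond("p", D(2021, 1, 1))],
            measurements=[vl("p", D(2021, 2, 1)), vl("p", D(2021, 6, 1))],
            drugs=[drug("p", DOLUTEGRAVIR, D(2021, 3, 1), 90)],
        )
        level, criterion = assign_plwh_confidence(p, RULES)
        assert level == 2

    def test_single_condition_date_alone_is_level_3(self, sets):
        p = profile_for(sets, conditions=[cond("p", D(2021, 1, 1))])
        assert assign_plwh_confidence(p, RULES) == (3, 12)

    def test_condition_contradicted_by_negative_tests_is_not_hiv(self, sets):
        p = profile_for(sets, conditions=[cond("p", D(2021, 1, 1))],
                        measurements=[qual("p", D(2021, 2, 1), "negative"),
                                      qual("p", D(2021, 6, 1), "negative")])
        assert assign_plwh_confidence(p, RULES) is None

    def test_corroborated_condition_survives_negative_tests(self, sets):
        p = profile_for(sets, conditions=[cond("p", D(2021, 1, 1))],
                        measurements=[qual("p", D(2021, 2, 1), "negative")],
                        drugs=[drug("p", DARUNAVIR, D(2021, 3, 1), 90)])
        assert assign_plwh_confidence(p, RULES) is not None

    def test_suppressed_vl_on_treatment_is_level_1(self, sets):
        p = profile_for(sets, measurements=[vl("p", D(2021, 1, 1), value=20.0)],
                        drugs=[drug("p", DOLUTEGRAVIR, D(2021, 2, 1), 90)])
        assert assign_plwh_confidence(p, RULES) == (1, 5)


class TestPipeline:
    def test_eight_archetypes_assign_exactly_as_intended(self, sets, eight_person_tables):
        tables, expected = eight_person_tables
        result = run_pipeline(tables, sets)
        got = {
            pid: (a.label.value, a.confidence)
            for pid, a in result.assignments.items()
        }
        assert got == expected
        assert result.assignments["A6"].exclusion_reason is ExclusionReason.paxlovid_only

    def test_empty_population_yields_empty_assignment(self, sets):
        result = run_pipeline(Tables([], [], [], []), sets)
        assert result.assignments == {}
        assert result.summary["n_persons"] == 0

    def test_row_order_and_duplication_do_not_change_assignments(self, sets, eight_person_tables):
        tables, _ = eight_person_tables
        baseline = run_pipeline(tables, sets).assignments

        rng = random.Random(11)
        shuffled = Tables(list(tables.persons), list(tables.conditions),
                          list(tables.measurements), list(tables.drugs))
        for coll in (shuffled.conditions, shuffled.measurements, shuffled.drugs):
            rng.shuffle(coll)
        assert run_pipeline(shuffled, sets).assignments == baseline

        duplicated = Tables(list(tables.persons),
                            tables.conditions + tables.conditions,
                            tables.measurements + tables.measurements,
                            tables.drugs + tables.drugs)
        # exact duplicates are collapsed before any predicate sees them
        assert run_pipeline(duplicated, sets).assignments == baseline

    def test_person_only_in_domain_table_is_still_labeled(self, sets):
        tables = Tables([], [cond("ghost", D(2021, 1, 1))], [], [])
        result = run_pipeline(tables, sets)
        assert result.assignments["ghost"].label is Label.plwh

    def test_summary_counts_are_consistent(self, sets, eight_person_tables):
        tables, _ = eight_person_tables
        s = run_pipeline(tables, sets).summary
        assert sum(s["labels"].values()) == s["n_persons"] == 8
        assert sum(s["plwh_levels"].values()) == s["labels"]["plwh"]
        assert sum(s["plwh_criteria"].values()) == s["labels"]["plwh"]
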