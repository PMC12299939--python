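import dataclasses
import datetime as dt
import json

import pytest

from hivphenotype.config import PipelineConfig
from hivphenotype.omop_model import (
    ConceptSet,
    Domain,
    QualResult,
    concept_member,
    load_concept_sets,
    load_tables,
    write_tables,
)

from conftest import D, cd4, cond, drug, qual, vl
from hivphenotype.omop_model import PersonRecord, Tables
from hivphenotype.synthetic import DOLUTEGRAVIR, FTC_TDF


def _write_json(path, obj):
    path.write_text(json.dumps(obj))


class TestConceptSets:
    def test_single_file_parses_into_registry(self, tmp_path):
        _write_json(tmp_path / "hbv.json",
                    {"name": "hbv", "domain": "condition", "concept_ids": [111, 112]})
        reg = load_concept_sets(tmp_path / "hbv.json")
        assert set(reg) == {"hbv"}
        assert len(reg["hbv"]) == 2

    def test_duplicate_name_across_files_is_hard_error(self, tmp_path):
        obj = {"name": "hbv", "domain": "condition", "concept_ids": [1]}
        _write_json(tmp_path / "a.json", obj)
        _write_json(tmp_path / "b.json", obj)
        with pytest.raises(ValueError, match="duplicate concept set name"):
            load_concept_sets(tmp_path)

    def test_duplicate_ids_dedup_with_warning(self, tmp_path):
        _write_json(tmp_path / "s.json",
                    {"name": "s", "domain": "drug", "concept_ids": [5, 5, 6]})
        with pytest.warns(UserWarning, match="duplicate concept IDs"):
            reg = load_concept_sets(tmp_path / "s.json")
        assert len(reg["s"]) == 2

    def test_unknown_domain_is_hard_error(self, tmp_path):
        _write_json(tmp_path / "s.json",
                    {"name": "s", "domain": "visit", "concept_ids": [1]})
        with pytest.raises(ValueError, match="unknown domain"):
            load_concept_sets(tmp_path / "s.json")

    def test_empty_set_loads_with_warning(self, tmp_path):
        _write_json(tmp_path / "s.json",
                    {"name": "s", "domain": "drug", "concept_ids": []})
        with pytest.warns(UserWarning, match="empty"):
            reg = load_concept_sets(tmp_path / "s.json")
        assert len(reg["s"]) == 0

    @pytest.mark.parametrize(
        "cid,ids,expected",
        [(111, [111, 112], True), (999, [111, 112], False), (111, [], False)],
    )
    def test_concept_member(self, cid, ids, expected):
        cs = ConceptSet("s", Domain.drug, frozenset(ids))
        assert concept_member(cid, cs) is expected


def _write_tables_csv(tmp_path, person="", condition="", measurement="", drug_rows=""):
    (tmp_path / "person.csv").write_text("person_id,age,sex,race_ethnicity\n" + person)
    (tmp_path / "condition_occurrence.csv").write_text(
        "person_id,condition_concept_id,condition_start_date\n" + condition)
    (tmp_path / "measurement.csv").write_text(
        "person_id,measurement_concept_id,measurement_date,value_as_number,"
        "value_as_concept,unit,value_source_value\n" + measurement)
    (tmp_path / "drug_exposure.csv").write_text(
        "person_id,drug_concept_id,drug_exposure_start_date,days_supply,drug_source_value\n"
        + drug_rows)
    return (tmp_path / "person.csv", tmp_path / "condition_occurrence.csv",
            tmp_path / "measurement.csv", tmp_path / "drug_exposure.csv")


class TestLoadTables:
    def test_well_formed_rows_load_as_typed_records(self, tmp_path):
        paths = _write_tables_csv(
            tmp_path,
            person="p1,44,female,Unknown\n",
            drug_rows="p1,3001,2021-01-01,90,\np1,3001,2021-04-01,90,\np1,3101,2021-01-01,28,\n",
        )
        tables = load_tables(*paths)
        assert len(tables.drugs) == 3
        assert tables.drugs[0].start_date == dt.date(2021, 1, 1)
        assert tables.drugs[0].days_supply == 90
        assert tables.dropped["drug_exposure"] == 0

    def test_na_days_supply_becomes_missing(self, tmp_path):
        paths = _write_tables_csv(tmp_path, drug_rows="p1,3001,2021-01-01,NA,\n")
        tables = load_tables(*paths)
        assert len(tables.drugs) == 1
        assert tables.drugs[0].days_supply is None

    def test_uncoercible_numeric_value_drops_row(self, tmp_path):
        paths = _write_tables_csv(
            tmp_path,
            measurement="p1,2101,2021-01-01,abc,,,\np1,2101,2021-02-01,1000,,copies/mL,\n",
        )
        tables = load_tables(*paths)
        assert len(tables.measurements) == 1
        assert tables.dropped["measurement"] == 1

    def test_missing_required_column_is_hard_error(self, tmp_path):
        paths = _write_tables_csv(tmp_path)
        (tmp_path / "drug_exposure.csv").write_text("person_id,drug_concept_id\n")
        with pytest.raises(ValueError, match="missing required column"):
            load_tables(*paths)

    def test_qualitative_synonyms_normalize_at_load(self, tmp_path):
        paths = _write_tables_csv(
            tmp_path,
            measurement=(
                "p1,2001,2021-01-01,,Reactive,,\n"
                "p1,2001,2021-02-01,,Not Detected,,\n"
                "p1,2001,2021-03-01,,indeterminate,,\n"
            ),
        )
        tables = load_tables(*paths)
        results = [m.value_as_concept for m in tables.measurements]
        assert results == [QualResult.positive, QualResult.negative, QualResult.none]

    def test_condition_rows_before_date_floor_are_dropped(self, tmp_path):
        paths = _write_tables_csv(
            tmp_path, condition="p1,1001,2015-06-01\np1,1001,2019-06-01\n")
        tables = load_tables(*paths)
        assert len(tables.conditions) == 1
        assert tables.dropped["condition_occurrence"] == 1

    def test_person_ids_never_altered(self, tmp_path):
        paths = _write_tables_csv(tmp_path, person="0007,30,male,Unknown\n",
                                  drug_rows="0007,3001,2021-01-01,90,\n")
        tables = load_tables(*paths)
        assert tables.persons[0].person_id == "0007"
        assert tables.drugs[0].person_id == "0007"


def test_write_then_load_round_trips_every_field(tmp_path):
    tables = Tables(
        persons=[PersonRecord("p1", 44.0, "female", "Unknown"),
                 PersonRecord("p2", None, "other_unknown", "Non-Hispanic White")],
        conditions=[cond("p1", D(2020, 1, 2))],
        measurements=[
            vl("p1", D(2020, 2, 3), value=1000.0),
            vl("p1", D(2020, 3, 4)),                       # resultless order
            qual("p2", D(2021, 1, 1), "negative"),
            cd4("p1", D(2020, 2, 3), value=150.0),
        ],
        drugs=[drug("p1", DOLUTEGRAVIR, D(2020, 4, 5), 90),
               drug("p2", FTC_TDF, D(2021, 6, 7), None, source="TRUVADA")],
    )
    paths = write_tables(tables, tmp_path)
    reloaded = load_tables(paths["person"], paths["condition_occurrence"],
                           paths["measurement"], paths["drug_exposure"])
    assert reloaded.persons == tables.persons
    assert reloaded.conditions == tables.conditions
    assert reloaded.measurements == tables.measurements
    assert reloaded.drugs == tables.drugs
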