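"""OMOP-shaped data model: typed records, table IO and concept sets.

The phenotype consumes four delimited tables shaped like the OMOP CDM
``person``, ``condition_occurrence``, ``measurement`` and ``drug_exposure``
domains, plus a registry of named, *pre-expanded* concept sets (flat lists of
integer concept IDs; vocabulary-descendant traversal happens upstream, e.g.
in OHDSI Atlas, and is out of scope here).

Loading is deliberately forgiving about row-level data quality — rows that
fail type coercion are dropped and counted, optional fields coerce to
``None`` — but strict about structure: a missing required column or a
duplicate concept-set name is a hard error.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import enum
import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .config import DEFAULT_CONFIG, PipelineConfig

log = logging.getLogger(__name__)


class Domain(str, enum.Enum):
    condition = "condition"
    measurement = "measurement"
    drug = "drug"


class QualResult(str, enum.Enum):
    """Normalized qualitative lab result."""

    positive = "positive"
    negative = "negative"
    none = "none"


@dataclasses.dataclass(frozen=True)
class ConceptSet:
    """A named, pre-expanded set of OMOP concept IDs."""

    name: str
    domain: Domain
    concept_ids: frozenset[int]

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.concept_ids):
            raise ValueError(f"concept set {self.name!r}: concept IDs must be positive")

    def __contains__(self, concept_id: int) -> bool:
        return concept_id in self.concept_ids

    def __len__(self) -> int:
        return len(self.concept_ids)


def concept_member(concept_id: int, concept_set: ConceptSet) -> bool:
    """True iff ``concept_id`` belongs to the (pre-expanded) set."""
    return concept_id in concept_set.concept_ids


@dataclasses.dataclass(frozen=True)
class PersonRecord:
    person_id: str
    age_years: float | None = None
    sex: str = "other_unknown"  # female | male | other_unknown
    race_ethnicity: str = "Unknown"


@dataclasses.dataclass(frozen=True)
class ConditionRecord:
    person_id: str
    condition_concept_id: int
    start_date: dt.date


@dataclasses.dataclass(frozen=True)
class MeasurementRecord:
    person_id: str
    measurement_concept_id: int
    date: dt.date
    value_as_number: float | None = None
    value_as_concept: QualResult = QualResult.none
    unit: str | None = None
    value_source_text: str | None = None  # raw text e.g. "<20 copies/mL"


@dataclasses.dataclass(frozen=True)
class DrugExposureRecord:
    person_id: str
    drug_concept_id: int
    start_date: dt.date
    days_supply: int | None = None
    drug_source_value: str | None = None


# ---------------------------------------------------------------------------
# concept-set IO
# ---------------------------------------------------------------------------

class ConceptSetRegistry(dict):
    """Mapping name -> ConceptSet with uniqueness enforcement."""

    def add(self, cs: ConceptSet) -> None:
        if cs.name in self:
            raise ValueError(f"duplicate concept set name: {cs.name!r}")
        self[cs.name] = cs


def _parse_concept_set(obj: Mapping) -> ConceptSet:
    try:
        name = obj["name"]
        domain = Domain(obj["domain"])
        ids = list(obj["concept_ids"])
    except KeyError as exc:
        raise ValueError(f"concept set JSON missing key: {exc}") from exc
    except ValueError as exc:
        raise ValueError(f"concept set {obj.get('name')!r}: unknown domain {obj.get('domain')!r}") from exc
    unique = frozenset(int(i) for i in ids)
    if len(unique) < len(ids):
        warnings.warn(f"concept set {name!r}: duplicate concept IDs removed", stacklevel=2)
    if not unique:
        warnings.warn(f"concept set {name!r}: empty concept_ids (placeholder set)", stacklevel=2)
    return ConceptSet(name=name, domain=domain, concept_ids=unique)


def load_concept_sets(path: str | Path) -> ConceptSetRegistry:
    """Load concept sets from a JSON file or a directory of JSON files.

    Each file holds either one object ``{name, domain, concept_ids}`` or a
    list of such objects.  Duplicate names across files are a hard error;
    empty sets load with a warning so placeholder sets can be shipped.
    """
    path = Path(path)
    files = sorted(path.glob("*.json")) if path.is_dir() else [path]
    if not files:
        raise FileNotFoundError(f"no concept-set JSON found under {path}")
    registry = ConceptSetRegistry()
    for file in files:
        raw = json.loads(file.read_text())
        objs = raw if isinstance(raw, list) else [raw]
        for obj in objs:
            registry.add(_parse_concept_set(obj))
    return registry


def builtin_concept_sets() -> ConceptSetRegistry:
    """The toy concept sets shipped with the package (stable small integers).

    These stand in for the real (vocabulary-derived) sets so the tool and its
    synthetic cohorts are self-contained; swap in real concept-set JSONs for
    production use.
    """
    return load_concept_sets(Path(__file__).parent / "data" / "concept_sets")


# ---------------------------------------------------------------------------
# table IO
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Tables:
    """The four loaded domains plus per-table dropped-row counts."""

    persons: list[PersonRecord]
    conditions: list[ConditionRecord]
    measurements: list[MeasurementRecord]
    drugs: list[DrugExposureRecord]
    dropped: dict[str, int] = dataclasses.field(default_factory=dict)

    def person_ids(self) -> list[str]:
        """Every person appearing anywhere, sorted (person table first-class)."""
        ids = {p.person_id for p in self.persons}
        for coll in (self.conditions, self.measurements, self.drugs):
            ids.update(r.person_id for r in coll)
        return sorted(ids)


_REQUIRED = {
    "person": ["person_id"],
    "condition_occurrence": ["person_id", "condition_concept_id", "condition_start_date"],
    "measurement": ["person_id", "measurement_concept_id", "measurement_date"],
    "drug_exposure": ["person_id", "drug_concept_id", "drug_exposure_start_date"],
}


def _read(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def _require(df: pd.DataFrame, table: str) -> None:
    missing = [c for c in _REQUIRED[table] if c not in df.columns]
    if missing:
        raise ValueError(f"{table}: missing required column(s) {missing}")


def _is_missing(v) -> bool:
    if v is None:
        return True
    s = str(v).strip()
    return s == "" or s.upper() in {"NA", "NAN", "NULL", "NONE"}


def _coerce_date(v) -> dt.date | None:
    if _is_missing(v):
        return None
    try:
        return dt.date.fromisoformat(str(v).strip()[:10])
    except ValueError:
        return None


def _coerce_float(v) -> tuple[float | None, bool]:
    """Return (value, ok). Missing -> (None, True); garbage -> (None, False)."""
    if _is_missing(v):
        return None, True
    try:
        return float(str(v).strip()), True
    except ValueError:
        return None, False


def _coerce_int(v) -> tuple[int | None, bool]:
    f, ok = _coerce_float(v)
    if not ok or f is None:
        return None, ok
    return int(f), True


def normalize_qual(text, synonyms: Mapping[str, str]) -> QualResult:
    """Normalize a free-text qualitative result to the 3-value enum."""
    if _is_missing(text):
        return QualResult.none
    return QualResult(synonyms.get(str(text).strip().lower(), "none"))


def load_tables(
    person_path: str | Path,
    condition_path: str | Path,
    measurement_path: str | Path,
    drug_path: str | Path,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> Tables:
    """Load and validate the four OMOP-shaped tables.

    Rows failing type coercion on a required field (bad dates, non-numeric
    values in numeric columns) are dropped and counted in ``Tables.dropped``.
    ``person_id`` values are never altered.  A person_id appearing in a
    domain table but not in the person table is kept with a warning.
    """
    dropped: dict[str, int] = {}

    pdf = _read(person_path)
    _require(pdf, "person")
    persons, n_drop = [], 0
    for row in pdf.to_dict("records"):
        age, ok = _coerce_float(row.get("age", row.get("age_years")))
        if not ok:
            n_drop += 1
            continue
        sex = str(row.get("sex", "")).strip().lower()
        persons.append(
            PersonRecord(
                person_id=str(row["person_id"]),
                age_years=age,
                sex=sex if sex in {"female", "male"} else "other_unknown",
                race_ethnicity=str(row.get("race_ethnicity", "Unknown")) or "Unknown",
            )
        )
    dropped["person"] = n_drop
    known = {p.person_id for p in persons}

    cdf = _read(condition_path)
    _require(cdf, "condition_occurrence")
    conditions, n_drop = [], 0
    for row in cdf.to_dict("records"):
        cid, ok = _coerce_int(row["condition_concept_id"])
        date = _coerce_date(row["condition_start_date"])
        if not ok or cid is None or date is None or date < config.condition_date_floor:
            n_drop += 1
            continue
        conditions.append(ConditionRecord(str(row["person_id"]), cid, date))
    dropped["condition_occurrence"] = n_drop

    mdf = _read(measurement_path)
    _require(mdf, "measurement")
    measurements, n_drop = [], 0
    for row in mdf.to_dict("records"):
        mid, ok_id = _coerce_int(row["measurement_concept_id"])
        date = _coerce_date(row["measurement_date"])
        value, ok_val = _coerce_float(row.get("value_as_number"))
        if not ok_id or not ok_val or mid is None or date is None:
            n_drop += 1
            continue
        unit = row.get("unit")
        text = row.get("value_source_value")
        measurements.append(
            MeasurementRecord(
                person_id=str(row["person_id"]),
                measurement_concept_id=mid,
                date=date,
                value_as_number=value,
                value_as_concept=normalize_qual(row.get("value_as_concept"), config.qual_synonyms),
                unit=None if _is_missing(unit) else str(unit).strip(),
                value_source_text=None if _is_missing(text) else str(text).strip(),
            )
        )
    dropped["measurement"] = n_drop

    ddf = _read(drug_path)
    _require(ddf, "drug_exposure")
    drugs, n_drop = [], 0
    for row in ddf.to_dict("records"):
        did, ok_id = _coerce_int(row["drug_concept_id"])
        date = _coerce_date(row["drug_exposure_start_date"])
        supply, ok_sup = _coerce_int(row.get("days_supply"))
        if not ok_id or not ok_sup or did is None or date is None or (supply is not None and supply < 0):
            n_drop += 1
            continue
        src = row.get("drug_source_value")
        drugs.append(
            DrugExposureRecord(
                person_id=str(row["person_id"]),
                drug_concept_id=did,
                start_date=date,
                days_supply=supply,
                drug_source_value=None if _is_missing(src) else str(src).strip(),
            )
        )
    dropped["drug_exposure"] = n_drop

    tables = Tables(persons, conditions, measurements, drugs, dropped)
    orphans = {r.person_id for coll in (conditions, measurements, drugs) for r in coll} - known
    if orphans:
        log.warning("%d person_id(s) in domain tables absent from person table", len(orphans))
    total_dropped = sum(dropped.values())
    if total_dropped:
        log.info("dropped %d row(s) failing type coercion: %s", total_dropped, dropped)
    return tables


def write_tables(tables: Tables, out_dir: str | Path) -> dict[str, Path]:
    """Write the four tables back to CSV (inverse of :func:`load_tables`)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    pdf = pd.DataFrame(
        [
            {
                "person_id": p.person_id,
                "age": "" if p.age_years is None else p.age_years,
                "sex": p.sex,
                "race_ethnicity": p.race_ethnicity,
            }
            for p in tables.persons
        ],
        columns=["person_id", "age", "sex", "race_ethnicity"],
    )
    paths["person"] = out / "person.csv"
    pdf.to_csv(paths["person"], index=False)

    cdf = pd.DataFrame(
        [
            {
                "person_id": c.person_id,
                "condition_concept_id": c.condition_concept_id,
                "condition_start_date": c.start_date.isoformat(),
            }
            for c in tables.conditions
        ],
        columns=["person_id", "condition_concept_id", "condition_start_date"],
    )
    paths["condition_occurrence"] = out / "condition_occurrence.csv"
    cdf.to_csv(paths["condition_occurrence"], index=False)

    mdf = pd.DataFrame(
        [
            {
                "person_id": m.person_id,
                "measurement_concept_id": m.measurement_concept_id,
                "measurement_date": m.date.isoformat(),
                "value_as_number": "" if m.value_as_number is None else m.value_as_number,
                "value_as_concept": "" if m.value_as_concept is QualResult.none else m.value_as_concept.value,
                "unit": m.unit or "",
                "value_source_value": m.value_source_text or "",
            }
            for m in tables.measurements
        ],
        columns=[
            "person_id", "measurement_concept_id", "measurement_date",
            "value_as_number", "value_as_concept", "unit", "value_source_value",
        ],
    )
    paths["measurement"] = out / "measurement.csv"
    mdf.to_csv(paths["measurement"], index=False)

    ddf = pd.DataFrame(
        [
            {
                "person_id": d.person_id,
                "drug_concept_id": d.drug_concept_id,
                "drug_exposure_start_date": d.start_date.isoformat(),
                "days_supply": "" if d.days_supply is None else d.days_supply,
                "drug_source_value": d.drug_source_value or "",
            }
            for d in tables.drugs
        ],
        columns=[
            "person_id", "drug_concept_id", "drug_exposure_start_date",
            "days_supply", "drug_source_value",
        ],
    )
    paths["drug_exposure"] = out / "drug_exposure.csv"
    ddf.to_csv(paths["drug_exposure"], index=False)
    return paths


def load_tables_dir(directory: str | Path, config: PipelineConfig = DEFAULT_CONFIG) -> Tables:
    """Load the four conventionally named CSVs from one directory."""
    d = Path(directory)
    return load_tables(
        d / "person.csv",
        d / "condition_occurrence.csv",
        d / "measurement.csv",
        d / "drug_exposure.csv",
        config=config,
    )
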