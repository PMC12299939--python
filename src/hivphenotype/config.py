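"""Pipeline configuration.

All clinically meaningful thresholds and switches live here so that the
classification cascade itself stays purely declarative.  Defaults encode the
published rule set: a viral load (VL) of >=50 copies/mL counts as detectable,
a CD4 count <=200 cells/uL as advanced immunosuppression, a post-exposure
prophylaxis (PEP) course is shorter than 30 days, and ritonavir exposures on
or after 2020-01-01 are ambiguous with nirmatrelvir/ritonavir (Paxlovid).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from pathlib import Path

#: qualitative-result strings mapped to the 3-value interpretation enum;
#: anything not listed (case-insensitive) normalizes to "none".
DEFAULT_QUAL_SYNONYMS: dict[str, str] = {
    "positive": "positive",
    "detected": "positive",
    "reactive": "positive",
    "pos": "positive",
    "negative": "negative",
    "not detected": "negative",
    "nonreactive": "negative",
    "non-reactive": "negative",
    "neg": "negative",
}


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the phenotyping cascade.

    Parameters
    ----------
    vl_threshold : float
        Copies/mL at or above which a viral load is "detectable" (default 50).
    cd4_threshold : float
        Cells/uL at or below which a CD4 count flags immunosuppression (200).
    strict_units : bool
        When True a CD4 value without a recorded unit is uninterpretable
        ("unknown"); when False (default) the value is accepted as cells/uL.
    cd4_alone_candidacy : bool
        Whether CD4 test orders by themselves pull a person into the candidate
        pool.  Off by default: CD4 counts are ordered for many non-HIV
        indications, so CD4 evidence only matters once another evidence class
        creates candidacy.
    ritonavir_cutoff : datetime.date
        Ritonavir exposures starting on/after this date (inclusive) are
        potentially COVID-19 therapy rather than a pharmacokinetic booster.
    pep_max_days_supply : int
        A PEP regimen component must have a supply strictly below this (or a
        null supply).
    condition_date_floor : datetime.date
        Condition rows dated before this floor are dropped at load time.
    obfuscation_threshold : int
        Displayed counts below this are masked in reports.
    qual_synonyms : mapping
        Free-text qualitative result -> {"positive", "negative"}.
    """

    vl_threshold: float = 50.0
    cd4_threshold: float = 200.0
    strict_units: bool = False
    cd4_alone_candidacy: bool = False
    ritonavir_cutoff: dt.date = dt.date(2020, 1, 1)
    pep_max_days_supply: int = 30
    condition_date_floor: dt.date = dt.date(2018, 1, 1)
    obfuscation_threshold: int = 20
    qual_synonyms: dict[str, str] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_QUAL_SYNONYMS)
    )

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        for key in ("ritonavir_cutoff", "condition_date_floor"):
            if key in raw:
                raw[key] = dt.date.fromisoformat(raw[key])
        return cls(**raw)


DEFAULT_CONFIG = PipelineConfig()
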