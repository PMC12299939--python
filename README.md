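# hivphenotype

Rule-based computational phenotyping of HIV status from OMOP-shaped
electronic health record (EHR) tables.

Identifying people living with HIV (PLWH) in EHR repositories from
diagnostic codes alone misclassifies badly: condition codes get applied
during screening visits, to PrEP and PEP users, and — since the arrival of
nirmatrelvir/ritonavir for COVID-19 — a lone antiretroviral exposure no
longer implies HIV treatment. `hivphenotype` implements a cascade that
combines three evidence classes (condition occurrences, laboratory
measurements, drug exposures) to partition a population into five mutually
exclusive cohorts:

| label | meaning |
|---|---|
| `plwh` | person living with HIV, with a confidence level 1–3 (1 strongest) and the criterion that fired |
| `prep` | pre-exposure prophylaxis user, with a confidence level 1–3 |
| `pep` | post-exposure prophylaxis user (a single short combination regimen) |
| `uncertain` | unadjudicable evidence: repeat resultless viral-load orders, or COVID-era ritonavir of unknown indication |
| `not_hiv` | everyone else, including carve-out exclusions (hepatitis-B monotherapy with tenofovir, Paxlovid-only ritonavir) and condition codes contradicted by negative tests |

It is aimed at observational-health researchers who need HIV cohorts from
OMOP CDM data (or anything shaped like its `person`,
`condition_occurrence`, `measurement` and `drug_exposure` domains) with an
explicit, auditable handle on misclassification.

## The cascade

1. **Candidates** — anyone with an HIV condition code, an HIV lab order
   (antigen/antibody, viral load), or an HIV-related drug exposure.
2. **PrEP carve-out** — emtricitabine/tenofovir exposure without an HIV
   condition or positive lab (VL ≥50 copies/mL, positive antigen/antibody,
   CD4 ≤200 cells/µL); persons with a chronic hepatitis-B condition are
   excluded as probable HBV monotherapy.
3. **PEP carve-out** — exactly one same-date regimen of
   emtricitabine/tenofovir plus dolutegravir or raltegravir, each component
   supplied <30 days (or null), and no other HIV drug rows.
4. **Ritonavir resolution** — drug-only candidates whose only exposure is
   ritonavir on/after 2020-01-01: Paxlovid-flagged rows → `not_hiv`;
   otherwise `uncertain`. Ritonavir next to another protease inhibitor is a
   booster and stays in the PLWH pathway.
5. **Uncertain flag** — ≥2 viral-load orders, none with a result, and no
   other evidence.
6. **Confidence typing** — a first-match-wins registry of 12 criteria
   assigns level 1 (positive lab results), level 2 (corroborated evidence
   without lab results) or level 3 (drug exposure alone or a single
   diagnosis); condition codes contradicted by exclusively negative tests
   with no corroboration resolve to `not_hiv`.

Everything is configurable: thresholds (`PipelineConfig`), concept sets
(pre-expanded JSON ID lists), and the criterion registry itself (JSON).
The package also ships a synthetic cohort generator with per-person ground
truth and the annotation-validation metrics (confusion matrices,
sensitivity/specificity/PPV/NPV/F1, Cohen's κ) used to verify recovery.

## Worked example

Generate a 200-person synthetic population with known ground truth and
phenotype it:

```bash
hiv-phenotype simulate --n 200 --seed 11 --out demo/data
hiv-phenotype run --tables demo/data --out demo/out
```

`demo/out/summary.json` (abridged):

```json
{
  "n_persons": 200,
  "labels": {"plwh": 52, "prep": 38, "pep": 8, "uncertain": 25, "not_hiv": 77},
  "plwh_levels": {"1": 19, "2": 16, "3": 17},
  "prep_levels": {"1": 10, "2": 9, "3": 19},
  "exclusions": {"paxlovid_only": 13, "hbv_monoinfection": 14}
}
```

The five label counts partition the 200 persons. Among the 52 PLWH, 19
carry level-1 confidence (positive lab results), 16 level-2 and 17
level-3; 13 persons with only Paxlovid-pattern ritonavir and 14 tenofovir
users with hepatitis B were kept out of the HIV/PrEP cohorts. Comparing
`demo/out/assignments.csv` against `demo/data/truth.csv` shows exact
label-and-confidence recovery, because the simulation ran with all noise
rates at zero.

The same thing in Python:

```python
from hivphenotype import builtin_concept_sets, run_pipeline
from hivphenotype.synthetic import SyntheticSpec, generate_cohort

tables, truth, _ = generate_cohort(SyntheticSpec(n_persons=200, seed=11))
result = run_pipeline(tables, builtin_concept_sets())
print(result.summary["labels"])
```

## Caveats

The shipped concept sets are small stable toy IDs so the tool is
self-contained; for production use, export real pre-expanded concept sets
(e.g. from OHDSI Atlas, including vocabulary descendants) to the same JSON
schema and pass them via `--concepts`. The 12 default confidence criteria
are a documented reconstruction — override them with `--criteria` if your
protocol differs. See `docs/methods.md` for the full model description,
parameter table and limitations.
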