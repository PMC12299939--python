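# Methods

## Problem and model

`hivphenotype` implements a deterministic, rule-based computational
phenotype: given OMOP-shaped EHR tables and pre-expanded concept sets, it
assigns every person exactly one of five labels (`plwh`, `prep`, `pep`,
`uncertain`, `not_hiv`), a confidence level for the PLWH and PrEP cohorts,
and the id of the criterion that fired. There is no fitting step and no
stochastic component in classification; the scientific content is the
ordering and the predicates of the cascade, which encode how three evidence
classes — condition codes, laboratory measurements and drug exposures —
corroborate or contradict one another.

The central difficulty the cascade addresses is dual-indication evidence:

* emtricitabine/tenofovir is HIV treatment backbone, PrEP, *and* (tenofovir
  alone) hepatitis-B therapy;
* ritonavir is a pharmacokinetic booster in HIV regimens *and* a component
  of nirmatrelvir/ritonavir (Paxlovid) for COVID-19, so after 2020-01-01 a
  lone ritonavir row is uninformative about HIV;
* HIV condition codes are applied during screening and prophylaxis visits,
  so a code contradicted by exclusively negative tests is treated as
  miscoding, not disease;
* lab orders frequently arrive without interpretable results after
  multi-site harmonization, so "ordered, no result" (`unknown`) is kept
  distinct from "never ordered" (`null`) everywhere.

## Laboratory interpretation

Viral load (VL) categories: `ge50` (detectable, ≥50 copies/mL), `lt50`
(suppressed), `unknown` (ordered without an interpretable result), `null`
(never ordered). CD4 categories: `le200` (≤200 cells/µL, advanced
immunosuppression), `gt200`, `unknown`, `null`. Both thresholds are
inclusive on the clinically meaningful side (exactly 50 is detectable,
exactly 200 is low). Per-person rollup takes the *worst* category under
the dominance orders `ge50 > lt50 > unknown > null` and
`le200 > gt200 > unknown > null` — "ever" semantics, since the phenotype
uses any-time evidence. Censored text results such as "<20 copies/mL"
count as suppressed when the assay floor is at or below the threshold; a
floor above it (e.g. "<400") is uninterpretable for the 50-copy rule and
maps to `unknown`. A CD4 value without a unit is accepted as cells/µL by
default (`strict_units=False`); strict mode maps it to `unknown`.

One documented ambiguity: the source protocol defines detectable as
≥50 copies/mL in its methods but writes ">50" once in its results prose;
this implementation follows the methods definition (50 → `ge50`).

## Cascade order and adjudication

Candidates are persons with ≥1 HIV condition, ≥1 HIV lab order
(antigen/antibody or VL), or ≥1 HIV-related drug row. CD4 orders alone do
not create candidacy by default (`cd4_alone_candidacy=False`): CD4 counts
are ordered for many non-HIV indications, and admitting them alone would
flood the candidate pool with immunology patients; a low CD4 still
contributes once any other evidence class creates candidacy.

Drug-only candidates (no condition, no positive lab) pass through the
carve-outs in order: PrEP, PEP, ritonavir resolution. Two reconstruction
choices matter here:

* **PrEP vs PEP.** A PEP user necessarily has an emtricitabine/tenofovir
  row, so a PrEP rule keyed only on backbone exposure would absorb every
  PEP user and the PEP rule could never fire. The PrEP predicate therefore
  excludes persons whose entire HIV drug history is a single PEP regimen
  instance (same-date backbone + dolutegravir/raltegravir, all supplies
  <30 days or null). Genuine PrEP users are unaffected: repeat dispensing
  spans multiple dates.
* **"One row of data" for PEP** is read as one *regimen instance*: the
  same-date component rows count as that instance, and no other HIV drug
  rows may exist on any other date. A literal single-row reading would make
  a two-drug criterion unsatisfiable.

Condition codes contradicted by negative tests: a person with HIV
condition codes, at least one negative antigen/antibody test, no positive
result, no HIV treatment exposure, no VL orders and no low CD4 resolves to
`not_hiv` (miscoded). Any of those corroborators — treatment rows, VL
orders, CD4 ≤200 — keeps the person in the PLWH pathway; repeated VL
monitoring in particular is treated as consistent with a correctly
assigned diagnosis.

A single resultless VL order (not "repeat") resolves to `not_hiv`, not
`uncertain`: one screening order without a result is far more often
screening than monitoring, and the uncertain class is reserved for
patterns that plausibly represent suppressed-VL care.

## Confidence criteria

The 12 default criteria (first match wins, ascending id) are listed in
`src/hivphenotype/data/criteria_default.json`. Level 1 (ids 1–6) requires
a positive lab signal, including suppressed VL *on treatment* (id 5) —
viral suppression is itself evidence of effective therapy. Level 2 (ids
7–9) covers corroborated evidence without usable lab results. Level 3 (ids
10–12) is drug exposure alone or a single diagnosis date. The source
protocol publishes only the level semantics and per-criterion counts, so
these predicates are this package's reconstruction; the registry is a JSON
interface precisely so a site can substitute its exact rules. Criterion 9
is "≥2 distinct condition dates" with or without lab orders: repeated
diagnosis dates alone must land somewhere, and multiple dates constitute
corroboration (level 2) rather than weak evidence.

Exhaustiveness is enforced: a surviving candidate that matches no
adjudication trigger and no criterion raises rather than being silently
dropped.

Duplicate handling: exact duplicate rows are collapsed before any
predicate runs (there is no visit structure to distinguish them), and all
counting predicates otherwise use distinct dates where temporality
matters. Consequently assignments are invariant to row order and row
duplication, and the whole pipeline is deterministic.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `vl_threshold` | 50 | copies/mL | detectability cut, inclusive |
| `cd4_threshold` | 200 | cells/µL | advanced immunosuppression, inclusive |
| `pep_max_days_supply` | 30 | days | PEP course strictly shorter |
| `ritonavir_cutoff` | 2020-01-01 | date (inclusive) | start of plausible COVID-19 indication |
| `condition_date_floor` | 2018-01-01 | date | data-window floor; earlier rows dropped at load |
| `strict_units` | off | — | permissive CD4 reading by default |
| `cd4_alone_candidacy` | off | — | CD4 orders are not HIV-specific |
| `obfuscation_threshold` | 20 | persons | governance-style small-cell masking |

## Synthetic cohorts

The generator emits 11 archetypes — `plwh_L1/L2/L3` (with intra-archetype
variants covering all 12 criteria), `prep_L1/L2/L3`, `pep`,
`paxlovid_only`, `uncertain_vl`, `hbv_tdf`, `negative` — whose rows
satisfy the target label's defining predicate exactly before noise. Dates
are integer offsets inside 2018-01-01..2023-11-02 (the emulated data
window) and all randomness flows through one seeded NumPy generator, so
output is byte-reproducible.

The default class mix is deliberately balanced-ish (24% negative, the rest
spread over the evidence-bearing archetypes) rather than
population-realistic: the phenotype's behavior is exercised per archetype,
and a realistic ~99%-negative mix would leave small cohorts empty at the
problem sizes used here (500 persons for recovery runs, 2000 for the
annotation exercise — sizes chosen so every stratum is well populated
while runs stay interactive). Prevalence-dependent quantities (e.g. PPV
against population truth) therefore do not transfer to real data from
these defaults; supply a custom mix to study them.

Three noise mechanisms emulate the real misclassification drivers:
`miscode_condition_rate` (an HIV condition code landing on a person
without HIV evidence), `resultless_lab_rate` (a result lost in ingestion)
and `cd4_unit_drop_rate` (a CD4 value without units). All default to 0;
noise is opt-in. What noise-free recovery shows is that the cascade
inverts the generator's archetypes exactly; it does not validate the
clinical rules against real charts, which requires annotation against
source data.

The generator does not model visit structure, coding intensity, site
heterogeneity, PrEP-to-HIV seroconversion timelines, or long-acting
injectable PrEP (cabotegravir/lenacapavir), and its demographics are
simple categorical draws that do not enter classification.

## Validation metrics

The evaluation module mirrors a blinded annotation exercise: a stratified
without-replacement sample (default 90/10/10/10 over
PLWH/PrEP/PEP/not-HIV, n=120), per-rater confusion matrices, one-vs-rest
sensitivity/specificity/PPV/NPV/precision/recall/F1, and pairwise Cohen's
κ. Zero-denominator metrics are reported as undefined (`None`), never 0 —
with 10-person strata, empty cells are routine. κ uses the standard
marginal-product expected agreement; the degenerate single-shared-class
case (pₑ=1, which forces pₒ=1) is defined as κ=1. Implementations are
closed-form and are cross-checked in the test suite against scikit-learn
on randomized inputs.

## Reporting

Counts below the obfuscation threshold are masked at display time only
("<20"); exact integers are available behind an explicit `--unsafe-exact`
flag. Percentages round half-up to one decimal with the trailing ".0"
stripped; a nonzero count that would display "0.0" extends to two decimals
instead (so small shares like 0.02% stay visible). The source tables this
formatting emulates mix precisions inconsistently for sub-0.05% shares;
the two-decimal fallback is this package's single consistent rule. The
PLWH evidence-source breakdown partitions the cohort into the 7 nonempty
intersections of {conditions, labs, drugs}.

## Known limitations

* The default criteria and PrEP tiers are reconstructions of a protocol
  whose exact appendix-level rules are not public; sites should override
  the JSON registries with their own definitions where available.
* No temporal incidence dating: the phenotype uses any-time evidence and
  cannot say when a person acquired HIV, nor distinguish PEP users who
  later seroconvert.
* Concept sets are consumed pre-expanded; vocabulary traversal and
  concept-set authoring are upstream concerns.
* CD4 percentage measurements and longitudinal suppression trajectories
  are out of scope (only the absolute count and worst-ever categories are
  used).
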