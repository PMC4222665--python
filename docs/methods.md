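# Methods

## Scope and data model

`pneumoclass` operates on seven flat tables treated as one linked unit (a
`CohortBundle`): hospital discharge abstracts (up to six ICD-9-CM diagnoses
and six procedures per stay, discharge status, ICU-contact flag, hospital
type, facility region), outpatient dialysis/chemotherapy services, drug
dispensings (domiciliary oxygen), influenza vaccinations, a mortality
register (at most one record per person), patient demographics, and census
resident counts per (year, 5-year age band, gender). Record linkage is exact
on an opaque patient identifier, as in regional information systems where
records are deterministically keyed; probabilistic linkage is out of scope.
Out-of-region hospitalisations of residents are ordinary admission rows
flagged `facility_region=other` — they complete episode capture and exposure
ascertainment but need no separate table.

Dates are ISO-8601 calendar dates and every interval is a whole-day
difference. Multi-valued code fields are pipe-delimited strings in one CSV
column, so the on-disk format round-trips byte-identically.

## Code sets

All ICD-9-CM lists are configuration with documented defaults, matched by
*dotless prefix* (`"480.1"` → `"4801"`, matching prefix `"480"`); three-digit
prefixes deliberately capture all fourth/fifth-digit children, the standard
category-level convention in claims phenotyping. Defaults:

* pneumonia case definition: 480–486, 487.0;
* complications of pneumonia: 510.0, 510.9, 511.1, 511.9, 513.0;
* COPD: 490, 491, 492, 494, 496;
* trauma: 800–959;
* surgery: any operative-chapter procedure 01–86;
* continuous invasive mechanical ventilation: 96.7x;
* acute stroke: 430–434, 436;
* respiratory failure: 518.5, 518.8x, 799.1;
* fourteen comorbidity categories with conventional groupings (heart
  failure 428; diabetes 250; chronic kidney 585–586; malignancy 140–208;
  hypertension 401–405; ischaemic heart 410–414; other heart disease
  420–425, 429; arrhythmias 426–427; cerebrovascular 430–438; digestive
  530–537, 555–558, 560, 562, 571, 577; anaemias/coagulopathies 280–287;
  neurological 330–335, 340–345, 348; psychiatric 290, 295–298, 300, 311;
  chronic respiratory other than COPD 493, 495, 500–505, 515–517);
* thirteen aetiology groups in a fixed priority order (specific organisms —
  Pseudomonas 482.1, Klebsiella 482.0, MSSA 482.41, E. coli 482.82, other
  gram-negatives 482.83, unspecified staphylococcus 482.40, pneumococcus
  481, other specified bacteria 482.8x — before chemical inhalation 506 and
  the unspecified categories 482.9, 485, 486; anything unmatched falls to
  `other`).

The exact registry lists used in production systems vary; keeping them
swappable makes the *algorithm* exact while the lists remain local policy.
`pneumoclass show-codesets` prints whatever configuration is in force.

## Episode construction

Selection is by **discharge date** inside the study window (2006-01-01 to
2008-12-31 by default) — the convention of discharge-abstract systems —
while **admission date** anchors age and every lookback window. Age is whole
years at admission.

Deduplication uses a rolling rule: scanning each patient's candidates in
admission-date order, a candidate is suppressed iff its admission date is
≤ 30 days after the admission date of the most recent *retained* episode.
The boundary is inclusive (day 30 suppressed, day 31 a new episode) and the
window is rolling rather than anchored, matching the incident-episode
convention of prior regional studies; both choices are declared here because
the verbal rule "only the first of multiple admissions over 30 days" does
not fix them. Same-day ties keep the earlier discharge, then the smaller
admission identifier, so the retained set is independent of input row order.
Transfer chains are not merged: consecutive stays count as distinct records
unless the 30-day rule absorbs them.

## Subtype rules

* **HCAP** — at least one of: dialysis ≤ 30 days before admission;
  chemotherapy ≤ 30 days; a prior acute-care stay discharged ≤ 180 days
  before the index admission that either lasted ≥ 2 days or carried any
  surgical procedure (regardless of that stay's length). All windows are
  inclusive at the stated bound and end the day before the index admission:
  day counts are ≥ 1 and the index admission can never qualify itself.
  Criterion-3 recency is measured from the prior stay's *discharge* date,
  which is also what makes the "within 10 days of a hospital stay"
  statistic well defined. The nursing-home residence criterion of the
  original clinical HCAP definition requires a residence registry and is
  deliberately absent. When several criteria fire, the recorded reason
  follows the listed order (dialysis, chemotherapy, prior stay).
* **PNP** — pneumonia secondary-only, principal diagnosis not in
  pneumonia ∪ complications ∪ COPD. A trauma principal satisfies this and
  is flagged as the classic special case rather than treated as a separate
  sufficient condition.
* **CAP** — the residual.

The HCAP-versus-PNP precedence is not determined by the residual definition
of CAP; the default puts HCAP first (the definitions are listed in that
order and HCAP is an exposure-based category), and a single configuration
switch (`precedence="pnp_first"`) flips it.

## Covariates and outcomes

Comorbidity flags are true iff a category code appears in any *secondary*
field of the index admission or in *any* field of a prior admission whose
admission date lies within 730 days strictly before the index admission.
COPD and respiratory-failure history use the same 730-day window but prior
admissions only. Oxygen (365 days) and vaccination (730 days) are strictly
prior — a dispensing on the admission day does not count. Widening any
window can only turn flags on, never off (a tested invariant).

Outcomes: in-hospital death is the discharge status; 30-day death is a
mortality-register record with 0 ≤ death − admission ≤ 30 days (a death
date before an index admission raises a data-inconsistency error); length
of stay is discharge (or death) minus admission in days. Summary tables
report within-subtype column percentages, mean stay to one decimal, the
lower-middle median for even counts, and Pearson chi-square on the
subtype × category table *without* continuity correction (p-values are
descriptive output, not an inferential claim).

## Incidence rates

Average annual rates divide stratum events by (single census-year resident
count × number of study years) × 1000 — deliberately reusing the one census
year for all study years, as surveillance reports do — while per-year rates
use each year's own denominators. Intervals are exact Poisson (Garwood)
intervals from chi-square quantiles, chosen because small-count strata need
asymmetric intervals; zero events yield [0, 3.689]/PY·1000. The trend
report flags strata whose rates never decrease and end higher, and strata
whose first- and last-year intervals do not overlap — an informal screen,
not a formal trend test (joinpoint/regression testing is out of scope, as
is age standardisation). An episode's calendar year is its discharge year,
consistent with selection by discharge.

## The synthetic cohort generator

The generator exists so that classification, deduplication, covariate
ascertainment, outcomes and rates are all testable end to end with known
ground truth. Its defaults are the study conditions of a region-wide
2006–2008 elderly cohort: subtype mixture 2257:6775:17107 (≈
8.6/25.9/65.4%), per-subtype in-hospital mortality 0.323/0.246/0.133,
30-day mortality 0.382/0.283/0.158, log-normal stay lengths with means
27.1/16.8/13.2 days (σ = 0.8 on the log scale), per-subtype age, gender,
residence, hospital-type, comorbidity and aetiology distributions, 51.9% of
HCAP episodes within 10 days of a prior stay, and census denominators
totalling 1,056,000 residents aged 65+ in the reference year (band and sex
shares chosen as a plausible elderly pyramid; earlier years scaled by
0.98/0.99). Default cohort size is 26,239 eligible members, the study
scale; tests use 1000–5000 for speed, which the recovery tolerances (3
binomial SE) absorb.

Mechanism planting details that matter:

* HCAP mechanisms are drawn 0.18/0.12/0.70 (dialysis/chemo/prior stay);
  within prior stays, the discharge gap is ≤ 10 days with probability
  0.519/0.70 so the within-10-days share over *all* HCAP episodes is the
  configured 0.519. One fifth of prior-stay mechanisms are surgical day
  stays (length 0–1 days plus an operative procedure), exercising the
  surgery clause.
* Comorbidity evidence for any subtype is planted either in the index
  admission's secondary fields (spilling to an extra prior stay when the
  six-diagnosis limit would be exceeded) or on a prior stay discharged
  181–729 days before index — inside the comorbidity window, strictly
  outside the healthcare-contact window, so it can never flip a CAP/PNP
  episode to HCAP.
* Non-HCAP patients receive decoy structure at low rates: dialysis or
  chemotherapy 35–365 days out, and non-qualifying 0–1-day prior stays
  without surgery, so boundary rules are exercised on both sides.
* Deaths follow the nested scheme: a 30-day death is designated with the
  subtype's 30-day probability and dated admission + U{0..30}; in-hospital
  deaths (nested within, at the in-hospital probability) set the discharge
  status and discharge = death date; otherwise a late death (day 31–365)
  occurs with probability 0.10. Consequence: stays ending in in-hospital
  death are capped at 30 days, so the realised mean stay in the
  high-mortality HCAP group sits a few days below the configured survivor
  mean. Survivor stays follow the configured log-normal.
* `plant_repeat_admissions` adds second pneumonia admissions k days after
  the index (k uniform over a range straddling 30, always after the index
  discharge, on non-HCAP patients without death records) and records the
  dedup fate: suppressed for k ≤ 30, a new episode otherwise. A surviving
  repeat whose index stay lasted ≥ 2 days is, by construction, itself
  healthcare-associated, and ground truth records it as such.
* Contamination (default off) adds a 30-day dialysis exposure to a sampled
  share of PNP-structured episodes, whose classification then depends on
  the precedence switch.

What the generator does **not** emulate — and what passing tests therefore
do not show about real registries: comorbidity categories are drawn
independently per episode, so the any-comorbidity share (~93%) is far above
the ~69% seen with correlated real-world multimorbidity; there is no
seasonality, no coding error or miscoding noise, no transfer chains, no
within-patient correlation beyond the planted structures, and aetiology is
a single planted code rather than a culture-confirmed finding. Recovery
tests demonstrate algorithmic correctness under the configured conditions,
not registry data quality.

## Numerical and degenerate-input choices

Empty registries yield empty results rather than errors; a stratum with
zero person-years errors only if it has events (zero/zero reports rate 0
with the degenerate interval). Validation returns violations as data
rather than raising, so dirty bundles are reportable; the pipeline refuses
to run on them unless checking is disabled. Chi-square is skipped with a
warning when a subtype column is empty. Aetiology assignment warns with a
count when episodes match no aetiology set. Exact-interval endpoints are
computed from `scipy.stats.chi2.ppf`; the test suite cross-checks them
against brute-force inversion of the Poisson CDF to 1e-6 and verifies
≥ 93% empirical coverage at the nominal 95% level.

## Known limitations

The algorithm is as sensitive to coding quality as any claims phenotype;
the shipped code sets are reasonable defaults, not a validated national
standard; HCAP under-ascertainment from missing nursing-home information is
inherent to the rule set (criterion 2 is not implementable from these
registries); per-year denominators for non-census years are scaled
estimates in the generator; and the probable-nosocomial category is
"probable" precisely because present-on-admission flags do not exist in
this data model.
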