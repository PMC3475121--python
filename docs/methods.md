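# Methods

## Problem and approach

Two UK-style HIV cohorts observe overlapping but unlinked populations: a
clinic cohort extracts each woman's full laboratory and treatment history
from participating HIV clinics, while a pregnancy-surveillance cohort
receives one report per pregnancy from maternity units, carrying only
summary labs (first/last CD4 and viral load in pregnancy) and antenatal ART.
Neither holds a unique patient identifier, so records for the same woman are
found by *deterministic* linkage: exact date-of-birth blocking followed by a
fixed cascade of agreement criteria over clinical dates, with demographic
fields used only as corroboration. The package implements that cascade, the
pre-merge discrepancy checks and field-harmonization rules, evaluation
statistics, and a ground-truthed simulator of the two data streams.

Deterministic rather than probabilistic (Fellegi–Sunter) linkage is a
deliberate scope decision: the method under study is a rule cascade whose
behaviour must be exactly auditable; no agreement weights are estimated.

## The cascade and its parameters

All thresholds live in `LinkageConfig`:

| parameter | default | units | role |
|---|---|---|---|
| `cd4_count_tolerance` | 10 | cells/mm³ | CD4 agreement bound (surveillance forms round to nearest 10) |
| `cd4_manual_check_threshold` | 100 | cells/mm³ | CD4 difference above which a criterion-2 match needs corroboration |
| `cd4_date_window_days` | 30 | days | CD4 date window of the second CD4 stage |
| `art_date_window_days` | 7 | days | ART date window of the second ART stage |
| `diagnosis_date_window_days` | 30 | days | diagnosis-date proximity for manual flagging |
| `proxy_diagnosis_dates` | 1 Jan, 30 Jun | — | month/day pairs treated as year-only proxies |
| `gestation_days` | 266 | days | gestation length used to estimate conception |
| `cd4_threshold_art_profile` | 350 | cells/mm³ | CD4 above which mid-pregnancy combination ART suggests prophylaxis |
| `first_trimester_days` | 91 | days | first-trimester boundary of the ART-profile rule |
| `corroboration_threshold` | 2 | agreements | manual/discrepancy confirmation bar |
| `site_equivalence` | {} | — | maternity site → HIV site(s) counted as the same site |

All date windows and the count tolerance are inclusive (`|Δ| ≤ w`); the
source material is inconsistent between "within 30 days" and "< 30 days",
so the inclusive reading was chosen once and exposed in configuration.

Conception is estimated as `anchor − (gestation_days − 1)` where the anchor
is the actual delivery date, or the expected delivery date for pregnancies
still continuing; the day count is inclusive of both conception and delivery
days.

### One-to-one resolution

Within a stage, when a record satisfies a criterion against several
counterparts the *strongest match* wins, scored lexicographically by
(number of exact-date CD4 agreements within the count tolerance,
diagnosis-date equality, number of exact ART-date agreements, site
equivalence, soundex equality), with ties broken by the smallest summed
distance from each pregnancy-reported CD4 date to the nearest clinic CD4
date, then by record-id order. This is a deterministic stand-in for human
review of multiple matches, using exactly the fields such review would
inspect. Decisions within a stage are processed in sorted
(pregnancy_id, clinic_id) order, which makes the confirmed set invariant to
input row order.

### Manual review as a corroboration rule

Human checking is replaced by a deterministic rule: a flagged pair is
confirmed when at least `corroboration_threshold` of {country of birth,
ethnicity, exact diagnosis date, exact viral-load value+date, soundex}
agree, at least one of them non-demographic (diagnosis date or viral load).
Soundex is counted as demographic because it derives from the surname. The
same rule vets CD4 criterion-2 decisions whose count difference exceeds the
manual-check threshold — such matches are confirmed only with corroboration,
mirroring the manual checking applied to large CD4 discrepancies in the
original workflow — and adjudicates discrepancy flags before merging.

### Harmonization

* **Diagnosis date.** Earliest of the two reported dates; but if the earlier
  is a proxy (1 Jan / 30 Jun) and the later falls in the same calendar year,
  the later, more specific date wins. The earliest CD4/viral-load/ART date
  substitutes when no diagnosis date exists and overrides any diagnosis date
  it precedes, so the harmonized date never postdates the first recorded
  care event.
* **Region of birth.** Country of birth is mapped to the six WHO regions; a
  European vs non-European conflict resolves to the non-European region
  (European entries are frequently a default), two distinct non-European
  regions resolve to Not Known. The rule is symmetric in its inputs.
* **Ethnicity.** Agreement stands; a strong black-vs-white conflict resolves
  to not-known; any other disagreement defers to the clinic cohort, whose
  ethnicity is re-reported across years of follow-up. The strong-conflict
  relation is a configurable table; only black↔white is irreconcilable by
  default, so black-other vs other defers to the clinic value.

## The synthetic twin cohorts

`generate_twin_cohorts` draws a latent population and reports each woman
into one or both cohorts. Latent structure: DOB uniform over ages 16–49 at
entry to care; finite follow-up of 2–8 years within a 1996–2009 study
window, extended through any pregnancy; CD4 as a clipped Gaussian random
walk (start ≈ N(500, 150²), step ≈ N(0, 30²)) sampled every 60–180 days,
with viral loads co-measured on CD4 dates; ART as an optional long-term
combination episode plus short antenatal courses (zidovudine monotherapy or
combination drugs, starting after the first trimester, sometimes with
"pregnant" as the recorded reason); 40 maternity units of which 13 pair with
clinic-cohort HIV sites — women outside the clinic cohort usually attend
units paired with non-participating clinics, reflecting partial cohort
coverage. Every pregnancy has at least one in-window CD4 measurement
(antenatal CD4 monitoring), which is what makes noiseless recovery at the
first stage exact.

Reporting noise (all rates configurable in `SimulationParams`): CD4
rounding to the nearest 10; CD4 date jitter (first dates jittered earlier,
last dates later, preserving their ordering); proxy DOBs with day = month,
used consistently by both studies; cross-study DOB typos (transposition or
small shift) that silently remove the pair from blocking; discrepant
ethnicity/COB; proxy diagnosis dates; per-field missingness. Rates observed
in the real merged data were adopted where published (same-site attendance
0.921, ethnicity discrepancy 0.086, COB discrepancy 0.047, diagnosis proxy
0.056, pregnancy-side soundex present 0.034); the remainder are plausible
defaults stated as configuration, not estimates.

What the simulator does **not** model: HIV natural history or realistic CD4
trajectories, infant outcomes, migration/death processes, duplicate records
within a cohort, or realistic joint distributions of noise. Passing tests
therefore demonstrate the cascade's logic and its tolerance of the modelled
error modes, not performance on real data — in particular real DOB
collision rates and real CD4-date coincidence rates may differ, and the
first-stage CD4 criterion can in principle confirm a coincidental pair in
any dataset, synthetic or real.

## Evaluation

Sensitivity and PPV are computed against the simulator's injective ground
truth; per-stage attribution is tallied in the shape of a criteria table
with cumulative percentages. The expected-match range uses a Wald
normal-approximation binomial interval scaled to a target population and
rounded to whole women; with zero events it degenerates to (0, 0) with a
warning. Odds ratios are cross-product ratios with Woolf log intervals
(`z·√(1/a+1/b+1/c+1/d)`); intervals are omitted when any cell is zero, and
reported values round to 2 decimals (1 decimal at ≥ 8). Group comparisons
use chi-squared tests (no continuity correction, matching logistic-regression
style analysis) and Mann–Whitney rank-sum tests for ages.

## Problem sizes and numerical choices

Simulated experiments use 500×400-record cohorts with 25% overlap for
headline runs, 120×100 for replicated noise-response sweeps (5 DOB-typo
levels × 50 replicates, paired seeds across levels as a variance-reduction
device), 40×30 for invariant sweeps over 100 seeds, and ≤ 20×16 for
exhaustive comparison against a brute-force reference cascade. All
randomness flows through a single `numpy` generator seeded from
`SimulationParams.seed`; identical parameters give byte-identical cohorts.

## Known limitations

* Exact-DOB blocking discards every pair whose DOB disagrees; the simulator
  reproduces this as lost sensitivity, and no fuzzy-DOB recovery is
  attempted (out of scope by design).
* The corroboration rule is a coarse proxy for expert review; its threshold
  is configurable but its field set is fixed.
* The criteria themselves can confirm coincidental pairs (two women sharing
  DOB, a compatible CD4 date and a site); the cascade prefers
  under-matching, but PPV = 1 is a property of favourable data, not a
  guarantee of the rules.
* Harmonization covers diagnosis date, region of birth and ethnicity only;
  route of infection is carried from the clinic record without a merge rule.
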