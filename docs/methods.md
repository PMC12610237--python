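# Methods

## Scope and design

`ucmseg` packages an expert-driven population-segmentation cascade as a
deterministic rule engine over derived per-resident state, plus the machinery
needed to exercise it without access to real administrative data: a
condition/weight catalog layer, a synthetic cohort generator with planted
ground truth, and a segment-distinctness evaluation layer. The segmentation
rules themselves are the scientific object; everything around them
(CSV schemas, summaries, standard tests) delegates to pandas, scipy and
statsmodels.

## The rule cascade and its assumptions

A resident's classification depends only on five derived quantities: chronic
conditions (set of catalog condition ids), disease stage, mental-health flag,
social-issues flag, and frailty (CFS). The cascade applies a strict
precedence — frailty ≻ disease stage ≻ psychosocial overlay — so the label is
a total, deterministic function of the profile. Design choices made where the
underlying model description is open:

* **Precedence order.** Frailty must dominate (a severely frail resident with
  advanced disease is Leaving Well, not Advanced Disease); stage must
  dominate the overlay for the LS3–LS6 tiers to be well defined. The engine
  states this order explicitly and the test suite enumerates the full input
  cross-product against an independent lookup-table oracle.
* **Mental-health-only residents.** A resident whose only diagnoses are
  F-chapter codes has no chronic *somatic* disease; by default they fall in
  LS1 (or LS2 with social issues), because the second segment is defined by
  social issues only. `route_mental_only_to_ls4=True` instead places them in
  Early Disease with Psychosocial Issues (sub-segment A3/A5).
* **Psychosocial digits and condition count.** Sub-segment digits 3–5 apply
  regardless of condition count (a single-condition resident with depression
  is A3). This keeps the ten cells collectively exhaustive; the alternative
  reading (psychosocial digits only for multiple conditions) is available as
  `psychosocial_requires_multiple=True`, under which such residents fall to
  digit 1.
* **PACS→acuity classes.** PACS 1 = high acuity, 2 = low acuity, 3/4 = low
  resource intensity, shipped as a replaceable mapping (`pacs_class_map`)
  because the exact episodic criteria are an operational, site-specific
  table.
* **Episodic psychosocial flag.** ES3/ES5 take the psychosocial overlay from
  the *lifelong* segment (LS2/LS4/LS6), not from any per-admission
  re-derivation: the episodic model is defined as lifelong segment × acuity.
* **Missing CFS** never fires the frailty rule (frailty scores are recorded
  only where clinically assessed).
* **Observation window.** Diagnoses count over the full recorded history;
  utilisation aggregates over the calendar year of the resident's latest
  visit (closed calendar-year window).

## Catalog layer

The chronic-condition registry is a CSV data file (38 entries), matched by
ICD-10 prefix on canonical (uppercase, undotted) codes with longest-prefix
resolution, so sub-code granularity differences across source systems do not
matter. The shipped list is **provisional**: it covers common chronic somatic
disease classes with clinically plausible prefixes and is intended to be
replaced by a site's official registry (same schema). Advanced-stage markers
are prefixes (typically complication sub-codes) that promote the condition to
the advanced stage; conditions without a natural marker are staged through
the per-diagnosis complication flag (a DRG/clinician-derived surrogate).
Mental-health F-codes are excluded from the somatic catalog by default and
drive the psychosocial flag instead (`mental_codes_count_as_chronic` flips
this). The Charlson index uses the Quan ICD-10 mapping with classic 1/2/3/6
weights and the three standard hierarchy suppressions; the weight table is a
replaceable CSV.

## Synthetic cohort generator

The generator emulates one observation year of a regional cohort seen through
four administrative tables. It works segment-first: a lifelong label is drawn
from the segment prevalence vector, a sub-segment from the conditional
distribution restricted to digits compatible with that label, and records are
then constructed to satisfy exactly the planted label's criteria under the
default rule configuration (early-stage codes only for A-cells, one advanced
marker or complication flag for B-cells, an F-code for digits 3/5, a
social-issue proxy for digits 4/5, CFS ≥ 8 only for Leaving Well). This makes
planted-label recovery an exact, seed-independent property rather than a
statistical one, and the suite asserts 100% agreement.

Default parameters are the published per-segment means: the ten sub-segment
rows of the utilisation/cost table (annual ED, specialist-outpatient and
inpatient visit counts, hospital bed-days, overall cost) and the six episodic
rows (mean length of stay, admission cost, 30-day readmission rate), plus the
published segment shares where printed (Living Well 43.1%, Early Disease
33.0%) and per-segment demographic profiles (mean age, sex, ethnicity mix).
Values not printed anywhere are fill-ins chosen once as plausible for this
kind of cohort and documented here:

* remaining lifelong prevalences LS2 = 1.0%, LS4 = 9.0%, LS5 = 8.0%,
  LS6 = 5.2%, LS7 = 0.7% (respecting the printed anchors and the ~55% share
  of the chronic block, and summing to one);
* sub-segment conditionals (early: 0.42/0.35/0.09/0.09/0.05 over A1–A5;
  advanced: 0.30/0.30/0.16/0.14/0.10 over B1–B5), dominated by the
  no-psychosocial cells as reported qualitatively;
* utilisation for segments outside the published sub-segment table (LS1,
  LS2, LS7), a PACS distribution of 0.15/0.55/0.20/0.10 over values 1–4
  roughly matching the published episodic case mix, one expected emergency
  admission per resident-year, and an age standard deviation of 15 years.

Distributional families: visit counts are negative-binomial parameterised by
mean and a quadratic over-dispersion α (default 0.3, mild over-dispersion;
α = 0 degenerates to Poisson); bed-days, costs and length of stay are gamma
with the configured mean and a coefficient of variation of 1 (right-skewed,
as cost data are). Only means are calibrated; dispersions are knobs. Annual
cost and bed-day totals must attach to encounter rows, so they are drawn
conditional on at least one eligible encounter with the mean rescaled by the
inclusion probability 1/P(≥1), computed exactly from the count-distribution
zero mass — the *unconditional* per-resident mean therefore equals the
configured table value exactly, which is what the calibration-recovery checks
measure.

What the generator deliberately does **not** model: within-year visit timing,
multi-year disease progression, correlation between a resident's utilisation
and their admission count beyond what the shared segment induces, coded-data
errors, or any dependence structure beyond segment-conditional independence.
Passing tests therefore demonstrate that the pipeline is a correct and
well-calibrated implementation of the rules and summaries — not that the
rules would show the same discriminative power on real, messier data.

## Evaluation layer

Per-segment tables report n, share, and mean/SD of age, Charlson index,
ED/outpatient/inpatient visit counts, bed-days and annual cost (lifelong and
sub-segment tables), and LOS, admission cost and readmission proportion
(episodic table), aggregated over the latest-visit calendar year. Residents
with no recorded visits contribute zeros. Between-segment tests: one-way
ANOVA (scipy) for continuous outcomes, Pearson chi-square without continuity
correction (matching the r×c closed form) for categorical associations, and
an OLS trend of outcome on segment rank with configurable covariates (age and
sex by default). P-values are reported raw — no multiple-testing correction
is applied, matching the evaluation design this mirrors. Degenerate inputs
(identical constant groups, zero margins, collinear designs, groups of size
one) raise typed errors rather than returning undefined statistics.

## Numerical and size choices

Gamma length-of-stay draws are floored at 1e-3 days to respect strict
positivity; ages are clipped to [0, 105]. Results are independent of input
row order (processing iterates in sorted id order) and byte-reproducible
under a fixed seed. The test suite exercises calibration recovery on a
20,000-resident cohort (≈20,000 admissions) with 3-standard-error bands; the
acceptance script uses 100,000 residents so the Monte-Carlo error on the
reported cell means is a few percent. Type-I-error checks for the tests use
1,000 null replicates with a 3σ binomial band around α = 0.05.

## Known limitations

* The shipped 38-condition catalog and its advanced-stage markers are a
  provisional stand-in for a site's official registry.
* Unprinted prevalence and dispersion parameters are documented fill-ins;
  absolute per-segment n's in synthetic runs are therefore illustrative.
* The evaluation reproduces discriminative summaries and tests only — no
  causal claims, survival analysis, or cost prediction.
* Segmentation is batch-oriented (whole tables in memory); streaming or
  EMR-connected classification is out of scope.
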