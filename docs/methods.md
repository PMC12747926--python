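# Methods

This package implements a claims-database analysis of juvenile idiopathic
arthritis (JIA) epidemiology and biologic treatment patterns, together with a
synthetic claims simulator that provides ground truth for every stage. The
pipeline operates on four flat tables (beneficiaries, diagnoses, prescription
fills, population denominators) and produces cohorts, rates, exposure
episodes, treatment-pattern classifications, drug-survival curves and
suppressed report tables.

## Case definition and cohorts

A person enters the **prevalent cohort** when, inside the identification
window (2012-01-01 to 2019-12-31, half-open at 2020-01-01), they have at
least one inpatient JIA code or three outpatient JIA codes on distinct days
whose first-to-third span is at most 365 days (sliding triples, not calendar
years); have an enrollment interval overlapping the window; are under 16
completed years at the index date (the first in-window JIA code); and have a
grace-merged NSAID episode spanning more than 14 days that intersects the 365
days after the index date. The **incident cohort** additionally requires no
JIA code before 2012-01-01 — the whole available pre-window history (the
database starts 2011) is the washout. Duplicate same-day outpatient codes
collapse to one visit day.

Two readings of the NSAID duration exist: union supply coverage versus the
span of the grace-merged episode. "More than 14 *consecutive* days" under a
grace rule is naturally the episode span, and that is the implemented
criterion (span ≥ 15 days); for a single fill both readings coincide.
Whether the episode must start inside the 365-day window or merely intersect
it is also ambiguous; the default is intersect.

The SpA subgroup label is assigned when any spondyloarthritis-feature code
(ankylosing spondylitis, sacroiliitis, other inflammatory spondylopathy,
psoriatic arthropathy) occurs anywhere in the record; a strict same-day
co-occurrence mode is available (`spa_same_day_only`). ICD-9-CM codes apply
to claims dated before 2016-01-01 and ICD-10-CM from that date; the shipped
code lists are documented stand-ins for the study-specific supplementary
lists, which are not public, and can be replaced from a YAML config.

## Rates

Annual prevalence divides prevalent cases counted in a year by the under-16
population of that year (per 100,000). The default numerator
(`prevalence_mode="cumulative"`) counts members whose index date has passed,
who are still in follow-up, and whose 16th birthday has not passed before the
year starts; `"active_claim"` instead requires a JIA claim during the year.
Annual incidence proportion divides new cases by the at-risk headcount
(under-16 population minus previously diagnosed, still-pediatric members).
The overall incidence rate divides all incident cases by accumulated under-16
person-years. Person-years of the (rare) already-diagnosed are not subtracted
from the overall denominator; at realistic hazards this is a ~1e-4 relative
effect. Rates are crude; no age standardisation is performed. Because the
registry has no pre-2011 history, cumulative prevalence in the first study
years is necessarily below its steady state — visible in any output covering
2012-2013.

## Exposure episodes and chronic use

A fill covers `[fill_date, fill_date + days_supply)`. Fills of one drug merge
into an episode while each new fill starts no more than the grace period
after the running episode end (14 days for NSAIDs, systemic steroids and
csDMARDs; 60 days for biologics), so retained gaps strictly exceed the grace.
Overlapping supply extends coverage from the maximum end; no stockpiling is
modelled. "Chronic" use means a single episode spanning at least 90 days.
csDMARD combination with a biologic is visit-based: a csDMARD fill must share
a `visit_id` with a biologic fill in the period (first treatment year versus
after), so same-day fills at different encounters do not count.

## Treatment-pattern state machine

The index biologic is the earliest fill of etanercept, adalimumab or
tocilizumab (ties: larger days_supply, then alphabetical). Abatacept is never
the index drug but counts as biologic exposure for switching and restart.
Walking events after the index start, the first qualifying event fixes the
pattern: a different biologic filled on or before the index-episode end + 60
days is **switching** (within gap; a fill during covered time counts, gap 0);
otherwise any biologic fill later than that is a **restart** (same or
different drug, the latter tabulated under restart with subtype
`after_interruption`); otherwise **discontinuation** if the episode ends more
than 60 days before follow-up end; otherwise **continuation** — so end-of-study
tails are not misread as discontinuation. Follow-up ends at
min(2020-12-31, enrollment end).

The drug-survival observation starts at the index fill and stops at the
switch date or the index-episode end (an interruption is the end of index-drug
use), censored at follow-up end for continuers (`event_definition=
"index_drug"`; `"any_biologic"` instead ends the clock only when all biologic
exposure stops). Time-to-restart is measured from the index-episode end to
the first later biologic fill. Note that a restart requires a gap above 60
days, so this quantity can never have a median below 0.164 years; analyses
that report smaller restart medians implicitly start the clock when the
interruption is established (episode end + 60 days).

## Survival estimation

The product-limit estimator is implemented directly:
S(t) = ∏_{t_i ≤ t} (1 − d_i/n_i), with events processed before censorings at
tied times, Greenwood's variance of log S, and 95% confidence bounds on the
log(−log) scale (guaranteed inside [0, 1]; plain Greenwood available). The
median is the smallest event time with S ≤ 0.5 and is reported as undefined
when S never reaches 0.5. Cumulative discontinuation at a horizon is
1 − S(horizon) with the transformed CI carried from the last event time at or
before the horizon. Years are days/365.25. The estimator is cross-checked in
the test suite against lifelines to 1e-10 on random datasets.

## Statistics and suppression

The chi-squared test is the plain Pearson statistic without continuity
correction; Fisher's exact test is a full two-sided hypergeometric
enumeration (sum of table probabilities not exceeding the observed, with a
1e-7 relative tie tolerance). The selection rule — Fisher when any expected
2×2 cell is below 5 — is conventional and config-overridable; emitted reports
name the test actually used. Odds ratios use Woolf log-scale intervals with a
0.5 continuity correction on zero cells. Suppression masks exactly the
non-zero counts below three (rendered "≤3"); zeros and counts ≥ 3 are shown,
the operation is idempotent, and it is applied last in report assembly.
Percentages over sex use non-missing denominators; "missing" is retained as a
category, never imputed.

## Synthetic data generator

The generator emulates the statistical structure of the study population:

- A pediatric population (default 300,000; 2,000,000 in the acceptance
  script) with uniform birth dates 1996-2020, fully enrolled from
  max(birth, 2011-01-01) to 2021-01-01, sex 50/50 with 0.5% recorded as
  missing in claims (denominators use true sex, as census data would).
- JIA onsets at an annual hazard of 5.5 per 100,000 under-16 population,
  applied per calendar year 2011-2019 to persons under 16 at mid-year. The
  hazard is weighted across joint (age band × sex) cells of the subgroup
  mixture — SpA fraction 0.492, male fraction 0.707 (SpA) / 0.444 (non-SpA),
  onset-age band shares per subgroup from the reference distribution — so the
  marginal hazard, the SpA fraction and the sex/age profiles are all
  recoverable in expectation. Subgroups are then assigned by the exact
  posterior given sex and band. Onset month is uniform (no seasonality).
  Because the at-risk band is fixed at mid-year while the onset day is
  uniform in the year, band shares observed at the exact onset date are
  slightly smeared across band boundaries.
- Cases emit claims that satisfy the case definition: an inpatient code
  (probability 0.15, forced when fewer than ~5 months of window remain) or an
  outpatient triple within 150 days, quarterly ongoing visits, SpA-feature /
  uveitis / psoriasis codes per subgroup probabilities, and an NSAID course
  starting within 10 days of diagnosis. 2011 onsets re-present with a fresh
  work-up shortly after the window opens; their pre-window codes exercise the
  washout. Near-miss controls (10% of the case count) each fail exactly one
  inclusion criterion; background rule-out noise adds non-qualifying JIA
  codes to 0.2% of the population.
- Chronic therapy (NSAID, methotrexate, sulfasalazine, steroid) is drawn
  independently per drug with subgroup-specific probabilities taken from the
  reference chronic-use shares. Independence across drugs means the "any
  chronic medication" share exceeds what a correlated real population shows.
- Biologic courses: uptake 15.2% (SpA) / 23.1% (non-SpA); index drug shares
  0.417/0.509/0.074; delay from diagnosis exponential with median 0.73 years;
  fills every 28 days (±3) with 28-day supply. Trajectories are
  piecewise-exponential per 30-day interval: stop hazard 0.016 (median raw
  duration ≈ 3.6 years), switch-within-gap probability 0.24 given a stop,
  restart probability 0.75 given an interruption with gap 61 + Exp(median 58)
  days, same-drug restarts 90%. The true terminal pattern is derived from the
  latent events by the pattern definitions, independently of the classifier.
  A course whose index would start within ~4 months of follow-up end is not
  initiated, so observed uptake runs a few points below the configured
  propensity — an end-of-study censoring effect the real cohort shares.
- Denominators are computed analytically from the simulated population (exact
  day counts per year, age band and sex; band boundaries use the mean year
  length of 365.2425 days), not re-counted from claims.
- One global seed; the population draw uses one stream and each case history
  a sub-stream keyed by (seed, person index), so output is byte-identical for
  a given config.

What the generator does **not** emulate: reimbursement adjudication,
mortality and disenrollment, dose/strength, diagnostic miscoding beyond the
configured near-misses, within-patient correlation of drug use, geographic or
provider structure. Passing tests therefore demonstrate correctness of the
analytic machinery on data with known truth, not robustness to every
real-claims pathology.

## Problem sizes and numerical choices

The test suite runs the hazard-recovery property at 20 seeds × 200,000
persons (the estimate must fall within three Monte-Carlo standard errors of
the configured hazard), episode merging against a day-bitmap oracle on 1,000
random timelines, classifier label recovery on four states × 100 adversarial
timelines, survival against an independent reference on 500 random datasets,
and Fisher p-values against an independent enumeration exhaustively for small
tables plus random tables with N ≤ 40. The acceptance script simulates
2,000,000 persons (~570 incident cases, ~90 biologic users), a scale chosen
to give stable rates while completing in well under a minute. Dates are
handled as integer days internally; intervals are half-open throughout; ages
are completed years by the birthday convention.

## Known limitations

- The exact diagnosis code lists are stand-ins; analyses on real claims must
  supply the validated lists via the config file.
- Prevalence in the first study years is structurally below steady state
  (no pre-2011 history), so min/max summaries over 2012-2019 mix ramp-up with
  equilibrium.
- The "under 16" versus "≤ 16" denominator ambiguity is resolved in favour of
  the inclusion-criterion wording (under 16); the cutoff is configurable.
- No log-rank test or regression modelling is provided, matching the scope of
  the analysis the pipeline reproduces.
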