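# jia-claims

Claims-database analysis of juvenile idiopathic arthritis (JIA) epidemiology
and biologic treatment patterns, with a synthetic claims simulator that
provides ground truth for every pipeline stage.

JIA is the most common chronic arthritis of childhood. In administrative
claims it can be studied at population scale, but every step is algorithmic:
a case definition over diagnosis codes (one inpatient or three outpatient JIA
codes within 365 days, plus sustained NSAID use), a washout for incident
status, ICD-9-CM/ICD-10-CM dialect handling around the 2016 switch,
prescription fills merged into exposure episodes under grace periods (14 days
for NSAIDs/steroids/csDMARDs, 60 days for biologics), a four-state
classifier of each patient's index-biologic course, and product-limit drug
survival. This package implements that machinery for epidemiologists and
pharmacoepidemiologists, and — because the source registry data are access
restricted — ships a calibrated generator so the whole pipeline is testable
against known truth.

## The core quantities

- Annual prevalence: cases counted in year *Y* over the under-16 population
  of *Y*, per 100,000; annual incidence proportion: new cases over the
  at-risk under-16 headcount; overall incidence rate: incident cases over
  accumulated under-16 person-years.
- Exposure episodes: a fill covers `[fill_date, fill_date + days_supply)`;
  fills merge while each starts within the grace period of the running
  episode end, so retained gaps strictly exceed the grace.
- Treatment patterns of the index biologic (first fill of etanercept,
  adalimumab or tocilizumab): **continuation** (episode persists to within 60
  days of follow-up end), **switching** (another biologic within the 60-day
  gap), **restart** (any biologic after a gap above 60 days), and
  **discontinuation** (nothing further, well before follow-up end).
- Drug survival: S(t) = ∏_{t_i ≤ t} (1 − d_i/n_i) with Greenwood variance and
  log(−log) 95% bounds; events are switches or the end of index-drug use,
  censored at study end.

See `docs/methods.md` for the full model description, generator calibration
and numerical conventions.

## Worked example

```python
import jia_claims as jc

cfg = jc.GeneratorConfig(seed=42, n_population=500_000)
bundle, truth = jc.generate_bundle(cfg)
assert not jc.validate_bundle(bundle)

prevalent, incident, flow = jc.build_cohorts(bundle)
print("flowchart:", flow)

inc = jc.cohort_frame(incident)
rate = jc.overall_incidence_rate(inc, bundle.denominators)
print(f"overall incidence: {rate.rate:.2f} per 100,000 person-years "
      f"({rate.numerator} cases)")

courses = jc.extract_courses(bundle, inc)
print(jc.tabulate_patterns(courses)[
    ["index_drug", "n", "continuation_pct", "switching_pct",
     "restart_pct", "discontinuation_pct"]].to_string(index=False))

curve = jc.km_fit([c.event_time_days for c in courses],
                  [c.event for c in courses])
med = jc.km_median(curve)
rate1y, ci = jc.cumulative_discontinuation(curve, 1)
print(f"median drug survival: {med / 365.25:.2f} y; "
      f"1-year discontinuation {100 * rate1y:.1f}% "
      f"({100 * ci[0]:.1f}-{100 * ci[1]:.1f}%)")
```

Output:

```
flowchart: {'candidates': 1153, 'excluded_case_definition': 1008, 'excluded_enrollment': 0,
 'excluded_age': 0, 'excluded_nsaid': 6, 'prevalent': 139, 'excluded_prior_history': 11,
 'incident': 128}
overall incidence: 4.80 per 100,000 person-years (128 cases)
 index_drug  n  continuation_pct  switching_pct  restart_pct  discontinuation_pct
 adalimumab  7              57.1           28.6          0.0                 14.3
 etanercept 12              50.0            8.3         16.7                 25.0
tocilizumab  2              50.0            0.0          0.0                 50.0
        all 21              52.4           14.3          9.5                 23.8
median drug survival: 3.50 y; 1-year discontinuation 19.6% (7.8-44.2%)
```

The flowchart logs every exclusion (the 1,008 non-qualifying candidates are
deliberate near-miss controls and background rule-out visits emitted by the
generator); the incidence estimate of 4.80/100,000 person-years recovers the
configured onset hazard of 5.5 within Monte-Carlo error at this population
size, and the pattern percentages partition the 21 biologic users of this
small run.

A command-line interface mirrors the library:

```bash
jia-claims run-all --out run/ --seed 1 --n-population 300000
jia-claims simulate --out bundle/ --seed 1
jia-claims build-cohort --bundle bundle/ --out cohort.csv --flowchart flow.json
jia-claims drug-survival --courses run/courses.csv --out km.csv --plot km.png
```

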