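# Methods

## Model structure

`darescreen` is an expected-value (cohort) Markov model, not a
microsimulation: the state vector holds population fractions and every
transition is deterministic given the inputs. A cohort of MSM living with
HIV enters cancer-free at age 35 and is followed in one-year cycles to a
maximum age of 100 (65 cycles). States:

- `no_cancer`;
- undetected localized, regional and distal cancer, each split into dwell
  years `0 … progression_interval − 1`. When the dwell completes, the
  cancer progresses one stage; completed undetected distal disease moves to
  cancer death. With the base progression interval of one year this encodes
  the natural-history assumption that undetected cancer advances
  local → regional → distal over one-year periods and kills one year after
  reaching distal stage undetected. Stages are never skipped;
- detected localized/regional/distal cancer, split into
  time-since-diagnosis tunnel years so that monitoring costs and the excess
  death probability can depend on elapsed time. The final tunnel layer
  absorbs. There is no separate remission state: a detected-cancer track
  with tunnel year ≥ 1 plays that role, because treated patients never
  return to the cancer-free state but follow their survival curve;
- two absorbing death states (cancer, other causes), separated only for
  validation bookkeeping — the economics are identical.

### Cycle event order

Within each cycle, events apply in a fixed order: (1) screening detection,
(2) background (symptomatic) detection, (3) progression of still-undetected
cancer, (4) incidence, (5) mortality — other-cause first, then excess
cancer mortality for detected states, (6) tunnel/dwell increments, with new
diagnoses entering tunnel year 0 at the next cycle start. Screening first
reflects a DARE performed at the routine HIV visit at the start of the
year; incidence after progression means a newly arisen cancer cannot
progress within its first cycle; diagnoses entering the tunnel at the next
cycle start realises the assumption that neither cancer death nor
monitoring cost precedes the first anniversary of diagnosis.

Newly diagnosed fractions are exposed to other-cause mortality in the
diagnosis cycle; undetected distal completions die of cancer regardless of
the other-cause draw. Conservation of probability mass is asserted at every
cycle to 1e-9 and the engine raises if it is violated.

## Screening test

The DARE's published sensitivity (0.9, range 0.7–1.0) is defined for
cancers under 2 cm, i.e. localized tumours. The package therefore applies
it to undetected localized cancer only; per-stage sensitivities for
regional and distal disease default to 0 and are configurable
(`dare_sensitivity_regional`, `dare_sensitivity_distal`). This matters: if
screening also detected advanced undetected cancer it would convert
never-diagnosed cancer deaths into late-stage diagnoses, and the localized
share of detections would no longer rise monotonically with screening
frequency — the opposite of the stage-shift mechanism the intervention is
predicated on.

The published "specificity" of 0.25 is, by its own definition, the
proportion of surgical referrals that turn out to be cancer — a positive
predictive value. It is stored as `dare_ppv` and inverted each screening
cycle into a per-screen false-positive probability

    f = TP · (1 − ppv) / (ppv · (1 − prev)),   TP = Σ_s prev_s · sens_s,

where `prev_s` is the current prevalence of undetected stage-`s` cancer in
the screened population (cancer-free plus undetected). Holding the PPV
fixed for life is conservative: every true positive is always accompanied
by (1 − ppv)/ppv = 3 false-positive referrals, each charged
`cost_false_positive` and an optional QALY decrement `fp_disutility`
(default 0, as no published value exists). Bayes post-test probabilities
for a single examinee are available via `posttest_probability`.

Whether false-positive costs accrue per screened person or per detected
case is not documented anywhere; the PPV-calibrated per-screen rate above
is this package's documented choice.

## Survival after diagnosis

Stage-specific relative survival is modelled as Weibull,
S(t) = exp(−(t/λ)^k), fitted to tabulated survival points by weighted least
squares on the linearised scale log(−log S) = k·log t − k·log λ. Weights
are `n_at_risk · (S ln S)²` — the delta-method inverse-variance weights for
the transformed response — which keeps the fit well-conditioned near S ≈ 1
and makes the fit exactly invertible on noiseless data. The fitted curve is
converted to annual conditional excess death probabilities
1 − S(t+1)/S(t), applied multiplicatively with other-cause survival (the
standard reading of relative survival as cancer-attributable excess
hazard). The same curve applies at every age at diagnosis; age-standardised
refits are out of scope for lack of data.

Because the clock starts at diagnosis, earlier detection *within* a stage
carries a lead-time penalty: the excess hazard starts earlier with no
offsetting stage shift. With one-year progression this is dominated by the
stage-shift benefit, but with slow progression (2–3-year intervals) or high
background detection, very frequent screening can yield slightly negative
incremental life-years. This is a recognised artifact of
survival-from-diagnosis modelling, visible in a handful of extreme PSA
draws, and is why PSA-level monotonicity claims are stated conditional on a
positive QALY gain.

## Parameters

Base-case values (AUD 2014): screening $16 per DARE [10–30]; false positive
$218 [100–500]; workup $1,864 [1,000–3,000]; treatment $10,386 / $11,093 /
$14,638 for localized/regional/distal [5,000–15,000, distal 10,000–20,000];
utilities 0.76 (no cancer) [0.66–0.86], 0.71 / 0.66 / 0.52 for
localized/regional/distal cancer; background detection of localized cancer
0.2/year [0.1–0.55]; 5 % of localized cancers treated by local excision
instead of chemoradiation; discount rate 3 % [0–5 %].

Quantities with no published value take documented defaults, all
configurable:

- **Background detection of regional/distal cancer** — 0.15 and 0.10 per
  year, obtained by inverting the published validation stage-at-diagnosis
  mix (52 % local, 31 % regional, 17 % distal) under the sequential
  progression model: local share = p_L / (p_L + (1−p_L)p_R +
  (1−p_L)(1−p_R)p_D) with p_L = 0.2. Larger values would make advanced
  disease more reliably symptomatic but push the unscreened localized share
  far below the validation anchor.
- **Monitoring costs** — $500 in the first year after diagnosis, $250/year
  in years 2–5, nothing after (the source prices monitoring only as
  "variable according to time from diagnosis"). Whether monitoring should
  continue for life is unknown; the schedule length is free.
- **Local-excision cost** — $1,864 (workup-scale surgery) for the 5 %
  surgical fraction.
- **Stage utility duration** — the stage utility applies for one year after
  diagnosis (the treatment year), then reverts to the no-cancer weight;
  `treatment_utility_years` generalises this. Undetected cancer carries its
  stage utility throughout.

Discounting uses half-cycle correction: a payoff in cycle t (1-based) is
valued at (1+r)^−(t−0.5), i.e. at the cycle midpoint; life-years and
utilities are accrued on start-of-cycle occupancy, costs on the cycle's
events.

## Synthetic data and calibration

The true age-specific incidence, HIV-cohort mortality and fitted survival
coefficients are not publicly deposited, so the package generates stand-ins
with the right macro-structure (all labelled synthetic; none are the
original study's inputs):

- **Incidence**: a logistic ramp in age (midpoint 56, width 4.4 years)
  plateauing at 65, with small smooth multiplicative jitter. The mean
  annual probability at ages 50–64 is ≈ 9.4× that at 35–49, consistent with
  registry data showing a near nine-fold rise. A global multiplier is then
  found by bisection so the no-screening cohort's lifetime probability of a
  cancer *diagnosis* is 3.0 % ± 0.2 pp — the model's published lifetime-risk
  validation anchor.
- **Other-cause mortality**: Gompertz, 0.004·e^{0.082(age−35)} pre-jitter,
  scaled by a multiplier found by bisection so the cancer-free discounted
  (3 %) life expectancy from 35 is 24.20 years, matching the published
  no-screening discounted life-years.
- **Survival**: Weibull stage curves with shapes 0.70/0.75/0.90 and scales
  40/12/4 years (5-year relative survival ≈ 0.79/0.60/0.29 — realistic for
  localized/regional/distal anal carcinoma). `gen_survival_dataset`
  produces noisy 30-year series (a realistic registry follow-up window) for
  exercising the fitting code; truncation to [0, 1] and isotonic clipping
  keep them valid survival curves.

Fixed seeds make every generator bit-reproducible.

What the fixture does *not* emulate: the real SEER age-incidence fine
structure, HIV-era mortality trends, correlated sampling error in registry
survival tables, or screening-uptake behaviour. Consequently the engine's
absolute dollar and QALY outputs on the fixture differ from the published
base case (e.g. discounted no-screening cost $156 vs the published $195;
screening QALY gains are larger here), and on this fixture the intermediate
≥50 intervals fall off the efficiency frontier. Tests of absolute outputs
are therefore property-based — calibration anchors, monotone stage shift,
directional sensitivity — while the published league-table arithmetic is
verified exactly on the published cells themselves.

## Frontier analysis

Strategies are sorted by effect (ties by cost); strictly dominated
strategies (another is at least as effective and no costlier, one strictly)
are removed with a named dominator; extended dominance is then applied
iteratively until frontier ICERs strictly increase, recording the witness
pair. ACERs compare each strategy with no screening. Reporting rounds to
the nearest dollar, halves away from zero; internal arithmetic is
unrounded.

One numerical convention deserves note: published league tables print costs
to the dollar and effects to four decimals, so consecutive ICERs recomputed
from printed cells can collide within a dollar when the unrounded values
did not (e.g. two adjacent per-life-year ICERs of 14,496.0 and 14,496.6).
`frontier()` therefore treats consecutive ICERs within `tie_tolerance`
(default $1, the reporting resolution) as tied and removes the intermediate
strategy as weakly extended-dominated — it is not the unique best buy at
any willingness to pay distinguishable at that resolution. Setting
`tie_tolerance=0` recovers the exact geometric (convex-hull) frontier,
which is what the randomised oracle-equivalence tests use.

## Sensitivity analyses

**One-way**: `owsa` re-runs the pipeline over a parameter grid and reports,
per grid value, the ICER of each screening strategy against the
next-less-intensive comparator in the supplied list — the published tornado
layout ("every two years compared with every three years"). These pairwise
ICERs exist for every grid value, unlike frontier ICERs, which vanish when
a strategy is dominated. Settings-level knobs (`discount_rate`),
parameters (`cost_false_positive`, `progression_interval_years`, …) and a
survival scenario (`survival_hazard_factor`, multiplying every annual
excess death probability) are all addressable by name.

**Probabilistic**: second-order Monte Carlo, 10,000 iterations by default.
Costs draw from gamma and utilities/probabilities from beta distributions,
method-of-moments matched to mean = base value and SD = 30 % of base
(per-parameter overrides supported; infeasible beta variances are clipped
to 95 % of the maximum with a warning). One parameter set per iteration is
applied to all strategies — common random numbers, which reduces the
variance of incremental comparisons and matches the "one combination of
values per repetition" design. Draws are deterministic in
(seed, iteration), so any iteration can be reproduced in isolation.

**CEAC**: the default acceptability curve is pairwise versus a comparator —
the fraction of iterations with λ·ΔQALY − ΔCost > 0 — because published
per-strategy curves are reported independently (their probabilities need
not sum to one). A multiway variant (probability of maximising net monetary
benefit across all strategies) is available via `method="multiway"`.

## Problem sizes used in the shipped checks

The end-to-end suite runs the full 65-cycle engine for all eleven
strategies, 1,000 random frontier instances against the brute-force oracle,
100 survival-recovery fits, 10,000 PSA parameter draws for the moment
checks, and a 120-iteration engine-backed PSA for the acceptability-curve
properties; the example PSA uses 300 iterations. These sizes give stable
checks of every property while keeping the whole suite at a few seconds;
the 10,000-iteration engine-backed PSA remains a single
`darescreen psa --iterations 10000` call (roughly 11 × 10,000 cohort runs).

## Known limitations

- No HSIL/precursor states: the model evaluates early cancer detection,
  not cytology-based prevention, and cannot speak to anoscopy pathways.
- Utilities are not adjusted for ageing or HIV comorbidity, so QALYs in the
  no-cancer state are flat across life.
- The same relative-survival curve applies at every age at diagnosis.
- Lead-time artifact within stages, discussed above.
- Currency is fixed at AUD 2014; no inflation or conversion machinery.
- The synthetic fixture reproduces calibration anchors, not the original
  supplementary inputs; absolute outputs on it are not the published ones.
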