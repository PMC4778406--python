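# darescreen

A probabilistic Markov cohort model for the cost-effectiveness of screening
for anal cancer with regular **digital ano-rectal examinations (DARE)** in
men who have sex with men (MSM) living with HIV.

Anal cancer is far more common in MSM living with HIV than in the general
population, and most cancers are palpable or visible on a simple clinical
examination. Because anal cytology programmes are not widely available, a
pragmatic alternative is early *cancer* detection: a DARE folded into the
routine HIV consultation. This package implements the decision model used
to weigh that policy — who to screen (from age 35 or from age 50) and how
often (every 1–5 years) — against no screening, from a government payer's
perspective in 2014 Australian dollars.

## The model

A cohort enters at age 35 and is followed in annual cycles to age 100
through the states *no cancer*, *localized / regional / distal cancer*
(each detected or undetected, with time-since-diagnosis tunnel layers), and
*death* (from cancer or other causes). Undetected cancer progresses
local → regional → distal over one-year periods (configurable to 2–3
years), and undetected distal cancer is fatal a year later. Detection
happens through screening (sensitivity 0.9 for localized, <2 cm cancers) or
symptomatically outside the programme (annual probability 0.2 while
localized). A positive DARE refers the patient to a colorectal surgeon;
referral PPV is held at 0.25, so each true positive is accompanied by
(1−0.25)/0.25 = 3 false-positive referrals at $218 each. After diagnosis,
survival follows stage-specific Weibull relative-survival curves,
S(t) = exp(−(t/λ)^k), applied as annual excess death probabilities
1 − S(t+1)/S(t) on top of other-cause mortality.

Per-cycle costs (screening, false positives, workup + stage-specific
treatment, monitoring) and utility-weighted life-years are discounted at
3 %/year with half-cycle correction, v·(1+r)^−(t−0.5). Strategies are then
ranked by the standard league-table algorithm: strict dominance, extended
dominance, and incremental cost-effectiveness ratios
ICER = ΔC/ΔE along the frontier, plus average ratios
ACER = (C − C₀)/(E − E₀) versus no screening. One-way sensitivity analysis
and a 10,000-iteration second-order Monte Carlo PSA (gamma costs, beta
utilities/probabilities, SD = 30 % of base) with cost-effectiveness
acceptability curves complete the analysis.

The published age-specific incidence and mortality schedules and the fitted
survival coefficients are not shipped anywhere public, so
`darescreen.synthetic_data` generates calibrated stand-ins: incidence rises
~9-fold from ages 35–49 to 50–64 and is calibrated by bisection to a 3 %
lifetime diagnosis risk; Gompertz mortality is tuned to ~24.2 discounted
life-years for the unscreened cohort; survival curves are Weibull with
realistic stage-specific 5-year survival. See `docs/methods.md`.

## Worked example

```sh
python examples/frontier_from_published_cells.py
```

feeds the eleven published discounted (cost, QALY) pairs through the
dominance algorithm and prints:

```
               strategy   cost  effect             status     icer     acer           dominated_by
           No screening  195.0 18.3857           frontier      NaN      NaN                   None
Age 35-49 every 5 years  529.0 18.3899 extended_dominated      NaN  79524.0                   None
Age 35-49 every 4 years  629.0 18.3919          dominated      NaN  70000.0 Age >=50 every 5 years
Age 35-49 every 3 years  736.0 18.3936          dominated      NaN  68481.0 Age >=50 every 5 years
Age 35-49 every 2 years 1033.0 18.3977          dominated      NaN  69833.0 Age >=50 every 5 years
 Age >=50 every 5 years  600.0 18.3993 extended_dominated      NaN  29779.0                   None
   Age 35-49 every year 1745.0 18.4008          dominated      NaN 102649.0 Age >=50 every 4 years
 Age >=50 every 4 years  692.0 18.4024           frontier  29760.0  29760.0                   None
 Age >=50 every 3 years  837.0 18.4069           frontier  32222.0  30283.0                   None
 Age >=50 every 2 years 1119.0 18.4131           frontier  45484.0  33723.0                   None
    Age >=50 every year 1915.0 18.4206           frontier 106133.0  49284.0                   None
```

Screening from age 35 is
never a best buy; among the age ≥50 strategies the frontier ICERs are
$29,760 (every four years), $32,222 (every three years), $45,484 (every
two years) and $106,133 (every year) per QALY gained — at a conventional
$50,000/QALY threshold, screening men aged ≥50 every two years is the
optimal policy.

The other examples run the cohort engine on the calibrated synthetic
fixture (`base_case_cohort.py`: 3.01 % lifetime diagnosis risk; stage mix
53/31/17 % local/regional/distal without screening; localized share of
detections rising from 70 % to 98 % as the ≥50 interval tightens from five
years to one), the tornado analysis (`one_way_sensitivity.py`), the PSA
acceptability curves (`psa_acceptability.py`) and the Weibull survival fit
(`survival_calibration.py`).

A thin CLI wraps the same pipeline:

```sh
darescreen synth --outdir fixture --seed 1
darescreen base-case --config config.yaml --outdir out
darescreen owsa --config config.yaml --parameter cost_false_positive --low 100 --high 500
darescreen psa --config config.yaml --iterations 10000 --seed 1
darescreen validate --config config.yaml
```

## Layout

- `src/darescreen/` — parameters & config I/O, synthetic data generators,
  Weibull survival calibration, screening test model, Markov cohort engine,
  frontier economics, sensitivity/PSA, reference tables, CLI
- `examples/` — one narrative script per capability
- `tests/` — unit, property and end-to-end acceptance tests
- `docs/methods.md` — modelling assumptions, calibration and limitations
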