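# Methods

## Decision model

The model is a one-year decision tree over a hypothetical national birth
cohort (default 2,923,535 live births). The cohort splits into CAH-affected
newborns — salt-wasting (SW) and simple virilizing (SV) at a fixed 75/25
ratio — and non-affected newborns. Each arm of the tree is costed in US$ at
public-health-system reimbursement values; the time horizon runs from
diagnosis to age 19, over which the modelled outcomes occur.

**Screening arm.** Every newborn is billed the filter-paper 17-OHP test
(`A` = US$ 2.45). Non-affected newborns who screen positive (first-tier
false-positive rate, base 0.2%) are split 25/75 into high- and low-risk
recalls. High-risk recalls get serum confirmation plus a consultation
(`A+B`, `B` = US$ 22.46); 8% stay inconclusive and need a second confirmatory
work-up (`A+2B`). Low-risk recalls get a filter-paper retest (`2A`); the 0.5%
still positive escalate to `2A+B`. Affected newborns are all detected
(the model has no false negatives): SW cases are billed the high-risk route
(`A+B`), SV cases the low-risk route (`2A+B`). Screened SW cases that are not
clinically recognized can still suffer a crisis while waiting for the result:
58% are hospitalized, 30% of those reach the ICU for 9 days. The arm has zero
deaths by assumption, and no long-term SV morbidity.

**Clinical-diagnosis arm.** No screening costs anywhere. Clinically
recognized cases (base: 36% of SW, 28% of SV) pay a diagnostic laboratory
panel (US$ 15.05). Unrecognized SW cases die at the assumed mortality rate
(base 8%); deaths are removed *before* the hospitalization rate applies
(survivor denominator — the convention that reproduces the published
hospitalization counts in all three scenarios) and incur no cost, since no
terminal-care line exists in the published ledger. Surviving unrecognized SW
cases are hospitalized at 91%, with 36% of the hospitalized in ICU for 23
days; the non-hospitalized survivors pay the laboratory panel. Unrecognized
SV cases accrue: growth hormone for 14% (5.9 UI/day for 3.2 years, 12-UI
ampoules at US$ 33.97), GnRH analog for 28% (one 11.25 mg ampoule per
quarter, 3.8 years, US$ 273.75 per ampoule), the masculinization process for
46,XX patients reared male (50% female fraction × 15% rearing rate ×
US$ 1,906.19), and the laboratory panel each.

**Effect measure and ICER.** Effectiveness is deaths averted (unscreened
deaths minus screened deaths, the latter zero). Each death averted is worth
30.2 discounted life-years — the fixed published conversion for a 3% rate
over 76 years of life expectancy. The closed-form annuity at those inputs is
29.81 LY (ordinary) or 30.70 (annuity-due); neither reproduces 30.2, so the
constant is adopted verbatim as the default, with both annuity conventions
available in `discounted_life_years`. The ICER is the cent-rounded cost per
death averted divided by the discounted LY, rounded to the cent.

## Numerical conventions

- **Count rounding.** Every `rate × count` node rounds half-away-from-zero to
  the nearest integer; the complementary branch is obtained by subtraction,
  which enforces conservation at each split exactly. This is the unique
  convention that reproduces every integer of the published three-scenario
  ledger. Floats are routed through their shortest decimal representation
  before rounding so binary representation noise cannot flip a half-way case.
- **Money.** Carried as `Decimal` quantized to cents, halves up. Per-patient
  therapy costs stay unrounded until the cohort total (required to match the
  published totals); ampoules are not rounded up to whole units; years are
  365 days.
- **Incidence** is stored as an exact rational (1/12,250) so the affected
  count has no decimal drift.
- **Known errata reproduced consistently:** the published base-case SV
  non-screening subtotal (174,160.23) disagrees with its own components; the
  engine reports the component-consistent 173,600.60, which is what the
  published strategy total 307,010.60 requires. Likewise the "dehydration
  without hospitalization" line is 10 × 15.05 = 150.50, not 150.05.
- `incremental_analysis` flags the cost-per-death and ICER as undefined
  (`None`) when no deaths are averted, rather than emitting a number.

## Sensitivity analysis

One-way sweeps re-run the full integer-rounded engine at each tested value —
no linearization — so a parameter swept to its base value returns the base
ICER exactly. The four reference ranges are incidence 1:15,000–1:10,000, the
SW/SV clinical-recognition pair moved jointly (16/11% ↔ 55/45%), SW mortality
4.2–11%, and FP rate 0.1–0.5%. Because the original analysis' evaluation mode
is not recoverable from the printed table, its endpoint ICERs are matched to
within 5% relative deviation (observed agreement ≈ 1%), with exact direction:
higher mortality or incidence lowers the ICER, higher recognition or FP rate
raises it. The published "births from 2000" row is implemented as the named
preset `group3_2000` (recognition 13%/11%, mortality 5% from the recent-cohort
SW-fraction deficit, ICU 61%/20 days, GH 40%/3.9 y/5.09 UI, GnRHa 30%/5.1 y);
its printed ICER is not numerically reproducible from the stated inputs and is
not asserted.

## Cohort estimators

`summarize_cohort` reports means with t-based 95% CIs and proportions as
exact fractions (Wilson score intervals via `proportion_ci`); empty subsets
yield "unavailable", never zero. `compare_cohorts` uses Welch's
unequal-variance t-test for means (the published analysis says only
"Student's t-test"; Welch is the safer default) and the chi-square test for
proportions, switching to Fisher's exact test when any expected cell is
below 5. "Recognized early" is operationalized as diagnosed before the SW
crisis (SW) and diagnosed within 30 days of life (SV). The SW mortality
estimator is the SW-frequency deficit: an assumed screened SW fraction
(default 75%) minus the per-group mean SW fraction of the recent birth groups
of the unscreened cohort, floored at zero. `params_from_cohorts` maps these
statistics onto dotted parameter paths, averaging any path with an externally
supplied published estimate — the mechanism behind the base-case 36% SW
recognition (average of the cohort's 16% and an external 56%). Note the
deliberately inherited denominators: the screened hospitalization rate is a
fraction of all SW patients, the unscreened one a fraction of dehydrated
patients.

## Synthetic cohort generator

`generate_cohort` draws patients with the conditional flag chain
crisis → dehydrated → hospitalized → ICU (SW) and recognition/therapy flags
(SV). Continuous variables are truncated normals: sodium within
100–150 mEq/L, ICU days ≥ 1, ages ≥ 0, therapy years > 0 only when the flag
is set. Distribution shapes are a modelling choice — the source summaries
report only means and CIs — and SDs are back-derived as
CI half-width × √n / t₀.₉₇₅(n−1) at the relevant subgroup size. SV-specific
constants (sodium 138 ± 2.5 mEq/L; late-diagnosis age 5.7 y ± 2 y, floored at
31 days; recognized ages uniform on 1–30 days) are chosen for internal
consistency with the 30-day recognition window, since the source reports no
SV-specific distributions. One integer seed drives named independent
sub-streams, one per variable, so adding a variable never perturbs existing
draws; the same seed reproduces the cohort byte-for-byte.

What the generator does *not* emulate: correlations among continuous
variables (sodium vs ICU days, etc. are drawn independently), 17-OHP analyte
values and birth-weight-specific cutoffs, and secular trends across birth
groups (each cohort carries a single group label). Passing recovery tests
therefore shows that the estimators are consistent for the stated marginal
structure, not that they are robust to the dependence patterns of real
hospital data. Truncation shifts empirical means away from the nominal
location parameters (e.g. sodium truncated at 100 pulls the mean a couple of
mEq/L above 121.2 at the published SD); recovery tests compare against the
truncated-normal theoretical moments.

## Problem sizes and test design

The decision model is closed-form at national-cohort scale (milliseconds per
scenario). Statistical tests use 10,000-patient synthetic cohorts for
parameter recovery (20-seed battery, 3 Monte-Carlo-SE bands), 200 replicate
pairs of 40-patient cohorts for the null-uniformity check of the comparison
p-values (Kolmogorov–Smirnov), and 200 randomized cascades for conservation
properties; the full suite runs in seconds.

## Limitations

- The model has no false negatives and assumes screening eliminates all
  long-term SV morbidity; both favour screening.
- Indirect/family costs, QALY weighting, and probabilistic (Monte-Carlo)
  sensitivity analysis are out of scope; uncertainty handling is purely
  deterministic.
- Unit costs are a single public-payer reimbursement schedule converted at a
  fixed 2016 exchange rate (R$ 3.26/US$, documentation only — no currency
  engine); results do not transfer across payers without re-costing.
- The 30.2 LY constant is inherited, not derived; switching to a computed
  annuity changes the ICER by about ±1.5%.
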