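# Methods

## Model structure

The projection is a deterministic multi-state cohort model in discrete
weekly cycles. Five health states are tracked: recurrence-free (the entry
state), locoregional recurrence, first-line (1L) metastatic, second-line
(2L) metastatic, and dead (absorbing). The metastatic phase is split into
1L/2L tunnels because treatments and adverse events are line-specific;
1L→2L progression is governed by the 1L progression-free-survival law of
the treatment actually received.

Clocks are semi-Markov: exits from the recurrence-free state are indexed
by time since adjuvant initiation, while locoregional and metastatic exits
are indexed by time since state entry. Time-in-state is implemented by
expanding each post-recurrence state over entry-cycle tunnels, so a state
occupant at tunnel index *a* in cycle *k* entered the state *a* weeks
earlier and experiences the transition probability for state-time
interval [a, a+1).

Within a cycle, deaths are resolved before progressions. With weekly
cycles the ordering effect is O(p²) per cycle and negligible; resolving
deaths first is the conservative choice and prevents double counting. No
half-cycle correction is applied — at weekly resolution its effect is well
under 1%. A cycle spent in a state is credited once the cycle's
transitions are resolved (end-of-cycle occupancy), so a cohort that is
wiped out during its entry cycle accrues no life-years.

## Survival laws and discrete conversion

Each transition carries a parametric law with time in weeks:
exponential (rate), Weibull (shape, scale), log-normal (mu, sigma),
log-logistic (shape, scale), Gompertz (shape, rate; shape 0 degenerates to
exponential) and generalized gamma in the (mu, sigma, Q) parameterization
(Q=0 log-normal, Q=1 Weibull). Treatment effects are hazard ratios acting
on the whole-curve hazard, S_hr(t) = S(t)^hr; proportional hazards is the
convention of the network-meta-analysis-based models this design follows,
and hr = 0 is accepted as the degenerate no-hazard limit.

The per-cycle transition probability is the exact conditional
p_k = 1 − S(k+1)/S(k) rather than a rate approximation; this makes the
telescoping identity ∏(1−p_k) = S(K) hold to numerical precision for every
family (verified to 1e-10 over 520 cycles), and p_k = 1 by convention once
S has reached zero. Competing exits from one state are treated as
independent marginals; in the pathological case where their per-cycle
probabilities sum past 1 they are rescaled proportionally and a warning is
logged.

Death probabilities are floored at background mortality: the applied
per-cycle probability is max(trial-based, life-table). Background
mortality converts the annual probability q(age) by
1 − (1−q)^(1/52), with age advancing deterministically by 1/52 year per
cycle from the cohort's mean entry age, and the two sexes pooled by the
configured fraction female (50.37% by default) because the model tracks a
single pooled cohort.

## Population, scenarios and retreatment

Annual eligible counts (the published national 10-year projection:
978 in 2022 rising to 1,123 from 2029, 10,658 summed) enter as 52 equal
weekly cohorts per model year; a model year is exactly 52 weeks (520-cycle
horizon), a deliberate simplification whose ~1.25 day/year drift is
irrelevant at this precision. The per-tumor split of the published totals
is not public; the default fixture uses melanoma 0.34 / RCC 0.22 / TNBC
0.44 (configurable), so every per-tumor figure is synthetic.

Scenario I allocates each cohort entirely to traditional early-setting
options. Scenario II sends an uptake fraction to early-setting
anti-PD-(L)1 therapy; the default schedule is the one implied by the
published treated/eligible counts (63.3% in 2022 ramping to 88.7%). The
launch-delay sensitivity shifts this ramp forward (default 2 years,
configurable — the source analysis does not state its delay length).

Patients initiating 1L metastatic therapy are assigned a treatment mix
conditional on their adjuvant arm and on whether initiation occurs before
or at/after the retreatment threshold (78 weeks = 18 months since adjuvant
initiation): early progressors after adjuvant anti-PD-(L)1 receive a mix
without the class, later progressors may be retreated. Disabling
retreatment maps every stratum to the restricted mix.

## Outcomes and accounting

Life-years and QALYs accrue per cycle (occupancy/52), discounted at
1.5%/year in **calendar time from model start** — the perspective is a
population/budget-impact horizon, so discounting follows calendar years,
not patient-level time since entry (switchable in principle by
re-attributing the discount at aggregation). QALYs weight occupancy by
state utility and a multiplicative age/sex adjustment, and subtract
adverse-event disutility losses at initiation cycles:
loss = initiations × events/patient × weeks/event × |disutility| / 52.

Event counts (recurrences, metastatic treatment initiations, adverse
events, deaths) are reported **undiscounted** by default: they are counts
of occurrences, and fractional discounted deaths are not meaningful in a
table of projected events. A config switch (`discount_event_counts`)
applies the calendar discount to counts as well for users who want fully
discounted outcomes.

Percent changes (scenario II vs I, and varied vs base case in sensitivity
analyses) are rounded half away from zero to integers; this rounding rule
reproduces all eight published cumulative percent changes from the
published scenario columns. Sensitivity percent changes are raw signed
changes, round(100 × (varied − base)/|base|); note that the published
sensitivity table instead annotates signs by direction of benefit, so a
deeper death reduction appears there with a plus sign but here as a
negative change of a negative impact.

## Pipeline mechanics

All weekly cohorts of one (tumor, arm) pair share the same transition
laws, so a single unit-entry trace over the full 520 cycles serves every
entry week. The trace's per-cycle accrual matrix is convolved with the
schedule of weekly entry weights, then discounted and attributed to
calendar years; truncation at the horizon falls out of the convolution.
Arms whose accrual matrices are byte-identical are merged before
convolution — an optimization that also guarantees the two scenarios
coincide exactly (to the bit) when treatment effects, mixes and
adverse-event profiles are all null.

## Synthetic data

The generator emulates the structure of the unavailable trial-derived
inputs, not their values:

* Recurrence-free exits: Weibull recurrence laws (shape 0.9–1.3, scales
  450–650/550–800 weeks, chosen so a high-risk early-stage cohort accrues
  roughly 40–60% events over its exposure window) plus a small
  exponential death rate; the anti-PD-(L)1 arm applies one hazard ratio
  drawn in [0.55, 0.80] to all three exits (the trial effect is on the
  composite recurrence-free endpoint), with a symmetric log-scale 95% CI.
* Post-recurrence laws are exponential, shared across arms within a tumor
  (validated at load).
* 1L metastatic progression/survival are exponential per treatment option,
  with anti-PD-(L)1 hazard ratios in [0.55, 0.80] and CIs; 2L survival is
  a single law.
* Utilities are drawn ordered (recurrence-free > locoregional > 1L > 2L,
  all in (0.5, 0.9)); age adjustments decline in bands from 1.0 to ~0.85.
* Adverse-event rates are 0.6–0.9 events/patient for adjuvant
  anti-PD-(L)1 versus 0 (watchful waiting) or 0.3–0.6 (chemotherapy or
  targeted therapy), and 0.8–1.4 in the metastatic lines, with the
  published disutilities (−0.05/−0.13/−0.14 melanoma, −0.06/−0.05/−0.05
  RCC, −0.02/−0.03/−0.03 TNBC). The early-setting excess is what produces
  the published time pattern of adverse-event differences (positive in the
  first years, negative later) once metastatic treatment aversion
  dominates.
* The life table is Gompertz, q(age) = a·e^(0.10·age) with a = 1.6e-5
  (female) / 2.4e-5 (male), closed at age 100.

What passing tests on synthetic bundles show: conservation, absorption,
closed-form and microsimulation agreement, linearity, additivity, null
equivalence and the direction of the treatment effect — properties of the
machinery. What they do not show: agreement with the published absolute
outcome values, which depend on unpublished fitted parameters and are not
reproducible; only the published comparison layer (differences, percent
changes) and population fixtures are reproduced exactly.

## Validation oracle

`microsim_oracle` simulates individual patient trajectories by Bernoulli
sampling from the same weekly transition probabilities and accumulates the
same outcomes per patient with Monte-Carlo standard errors. The cohort
engine is the exact expectation of this process, so agreement within
sampling error (3 SE at n = 50,000 in the acceptance suite) is a sharp
check of the deterministic propagation, treatment-mix assignment and
accounting. Adverse events are expected counts per initiation in both
engines (a per-initiation intensity, not a per-patient lottery).

## Numerical choices and degenerate inputs

* Conservation is maintained to 1e-9 of entry size per cycle; tiny
  negative occupancies from floating-point are clamped at zero (warning
  above 1e-9).
* Arm allocation assigns the last traditional option by residual
  subtraction, so arm sizes sum to the cohort size exactly.
* An entry cohort of zero persons, a zero-population year, and zero-hazard
  laws (hr = 0) are all valid and produce exact zeros.
* Ages beyond the life table use the closing row (q = 1).
* Retreatment-threshold boundary: week 77 is "before", week 78 "at/after".

## Known limitations

* No patient heterogeneity beyond the cohort means (age, sex fraction);
  no treatment switching within a line; no cure fractions.
* The weekly grid slightly biases life-year integrals (O(hazard/2) per
  week, ~0.1–0.3% at realistic rates).
* Body weight is carried as a demographic input but is inert: it affected
  dosing and costs in the cost-effectiveness models this design descends
  from, and this package reports health outcomes only.
* Costs, budget impact and probabilistic sensitivity analysis are out of
  scope.
* Whether metastasis can bypass locoregional recurrence is configurable
  rather than asserted: `rf_to_met` may be a zero-hazard law if all
  metastasis should pass through the locoregional state.
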