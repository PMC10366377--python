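# Methods

## Model structure

A closed cohort of employees, mean age 50, disease-free at entry, is
propagated through an annual-cycle Markov model with 22 health states for
5 cycles:

* **6 event-free strata** — 10-year pooled-cohort-equation (PCE) risk
  category {low, moderate, high} crossed with CAD polygenic risk score
  group {bottom 80%, top 20%}. The initial PCE shares (0.410/0.363/0.227)
  are renormalized to sum to one; the PRS split is 20%/80% within every
  PCE category (no published joint distribution exists).
* **5 single-condition states** — coronary artery disease (CAD), ischemic
  stroke, and the statin side effects hemorrhagic stroke, new-onset
  diabetes and myopathy.
* **10 comorbid states** — every unordered pair of the five conditions.
  This is the unique enumeration consistent with the state count
  (6+5+10+1 = 22). A fraction already carrying two conditions that would
  acquire a third stays in its pair state.
* **1 absorbing death state.**

The fixed *risk-bearing* set — top-quintile PRS with moderate or high PCE
risk, plus bottom-80% PRS with high PCE risk (29.96% of the cohort at the
default initial distribution) — incurs CAD incidence (0.022/yr high PCE,
0.013/yr moderate, annualized from 20% and 12.5% 10-year risks; a 1.9-fold
direct multiplier for the top PRS quintile) and ischemic stroke incidence
(0.004/yr) in **every** strategy. Strategies differ only in treatment:
who initiates statins. Non-risk-bearing strata face background mortality
only. (The alternative reading in which all moderate/high-PCE employees
bear CAD risk raises all three strategies' totals roughly equally and
leaves every incremental result materially unchanged, because the extra
events occur in strata no strategy ever treats.)

## Strategies, enrollment and adherence

Enrollment (0.52) mixes program dynamics with no-program dynamics: the
cohort is split at cycle 0 into three persistent sub-cohorts (arms) —
enrolled-adherent (enrollment × adherence = 0.26), enrolled-non-adherent,
and non-enrolled — which are propagated separately and summed. Only the
enrolled-adherent arm, in strata its strategy treats, receives the statin
hazard-ratio risk reductions (CAD HR 0.560, ischemic stroke HR 0.770,
applied on the hazard scale: p → 1 − (1 − p)^HR), pays the $132/yr statin
cost, and is exposed to the statin side-effect risks (myopathy 0.0001,
diabetes 0.0015, hemorrhagic stroke 0.0002 per year). The hazard ratios
are applied as genuine hazard ratios — the residual risk factor is
~0.57/0.77, not 1 − HR. Treatment eligibility is re-evaluated every cycle
from the current (PCE category, PRS) pair, which matters only when
risk-category migration is active (annual PCE re-screening is part of
both programs).

Program cost schedules, charged to enrolled members alive at the start of
each cycle: PCE screening $58/yr (both programs); PRS-guided program adds
the one-time $145 PRS test in year 0, a one-time $114 primary-care
genetic-consultation visit for top-quintile-PRS members in year 0, and a
$6/yr mobile-app fee from year 1.

## Within-cycle ordering and reward conventions

Within a cycle, events are resolved first; the acute case fatality of the
entered state applies within the same cycle. Acute-event consequences are
charged as **transition tolls** at the cycle of the event (the standard
transition-reward idiom of decision-tree/Markov software): the acute
treatment cost weighted by within-cycle death (fatal vs non-fatal
variant), first-year lost productivity ($73,492 = absenteeism 14,698.4 +
4× presenteeism) for survivors of CAD/stroke events, and the acute
disutility (CAD 0.041, stroke 0.220) for all entrants. Survivors occupy
the chronic condition state from the next cycle. Diabetes and myopathy
have no acute phase: their follow-up costs and utilities apply from the
first full cycle in state. Competing acquisitions within a cycle use
independent probabilities, normalized only if their sum exceeds 1 (never
at default values).

Continuous rewards (utility, background cost $4,941/yr, condition
follow-up costs, follow-up productivity) accrue **trapezoidally** over
the occupancy snapshots at cycle boundaries 0..5 (half weight at both
ends), discounted at (1.03)^-t. Scheduled program charges use
start-of-cycle occupancy with full weight. The half-cycle choice is
deliberate: with pure start-of-cycle accrual the discounted QALY ceiling
of an event-free member is Σ(1−0.004t)/1.03^t ≈ 4.68, which overstates a
5-year horizon by about half a cycle; the trapezoid is the standard
correction. `RunConfig(cycle_correction="none"|"end")` switches to the
uncorrected conventions, and the closed form above is exactly reproduced
under `"none"`.

## Mortality

Event-free members die at the life-table rate q(age). Established
conditions use disease-specific annual risks alone (acute CAD 0.228,
chronic CAD 0.070, acute ischemic stroke 0.100, acute hemorrhagic stroke
0.390, chronic stroke 0.069, CAD+stroke pairs 0.075), with diabetes
multipliers on the hazard scale (×1.81 with CAD, ×1.67 with ischemic
stroke, ×1.68 otherwise). `RunConfig(condition_mortality_includes_background=True)`
additionally compounds the life-table hazard into condition states; the
default keeps disease-specific risks alone, because the published
condition-specific death risks are all-cause observational estimates that
already embed background mortality.

## Utilities and costs

Event-free utility is 1; condition states multiply their weights (CAD
0.790, stroke 0.630 shared between ischemic and hemorrhagic, diabetes
0.800, myopathy 0.917) — multiplicative combination is the standard
choice for comorbid states. An aging decrement of 0.004 per elapsed year
applies to all alive states; utilities are floored at 0. Costs are
additive: background + follow-up treatment (CAD 11,815; stroke 20,005;
diabetes 10,026; myopathy 20,438) + lost productivity (9,056/yr for
CAD/stroke/myopathy, 9,242/yr for diabetes; summed over a pair's
components) + program charges. The ledger decomposition
(background/medical/productivity/program) is exposed per cycle and sums
exactly to the total. Money is consumed as already-adjusted US$2019. All
results are per cohort member; a per-enrolled-member normalization is
also exposed (`CohortTrace.total_cost_per_enrolled`) since program
summaries sometimes quote "per employee screened".

## Parameters and distributions

Every annual input ships in `src/cardiocea/data/annual_parameters.csv`
with baseline, one-way range and sampling family: beta for probabilities,
utilities and disutilities; log-normal (log-scale μ, σ) for relative
effects; gamma (shape, rate) for costs. Where a published shape pair does
not reproduce its published baseline within 2%, the second shape
parameter is recalibrated so the mean equals the baseline while the first
parameter (hence the relative dispersion) is kept; the data dictionary
lists all such rows. The post-CAD ischemic stroke risk (0.015) has no
published range: it is held fixed in one-way analysis and sampled in PSA
from a beta calibrated to a ±25% 95%-interval. Sampling uses independent
per-parameter substreams derived from one master seed (a CRC of the
parameter name), so adding or removing a parameter never perturbs another
parameter's draws; no cross-parameter correlation is modeled.

## Sensitivity analyses

**One-way**: every parameter with a range is set to its low and then high
endpoint with all else at baseline, the full three-strategy model is
rerun (batched into a single vectorized cohort run), and parameters are
ranked by the width of the induced swing in incremental net monetary
benefit at $50,000/QALY. The three initial-distribution shares are
renormalized to the simplex after perturbation (the engine always
normalizes them).

**Probabilistic**: n independent joint draws (default 10,000), one
vectorized model run per strategy with draw-indexed parameters,
(ΔC, ΔE) clouds per comparison and acceptability curves on a WTP grid
including $50,000. Degenerate all-fixed parameter sets reproduce the base
case exactly.

## Risk-migration scenario

Annual 3×3 row-stochastic matrices move event-free mass between PCE
categories, composed before event transitions, starting after the first
year. The no-program cohort follows the natural annual change (off-
diagonals 25, 5, 35, 20, 6, 31% in the order low→mod, low→high, mod→low,
mod→high, high→low, high→mod); program cohorts follow the
enrollment-weighted convex blend of the natural and in-program (12.05,
0.62, 46.35, 7.66, 15.65, 48.70%) matrices. The default blend weight puts
0.52 on the *natural* matrix because that weighting reproduces the
published blended vector (18.780, 2.900, 40.450, 14.080, 10.630, 39.500%)
to within ~0.004 percentage points, even though the enrolled share is
itself 52%; `w_natural` is exposed for the alternative reading. Migrating
fractions keep their PRS tag; condition-state fractions do not migrate.
Identity matrices reproduce the base case bit for bit.

## Synthetic life table

The published background-mortality table is not redistributable, so the
default is a Gompertz stand-in q(age) = 0.004·exp(0.09·(age−50)), matching
the order of magnitude of US period tables at age 50 and giving a
remaining life expectancy at 50 of ~32 years (validated against a 28–35
year band by running the event-free cohort to extinction). Over a 5-year
horizon the results are insensitive to the exact table; any `age,qx` CSV
can be supplied instead. The life table is a simplification: it has no
sex/ancestry structure and no mortality improvement, so absolute survival
beyond the modeled horizon should not be read off it.

## Verification strategy

The tests cross-check the cohort engine against independent routes: dense
per-cycle transition matrices assembled from the same probability
primitives (row-stochasticity to 1e-9 and matrix-vs-flux agreement), an
individual-level Monte-Carlo simulation of 10^5 sampled employees
(occupancy agreement within 3 standard errors at every cycle), closed
forms for event-free cohorts, and structural invariants (mass
conservation to 1e-9, monotone death, adherence→0 collapsing program
dynamics onto the no-program path, CEAC monotonicity when every draw
gains QALYs). The synthetic-data fixtures emulate the published inputs,
not real claims data: passing tests demonstrate internal correctness of
the decision model under those inputs, not predictive validity for any
actual workforce.

## Known limitations

* Statin effectiveness is uniform across eligible strata, constant over
  the horizon, and adherence is a persistent 50/50 split fixed at entry.
* No parameter correlation in PSA; no treatment switching; no recurrence
  states (recurrent-event costs are carried inside the follow-up cost
  inputs); no ancestry/sex structure.
* Several literature-derived shape parameters and the productivity
  decompositions are internally inconsistent at printed precision; the
  packaged fixture resolves each case toward the printed baseline value
  and documents the resolution in the data dictionary.
* With the printed inputs read at face value (true hazard-ratio
  semantics, survivors-only first-year productivity), the model's
  incremental cost advantage of the PRS-guided program over no program is
  smaller than some published point estimates derived from the same
  inputs; the dominance ordering, QALY totals and gains, scenario
  incrementals and acceptability probabilities are insensitive to this.
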