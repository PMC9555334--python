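# Methods

## Model structure and assumptions

`dpcvalue` is a deterministic budget-impact model with a one-year horizon.
It values the incremental primary-care activity of patients with diabetes who
are currently unengaged with care, from the health system's perspective
(revenue and provider cost; no patient costs, no QALYs, no discounting).

The chain has five stages, each a pure function of its inputs:

1. **Segmentation.** The population with diabetes is split by last HbA1c into
   controlled (<7), moderately controlled (7 to <9, half-open) and
   uncontrolled (>=9). Records without an HbA1c are treated as moderately
   controlled: the provider is expected to order the test at an early visit,
   after which the patient can be reclassified. Boundary values classify
   upward (9.0 is uncontrolled).
2. **Engagement funnel.** Per segment, `overdue = population x overdue_rate`
   and `unengaged = overdue x no_future_visit_rate`. The rates are inputs
   (typically measured from the system's own registry), not estimated by the
   model. At the record level, "overdue" means the last primary-care visit is
   *strictly* more than the segment lookback (11/5/2 calendar months,
   day-anchored, clamped to month end) before the evaluation date; a patient
   never seen is overdue. "Unengaged" additionally requires no visit scheduled
   within 3 months after the evaluation date.
3. **Professional revenue.** Each of ten billable services carries an
   allocation fraction (comorbidity base rate), a per-payer status
   (payable / bundled into the office visit / not covered) and a unit fee per
   payer. Revenue per (payer, code) cell is
   `allocated x visits_per_year x fee`; allocated services recur at every
   recommended annual visit (a per-code `per_visit` flag can switch a code to
   once-per-year billing). The payer split and code allocations are counts;
   dollar amounts are never re-rounded inside the table.
4. **Provider compensation.** An uptake fraction (default 10%) gates the
   unengaged population down to an engaged cohort. RVU-bearing codes
   contribute `allocated x work_RVU` annually; the total times a single
   conversion factor (default $41.94/RVU, the MGMA median; no GPCI
   adjustment) is the annual compensation, and monthly is annual/12.
5. **Inpatient margin and summary.** Expected admissions are
   `floor(engaged x 0.339)` (the national annual hospitalization rate among
   people with diabetes; floor matches the published count, configurable).
   Admissions are spread across payers proportionally to the payer mix
   (default) or as equal thirds, each reimbursed at a per-payer amount
   (defaults $2700/$2000/$1280). The waterfall is
   `margin = professional + inpatient - compensation`, held in integer cents
   so the identity is exact, and `value per appointment = margin / attended`.
   Attended appointments default to the engaged patient count (one valued
   appointment per engaged patient per year); an `attended_basis="visits"`
   alternative counts every cadence visit.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| segment fractions | .50/.355/.145 | share | national (CDC) distribution of HbA1c control |
| overdue rates | .131/.298/.611 | share | measured engagement of the reference system |
| no-future-visit rates | .962/.867/.756 | share | measured scheduling behaviour |
| payer mix | .663/.205/.132 | share | national payer distribution, commercial rounded down to make the shares sum to 1 |
| uptake | 0.10 | share | conservative attendance estimate for digital outreach; first thing to revisit with real data |
| conversion factor | 41.94 | $/RVU | MGMA median |
| hospitalization rate | 0.339 | admissions/person/yr | national rate for people with diabetes |
| inpatient reimbursement | 2700/2000/1280 | $/admission | Medicare operating base; commercial at 135%, Medicaid at 64% of it |
| rounding | half_up | — | see below |

## Rounding

No rounding rule is published for the source tables; half-up at every count
stage reproduces every printed integer (8859.5 -> 8860, 9613.5 -> 9614,
6537.5 -> 6538, 2403.5 -> 2404, 478.5 -> 479), so it is the default, with
`floor` and `none` (fractional counts, used as the closed-form oracle)
selectable. Implementation detail: products are snapped to nine decimal
places (half-even) before the half-up step, because binary floating point
renders 14500 x 0.611 as 8859.4999999999998. Payer splits round each payer
independently by default, so a split may over- or under-count by up to
(payers - 1) — exactly as the source table's 9614+2973+1914 = 14,501 does;
a largest-remainder mode conserves the total exactly for analytic use.

## Calibration of the packaged fixture

The published example prints revenue cells and RVU components but not unit
fees or per-code work RVUs. The fixture back-derives
`fee = printed revenue / (allocated x 4)` and
`work_RVU = printed component / allocated` at full float precision, so the
printed tables are reproduced to the printed digit. These are calibration
values, not authoritative CMS/Palmetto/Medicaid amounts; the office-visit RVU
lands exactly on 1.92, while the education/cessation codes sit near 0.18/0.24
but not on them (the printed rows are not consistent with any single
two-decimal RVU). Users with real fee schedules should supply their own CSVs.

## Documented source inconsistencies

Three published figures cannot be reproduced from the published inputs, and
the package deliberately never asserts them as equalities:

* The inpatient total $1,796,506 is not recoverable from any stated
  combination of count and rates; the payer-proportional reconstruction gives
  $1,793,378 (within 0.2%), and tests assert a 0.5% band. "Even mix across
  payer type" is read as payer-proportional because equal thirds lands ~16%
  low.
* The engaged cohort is 2217 (= half-up 10% of 22,171) in the compensation
  table but 2235 in the inpatient text; the model computes 2217 and offers
  `engaged_override` to replicate either.
* The summary's printed margin ($3,050,957) and per-appointment value ($1297)
  are inconsistent with its own printed components, which recombine to
  $2,899,695 and $1307.94; the package reports recomputed values only.

The model's own end-to-end value per appointment on the packaged scenario is
$1,167.93 — lower than the published-components figure because the engaged
cohort's professional revenue is recomputed from the calibrated fee schedule
rather than taken from the unpublished per-segment tables. The professional
revenue entering the waterfall is computed on the engaged cohort by default
(`revenue_basis="engaged"`); `"unengaged"` and `"segment_population"` bases
are available for potential-revenue analyses. With the engaged basis every
waterfall term scales with uptake, which is why per-appointment value is
structurally insensitive to the uptake assumption (exactly so without count
rounding; to within rounding granularity otherwise).

## Synthetic registry

The generator draws segment, overdue status, scheduling status, payer and
diabetes type independently per patient at the configured rates, then places
last-visit and next-visit dates strictly inside or outside the corresponding
calendar windows, so the record-level eligibility engine recovers the drawn
statuses exactly. HbA1c values are sampled uniformly within each band (capped
just below band edges so one-decimal display rounding cannot cross a
boundary); missing HbA1c is only assigned within the moderately-controlled
draw so the classification rule preserves the requested segment frequencies.
It emulates marginal rates only: no correlation between payer and severity,
no seasonality in scheduling, no visit-history dynamics, no gestational or
medication-induced diabetes. Passing oracle-equivalence tests therefore
demonstrates that the aggregate arithmetic and the record-level rules agree —
not that either matches any real system's registry.

Problem sizes in the test suite (50,000-record census; 20 x 4,000-record
recovery study; 1,000 random waterfall configurations; 100–200 PSA draws)
were chosen to keep binomial standard errors small relative to the asserted
3-sigma bands while the whole suite runs in seconds.

## Sensitivity analysis

One-way analysis reruns the scenario at two bounds of one registered scalar
(uptake, hospitalization rate, conversion factor, a global fee scale, or a
payer share with proportional renormalization of the other two). The
probabilistic analysis samples registered parameters independently from
point/uniform/triangular/scaled-beta distributions with a seeded generator,
reruns the scenario per draw, and summarises per-appointment value by
quantiles; fixed seeds give identical draws.

## Known limitations

Comorbidity allocations, engagement rates and fees are system-specific; the
packaged values describe one hypothetical system. The model bills every
allocated code at every recommended visit, applies the flat national
hospitalization rate to the engaged cohort (no engagement-driven reduction;
`rate_multiplier` exposes that scenario), ignores claim-level adjudication
(denials, deductibles, modifiers), and treats inpatient demand as revenue
rather than cost — appropriate for the health-system lens, not a societal
one.
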