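# dpcvalue

**What is a primary-care visit by an unengaged patient with diabetes worth to a
health system?** `dpcvalue` is a budget-impact engine that answers this with a
transparent, fully testable calculation chain. It was built for health-economics
analysts and digital-health vendors who need to price or prioritise
interventions that bring unengaged patients with diabetes back to primary care.

## The model

Patients with diabetes are segmented by their last HbA1c value
(HEDIS bands: `<7` controlled, `7–<9` moderately controlled, `≥9`
uncontrolled), each band carrying an ADA-recommended visit cadence
(1 / 2 / 4 visits per year) and a matching overdue lookback
(`>11` / `>5` / `>2` months). A patient is **unengaged** when they are overdue
*and* have no visit scheduled in the next 3 months. The value chain is then:

```
population ─▶ overdue ─▶ unengaged ─▶ engaged (uptake, default 10%)
                                          │
        ┌─────────────────────────────────┼──────────────────────┐
        ▼                                 ▼                      ▼
 professional revenue          provider compensation      inpatient margin
 Σ_payer Σ_code  alloc ×       Σ_code alloc × wRVU ×      ⌊engaged × 0.339⌋ ×
 visits/yr × fee(payer,code)   CF ($/RVU, default 41.94)  Σ_payer mix_p × rate_p

 total margin = professional + inpatient − compensation
 value per appointment = total margin / attended appointments
```

Revenue is apportioned across a commercial / Medicare / Medicaid payer mix;
each CPT-style code carries a comorbidity-derived allocation fraction (e.g.
44% of patients need a lipid panel) and can be payable, bundled into the
office visit, or not covered per payer. All counts round half-up at each
pipeline stage (configurable); dollars are carried at full precision and the
waterfall holds integer cents, so the margin identity is exact.

The package also ships a **synthetic registry generator** that emulates an EHR
diabetes registry record-by-record (HbA1c, visit dates, payer) and serves as
an independent oracle for the aggregate arithmetic, plus one-way and
probabilistic (Monte-Carlo) sensitivity analysis.

## Worked example

The packaged configuration describes a hypothetical system of 100,000 patients
with diabetes (CDC segment shares, national payer mix, calibrated fee
schedule):

```bash
dpcvalue value --format report
```

prints

```
Engagement funnel
  segment                   population   overdue  unengaged
  controlled                     50000      6550       6301
  moderately_controlled          35500     10579       9172
  uncontrolled                   14500      8860       6698
  total                         100000     25989      22171

Provider compensation
  engaged patients          2217
  annual work RVUs          5,006.87
  conversion factor         $41.94/RVU
  annual compensation       $209,988
  monthly compensation      $17,499

Value waterfall (annual)
  professional revenue      $1,020,122
  inpatient revenue         $1,779,164
  provider compensation    -$209,988
  total margin              $2,589,298
  attended appointments     2217
  value per appointment     $1,167.93
```

Of the 100,000 patients, 22,171 are unengaged; at 10% uptake, 2,217 attend an
appointment. Their visits generate ~$1.02M of professional revenue a year,
~$1.78M of inpatient margin (751 expected admissions at the 339-per-1000
national rate), minus $209,988 of provider compensation — about $1,168 of
margin per appointment the intervention produces. `dpcvalue replicate-paper`
runs the same scenario as a pass/fail checklist against the published source
tables, and `dpcvalue sensitivity --one-way uptake_fraction 0.05 0.20` shows
the per-appointment value is structurally flat in uptake (every term scales
with the engaged cohort).

## Layout

| module | role |
|---|---|
| `dpcvalue.cohort` | segmentation, engagement funnel, payer split, rounding policy |
| `dpcvalue.registry` | synthetic registry generator + record-level eligibility |
| `dpcvalue.revenue` | per-payer per-code professional revenue |
| `dpcvalue.compensation` | uptake gating, work RVUs, conversion factor |
| `dpcvalue.inpatient` | hospitalization counts and inpatient margin |
| `dpcvalue.summary` | waterfall, ROI, one-way & probabilistic sensitivity |
| `dpcvalue.config` / `report` / `cli` | YAML/CSV I/O, deterministic reports, CLI |
| `dpcvalue.fixtures` | calibrated replication catalog and fee schedule |

See `docs/methods.md` for assumptions, calibration details and limitations.
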