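"""Synthetic diabetes-registry generator and record-level eligibility engine.

This module mirrors what a health system extracts from its EHR diabetes
registry: one row per patient with their latest HbA1c, last primary-care
visit date, next scheduled visit date and payer.  The same segmentation and
engagement criteria that the aggregate cohort model applies to counts are
applied here patient-by-patient, which makes a generated registry an
independent oracle for the aggregate funnel arithmetic.

The generator draws each patient's segment, overdue status, scheduling
status and payer as independent Bernoulli/categorical draws at the requested
rates, then synthesises visit dates that realise those statuses under the
calendar-month window rules.  Gestational and medication-induced diabetes
are excluded by construction (the generator never emits them).
"""

from __future__ import annotations

import calendar
import csv
import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cohort import (
    DEFAULT_POLICIES,
    PAYERS,
    ControlSegment,
    FunnelRow,
    FunnelTable,
    PayerMix,
    SegmentPolicy,
    ValidationError,
)

__all__ = [
    "PatientRecord",
    "RegistryParams",
    "classify_control",
    "is_overdue",
    "is_unengaged",
    "generate_registry",
    "aggregate_registry",
    "add_months",
    "write_registry_csv",
    "read_registry_csv",
]

#: HbA1c sampling ranges per segment (percent units), loosely matching the
#: clinical distribution within each control band.
_HBA1C_RANGES = {
    # upper bounds sit below the band edge so one-decimal rounding of the
    # sampled value can never cross into the next segment
    ControlSegment.controlled: (5.2, 6.94),
    ControlSegment.moderately_controlled: (7.0, 8.94),
    ControlSegment.uncontrolled: (9.0, 13.4),
}


@dataclass(frozen=True)
class PatientRecord:
    """One diabetes-registry row."""

    patient_id: str
    hba1c: float | None
    last_pcp_visit_date: dt.date | None
    next_scheduled_visit_date: dt.date | None
    payer: str
    diabetes_type: str = "type2"

    def __post_init__(self):
        errs = []
        if self.hba1c is not None and self.hba1c <= 0:
            errs.append(f"hba1c must be positive or absent, got {self.hba1c}")
        if self.payer not in PAYERS:
            errs.append(f"unknown payer {self.payer!r}")
        if self.diabetes_type not in ("type1", "type2"):
            errs.append(f"unknown diabetes_type {self.diabetes_type!r}")
        if errs:
            raise ValidationError(errs)


@dataclass(frozen=True)
class RegistryParams:
    """Controls for the synthetic registry generator.

    The rates have the same meaning as in :class:`~dpcvalue.cohort.CohortSpec`;
    ``random_seed`` fully determines the output.  ``missing_hba1c_fraction``
    applies only to patients assigned to the moderately-controlled segment so
    that the "absent HbA1c counts as moderately controlled" classification
    rule cannot distort the requested segment frequencies.
    """

    n_patients: int
    segment_fractions: Mapping[ControlSegment, float]
    overdue_rate: Mapping[ControlSegment, float]
    no_future_visit_rate: Mapping[ControlSegment, float]
    payer_mix: PayerMix
    evaluation_date: dt.date = dt.date(2022, 7, 1)
    missing_hba1c_fraction: float = 0.0
    type1_fraction: float = 0.05
    random_seed: int = 0

    def __post_init__(self):
        errs = []
        if self.n_patients < 0:
            errs.append("n_patients must be >= 0")
        if not 0.0 <= self.missing_hba1c_fraction <= 1.0:
            errs.append("missing_hba1c_fraction outside [0, 1]")
        if not 0.0 <= self.type1_fraction <= 1.0:
            errs.append("type1_fraction outside [0, 1]")
        if errs:
            raise ValidationError(errs)


def add_months(date: dt.date, months: int) -> dt.date:
    """Shift a date by calendar months, clamping to month end.

    July 31 minus 5 months lands on February 28 (or 29 in leap years).
    """
    month_index = date.month - 1 + months
    year = date.year + month_index // 12
    month = month_index % 12 + 1
    day = min(date.day, calendar.monthrange(year, month)[1])
    return dt.date(year, month, day)


def classify_control(hba1c: float | None) -> ControlSegment:
    """Map an HbA1c value to its control segment.

    Half-open bands: <7 controlled, [7, 9) moderately controlled, >=9
    uncontrolled.  A missing value is treated as moderately controlled —
    the provider is expected to order an HbA1c at the first or second
    visit, after which the patient can be reclassified.
    """
    if hba1c is None:
        return ControlSegment.moderately_controlled
    if hba1c <= 0:
        raise ValidationError(f"hba1c must be positive or absent, got {hba1c}")
    if hba1c < 7.0:
        return ControlSegment.controlled
    if hba1c < 9.0:
        return ControlSegment.moderately_controlled
    return ControlSegment.uncontrolled


def is_overdue(record: PatientRecord, policy: SegmentPolicy, as_of: dt.date) -> bool:
    """True when the last visit is strictly more than the lookback ago.

    A patient with no recorded visit at all is overdue: never seen is
    maximally unengaged.  The boundary is strict — a visit exactly
    ``lookback`` calendar months before ``as_of`` is not yet overdue.
    """
    if record.last_pcp_visit_date is None:
        return True
    threshold = add_months(as_of, -policy.overdue_lookback_months)
    return record.last_pcp_visit_date < threshold


def is_unengaged(record: PatientRecord, policy: SegmentPolicy, as_of: dt.date) -> bool:
    """True when overdue AND nothing is scheduled inside the forward window."""
    if not is_overdue(record, policy, as_of):
        return False
    nxt = record.next_scheduled_visit_date
    if nxt is None:
        return True
    horizon = add_months(as_of, policy.future_window_months)
    return nxt > horizon


def generate_registry(params: RegistryParams) -> list[PatientRecord]:
    """Draw a synthetic registry whose marginal rates match ``params``.

    Segment, overdue status, no-future-visit status and payer are sampled
    independently per patient; dates are then placed inside or outside the
    policy windows so that applying :func:`is_overdue` / :func:`is_unengaged`
    with :data:`~dpcvalue.cohort.DEFAULT_POLICIES` at ``evaluation_date``
    recovers exactly the drawn statuses.  Output is deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(params.random_seed)
    n = params.n_patients
    if n == 0:
        return []
    as_of = params.evaluation_date

    seg_probs = [params.segment_fractions[s] for s in ControlSegment]
    seg_idx = rng.choice(len(seg_probs), size=n, p=np.asarray(seg_probs) / sum(seg_probs))
    payer_probs = np.array([params.payer_mix[p] for p in PAYERS])
    payer_idx = rng.choice(len(PAYERS), size=n, p=payer_probs / payer_probs.sum())
    u_overdue = rng.random(n)
    u_nofuture = rng.random(n)
    u_missing = rng.random(n)
    u_type1 = rng.random(n)
    hba1c_u = rng.random(n)
    day_jitter = rng.integers(1, 365, size=n)
    inside_jitter = rng.random(n)
    sched_absent = rng.random(n)
    sched_far = rng.integers(1, 181, size=n)

    records: list[PatientRecord] = []
    for i in range(n):
        seg = ControlSegment(int(seg_idx[i]) + 1)
        policy = DEFAULT_POLICIES[seg]
        lo, hi = _HBA1C_RANGES[seg]
        hba1c: float | None = round(lo + (hi - lo) * float(hba1c_u[i]), 1)
        if (
            seg is ControlSegment.moderately_controlled
            and u_missing[i] < params.missing_hba1c_fraction
        ):
            hba1c = None

        threshold = add_months(as_of, -policy.overdue_lookback_months)
        overdue = u_overdue[i] < params.overdue_rate[seg]
        if overdue:
            last_visit = threshold - dt.timedelta(days=int(day_jitter[i]))
        else:
            span = (as_of - threshold).days
            last_visit = threshold + dt.timedelta(days=int(inside_jitter[i] * (span + 1)))

        horizon = add_months(as_of, policy.future_window_months)
        if overdue and u_nofuture[i] < params.no_future_visit_rate[seg]:
            # unengaged: either nothing on the books or something too far out
            if sched_absent[i] < 0.7:
                nxt = None
            else:
                nxt = horizon + dt.timedelta(days=int(sched_far[i]))
        else:
            # a visit inside the forward window keeps the patient engaged
            span = (horizon - as_of).days
            nxt = as_of + dt.timedelta(days=1 + int(inside_jitter[i] * (span - 1)))

        records.append(
            PatientRecord(
                patient_id=f"P{i:07d}",
                hba1c=hba1c,
                last_pcp_visit_date=last_visit,
                next_scheduled_visit_date=nxt,
                payer=PAYERS[int(payer_idx[i])],
                diabetes_type="type1" if u_type1[i] < params.type1_fraction else "type2",
            )
        )
    return records


def aggregate_registry(
    records: Iterable[PatientRecord],
    policies: Mapping[ControlSegment, SegmentPolicy] = DEFAULT_POLICIES,
    as_of: dt.date = dt.date(2022, 7, 1),
) -> FunnelTable:
    """Exact record-level census of the engagement funnel (no rounding)."""
    pop = {s: 0 for s in ControlSegment}
    over = {s: 0 for s in ControlSegment}
    unen = {s: 0 for s in ControlSegment}
    for rec in records:
        seg = classify_control(rec.hba1c)
        policy = policies[seg]
        pop[seg] += 1
        if is_overdue(rec, policy, as_of):
            over[seg] += 1
            if is_unengaged(rec, policy, as_of):
                unen[seg] += 1
    rows = tuple(
        FunnelRow(s, float(pop[s]), float(over[s]), float(unen[s]))
        for s in ControlSegment
    )
    return FunnelTable(rows)


# ---------------------------------------------------------------------------
# CSV round-trip (ISO-8601 dates, empty string for absent values)
# ---------------------------------------------------------------------------

_COLUMNS = [
    "patient_id",
    "hba1c",
    "last_pcp_visit_date",
    "next_scheduled_visit_date",
    "payer",
    "diabetes_type",
]


def write_registry_csv(records: Sequence[PatientRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.patient_id,
                    "" if r.hba1c is None else f"{r.hba1c:g}",
                    "" if r.last_pcp_visit_date is None else r.last_pcp_visit_date.isoformat(),
                    ""
                    if r.next_scheduled_visit_date is None
                    else r.next_scheduled_visit_date.isoformat(),
                    r.payer,
                    r.diabetes_type,
                ]
            )


def read_registry_csv(path) -> list[PatientRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            records.append(
                PatientRecord(
                    patient_id=row["patient_id"],
                    hba1c=float(row["hba1c"]) if row["hba1c"] else None,
                    last_pcp_visit_date=dt.date.fromisoformat(row["last_pcp_visit_date"])
                    if row["last_pcp_visit_date"]
                    else None,
                    next_scheduled_visit_date=dt.date.fromisoformat(
                        row["next_scheduled_visit_date"]
                    )
                    if row["next_scheduled_visit_date"]
                    else None,
                    payer=row["payer"],
                    diabetes_type=row["diabetes_type"],
                )
            )
    return records
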