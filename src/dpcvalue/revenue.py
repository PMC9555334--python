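"""Professional-practice revenue per payer per CPT code.

Each billable service carries an allocation fraction — the share of patients
with diabetes expected to receive it at a visit, driven by comorbidity base
rates (e.g. 44% need a lipid panel, 100% the office visit itself).  For a
segment's payer sub-population the engine allocates patients per code,
multiplies by the segment's annual visit cadence to get a service volume,
and prices each service from a per-payer fee schedule.  Services bundled
into the office-visit payment, or not covered by a payer, retain their
allocation but contribute zero revenue.

Dollars are carried at full floating-point precision through the table;
rounding to whole dollars happens only at presentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .cohort import (
    PAYERS,
    PayerMix,
    RoundingPolicy,
    SegmentPolicy,
    ValidationError,
    payer_split,
)

__all__ = [
    "CptCatalogEntry",
    "FeeSchedule",
    "RevenueCell",
    "RevenueTable",
    "PAYABLE",
    "BUNDLED",
    "NOT_COVERED",
    "allocate_patients",
    "annual_service_volume",
    "professional_revenue",
]

PAYABLE = "payable"
BUNDLED = "bundled"
NOT_COVERED = "not_covered"
_STATUSES = (PAYABLE, BUNDLED, NOT_COVERED)


@dataclass(frozen=True)
class CptCatalogEntry:
    """One billable service: allocation share, work RVU, per-payer status.

    ``code_key`` is an opaque identifier, never authoritative CPT text.
    ``work_rvu`` is the provider work credit per billed service; absent for
    codes that carry no physician work (pure lab codes).  ``per_visit=True``
    means the service recurs at every recommended annual visit; ``False``
    bills it once per year regardless of cadence.
    """

    code_key: str
    description: str
    allocation_fraction: float
    work_rvu: float | None = None
    payer_payable: Mapping[str, str] = None  # type: ignore[assignment]
    per_visit: bool = True

    def __post_init__(self):
        if self.payer_payable is None:
            object.__setattr__(self, "payer_payable", {p: PAYABLE for p in PAYERS})
        errs = []
        if not 0.0 <= self.allocation_fraction <= 1.0:
            errs.append(
                f"{self.code_key}: allocation_fraction {self.allocation_fraction} "
                "outside [0, 1]"
            )
        if self.work_rvu is not None and self.work_rvu < 0:
            errs.append(f"{self.code_key}: work_rvu must be >= 0")
        for p in PAYERS:
            status = self.payer_payable.get(p)
            if status not in _STATUSES:
                errs.append(f"{self.code_key}: invalid payable status {status!r} for {p}")
        if errs:
            raise ValidationError(errs)


@dataclass(frozen=True)
class FeeSchedule:
    """Dollars per service, keyed by (payer, code_key)."""

    fees: Mapping[tuple[str, str], float]
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        errs = [
            f"fee for {key} is negative ({v})"
            for key, v in self.fees.items()
            if v < 0
        ]
        if errs:
            raise ValidationError(errs)

    def fee(self, payer: str, code_key: str) -> float:
        try:
            return self.fees[(payer, code_key)]
        except KeyError:
            raise ValidationError(
                f"no fee for payable pair payer={payer!r} code={code_key!r}"
            ) from None

    def scaled(self, k: float) -> "FeeSchedule":
        return FeeSchedule({key: v * k for key, v in self.fees.items()}, self.provenance)


@dataclass(frozen=True)
class RevenueCell:
    payer: str
    code_key: str
    allocated_patients: float
    services_per_year: float
    status: str
    revenue: float


@dataclass(frozen=True)
class RevenueTable:
    """Per-(payer, code) revenue with per-payer and grand totals."""

    cells: tuple[RevenueCell, ...]
    payer_counts: Mapping[str, float]

    @property
    def payer_totals(self) -> dict[str, float]:
        totals = {p: 0.0 for p in PAYERS}
        for c in self.cells:
            totals[c.payer] += c.revenue
        return totals

    @property
    def grand_total(self) -> float:
        return sum(c.revenue for c in self.cells)

    def cell(self, payer: str, code_key: str) -> RevenueCell:
        for c in self.cells:
            if c.payer == payer and c.code_key == code_key:
                return c
        raise KeyError((payer, code_key))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "payer": [c.payer for c in self.cells],
                "code_key": [c.code_key for c in self.cells],
                "allocated_patients": [c.allocated_patients for c in self.cells],
                "services_per_year": [c.services_per_year for c in self.cells],
                "status": [c.status for c in self.cells],
                "revenue_usd": [round(c.revenue, 2) for c in self.cells],
            }
        )


def allocate_patients(
    payer_count: float,
    entry: CptCatalogEntry,
    rounding: RoundingPolicy = RoundingPolicy.half_up,
) -> float:
    """Number of patients in a payer sub-population expected to need a code."""
    if payer_count < 0:
        raise ValidationError(f"payer_count must be >= 0, got {payer_count}")
    return rounding.round(payer_count * entry.allocation_fraction)


def annual_service_volume(allocated: float, visits_per_year: int) -> float:
    """Services billed per year: allocated patients times visit cadence."""
    if allocated < 0 or visits_per_year < 0:
        raise ValidationError("allocated and visits_per_year must be >= 0")
    return allocated * visits_per_year


def professional_revenue(
    segment_population: float,
    mix: PayerMix,
    catalog: Sequence[CptCatalogEntry],
    fees: FeeSchedule,
    policy: SegmentPolicy,
    rounding: RoundingPolicy = RoundingPolicy.half_up,
    apportion: bool = False,
) -> RevenueTable:
    """Annual professional revenue for one segment, by payer and code.

    revenue(payer, code) = allocated x services/yr x fee, zero when the code
    is bundled into the office visit or not covered by the payer.
    """
    counts = payer_split(segment_population, mix, rounding, apportion=apportion)
    cells = []
    for payer in PAYERS:
        for entry in catalog:
            allocated = allocate_patients(counts[payer], entry, rounding)
            visits = policy.visits_per_year if entry.per_visit else 1
            volume = annual_service_volume(allocated, visits)
            status = entry.payer_payable[payer]
            if status == PAYABLE:
                revenue = volume * fees.fee(payer, entry.code_key)
            else:
                revenue = 0.0
            cells.append(
                RevenueCell(payer, entry.code_key, allocated, volume, status, revenue)
            )
    return RevenueTable(tuple(cells), counts)
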