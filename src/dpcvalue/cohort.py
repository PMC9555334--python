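"""Aggregate cohort model: HbA1c segmentation, engagement funnel, payer split.

The population with diabetes is segmented by glycemic control (HbA1c
<7 / 7-<9 / >=9), each segment carries a recommended annual visit cadence
(1 / 2 / 4 visits per year, per ADA guidance) and a matching overdue lookback
(>11 / >5 / >2 months since the last primary-care visit).  The engagement
funnel narrows each segment: population -> overdue -> unengaged (overdue AND
no visit scheduled inside the next 3 months).  Counts are produced by
multiplying the upstream count by a rate and rounding at every stage, so that
each rounded intermediate feeds the next stage.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, ROUND_HALF_UP, Decimal
from typing import Mapping

import pandas as pd

__all__ = [
    "ControlSegment",
    "SegmentPolicy",
    "CohortSpec",
    "PayerMix",
    "RoundingPolicy",
    "FunnelRow",
    "FunnelTable",
    "ValidationError",
    "PAYERS",
    "DEFAULT_POLICIES",
    "segment_counts",
    "engagement_funnel",
    "payer_split",
]

PAYERS = ("commercial", "medicare", "medicaid")

_FRACTION_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when a model input violates its contract.

    ``errors`` lists every failure found, not just the first.
    """

    def __init__(self, errors):
        if isinstance(errors, str):
            errors = [errors]
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class ControlSegment(enum.IntEnum):
    """Glycemic-control segment, ordered by severity."""

    controlled = 1           # HbA1c < 7
    moderately_controlled = 2  # 7 <= HbA1c < 9
    uncontrolled = 3         # HbA1c >= 9

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


SEGMENTS = tuple(ControlSegment)


class RoundingPolicy(enum.Enum):
    """How fractional counts are turned into integers at each funnel stage.

    ``half_up`` rounds .5 away from zero at each stage (this reproduces every
    integer count in the published tables); ``floor`` truncates; ``none``
    keeps fractional counts, which is useful as a closed-form oracle.
    """

    half_up = "half_up"
    floor = "floor"
    none = "none"

    def round(self, x: float) -> float:
        # Snap float noise at the ninth decimal before rounding: products
        # such as 14500 * 0.611 evaluate to 8859.499999999998 in binary
        # floating point but are exactly 8859.5 in decimal arithmetic.
        if self is RoundingPolicy.none:
            return float(x)
        d = Decimal(x).quantize(Decimal("1e-9"), rounding=ROUND_HALF_EVEN)
        if self is RoundingPolicy.half_up:
            return float(d.to_integral_value(rounding=ROUND_HALF_UP))
        return float(math.floor(d))


@dataclass(frozen=True)
class SegmentPolicy:
    """Visit cadence and eligibility windows for one control segment."""

    segment: ControlSegment
    visits_per_year: int
    overdue_lookback_months: int
    future_window_months: int = 3

    def __post_init__(self):
        errs = []
        if self.visits_per_year not in (1, 2, 4):
            errs.append(
                f"visits_per_year must be 1, 2 or 4, got {self.visits_per_year}"
            )
        if self.overdue_lookback_months <= 0:
            errs.append("overdue_lookback_months must be positive")
        if self.future_window_months <= 0:
            errs.append("future_window_months must be positive")
        if errs:
            raise ValidationError(errs)


#: HEDIS/ADA defaults: 1 visit/yr (>11-month lookback) when controlled,
#: 2 visits/yr (>5 months) when moderately controlled, 4 visits/yr
#: (>2 months) when uncontrolled; all with a 3-month forward window.
DEFAULT_POLICIES: Mapping[ControlSegment, SegmentPolicy] = {
    ControlSegment.controlled: SegmentPolicy(ControlSegment.controlled, 1, 11),
    ControlSegment.moderately_controlled: SegmentPolicy(
        ControlSegment.moderately_controlled, 2, 5
    ),
    ControlSegment.uncontrolled: SegmentPolicy(ControlSegment.uncontrolled, 4, 2),
}


def _check_fractions(name: str, fractions: Mapping, keys, errs: list[str]) -> None:
    missing = [str(k) for k in keys if k not in fractions]
    if missing:
        errs.append(f"{name} missing entries for: {', '.join(missing)}")
        return
    for k in keys:
        v = fractions[k]
        if not 0.0 <= v <= 1.0:
            errs.append(f"{name}[{k}] = {v} outside [0, 1]")
    total = sum(fractions[k] for k in keys)
    if abs(total - 1.0) > _FRACTION_TOL:
        errs.append(
            f"{name} must sum to 1 (got {total!r}, deficit {1.0 - total:+.3g})"
        )


def _check_rates(name: str, rates: Mapping, keys, errs: list[str]) -> None:
    missing = [str(k) for k in keys if k not in rates]
    if missing:
        errs.append(f"{name} missing entries for: {', '.join(missing)}")
        return
    for k in keys:
        v = rates[k]
        if not 0.0 <= v <= 1.0:
            errs.append(f"{name}[{k}] = {v} outside [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Aggregate description of a health system's diabetes population."""

    total_population: int
    segment_fractions: Mapping[ControlSegment, float]
    overdue_rate: Mapping[ControlSegment, float]
    no_future_visit_rate: Mapping[ControlSegment, float]

    def __post_init__(self):
        errs: list[str] = []
        if self.total_population < 0:
            errs.append(f"total_population must be >= 0, got {self.total_population}")
        _check_fractions("segment_fractions", self.segment_fractions, SEGMENTS, errs)
        _check_rates("overdue_rate", self.overdue_rate, SEGMENTS, errs)
        _check_rates("no_future_visit_rate", self.no_future_visit_rate, SEGMENTS, errs)
        if errs:
            raise ValidationError(errs)


@dataclass(frozen=True)
class PayerMix:
    """Fractional split of patients across commercial / Medicare / Medicaid."""

    fractions: Mapping[str, float]

    def __post_init__(self):
        errs: list[str] = []
        unknown = set(self.fractions) - set(PAYERS)
        if unknown:
            errs.append(f"unknown payers: {sorted(unknown)}")
        _check_fractions("payer_mix", self.fractions, PAYERS, errs)
        if errs:
            raise ValidationError(errs)

    def __getitem__(self, payer: str) -> float:
        return self.fractions[payer]


@dataclass(frozen=True)
class FunnelRow:
    segment: ControlSegment
    population: float
    overdue: float
    unengaged: float


@dataclass(frozen=True)
class FunnelTable:
    """Per-segment population/overdue/unengaged counts with column totals."""

    rows: tuple[FunnelRow, ...]
    total_population: float = field(init=False)
    total_overdue: float = field(init=False)
    total_unengaged: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(
            self, "total_population", sum(r.population for r in self.rows)
        )
        object.__setattr__(self, "total_overdue", sum(r.overdue for r in self.rows))
        object.__setattr__(
            self, "total_unengaged", sum(r.unengaged for r in self.rows)
        )

    def row(self, segment: ControlSegment) -> FunnelRow:
        for r in self.rows:
            if r.segment is segment:
                return r
        raise KeyError(segment)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "segment": [r.segment.name for r in self.rows],
                "population": [r.population for r in self.rows],
                "overdue": [r.overdue for r in self.rows],
                "unengaged": [r.unengaged for r in self.rows],
            }
        )
        total = pd.DataFrame(
            {
                "segment": ["total"],
                "population": [self.total_population],
                "overdue": [self.total_overdue],
                "unengaged": [self.total_unengaged],
            }
        )
        return pd.concat([df, total], ignore_index=True)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def segment_counts(
    total: int,
    fractions: Mapping[ControlSegment, float],
    rounding: RoundingPolicy = RoundingPolicy.half_up,
) -> dict[ControlSegment, float]:
    """Split a total population into control segments.

    Each segment count is ``round(total * fraction)`` under the policy,
    rounded independently (so the rounded counts may not sum exactly to
    ``total``; use :class:`RoundingPolicy.none` for exact fractional counts).
    """
    errs: list[str] = []
    if total < 0:
        errs.append(f"total must be >= 0, got {total}")
    _check_fractions("segment_fractions", fractions, SEGMENTS, errs)
    if errs:
        raise ValidationError(errs)
    return {seg: rounding.round(total * fractions[seg]) for seg in SEGMENTS}


def engagement_funnel(
    spec: CohortSpec, rounding: RoundingPolicy = RoundingPolicy.half_up
) -> FunnelTable:
    """Apply the population -> overdue -> unengaged funnel per segment.

    Rounding is applied stage by stage: the rounded overdue count feeds the
    unengaged multiplication, matching how the published counts chain.
    """
    pops = segment_counts(spec.total_population, spec.segment_fractions, rounding)
    rows = []
    for seg in SEGMENTS:
        population = pops[seg]
        overdue = rounding.round(population * spec.overdue_rate[seg])
        unengaged = rounding.round(overdue * spec.no_future_visit_rate[seg])
        rows.append(FunnelRow(seg, population, overdue, unengaged))
    return FunnelTable(tuple(rows))


def payer_split(
    count: int,
    mix: PayerMix,
    rounding: RoundingPolicy = RoundingPolicy.half_up,
    apportion: bool = False,
) -> dict[str, float]:
    """Split a patient count across payers.

    With ``apportion=False`` (replication mode) each payer count is rounded
    independently, so the counts may sum to slightly more or less than
    ``count`` (at most payers-1 off).  With ``apportion=True`` the
    largest-remainder method is used and the split conserves ``count``
    exactly.
    """
    if count < 0:
        raise ValidationError(f"count must be >= 0, got {count}")
    if not apportion:
        return {p: rounding.round(count * mix[p]) for p in PAYERS}
    exact = {p: count * mix[p] for p in PAYERS}
    base = {p: math.floor(exact[p]) for p in PAYERS}
    shortfall = int(round(count - sum(base.values())))
    # hand leftover units to the largest remainders; ties broken by payer order
    order = sorted(PAYERS, key=lambda p: (-(exact[p] - base[p]), PAYERS.index(p)))
    for p in order[:shortfall]:
        base[p] += 1
    return {p: float(base[p]) for p in PAYERS}
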