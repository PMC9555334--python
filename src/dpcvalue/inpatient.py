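"""Inpatient-care margin attributable to the engaged cohort.

Nationally, 339 of every 1000 people with diabetes need inpatient care in a
year.  Applying that rate to the engaged cohort gives an expected admission
count; each admission is reimbursed at a per-payer amount (defaults $2700
commercial / $2000 Medicare / $1280 Medicaid).  Admissions are spread across
payers either in proportion to the population payer mix (default) or as
equal thirds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .cohort import PAYERS, PayerMix, RoundingPolicy, ValidationError

__all__ = ["InpatientParams", "hospitalized_count", "inpatient_revenue"]

PAYER_PROPORTIONAL = "payer_proportional"
EQUAL_THIRDS = "equal_thirds"


def _default_reimbursement() -> dict[str, float]:
    return {"commercial": 2700.0, "medicare": 2000.0, "medicaid": 1280.0}


@dataclass(frozen=True)
class InpatientParams:
    """Hospitalization rate, per-payer reimbursement, and mixing mode.

    ``rate_multiplier`` scales the national hospitalization rate for
    scenario analysis (e.g. to model engagement reducing admissions);
    it defaults to 1 (no reduction).
    """

    hospitalization_rate: float = 0.339
    per_payer_reimbursement: Mapping[str, float] = field(
        default_factory=_default_reimbursement
    )
    mix_mode: str = PAYER_PROPORTIONAL
    count_rounding: RoundingPolicy = RoundingPolicy.floor
    rate_multiplier: float = 1.0

    def __post_init__(self):
        errs = []
        if not 0.0 <= self.hospitalization_rate <= 1.0:
            errs.append("hospitalization_rate outside [0, 1]")
        if self.rate_multiplier < 0:
            errs.append("rate_multiplier must be >= 0")
        for p in PAYERS:
            if p not in self.per_payer_reimbursement:
                errs.append(f"missing inpatient reimbursement for {p}")
            elif self.per_payer_reimbursement[p] < 0:
                errs.append(f"inpatient reimbursement for {p} is negative")
        if self.mix_mode not in (PAYER_PROPORTIONAL, EQUAL_THIRDS):
            errs.append(f"unknown mix_mode {self.mix_mode!r}")
        if errs:
            raise ValidationError(errs)


def hospitalized_count(engaged: float, params: InpatientParams) -> float:
    """Expected admissions among the engaged cohort over one year.

    The default rounding is floor — the published count truncates the
    fractional expectation.
    """
    if engaged < 0:
        raise ValidationError("engaged must be >= 0")
    return params.count_rounding.round(
        engaged * params.hospitalization_rate * params.rate_multiplier
    )


def inpatient_revenue(
    hospitalized: float, mix: PayerMix, params: InpatientParams
) -> float:
    """Annual inpatient reimbursement across payers, full precision."""
    if hospitalized < 0:
        raise ValidationError("hospitalized must be >= 0")
    rates = params.per_payer_reimbursement
    if params.mix_mode == EQUAL_THIRDS:
        mean_rate = math.fsum(rates[p] for p in PAYERS) / len(PAYERS)
        return hospitalized * mean_rate
    return math.fsum(hospitalized * mix[p] * rates[p] for p in PAYERS)
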