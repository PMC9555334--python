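"""Provider compensation: uptake-gated engaged cohort -> work RVUs -> dollars.

Only a fraction of the unengaged population is expected to respond to
outreach and attend an appointment (a conservative default of 10%).  For the
resulting engaged cohort, each RVU-bearing code contributes
``allocated_patients x work_rvu`` relative value units; the annual total is
converted to dollars with a single conversion factor (dollars per RVU, e.g.
the MGMA median of $41.94).  Codes without a work RVU — lab services whose
technical component is billed elsewhere — contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .cohort import RoundingPolicy, ValidationError
from .revenue import CptCatalogEntry, allocate_patients

__all__ = [
    "UptakeParams",
    "CompensationResult",
    "engaged_cohort",
    "rvu_totals",
    "provider_compensation",
]


@dataclass(frozen=True)
class UptakeParams:
    """Expected appointment attendance among the unengaged population."""

    uptake_fraction: float = 0.10
    engaged_override: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.uptake_fraction <= 1.0:
            raise ValidationError(
                f"uptake_fraction {self.uptake_fraction} outside [0, 1]"
            )
        if self.engaged_override is not None and self.engaged_override < 0:
            raise ValidationError("engaged_override must be >= 0")


@dataclass(frozen=True)
class CompensationResult:
    engaged_count: float
    rvu_components: Mapping[str, float]
    rvu_total: float
    conversion_factor: float
    annual_compensation: float
    monthly_compensation: float


def engaged_cohort(
    unengaged_total: float,
    uptake: UptakeParams,
    rounding: RoundingPolicy = RoundingPolicy.half_up,
) -> float:
    """Patients expected to attend: rounded uptake share of the unengaged."""
    if unengaged_total < 0:
        raise ValidationError("unengaged_total must be >= 0")
    if uptake.engaged_override is not None:
        return float(uptake.engaged_override)
    return rounding.round(unengaged_total * uptake.uptake_fraction)


def rvu_totals(
    engaged: float,
    catalog: Sequence[CptCatalogEntry],
    rounding: RoundingPolicy = RoundingPolicy.half_up,
) -> dict[str, float]:
    """Annual work RVUs per RVU-bearing code for the engaged cohort."""
    if engaged < 0:
        raise ValidationError("engaged must be >= 0")
    components: dict[str, float] = {}
    for entry in catalog:
        if entry.work_rvu is None:
            continue
        allocated = allocate_patients(engaged, entry, rounding)
        components[entry.code_key] = allocated * entry.work_rvu
    return components


def provider_compensation(
    rvu_total: float,
    conversion_factor: float,
    rvu_components: Mapping[str, float] | None = None,
    engaged_count: float = 0.0,
) -> CompensationResult:
    """Convert annual work RVUs to dollars; monthly is annual / 12."""
    if rvu_total < 0 or conversion_factor < 0:
        raise ValidationError("rvu_total and conversion_factor must be >= 0")
    annual = rvu_total * conversion_factor
    return CompensationResult(
        engaged_count=engaged_count,
        rvu_components=dict(rvu_components or {}),
        rvu_total=rvu_total,
        conversion_factor=conversion_factor,
        annual_compensation=annual,
        monthly_compensation=annual / 12.0,
    )


def compute_compensation(
    unengaged_total: float,
    uptake: UptakeParams,
    catalog: Sequence[CptCatalogEntry],
    conversion_factor: float,
    rounding: RoundingPolicy = RoundingPolicy.half_up,
) -> CompensationResult:
    """End-to-end convenience: unengaged total -> CompensationResult."""
    engaged = engaged_cohort(unengaged_total, uptake, rounding)
    components = rvu_totals(engaged, catalog, rounding)
    return provider_compensation(
        sum(components.values()), conversion_factor, components, engaged
    )
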