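"""Value waterfall, return on investment, and sensitivity analysis.

The waterfall assembles the model's bottom line:

    professional revenue (annual) + inpatient revenue (annual)
      - provider compensation (annual)  =  total margin (annual)

divided by the number of attended appointments to give a dollar value per
primary-care appointment.  Dollar components are held as integer cents so
the margin identity is exact, not merely close.

Sensitivity analysis reruns the full scenario with perturbed inputs:
one-way over a registered scalar parameter, or Monte-Carlo (probabilistic
sensitivity analysis) with independent input distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .cohort import (
    ControlSegment,
    FunnelTable,
    PayerMix,
    RoundingPolicy,
    ValidationError,
    engagement_funnel,
)
from .compensation import (
    CompensationResult,
    engaged_cohort,
    provider_compensation,
    rvu_totals,
)
from .config import ModelConfig
from .inpatient import hospitalized_count, inpatient_revenue
from .revenue import RevenueTable, professional_revenue

__all__ = [
    "UndefinedValueError",
    "ValueWaterfall",
    "ScenarioResult",
    "SensitivityResult",
    "value_per_appointment",
    "run_scenario",
    "roi",
    "one_way_sensitivity",
    "probabilistic_sensitivity",
    "REGISTERED_PARAMETERS",
]


class UndefinedValueError(ArithmeticError):
    """Raised when a per-appointment value is requested with zero appointments."""


def _cents(dollars: float) -> int:
    return int(round(dollars * 100))


@dataclass(frozen=True)
class ValueWaterfall:
    """Assembled annual result, components in integer cents."""

    professional_revenue_cents: int
    inpatient_revenue_cents: int
    provider_compensation_cents: int
    attended_appointments: float

    @property
    def total_margin_cents(self) -> int:
        return (
            self.professional_revenue_cents
            + self.inpatient_revenue_cents
            - self.provider_compensation_cents
        )

    @property
    def professional_revenue_annual(self) -> float:
        return self.professional_revenue_cents / 100.0

    @property
    def inpatient_revenue_annual(self) -> float:
        return self.inpatient_revenue_cents / 100.0

    @property
    def provider_compensation_annual(self) -> float:
        return self.provider_compensation_cents / 100.0

    @property
    def total_margin_annual(self) -> float:
        return self.total_margin_cents / 100.0

    @property
    def value_per_appointment(self) -> float | None:
        """Dollars of margin per attended appointment; None when undefined."""
        if self.attended_appointments <= 0:
            return None
        return self.total_margin_annual / self.attended_appointments


@dataclass(frozen=True)
class ScenarioResult:
    """Waterfall plus every intermediate table from a scenario run."""

    config: ModelConfig
    funnel: FunnelTable
    revenue_tables: Mapping[ControlSegment, RevenueTable]
    revenue_basis_counts: Mapping[ControlSegment, float]
    compensation: CompensationResult
    hospitalized: float
    waterfall: ValueWaterfall


@dataclass(frozen=True)
class SensitivityResult:
    parameter: str
    low: float | None = None
    high: float | None = None
    low_value_per_appointment: float | None = None
    high_value_per_appointment: float | None = None
    draws: int = 0
    seed: int | None = None
    quantiles: Mapping[float, float] = field(default_factory=dict)
    samples: tuple[float, ...] = ()


def value_per_appointment(
    prof: float, inpat: float, comp: float, attended: float
) -> float:
    """(prof + inpat - comp) / attended, full precision.

    Raises :class:`UndefinedValueError` when ``attended`` is zero rather
    than returning an infinity.
    """
    if attended <= 0:
        raise UndefinedValueError(
            f"value per appointment undefined for attended={attended}"
        )
    return (prof + inpat - comp) / attended


def run_scenario(config: ModelConfig) -> ScenarioResult:
    """Run the full calculation chain for one configuration.

    cohort funnel -> per-segment professional revenue -> provider
    compensation -> inpatient revenue -> waterfall.  Deterministic: the
    same configuration always yields the same result.
    """
    rounding = config.rounding
    fees = config.fees if config.fee_scale == 1.0 else config.fees.scaled(config.fee_scale)

    funnel = engagement_funnel(config.cohort, rounding)

    engaged_total = engaged_cohort(funnel.total_unengaged, config.uptake, rounding)

    basis_counts: dict[ControlSegment, float] = {}
    revenue_tables: dict[ControlSegment, RevenueTable] = {}
    prof_total = 0.0
    for seg in ControlSegment:
        row = funnel.row(seg)
        if config.revenue_basis == "segment_population":
            base = row.population
        elif config.revenue_basis == "unengaged":
            base = row.unengaged
        else:  # engaged (default): uptake-gated share of the unengaged
            base = rounding.round(row.unengaged * config.uptake.uptake_fraction)
        basis_counts[seg] = base
        table = professional_revenue(
            base,
            config.payer_mix,
            config.catalog,
            fees,
            config.policies[seg],
            rounding,
        )
        revenue_tables[seg] = table
        prof_total += table.grand_total

    components = rvu_totals(engaged_total, config.catalog, rounding)
    comp = provider_compensation(
        sum(components.values()),
        config.conversion_factor,
        components,
        engaged_total,
    )

    hospitalized = hospitalized_count(engaged_total, config.inpatient)
    inpat = inpatient_revenue(hospitalized, config.payer_mix, config.inpatient)

    if config.attended_basis == "visits":
        attended = sum(
            basis_counts[s] * config.policies[s].visits_per_year
            for s in ControlSegment
        )
    else:
        attended = engaged_total

    waterfall = ValueWaterfall(
        professional_revenue_cents=_cents(prof_total),
        inpatient_revenue_cents=_cents(inpat),
        provider_compensation_cents=_cents(comp.annual_compensation),
        attended_appointments=attended,
    )
    return ScenarioResult(
        config=config,
        funnel=funnel,
        revenue_tables=revenue_tables,
        revenue_basis_counts=basis_counts,
        compensation=comp,
        hospitalized=hospitalized,
        waterfall=waterfall,
    )


def roi(waterfall: ValueWaterfall, intervention_cost_annual: float) -> float:
    """Return on investment: (margin - cost) / cost."""
    if intervention_cost_annual <= 0:
        raise ValidationError(
            f"intervention_cost_annual must be > 0, got {intervention_cost_annual}"
        )
    return (
        waterfall.total_margin_annual - intervention_cost_annual
    ) / intervention_cost_annual


# ---------------------------------------------------------------------------
# parameter registry for sensitivity analysis
# ---------------------------------------------------------------------------


def _set_uptake(cfg: ModelConfig, v: float) -> ModelConfig:
    return replace(cfg, uptake=replace(cfg.uptake, uptake_fraction=v))


def _set_hosp_rate(cfg: ModelConfig, v: float) -> ModelConfig:
    return replace(cfg, inpatient=replace(cfg.inpatient, hospitalization_rate=v))


def _set_cf(cfg: ModelConfig, v: float) -> ModelConfig:
    return replace(cfg, conversion_factor=v)


def _set_fee_scale(cfg: ModelConfig, v: float) -> ModelConfig:
    return replace(cfg, fee_scale=v)


def _payer_setter(payer: str):
    def setter(cfg: ModelConfig, v: float) -> ModelConfig:
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"payer share {v} outside [0, 1]")
        old = dict(cfg.payer_mix.fractions)
        rest = 1.0 - old[payer]
        new = {}
        for p, f in old.items():
            if p == payer:
                new[p] = v
            elif rest > 0:
                new[p] = f * (1.0 - v) / rest
            else:
                new[p] = (1.0 - v) / (len(old) - 1)
        return replace(cfg, payer_mix=PayerMix(new))

    return setter


REGISTERED_PARAMETERS = {
    "uptake_fraction": _set_uptake,
    "hospitalization_rate": _set_hosp_rate,
    "conversion_factor": _set_cf,
    "fee_scale": _set_fee_scale,
    "payer_mix.commercial": _payer_setter("commercial"),
    "payer_mix.medicare": _payer_setter("medicare"),
    "payer_mix.medicaid": _payer_setter("medicaid"),
}


def _apply(cfg: ModelConfig, name: str, value: float) -> ModelConfig:
    try:
        setter = REGISTERED_PARAMETERS[name]
    except KeyError:
        raise ValidationError(
            f"unknown parameter {name!r}; registered parameters: "
            + ", ".join(sorted(REGISTERED_PARAMETERS))
        ) from None
    return setter(cfg, value)


def one_way_sensitivity(
    config: ModelConfig, parameter: str, low: float, high: float
) -> SensitivityResult:
    """Rerun the scenario at two bounds of one parameter, all else fixed."""
    lo_res = run_scenario(_apply(config, parameter, low))
    hi_res = run_scenario(_apply(config, parameter, high))
    return SensitivityResult(
        parameter=parameter,
        low=low,
        high=high,
        low_value_per_appointment=lo_res.waterfall.value_per_appointment,
        high_value_per_appointment=hi_res.waterfall.value_per_appointment,
    )


def _sample(rng: np.random.Generator, spec: Mapping) -> float:
    family = spec.get("dist")
    if family == "point":
        return float(spec["value"])
    if family == "uniform":
        return float(rng.uniform(spec["low"], spec["high"]))
    if family == "triangular":
        return float(rng.triangular(spec["low"], spec["mode"], spec["high"]))
    if family == "beta":
        lo = float(spec.get("low", 0.0))
        hi = float(spec.get("high", 1.0))
        a, b = float(spec["a"]), float(spec["b"])
        if a <= 0 or b <= 0 or hi <= lo:
            raise ValidationError(f"invalid beta parameters: {dict(spec)}")
        return lo + (hi - lo) * float(rng.beta(a, b))
    raise ValidationError(
        f"unknown distribution family {family!r}; supported: "
        "point, uniform, triangular, beta"
    )


def probabilistic_sensitivity(
    config: ModelConfig,
    distributions: Mapping[str, Mapping],
    n_draws: int,
    seed: int,
) -> SensitivityResult:
    """Monte-Carlo propagation of input distributions through the model.

    Each draw samples every listed parameter independently, reruns the
    scenario, and records the value per appointment.  Fixed seed gives
    identical draws and quantiles on every run.
    """
    if n_draws <= 0:
        raise ValidationError("n_draws must be positive")
    for name in distributions:
        if name not in REGISTERED_PARAMETERS:
            raise ValidationError(
                f"unknown parameter {name!r}; registered parameters: "
                + ", ".join(sorted(REGISTERED_PARAMETERS))
            )
    # validate distribution specs up front with a throwaway stream
    probe = np.random.default_rng(0)
    for spec in distributions.values():
        _sample(probe, spec)

    rng = np.random.default_rng(seed)
    samples: list[float] = []
    for _ in range(n_draws):
        cfg = config
        for name, spec in distributions.items():
            cfg = _apply(cfg, name, _sample(rng, spec))
        v = run_scenario(cfg).waterfall.value_per_appointment
        if v is not None:
            samples.append(v)
    arr = np.asarray(samples)
    qs = (0.025, 0.25, 0.5, 0.75, 0.975)
    quantiles = {q: float(np.quantile(arr, q)) for q in qs} if len(arr) else {}
    return SensitivityResult(
        parameter=",".join(distributions),
        draws=n_draws,
        seed=seed,
        quantiles=quantiles,
        samples=tuple(samples),
    )
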