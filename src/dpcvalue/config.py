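"""Configuration loading, validation, and delimited-table I/O.

A scenario is described by a YAML (or JSON) document with sections for the
cohort, payer mix, visit policies, CPT catalog, fee schedule, uptake,
conversion factor, inpatient parameters and rounding.  Validation is total:
either a fully constructed :class:`ModelConfig` is returned or a
:class:`~dpcvalue.cohort.ValidationError` listing *every* failure is raised.
Catalog and fee schedules travel as CSV; ``"packaged"`` selects the
calibrated replication fixture shipped with the package.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import fixtures
from .cohort import (
    DEFAULT_POLICIES,
    PAYERS,
    CohortSpec,
    ControlSegment,
    PayerMix,
    RoundingPolicy,
    SegmentPolicy,
    ValidationError,
)
from .compensation import UptakeParams
from .inpatient import InpatientParams
from .revenue import CptCatalogEntry, FeeSchedule

__all__ = [
    "ModelConfig",
    "load_config",
    "replication_config",
    "read_catalog_csv",
    "write_catalog_csv",
    "read_fee_schedule_csv",
    "write_fee_schedule_csv",
]

logger = logging.getLogger("dpcvalue")

REVENUE_BASES = ("engaged", "unengaged", "segment_population")
ATTENDED_BASES = ("engaged_patients", "visits")


@dataclass(frozen=True)
class ModelConfig:
    """Complete, validated input set for one scenario run."""

    cohort: CohortSpec
    payer_mix: PayerMix
    catalog: Sequence[CptCatalogEntry]
    fees: FeeSchedule
    policies: Mapping[ControlSegment, SegmentPolicy] = field(
        default_factory=lambda: dict(DEFAULT_POLICIES)
    )
    uptake: UptakeParams = field(default_factory=UptakeParams)
    conversion_factor: float = fixtures.CONVERSION_FACTOR
    inpatient: InpatientParams = field(default_factory=InpatientParams)
    rounding: RoundingPolicy = RoundingPolicy.half_up
    revenue_basis: str = "engaged"
    attended_basis: str = "engaged_patients"
    fee_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        errs = []
        if self.conversion_factor < 0:
            errs.append("conversion_factor must be >= 0")
        if self.fee_scale < 0:
            errs.append("fee_scale must be >= 0")
        if self.revenue_basis not in REVENUE_BASES:
            errs.append(
                f"revenue_basis {self.revenue_basis!r} not in {REVENUE_BASES}"
            )
        if self.attended_basis not in ATTENDED_BASES:
            errs.append(
                f"attended_basis {self.attended_basis!r} not in {ATTENDED_BASES}"
            )
        for seg in ControlSegment:
            if seg not in self.policies:
                errs.append(f"missing policy for segment {seg.name}")
        if errs:
            raise ValidationError(errs)


def replication_config(**overrides) -> ModelConfig:
    """The packaged worked-example configuration (100,000 patients)."""
    cfg = ModelConfig(
        cohort=fixtures.replication_cohort(),
        payer_mix=fixtures.replication_payer_mix(),
        catalog=fixtures.paper_catalog(),
        fees=fixtures.paper_fee_schedule(),
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# YAML config loading
# ---------------------------------------------------------------------------


def _segment_map(raw: Mapping, what: str, errs: list[str]) -> dict:
    out = {}
    for key, value in (raw or {}).items():
        try:
            out[ControlSegment[key]] = value
        except KeyError:
            errs.append(f"{what}: unknown segment {key!r}")
    return out


def load_config(path) -> ModelConfig:
    """Read and validate a scenario configuration file.

    Missing optional sections are filled with defaults and logged;
    semantic failures are aggregated into one error.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: top level must be a mapping")

    errs: list[str] = []
    base = path.parent

    cohort = None
    if "cohort" not in raw:
        errs.append("missing required section 'cohort'")
    else:
        c = raw["cohort"]
        try:
            cohort = CohortSpec(
                total_population=int(c.get("total_population", 0)),
                segment_fractions=_segment_map(
                    c.get("segment_fractions"), "segment_fractions", errs
                ),
                overdue_rate=_segment_map(c.get("overdue_rate"), "overdue_rate", errs),
                no_future_visit_rate=_segment_map(
                    c.get("no_future_visit_rate"), "no_future_visit_rate", errs
                ),
            )
        except ValidationError as exc:
            errs.extend(f"cohort: {e}" for e in exc.errors)

    payer_mix = None
    if "payer_mix" not in raw:
        errs.append("missing required section 'payer_mix'")
    else:
        try:
            payer_mix = PayerMix(dict(raw["payer_mix"]))
        except ValidationError as exc:
            errs.extend(f"payer_mix: {e}" for e in exc.errors)

    policies = dict(DEFAULT_POLICIES)
    if "policies" in raw:
        for key, p in raw["policies"].items():
            try:
                seg = ControlSegment[key]
            except KeyError:
                errs.append(f"policies: unknown segment {key!r}")
                continue
            try:
                policies[seg] = SegmentPolicy(
                    segment=seg,
                    visits_per_year=int(p["visits_per_year"]),
                    overdue_lookback_months=int(p["overdue_lookback_months"]),
                    future_window_months=int(p.get("future_window_months", 3)),
                )
            except ValidationError as exc:
                errs.extend(f"policies.{key}: {e}" for e in exc.errors)
    else:
        logger.info("policies not given; using HEDIS/ADA defaults")

    catalog_src = raw.get("catalog", "packaged")
    if catalog_src == "packaged":
        catalog = fixtures.paper_catalog()
    else:
        try:
            catalog = read_catalog_csv(base / catalog_src)
        except (OSError, ValidationError, KeyError) as exc:
            errs.append(f"catalog: {exc}")
            catalog = fixtures.paper_catalog()

    fees_src = raw.get("fee_schedule", "packaged")
    if fees_src == "packaged":
        fees = fixtures.paper_fee_schedule()
    else:
        try:
            fees = read_fee_schedule_csv(base / fees_src)
        except (OSError, ValidationError, KeyError) as exc:
            errs.append(f"fee_schedule: {exc}")
            fees = fixtures.paper_fee_schedule()

    uptake = UptakeParams()
    if "uptake" in raw:
        u = raw["uptake"]
        try:
            uptake = UptakeParams(
                uptake_fraction=float(u.get("uptake_fraction", 0.10)),
                engaged_override=u.get("engaged_override"),
            )
        except ValidationError as exc:
            errs.extend(f"uptake: {e}" for e in exc.errors)
    else:
        logger.info("uptake not given; defaulting to 10%% attendance")

    inpatient = InpatientParams()
    if "inpatient" in raw:
        i = raw["inpatient"]
        try:
            inpatient = InpatientParams(
                hospitalization_rate=float(i.get("hospitalization_rate", 0.339)),
                per_payer_reimbursement=dict(
                    i.get(
                        "per_payer_reimbursement",
                        InpatientParams().per_payer_reimbursement,
                    )
                ),
                mix_mode=i.get("mix_mode", "payer_proportional"),
                count_rounding=RoundingPolicy(i.get("count_rounding", "floor")),
                rate_multiplier=float(i.get("rate_multiplier", 1.0)),
            )
        except (ValidationError, ValueError) as exc:
            errs.append(f"inpatient: {exc}")
    else:
        logger.info("inpatient not given; using national-rate defaults")

    if "rounding" not in raw:
        logger.info("rounding not given; defaulting to half_up")
    try:
        rounding = RoundingPolicy(raw.get("rounding", "half_up"))
    except ValueError:
        errs.append(
            f"rounding: unknown mode {raw.get('rounding')!r}; "
            f"expected one of {[m.value for m in RoundingPolicy]}"
        )
        rounding = RoundingPolicy.half_up

    if errs:
        raise ValidationError(errs)

    try:
        return ModelConfig(
            cohort=cohort,
            payer_mix=payer_mix,
            catalog=catalog,
            fees=fees,
            policies=policies,
            uptake=uptake,
            conversion_factor=float(
                raw.get("conversion_factor", fixtures.CONVERSION_FACTOR)
            ),
            inpatient=inpatient,
            rounding=rounding,
            revenue_basis=raw.get("revenue_basis", "engaged"),
            attended_basis=raw.get("attended_basis", "engaged_patients"),
            fee_scale=float(raw.get("fee_scale", 1.0)),
            seed=int(raw.get("seed", 0)),
        )
    except ValidationError:
        raise


# ---------------------------------------------------------------------------
# catalog / fee-schedule CSV round-trip
# ---------------------------------------------------------------------------

_CATALOG_COLUMNS = [
    "code_key",
    "description",
    "allocation",
    "work_rvu",
    "payable_commercial",
    "payable_medicare",
    "payable_medicaid",
    "per_visit",
]


def write_catalog_csv(catalog: Sequence[CptCatalogEntry], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CATALOG_COLUMNS)
        for e in catalog:
            writer.writerow(
                [
                    e.code_key,
                    e.description,
                    repr(e.allocation_fraction),
                    "" if e.work_rvu is None else repr(e.work_rvu),
                    e.payer_payable["commercial"],
                    e.payer_payable["medicare"],
                    e.payer_payable["medicaid"],
                    "true" if e.per_visit else "false",
                ]
            )


def read_catalog_csv(path) -> list[CptCatalogEntry]:
    entries = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            entries.append(
                CptCatalogEntry(
                    code_key=row["code_key"],
                    description=row["description"],
                    allocation_fraction=float(row["allocation"]),
                    work_rvu=float(row["work_rvu"]) if row["work_rvu"] else None,
                    payer_payable={
                        "commercial": row["payable_commercial"],
                        "medicare": row["payable_medicare"],
                        "medicaid": row["payable_medicaid"],
                    },
                    per_visit=row.get("per_visit", "true") != "false",
                )
            )
    if not entries:
        raise ValidationError(f"catalog file {path} contains no entries")
    return entries


def write_fee_schedule_csv(fees: FeeSchedule, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["payer", "code_key", "fee_usd"])
        for (payer, code), fee in sorted(fees.fees.items()):
            # repr round-trips the float exactly, preserving calibration
            writer.writerow([payer, code, repr(fee)])


def read_fee_schedule_csv(path) -> FeeSchedule:
    fees = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            if row["payer"] not in PAYERS:
                raise ValidationError(f"unknown payer {row['payer']!r} in {path}")
            fees[(row["payer"], row["code_key"])] = float(row["fee_usd"])
    if not fees:
        raise ValidationError(f"fee schedule {path} contains no entries")
    return FeeSchedule(fees)


def packaged_config_path() -> Path:
    """Path to the shipped replication YAML (usable as a CLI --config)."""
    return Path(resources.files("dpcvalue") / "data" / "replication.yaml")
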