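"""Deterministic report rendering: funnel, revenue, RVU and waterfall tables.

Two formats: ``csv`` (a dict of named CSV documents, byte-stable across
runs of the same scenario) and ``report`` (one human-readable text summary).
"""

from __future__ import annotations

from pathlib import Path

from .cohort import PAYERS, ControlSegment, ValidationError
from .summary import ScenarioResult

__all__ = ["render_report", "write_report"]

FORMATS = ("csv", "report")


def _count(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:.3f}"


def _usd(x: float) -> str:
    return f"{x:.2f}"


def _funnel_csv(result: ScenarioResult) -> str:
    lines = ["segment,population,overdue,unengaged"]
    f = result.funnel
    for row in f.rows:
        lines.append(
            f"{row.segment.name},{_count(row.population)},"
            f"{_count(row.overdue)},{_count(row.unengaged)}"
        )
    lines.append(
        f"total,{_count(f.total_population)},{_count(f.total_overdue)},"
        f"{_count(f.total_unengaged)}"
    )
    return "\n".join(lines) + "\n"


def _revenue_csv(result: ScenarioResult, seg: ControlSegment) -> str:
    table = result.revenue_tables[seg]
    lines = ["payer,code_key,allocated_patients,services_per_year,status,revenue_usd"]
    for c in table.cells:
        lines.append(
            f"{c.payer},{c.code_key},{_count(c.allocated_patients)},"
            f"{_count(c.services_per_year)},{c.status},{_usd(c.revenue)}"
        )
    for payer, total in table.payer_totals.items():
        lines.append(f"{payer},total,,,,{_usd(total)}")
    lines.append(f"all,total,,,,{_usd(table.grand_total)}")
    return "\n".join(lines) + "\n"


def _rvu_csv(result: ScenarioResult) -> str:
    comp = result.compensation
    lines = ["code_key,annual_work_rvus"]
    for code, rvus in comp.rvu_components.items():
        lines.append(f"{code},{rvus:.4f}")
    lines.append(f"total,{comp.rvu_total:.4f}")
    return "\n".join(lines) + "\n"


def _waterfall_csv(result: ScenarioResult) -> str:
    w = result.waterfall
    vpa = w.value_per_appointment
    lines = [
        "metric,value",
        f"professional_revenue_annual_usd,{_usd(w.professional_revenue_annual)}",
        f"inpatient_revenue_annual_usd,{_usd(w.inpatient_revenue_annual)}",
        f"provider_compensation_annual_usd,{_usd(w.provider_compensation_annual)}",
        f"total_margin_annual_usd,{_usd(w.total_margin_annual)}",
        f"engaged_count,{_count(result.compensation.engaged_count)}",
        f"hospitalized_count,{_count(result.hospitalized)}",
        f"attended_appointments,{_count(w.attended_appointments)}",
        f"value_per_appointment_usd,{'' if vpa is None else _usd(vpa)}",
    ]
    return "\n".join(lines) + "\n"


def _text_report(result: ScenarioResult) -> str:
    w = result.waterfall
    f = result.funnel
    comp = result.compensation
    out = []
    out.append("Diabetes primary-care value model — scenario summary")
    out.append("=" * 55)
    out.append("")
    out.append("Engagement funnel")
    out.append(f"  {'segment':<24}{'population':>12}{'overdue':>10}{'unengaged':>11}")
    for row in f.rows:
        out.append(
            f"  {row.segment.name:<24}{_count(row.population):>12}"
            f"{_count(row.overdue):>10}{_count(row.unengaged):>11}"
        )
    out.append(
        f"  {'total':<24}{_count(f.total_population):>12}"
        f"{_count(f.total_overdue):>10}{_count(f.total_unengaged):>11}"
    )
    out.append("")
    out.append("Professional revenue (annual, by segment)")
    for seg in ControlSegment:
        table = result.revenue_tables[seg]
        per_payer = "  ".join(
            f"{p}: ${table.payer_totals[p]:,.0f}" for p in PAYERS
        )
        out.append(f"  {seg.name:<24}{per_payer}")
    out.append("")
    out.append("Provider compensation")
    out.append(f"  engaged patients          {_count(comp.engaged_count)}")
    out.append(f"  annual work RVUs          {comp.rvu_total:,.2f}")
    out.append(f"  conversion factor         ${comp.conversion_factor:,.2f}/RVU")
    out.append(f"  annual compensation       ${comp.annual_compensation:,.0f}")
    out.append(f"  monthly compensation      ${comp.monthly_compensation:,.0f}")
    out.append("")
    out.append("Value waterfall (annual)")
    out.append(f"  professional revenue      ${w.professional_revenue_annual:,.0f}")
    out.append(f"  inpatient revenue         ${w.inpatient_revenue_annual:,.0f}")
    out.append(f"  provider compensation    -${w.provider_compensation_annual:,.0f}")
    out.append(f"  total margin              ${w.total_margin_annual:,.0f}")
    out.append(f"  attended appointments     {_count(w.attended_appointments)}")
    if w.value_per_appointment is None:
        out.append("  value per appointment     undefined (no attended appointments)")
    else:
        out.append(f"  value per appointment     ${w.value_per_appointment:,.2f}")
    return "\n".join(out) + "\n"


def render_report(result: ScenarioResult, fmt: str = "report") -> dict[str, str]:
    """Render a scenario as named text artifacts.

    ``csv`` yields one document per section; ``report`` a single text
    summary.  Unknown formats raise an error listing the supported ones.
    """
    if fmt not in FORMATS:
        raise ValidationError(
            f"unknown format {fmt!r}; supported formats: {', '.join(FORMATS)}"
        )
    if fmt == "report":
        return {"report.txt": _text_report(result)}
    artifacts = {"funnel.csv": _funnel_csv(result)}
    for seg in ControlSegment:
        artifacts[f"revenue_{seg.name}.csv"] = _revenue_csv(result, seg)
    artifacts["rvu.csv"] = _rvu_csv(result)
    artifacts["waterfall.csv"] = _waterfall_csv(result)
    return artifacts


def write_report(result: ScenarioResult, out_dir, fmt: str = "csv") -> list[Path]:
    """Render and write artifacts under ``out_dir``; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, text in render_report(result, fmt).items():
        p = out_dir / name
        p.write_text(text)
        paths.append(p)
    return paths
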