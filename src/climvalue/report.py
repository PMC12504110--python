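"""End-to-end reproduction of the published valuation figures.

``build_reproduction_report`` reruns the whole pipeline from first
inputs — the extrapolation-route ingredients, the cumulative heat toll,
the block records and the VSL parameter set — and compares every
recomputed quantity with the corresponding published figure at its
printed precision. It is the executable form of the package's acceptance
surface: it needs only the bundled data and no network.
"""

from __future__ import annotations

from typing import List, Optional, Union

from pydantic import BaseModel

from .datasets import (
    REFERENCE_BLOCK_TOTALS,
    dengue_fraction_input,
    load_reference_estimates,
    malaria_prevalence_input,
    reference_vsl_parameters,
)
from .extrapolate import (
    annualize_deaths,
    attributable_deaths_from_fraction,
    attributable_deaths_from_prevalence,
)
from .intervals import IntervalValue, round_persons
from .valuation import aggregate, format_money, monetize_estimate
from .vsl import VSLParameters, adjust_vsl

__all__ = ["ReproductionRow", "ReproductionReport", "build_reproduction_report"]

Value = Union[str, float, int]

#: Published figures the pipeline must land on, at printed precision.
REFERENCE_FIGURES = {
    "adjusted_vsl": "US$3.2 million",
    "dengue_deaths": "3,925 (95% CI 1,915 to 7,028)",
    "malaria_deaths": "2,366 (95% CI -4,925 to 19,423)",
    "heat_annualized": 9_702,
    "attribution_total": "31,119 deaths per year",
    "attribution_vsl_range": "US$99.6 billion to US$357.9 billion",
    "mcmichael_total": "166,000 deaths per year",
    "mcmichael_vsl_range": "US$531.2 billion to US$1.9 trillion",
    "hales_total": "241,227 deaths per year",
    "hales_vsl_range": "US$771.9 billion to US$2.8 trillion",
    "heat_annual_loss": "US$31.0 billion (unadjusted: US$111.6 billion)",
    "heat_cumulative_loss": "US$869.3 billion (unadjusted: US$3.1 trillion)",
    "wildfire_loss": "US$40.2 billion (unadjusted: US$144.5 billion)",
    "neonatal_loss": "US$29.5 billion (unadjusted: US$106.0 billion)",
    "chevron_loss": "US$188.8 million (unadjusted: US$678.5 million)",
    "exxonmobil_loss": "US$172.8 million (unadjusted: US$621.0 million)",
    "saudi_aramco_loss": "US$169.6 million (unadjusted: US$609.5 million)",
}


class ReproductionRow(BaseModel):
    label: str
    recomputed: Value
    reference: Value
    match: bool
    note: str = ""

    model_config = {"frozen": True}


class ReproductionReport(BaseModel):
    rows: List[ReproductionRow]
    all_match: bool

    model_config = {"frozen": True}

    def to_text(self) -> str:
        width = max(len(r.label) for r in self.rows)
        lines = []
        for r in self.rows:
            flag = "ok " if r.match else "FAIL"
            line = f"{flag} {r.label:<{width}}  {r.recomputed}"
            if not r.match:
                line += f"  (reference: {r.reference})"
            if r.note:
                line += f"  [{r.note}]"
            lines.append(line)
        lines.append("all figures reproduced" if self.all_match else "MISMATCHES FOUND")
        return "\n".join(lines)


def _format_interval(deaths: IntervalValue) -> str:
    rounded = deaths.rounded()
    return (
        f"{round_persons(rounded.central):,} (95% CI "
        f"{round_persons(rounded.lower):,} to {round_persons(rounded.upper):,})"
    )


def _row(label: str, recomputed: Value, note: str = "") -> ReproductionRow:
    reference = REFERENCE_FIGURES[label]
    return ReproductionRow(
        label=label,
        recomputed=recomputed,
        reference=reference,
        match=recomputed == reference,
        note=note,
    )


def _loss_pair(loss) -> str:
    return (
        f"{format_money(loss.vsl_adjusted_loss.central)} "
        f"(unadjusted: {format_money(loss.vsl_unadjusted_loss.central)})"
    )


def build_reproduction_report(
    params: Optional[VSLParameters] = None,
) -> ReproductionReport:
    """Recompute every published figure from bundled first inputs."""
    params = params or reference_vsl_parameters()
    records = load_reference_estimates()
    by_label = {(r.study_label, r.deaths_basis): r for r in records}
    rows: List[ReproductionRow] = []

    # VSL benefit transfer
    vsl = adjust_vsl(params)
    rows.append(_row("adjusted_vsl", format_money(vsl.rounded_for_reporting)))

    # extrapolation routes, from Methods-level ingredients
    dengue = attributable_deaths_from_fraction(dengue_fraction_input())
    rows.append(_row("dengue_deaths", _format_interval(dengue)))
    malaria = attributable_deaths_from_prevalence(malaria_prevalence_input())
    rows.append(_row("malaria_deaths", _format_interval(malaria)))

    # annualization of the cumulative heat toll
    heat_cum = by_label[("Vicedo-Cabrera et al.", "cumulative")]
    heat_annual = annualize_deaths(heat_cum)
    rows.append(_row("heat_annualized", round_persons(heat_annual.deaths.central)))

    # block totals and their VSL ranges
    for block, key in (
        ("core_attribution", "attribution"),
        ("mcmichael_2000", "mcmichael"),
        ("hales_2030", "hales"),
    ):
        block_records = [r for r in records if r.collection == block]
        reported = REFERENCE_BLOCK_TOTALS[block]
        agg = aggregate(block_records, params=params, reported_total=reported)
        note = ""
        if agg.total_discrepancy:
            note = (
                f"published total {agg.reported_total_deaths:,.0f} differs from "
                f"component sum {agg.computed_total_deaths:,.0f}; published value used"
            )
        rows.append(
            _row(f"{key}_total", f"{agg.total_deaths:,.0f} deaths per year", note)
        )
        rows.append(
            _row(
                f"{key}_vsl_range",
                f"{format_money(agg.loss_low)} to {format_money(agg.loss_high)}",
            )
        )

    # monetized figures quoted in the running text
    heat_loss = monetize_estimate(by_label[("Vicedo-Cabrera et al.", "annual")], params)
    rows.append(_row("heat_annual_loss", _loss_pair(heat_loss)))
    rows.append(_row("heat_cumulative_loss", _loss_pair(monetize_estimate(heat_cum, params))))
    rows.append(_row("wildfire_loss", _loss_pair(monetize_estimate(by_label[("Park et al.", "annual")], params))))
    rows.append(
        _row(
            "neonatal_loss",
            _loss_pair(
                monetize_estimate(
                    by_label[("Temperature-related neonatal deaths", "annual")], params
                )
            ),
            note="death count implied from the published losses, not independently reported",
        )
    )
    for emitter, key in (
        ("Chevron", "chevron_loss"),
        ("ExxonMobil", "exxonmobil_loss"),
        ("Saudi Aramco", "saudi_aramco_loss"),
    ):
        loss = monetize_estimate(by_label[(emitter, "cumulative")], params)
        rows.append(_row(key, _loss_pair(loss)))

    return ReproductionReport(rows=rows, all_match=all(r.match for r in rows))
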