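"""Monetization of attributable deaths and aggregation across studies.

Losses are exact linear images of death counts: every interval component
is multiplied by the VSL, so negative death bounds yield negative losses
and sums commute with monetization. Aggregated totals carry no propagated
interval — published block totals print central sums only — but the range
spanned by the adjusted and unadjusted VSL variants is attached to each
total.
"""

from __future__ import annotations

from typing import Literal, Optional, Sequence

from pydantic import BaseModel

from .estimates import AttributionEstimate
from .intervals import IntervalValue, round_half_away
from .vsl import VSLParameters, VSLValue, adjust_vsl, unadjusted_vsl

__all__ = [
    "MonetizedLoss",
    "AggregateLoss",
    "monetize",
    "monetize_estimate",
    "aggregate",
    "format_money",
]


def monetize(
    deaths: IntervalValue, vsl: VSLValue, use_reported_vsl: bool = True
) -> IntervalValue:
    """Multiply every death-count component by the VSL.

    With ``use_reported_vsl`` the reporting-rounded VSL (e.g. 3.2e6, not
    3.19595...e6) is used, which is what reproduces quoted dollar figures
    at their printed precision; pass ``False`` for the unrounded value in
    fresh analyses.
    """
    rate = vsl.rounded_for_reporting if use_reported_vsl else vsl.amount
    if rate <= 0:
        raise ValueError(f"VSL must be positive, got {rate}")
    return deaths.scale(rate)


class MonetizedLoss(BaseModel):
    """Adjusted and unadjusted dollar valuations of one estimate."""

    estimate_ref: str
    deaths_used: IntervalValue
    vsl_adjusted_loss: IntervalValue
    vsl_unadjusted_loss: IntervalValue
    basis: Literal["annual", "cumulative"]

    model_config = {"frozen": True}


def monetize_estimate(
    estimate: AttributionEstimate,
    params: Optional[VSLParameters] = None,
    use_reported_vsl: bool = True,
) -> MonetizedLoss:
    """Value one record under both VSL variants.

    Cumulative records are valued as cumulative losses (no annualization
    is applied here); the basis is recorded on the output.
    """
    params = params or VSLParameters()
    return MonetizedLoss(
        estimate_ref=estimate.study_label,
        deaths_used=estimate.deaths,
        vsl_adjusted_loss=monetize(estimate.deaths, adjust_vsl(params), use_reported_vsl),
        vsl_unadjusted_loss=monetize(
            estimate.deaths, unadjusted_vsl(params), use_reported_vsl
        ),
        basis=estimate.deaths_basis,
    )


class AggregateLoss(BaseModel):
    """A block total with its VSL valuation range.

    ``computed_total_deaths`` is the sum of the component central values;
    when a source prints a total that differs from its own component sum
    (it happens), the printed value is carried in ``reported_total_deaths``
    and used for valuation, and ``total_discrepancy`` flags the mismatch
    rather than hiding it.
    """

    computed_total_deaths: float
    reported_total_deaths: Optional[float] = None
    loss_low: float
    loss_high: float
    total_discrepancy: bool = False

    model_config = {"frozen": True}

    @property
    def total_deaths(self) -> float:
        """The total used for valuation: the reported override if present."""
        if self.reported_total_deaths is not None:
            return self.reported_total_deaths
        return self.computed_total_deaths


def aggregate(
    records: Sequence[AttributionEstimate],
    params: Optional[VSLParameters] = None,
    use_reported_vsl: bool = True,
    reported_total: Optional[float] = None,
) -> AggregateLoss:
    """Sum central death counts across annual-basis records and value the total.

    Bounds are not summed — block totals are central-only. ``loss_low``
    values the total at the adjusted VSL, ``loss_high`` at the unadjusted
    one. Mixing cumulative records in raises: annualize them first.
    """
    mixed = [r.study_label for r in records if r.deaths_basis != "annual"]
    if mixed:
        raise ValueError(
            f"aggregate() needs annual-basis records; annualize first: {mixed}"
        )
    params = params or VSLParameters()
    computed = float(sum(r.deaths.central for r in records))
    discrepancy = reported_total is not None and reported_total != computed
    total = reported_total if reported_total is not None else computed
    low_rate = adjust_vsl(params)
    high_rate = unadjusted_vsl(params)
    low = total * (low_rate.rounded_for_reporting if use_reported_vsl else low_rate.amount)
    high = total * (
        high_rate.rounded_for_reporting if use_reported_vsl else high_rate.amount
    )
    return AggregateLoss(
        computed_total_deaths=computed,
        reported_total_deaths=reported_total,
        loss_low=low,
        loss_high=high,
        total_discrepancy=discrepancy,
    )


_SCALES = [("trillion", 1e12), ("billion", 1e9), ("million", 1e6)]


def format_money(amount: float, scale: str = "auto") -> str:
    """Format as "US$X.Y million|billion|trillion", one decimal, ties away
    from zero. ``auto`` picks the largest scale at which the magnitude is
    at least 1 (falling back to millions below US$1 million)."""
    if scale == "auto":
        for name, factor in _SCALES:
            if abs(amount) >= factor:
                chosen, divisor = name, factor
                break
        else:
            chosen, divisor = "million", 1e6
    else:
        for name, factor in _SCALES:
            if scale == name:
                chosen, divisor = name, factor
                break
        else:
            raise ValueError(f"unknown money scale: {scale!r}")
    value = round_half_away(amount / divisor, 1)
    return f"US${value:.1f} {chosen}"
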