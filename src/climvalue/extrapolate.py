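"""Mortality extrapolation routes and annualization.

Two routes turn published climate-attribution results into annual
attributable deaths:

* **Attributable-fraction route** (used for dengue): the fraction of
  present-day cases attributable to climate change, multiplied by
  baseline annual deaths from the same burden database.

* **Prevalence-scaling route** (used for childhood malaria): an
  attributable change in prevalence, expressed in percentage points, is
  converted to a proportional change in mortality by dividing by baseline
  prevalence and scaling total deaths:

      deaths = (pp_change / 100) / baseline_prevalence * total_deaths

  This assumes changes in prevalence translate proportionally into
  mortality across all ages — there is no age-structured epidemiological
  model behind it, and the attributable-death bounds may be negative
  (climate change may have averted deaths at that bound).

Both routes propagate 95% intervals by endpoint pairing (lower x lower,
upper x upper); see :mod:`climvalue.simulate` for what that convention
does and does not capture statistically.

``annualize_deaths`` converts a cumulative multi-year toll to a per-year
rate by dividing by the inclusive year count of the study period.
"""

from __future__ import annotations

import warnings

from pydantic import BaseModel, model_validator

from .estimates import AttributionEstimate
from .intervals import IntervalValue

__all__ = [
    "AttributableFractionInput",
    "PrevalenceAttributionInput",
    "annualize_deaths",
    "attributable_deaths_from_fraction",
    "attributable_deaths_from_prevalence",
]


class AttributableFractionInput(BaseModel):
    """Attributable fraction (0-1 scale) plus baseline annual deaths."""

    fraction: IntervalValue
    baseline_deaths_annual: IntervalValue

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check_fraction(self) -> "AttributableFractionInput":
        f = self.fraction
        if not (0.0 <= f.central <= 1.0):
            raise ValueError(f"attributable fraction central {f.central} outside [0, 1]")
        for bound in (f.lower, f.upper):
            if bound is not None and not (-1.0 <= bound <= 1.0):
                raise ValueError(f"attributable fraction bound {bound} outside [-1, 1]")
        return self


class PrevalenceAttributionInput(BaseModel):
    """Prevalence change in percentage points (0-100 scale), baseline
    prevalence as a proportion (0-1 scale), and total annual deaths."""

    prevalence_pp_change: IntervalValue
    baseline_prevalence: float
    total_deaths: IntervalValue

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check_prevalence(self) -> "PrevalenceAttributionInput":
        if self.baseline_prevalence <= 0:
            raise ValueError(
                f"baseline prevalence must be positive (it divides): "
                f"{self.baseline_prevalence}"
            )
        return self


def annualize_deaths(estimate: AttributionEstimate) -> AttributionEstimate:
    """Convert a cumulative record to an annual one.

    Each interval component is divided by the inclusive year count of the
    study period; nothing is rounded here (rounding happens only at
    reporting). An already-annual record is returned unchanged with a
    warning.
    """
    if estimate.deaths_basis == "annual":
        warnings.warn(
            f"record {estimate.study_label!r} is already annual; annualization is a no-op",
            stacklevel=2,
        )
        return estimate
    n_years = estimate.period.n_years  # cumulative records always carry a period
    return estimate.model_copy(
        update={
            "deaths": estimate.deaths.scale(1.0 / n_years),
            "deaths_basis": "annual",
        }
    )


def attributable_deaths_from_fraction(
    input: AttributableFractionInput,
) -> IntervalValue:
    """Attributable annual deaths = fraction x baseline deaths, endpoint-paired.

    Bounds absent on either factor leave the output bounds absent.
    """
    return input.fraction.multiply(input.baseline_deaths_annual)


def attributable_deaths_from_prevalence(
    input: PrevalenceAttributionInput,
) -> IntervalValue:
    """Attributable annual deaths under prevalence-to-mortality proportionality.

    Componentwise: (pp_i / 100) / baseline_prevalence * total_deaths_i,
    low paired with low and high with high. A negative pp bound yields a
    negative death bound; it is never clamped.
    """
    relative = input.prevalence_pp_change.scale(1.0 / (100.0 * input.baseline_prevalence))
    return relative.multiply(input.total_deaths)
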