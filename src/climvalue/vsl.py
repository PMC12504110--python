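"""Value-of-statistical-life parameter sets and income-elasticity adjustment.

The VSL monetizes a marginal reduction in mortality risk from individual
willingness-to-pay estimates. A VSL estimated for a reference (US)
population is transferred to a target (global-average) population by the
standard benefit-transfer power law

    VSL_target = VSL_reference * (y_target / y_reference) ** epsilon

where y is PPP-adjusted GDP per capita and epsilon is the income
elasticity of the VSL (epsilon = 1, the recent consensus value, makes VSL
proportional to income). Two variants are carried throughout the package:
``adjusted`` (the power law above) and ``unadjusted`` (the reference VSL
applied everywhere, on equity grounds).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, model_validator

from .intervals import round_half_away

__all__ = [
    "VSLParameters",
    "VSLValue",
    "adjust_vsl",
    "unadjusted_vsl",
    "load_vsl_parameters",
]

#: Default parameter set: the US EPA VSL (US$7.4 million in 2006 dollars)
#: inflated to 2024 dollars, with 2023 World Bank PPP GDP per capita for
#: the US and the world (both in 2024 dollars), and unit income elasticity.
DEFAULT_BASE_VSL = 11.5e6
DEFAULT_BASE_VSL_SOURCE = 7.4e6
DEFAULT_GDP_REFERENCE = 84_211.0
DEFAULT_GDP_TARGET = 23_403.0
DEFAULT_ELASTICITY = 1.0

#: Reported VSL values round to the nearest 0.1 million USD.
_REPORTING_QUANTUM = 0.1e6


class VSLParameters(BaseModel):
    """Inputs to the benefit-transfer adjustment. Money in 2024 USD."""

    base_vsl: float = DEFAULT_BASE_VSL
    base_vsl_source_value: Optional[float] = DEFAULT_BASE_VSL_SOURCE
    gdp_reference: float = DEFAULT_GDP_REFERENCE
    gdp_target: float = DEFAULT_GDP_TARGET
    elasticity: float = DEFAULT_ELASTICITY

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check_positive(self) -> "VSLParameters":
        if self.base_vsl <= 0:
            raise ValueError(f"base_vsl must be positive: {self.base_vsl}")
        if self.gdp_reference <= 0 or self.gdp_target <= 0:
            raise ValueError(
                "GDP per capita inputs must be positive: "
                f"reference={self.gdp_reference}, target={self.gdp_target}"
            )
        if self.elasticity < 0:
            raise ValueError(f"income elasticity must be >= 0: {self.elasticity}")
        return self


class VSLValue(BaseModel):
    """A VSL with its reporting-rounded companion.

    ``rounded_for_reporting`` is ``amount`` rounded to the nearest 0.1
    million USD — the precision at which VSL values are quoted, and the
    value used when monetized losses are reproduced at quoted precision.
    """

    amount: float
    variant: Literal["adjusted", "unadjusted"]
    rounded_for_reporting: float

    model_config = {"frozen": True}


def _with_reporting(amount: float, variant: str) -> VSLValue:
    reported = round_half_away(amount / _REPORTING_QUANTUM) * _REPORTING_QUANTUM
    return VSLValue(amount=amount, variant=variant, rounded_for_reporting=reported)


def adjust_vsl(params: VSLParameters) -> VSLValue:
    """Income-elasticity benefit transfer of the reference VSL.

    With the default parameters this yields US$3,195,952.55, reported as
    US$3.2 million.
    """
    amount = params.base_vsl * (params.gdp_target / params.gdp_reference) ** params.elasticity
    return _with_reporting(amount, "adjusted")


def unadjusted_vsl(params: VSLParameters) -> VSLValue:
    """The reference VSL applied everywhere, untouched."""
    return _with_reporting(params.base_vsl, "unadjusted")


def load_vsl_parameters(path) -> VSLParameters:
    """Load a parameter set from a JSON or YAML key-value file.

    Keys missing from the file fall back to the built-in defaults.
    """
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(fh) or {}
        else:
            data = json.load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path.name}: expected a key-value mapping")
    return VSLParameters(**data)
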