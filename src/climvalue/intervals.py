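"""Uncertainty intervals and study periods.

``IntervalValue`` is the universal uncertainty carrier of the package: a
central estimate with optional lower/upper 95% bounds sharing one unit.
All downstream arithmetic (extrapolation, monetization) propagates
uncertainty by *endpoint pairing* — lower bounds combine with lower
bounds and upper with upper. For monotone positive-scalar transforms this
is exact quantile propagation; for products of independent quantities it
is conservative (see :mod:`climvalue.simulate` for the Monte Carlo oracle
that measures the gap).
"""

from __future__ import annotations

import math
import re
from typing import Optional

from pydantic import BaseModel, model_validator

__all__ = [
    "IntervalValue",
    "StudyPeriod",
    "round_half_away",
    "round_persons",
]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals, ties away from zero.

    Python's built-in ``round`` uses banker's rounding; reported person
    counts and dollar figures conventionally round half away from zero
    (19,422.5 -> 19,423).
    """
    factor = 10.0**ndigits
    scaled = x * factor
    return math.copysign(math.floor(abs(scaled) + 0.5), scaled) / factor


def round_persons(x: float) -> int:
    """Round a person count to the nearest integer (half away from zero)."""
    return int(round_half_away(x))


class IntervalValue(BaseModel):
    """A central estimate with optional 95% lower/upper bounds.

    Bounds may be negative (an attributable-mortality lower bound below
    zero means the exposure may have averted deaths at that bound) and may
    be absent when the source study reported no interval. Absent bounds
    propagate as absent — they are never silently replaced by the central
    value.

    ``bound_kind`` records provenance: published intervals are variously
    labelled "95% CI" or "range"; the arithmetic is identical but the
    label must not be lost.
    """

    central: float
    lower: Optional[float] = None
    upper: Optional[float] = None
    level: float = 0.95
    bound_kind: Optional[str] = None

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check_ordering(self) -> "IntervalValue":
        if self.lower is not None and self.lower > self.central:
            raise ValueError(
                f"lower bound {self.lower} exceeds central {self.central}"
            )
        if self.upper is not None and self.upper < self.central:
            raise ValueError(
                f"upper bound {self.upper} is below central {self.central}"
            )
        if not (0.0 < self.level <= 1.0):
            raise ValueError(f"interval level must be in (0, 1]: {self.level}")
        return self

    @property
    def has_bounds(self) -> bool:
        return self.lower is not None and self.upper is not None

    def scale(self, factor: float) -> "IntervalValue":
        """Multiply every component by a positive scalar.

        Exact quantile propagation: scaling by ``factor > 0`` is monotone,
        so the scaled bounds are the true bounds of the scaled quantity.
        """
        if factor <= 0:
            raise ValueError(f"scale factor must be positive, got {factor}")
        return IntervalValue(
            central=self.central * factor,
            lower=None if self.lower is None else self.lower * factor,
            upper=None if self.upper is None else self.upper * factor,
            level=self.level,
            bound_kind=self.bound_kind,
        )

    def multiply(self, other: "IntervalValue") -> "IntervalValue":
        """Endpoint-paired product: lower x lower, central x central, upper x upper.

        The convention used throughout the attribution literature this
        package reproduces. It ignores the dependence structure between
        the factors; it is exact only if they are comonotone.
        """
        return IntervalValue(
            central=self.central * other.central,
            lower=None
            if self.lower is None or other.lower is None
            else self.lower * other.lower,
            upper=None
            if self.upper is None or other.upper is None
            else self.upper * other.upper,
            level=self.level,
            bound_kind=self.bound_kind or other.bound_kind,
        )

    def add(self, other: "IntervalValue") -> "IntervalValue":
        """Componentwise sum; bounds absent if absent on either term."""
        return IntervalValue(
            central=self.central + other.central,
            lower=None
            if self.lower is None or other.lower is None
            else self.lower + other.lower,
            upper=None
            if self.upper is None or other.upper is None
            else self.upper + other.upper,
            level=self.level,
            bound_kind=self.bound_kind or other.bound_kind,
        )

    def rounded(self) -> "IntervalValue":
        """Components rounded to nearest integer, for reporting only."""
        return IntervalValue(
            central=float(round_persons(self.central)),
            lower=None if self.lower is None else float(round_persons(self.lower)),
            upper=None if self.upper is None else float(round_persons(self.upper)),
            level=self.level,
            bound_kind=self.bound_kind,
        )


_PERIOD_RE = re.compile(r"^\s*(\d{4})\s*[-–]\s*(\d{4})\s*$")
_YEAR_RE = re.compile(r"^\s*(\d{4})\s*$")


class StudyPeriod(BaseModel):
    """An inclusive span of calendar years, e.g. 1991-2018 (28 years)."""

    start_year: int
    end_year: int

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check_order(self) -> "StudyPeriod":
        if self.start_year > self.end_year:
            raise ValueError(
                f"period start {self.start_year} after end {self.end_year}"
            )
        return self

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    @classmethod
    def parse(cls, text: str) -> "StudyPeriod":
        """Parse "YYYY-YYYY" (hyphen or en dash) or a single "YYYY"."""
        m = _PERIOD_RE.match(text)
        if m:
            return cls(start_year=int(m.group(1)), end_year=int(m.group(2)))
        m = _YEAR_RE.match(text)
        if m:
            year = int(m.group(1))
            return cls(start_year=year, end_year=year)
        raise ValueError(f"unparseable study period: {text!r}")

    def __str__(self) -> str:
        return f"{self.start_year}-{self.end_year}"
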