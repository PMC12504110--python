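"""Attribution-estimate records and tabular I/O.

One record per study x cause: the mortality estimate a published
climate-attribution or projection study reports, with its interval, study
period and provenance. Records round-trip losslessly through CSV and JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Literal, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ValidationError, model_validator

from .intervals import IntervalValue, StudyPeriod

__all__ = [
    "AttributionEstimate",
    "EstimateValidationError",
    "read_estimates",
    "write_estimates",
]

DeathsBasis = Literal["cumulative", "annual"]
EstimateType = Literal["attribution", "projection"]


class EstimateValidationError(ValueError):
    """A record failed validation; the message names the offending row."""


class AttributionEstimate(BaseModel):
    """One study x cause mortality record.

    ``deaths_basis`` distinguishes per-year rates from cumulative tolls
    over the study period; cumulative records must carry a period so they
    can be annualized. ``estimate_type`` separates attribution studies
    (counterfactual-based, present day) from projection studies (modelled
    future or circa-2000 burdens). ``collection`` groups rows that are
    aggregated together (e.g. the five-study attribution block).
    """

    study_label: str
    cause: str
    region: str = ""
    period: Optional[StudyPeriod] = None
    deaths: IntervalValue
    deaths_basis: DeathsBasis
    estimate_type: EstimateType
    collection: str = ""
    notes: str = ""

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _cumulative_needs_period(self) -> "AttributionEstimate":
        if self.deaths_basis == "cumulative" and self.period is None:
            raise ValueError(
                f"cumulative record {self.study_label!r} requires a study period"
            )
        return self


_CSV_COLUMNS = [
    "study_label",
    "cause",
    "region",
    "period",
    "deaths_central",
    "deaths_lower",
    "deaths_upper",
    "bound_kind",
    "deaths_basis",
    "estimate_type",
    "collection",
    "notes",
]


def _record_to_flat(rec: AttributionEstimate) -> dict:
    return {
        "study_label": rec.study_label,
        "cause": rec.cause,
        "region": rec.region,
        "period": "" if rec.period is None else str(rec.period),
        "deaths_central": rec.deaths.central,
        "deaths_lower": rec.deaths.lower,
        "deaths_upper": rec.deaths.upper,
        "bound_kind": rec.deaths.bound_kind or "",
        "deaths_basis": rec.deaths_basis,
        "estimate_type": rec.estimate_type,
        "collection": rec.collection,
        "notes": rec.notes,
    }


def _opt_float(value) -> Optional[float]:
    if value is None or value == "":
        return None
    parsed = float(value)
    return None if pd.isna(parsed) else parsed


def _record_from_flat(row: dict, where: str) -> AttributionEstimate:
    period_text = str(row.get("period") or "").strip()
    if period_text in ("", "nan"):
        period = None
    else:
        try:
            period = StudyPeriod.parse(period_text)
        except ValueError as exc:
            raise EstimateValidationError(f"{where}: {exc}") from exc
    try:
        deaths = IntervalValue(
            central=float(row["deaths_central"]),
            lower=_opt_float(row.get("deaths_lower")),
            upper=_opt_float(row.get("deaths_upper")),
            bound_kind=(str(row.get("bound_kind") or "").strip() or None),
        )
        return AttributionEstimate(
            study_label=str(row["study_label"]),
            cause=str(row["cause"]),
            region=str(row.get("region") or ""),
            period=period,
            deaths=deaths,
            deaths_basis=row["deaths_basis"],
            estimate_type=row["estimate_type"],
            collection=str(row.get("collection") or ""),
            notes=str(row.get("notes") or ""),
        )
    except (ValidationError, ValueError, KeyError) as exc:
        raise EstimateValidationError(f"{where}: {exc}") from exc


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in ("csv", "json"):
            raise ValueError(f"unknown estimates format: {fmt!r}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "json"):
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_estimates(path, format: Optional[str] = None) -> List[AttributionEstimate]:
    """Read attribution estimates from a CSV or JSON file.

    Missing interval bounds (empty CSV cells, JSON nulls) are stored as
    absent, never as zero. Malformed periods and inverted bounds raise
    :class:`EstimateValidationError` naming the row.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        frame = pd.read_csv(
            path,
            dtype={c: str for c in _CSV_COLUMNS if not c.startswith("deaths_")},
            keep_default_na=False,
            float_precision="round_trip",
        )
        missing = [c for c in ("study_label", "cause", "deaths_central",
                               "deaths_basis", "estimate_type") if c not in frame.columns]
        if missing:
            raise EstimateValidationError(
                f"{path.name}: missing required columns {missing}"
            )
        rows = frame.to_dict(orient="records")
    else:
        with open(path) as fh:
            rows = json.load(fh)
        if not isinstance(rows, list):
            raise EstimateValidationError(f"{path.name}: expected a JSON array")
    return [
        _record_from_flat(row, where=f"{path.name} row {i + 1}")
        for i, row in enumerate(rows)
    ]


def write_estimates(
    records: Sequence[AttributionEstimate], path, format: Optional[str] = None
) -> None:
    """Write records to CSV or JSON such that re-reading is the identity."""
    path = Path(path)
    fmt = _infer_format(path, format)
    flat = [_record_to_flat(rec) for rec in records]
    if fmt == "csv":
        frame = pd.DataFrame(flat, columns=_CSV_COLUMNS)
        # repr is the shortest exact decimal form of a double; the default
        # float formatting tops out at 16 significant digits and can lose
        # the last bit on round-trip
        for col in ("deaths_central", "deaths_lower", "deaths_upper"):
            frame[col] = frame[col].map(
                lambda v: "" if v is None or pd.isna(v) else repr(float(v))
            )
        frame.to_csv(path, index=False)
    else:
        with open(path, "w") as fh:
            json.dump(flat, fh, indent=1)
            fh.write("\n")
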