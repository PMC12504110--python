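"""Bundled reference dataset of published attribution estimates.

The package ships, as plain CSV/JSON data files, the mortality estimates
reported by the end-to-end climate-attribution and projection literature
it is built to value: five global cause-specific attribution studies
(malaria, extreme weather, dengue, heat, wildfire smoke), the circa-2000
and 2030 projection blocks, the cumulative heat toll underlying the
annual heat record, emitter-specific source-attribution counts, and a
partial set of community-level heat estimates. Alongside the records it
provides the raw ingredients of the two vector-borne-disease
extrapolation routes and the consensus VSL parameter set, so the whole
valuation pipeline can be rerun from first inputs.

Collections
-----------
``core_attribution``
    The five attribution studies whose annual deaths are summed into the
    headline total (31,119/yr as printed).
``mcmichael_2000`` / ``hales_2030``
    Projection blocks (circa-2000 burden; 2030 projection). The printed
    circa-2000 total (166,000) differs from its own component sum
    (165,000); the printed value is kept as an override, flagged, never
    silently recomputed away.
``emitters``
    Source-attribution counts for Chevron, ExxonMobil and Saudi Aramco
    (heat deaths in Zurich, 1969-2018, cumulative).
``community`` / ``supplementary``
    Community-level heat estimates (partial set) and records kept for
    specific reproductions (cumulative heat; implied neonatal count).
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, List, Optional

from .estimates import AttributionEstimate, read_estimates
from .extrapolate import AttributableFractionInput, PrevalenceAttributionInput
from .intervals import IntervalValue
from .vsl import VSLParameters

__all__ = [
    "load_reference_estimates",
    "reference_vsl_parameters",
    "dengue_fraction_input",
    "malaria_prevalence_input",
    "REFERENCE_BLOCK_TOTALS",
]

#: Printed block totals (annual deaths) keyed by collection. The
#: circa-2000 projection total is the published override; its component
#: rows sum to 165,000.
REFERENCE_BLOCK_TOTALS: Dict[str, float] = {
    "core_attribution": 31_119.0,
    "mcmichael_2000": 166_000.0,
    "hales_2030": 241_227.0,
}


def _data_path(name: str):
    return resources.files("climvalue").joinpath("data").joinpath(name)


def load_reference_estimates(
    format: str = "csv", collection: Optional[str] = None
) -> List[AttributionEstimate]:
    """Load the bundled estimates, optionally one collection.

    Both serializations (CSV and JSON) are shipped and are record-for-record
    identical; ``format`` selects which file backs the load.
    """
    name = f"reference_estimates.{format}"
    with resources.as_file(_data_path(name)) as path:
        records = read_estimates(path, format=format)
    if collection is not None:
        records = [r for r in records if r.collection == collection]
    return records


def reference_vsl_parameters() -> VSLParameters:
    """The consensus VSL parameter set (2024 USD).

    US EPA VSL of US$7.4 million (2006 dollars) inflated to US$11.5
    million; US and world PPP GDP per capita US$84,211 and US$23,403;
    income elasticity 1.
    """
    return VSLParameters()


def dengue_fraction_input() -> AttributableFractionInput:
    """Attributable-fraction ingredients for dengue fever.

    18% (95% CI 11% to 27%) of present-day (1995-2014) dengue cases
    attributable to climate change, times 21,803 (95% CI 17,408 to
    26,030) baseline annual dengue deaths from the Global Burden of
    Disease database over the same window.
    """
    return AttributableFractionInput(
        fraction=IntervalValue(central=0.18, lower=0.11, upper=0.27, bound_kind="ci95"),
        baseline_deaths_annual=IntervalValue(
            central=21_803, lower=17_408, upper=26_030, bound_kind="ci95"
        ),
    )


def malaria_prevalence_input() -> PrevalenceAttributionInput:
    """Prevalence-scaling ingredients for childhood malaria.

    Climate change responsible for 0.09 (95% CI -0.30 to 0.51) percentage
    points of childhood (ages 2-10) malaria prevalence in sub-Saharan
    Africa, against a continent-wide prevalence of 24% in 2015 and
    631,000 (95% CI 394,000 to 914,000) total malaria deaths across ages
    in 2015.
    """
    return PrevalenceAttributionInput(
        prevalence_pp_change=IntervalValue(
            central=0.09, lower=-0.30, upper=0.51, bound_kind="ci95"
        ),
        baseline_prevalence=0.24,
        total_deaths=IntervalValue(
            central=631_000, lower=394_000, upper=914_000, bound_kind="ci95"
        ),
    )
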