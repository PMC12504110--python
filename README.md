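# climvalue

Monetized valuation of climate-change-attributable mortality.

End-to-end climate–health attribution studies estimate how many deaths
anthropogenic climate change has caused — for heat, wildfire smoke,
vector-borne diseases, extreme weather — by comparing observed outcomes
with a counterfactual climate lacking human forcings. `climvalue` turns
those published estimates into monetized losses with propagated
uncertainty, for researchers and analysts synthesising the attribution
literature or preparing loss-and-damage style valuations.

## What it computes

**Burden extrapolation.** Two routes convert attribution results into
annual attributable deaths *D*:

- *Attributable-fraction route*: `D = AF × B`, where AF is the fraction
  of present-day cases attributable to climate change and B is baseline
  annual deaths from a burden database (used for dengue:
  0.18 × 21,803 = 3,925 deaths/yr).
- *Prevalence-scaling route*: `D = (Δp / 100) / p₀ × M`, where Δp is the
  attributable prevalence change in percentage points, p₀ the baseline
  prevalence and M total annual deaths, assuming prevalence changes map
  proportionally onto mortality (used for childhood malaria:
  (0.09 / 100) / 0.24 × 631,000 = 2,366 deaths/yr).

Cumulative multi-year tolls are annualized by dividing by the inclusive
year count of the study period (271,656 heat deaths over 1991–2018, i.e.
28 years, → 9,702/yr).

**VSL benefit transfer.** A US-reference value of statistical life is
transferred to the global population by the income-elasticity power law

    VSL_world = VSL_US × (y_world / y_US)^ε

with ε = 1: 11.5×10⁶ × (23,403 / 84,211) ≈ US$3.2 million. The
unadjusted variant applies the full US value everywhere.

**Uncertainty propagation.** Every 95% interval is propagated by
endpoint pairing (lower × lower, upper × upper) — exact for monotone
scalings, conservative for products of independent factors; a Monte
Carlo oracle in `climvalue.simulate` quantifies the difference.

## Worked example

```python
from climvalue import (adjust_vsl, attributable_deaths_from_fraction,
                       dengue_fraction_input, format_money, monetize,
                       reference_vsl_parameters)

deaths = attributable_deaths_from_fraction(dengue_fraction_input())
print(deaths.rounded())
# central=3925.0 lower=1915.0 upper=7028.0 level=0.95 bound_kind='ci95'
# -> deaths/yr attributable to climate change, with 95% bounds from
#    endpoint-paired CI arithmetic

vsl = adjust_vsl(reference_vsl_parameters())
print(format_money(vsl.rounded_for_reporting))   # US$3.2 million
loss = monetize(deaths, vsl)
print(format_money(loss.central))                # US$12.6 billion
```

The first line is the annual dengue death toll attributable to climate
change; the last is its monetized value at the globally adjusted VSL.

The command-line entry point exposes the same pipeline
(`climvalue validate | extrapolate | value | table | simulate |
reproduce`); `climvalue reproduce` reruns every published figure from
the bundled inputs and exits non-zero on any mismatch:

```text
$ climvalue table
[core_attribution]
  Carlson et al. (2010-2015) Malaria: 2,366 (-4,925 to 19,423)
  ...
  Total 31,119 deaths per year (VSL: US$99.6 billion to US$357.9 billion)
```

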