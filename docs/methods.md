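# Methods

## The valuation pipeline

`climvalue` synthesises published end-to-end climate–health attribution
estimates into monetized mortality losses. The pipeline has four stages,
each a pure function of validated records:

1. **Extrapolation** of attributable deaths where the source literature
   reports attribution in other units (an attributable fraction of
   cases; a prevalence change in percentage points).
2. **Annualization** of cumulative multi-year death tolls.
3. **VSL benefit transfer**: income-elasticity adjustment of a
   US-reference value of statistical life to a global-average value.
4. **Monetization and aggregation**: linear valuation of death counts
   under both VSL variants, and block sums with their valuation ranges.

Every uncertain quantity is an `IntervalValue`: a central estimate with
optional lower/upper 95% bounds. Bounds may be negative (a negative
attributable-mortality bound means climate change may have averted
deaths at that bound; it is never clamped) and may be absent, in which
case they propagate as absent rather than being imputed.

## Extrapolation routes

**Attributable-fraction route.** `D = AF × B` with endpoint-paired
bounds: `D_lo = AF_lo × B_lo`, `D_hi = AF_hi × B_hi`. Fractions are
proportions on the 0–1 scale; the central value must lie in [0, 1] while
bounds may extend to [−1, 1].

**Prevalence-scaling route.** `D_i = (Δp_i / 100) / p₀ × M_i` for each
interval component i, where Δp is in percentage points (0–100 scale),
p₀ is a proportion (0–1) and M is total annual deaths. The route assumes
changes in (childhood) prevalence translate proportionally into
(all-age) mortality; no age-structured epidemiological model stands
behind that proportionality, and the package deliberately does not add
one — the route reproduces how such extrapolations are actually made in
the synthesis literature, mixed age ranges and all.

**Annualization** divides every interval component by the inclusive year
count `end − start + 1`. Nothing is rounded internally; person counts
round to the nearest integer (ties away from zero) only at reporting.

## The endpoint-pairing convention

Pairing like-ordered endpoints is exact quantile propagation for
monotone positive-scalar transforms (scaling, annualization,
monetization). For a product of two genuinely uncertain factors it is
exact only under comonotone dependence; under independence it is
conservative — the paired interval is strictly wider than the true 95%
interval of the product. The package keeps the convention because it is
what the published figures embody, and makes the gap measurable:
`mc_propagate` samples the factors independently (an explicit modelling
choice; the sources are silent on dependence) and returns the empirical
2.5/50/97.5 percentiles of the product next to the endpoint-paired
interval. Tests assert agreement within 3 standard errors of the
empirical quantile in the constant-factor limit (n = 100,000 samples)
and strict conservatism for two independent lognormal factors.

## VSL benefit transfer

`VSL_target = VSL_ref × (y_target / y_ref)^ε`, all money in 2024 USD.

| parameter | default | meaning |
|---|---|---|
| `base_vsl` | 11.5e6 | US EPA VSL (US$7.4M in 2006 dollars, inflated to 2024) |
| `gdp_reference` | 84,211 | US PPP GDP per capita, 2024 USD |
| `gdp_target` | 23,403 | world-average PPP GDP per capita, 2024 USD |
| `elasticity` | 1.0 | income elasticity of the VSL (consensus value) |

The inflation step is not computed here: the deflator series is external
data and the inflated value is taken as a parameter. ε = 1 makes VSL
proportional to income; ε = 0 recovers the unadjusted variant, which the
package also exposes directly (the equity position that a death is
valued identically everywhere at the US figure).

**Reporting rounding feeds monetization.** VSL values are quoted to the
nearest 0.1 million (3.19595…e6 → 3.2e6), and the published dollar
figures are products of death counts with the *quoted* VSL (59 × 3.2e6 =
US$188.8M, not 59 × 3.19595e6 = US$188.6M). `monetize` therefore takes a
`use_reported_vsl` flag, default true, reproducing quoted figures
exactly; analyses wanting full precision pass false. Money strings
render as `US$X.Y million|billion|trillion` with one decimal, ties away
from zero, the scale chosen before rounding.

## Aggregation

Block totals sum central values only — the published tables print no
interval on totals — and carry the range spanned by the adjusted and
unadjusted VSL. Where a source's printed total differs from its own
component sum (the circa-2000 projection block: components sum to
165,000, the printed total is 166,000), the printed value is stored as
an override and used for valuation, and the discrepancy is flagged on
the result rather than silently resolved either way. Mixing cumulative
records into an aggregation is an error; annualize first. Cumulative
records can also be monetized directly as cumulative losses (the
US$869.3B heat figure), with the basis recorded on the output.

## The bundled dataset

Shipped as identical CSV and JSON files (23 records): the five-study
attribution block, the two projection blocks, the cumulative heat toll,
three emitter source-attribution counts, three community-level heat
estimates (a partial set, flagged in notes), and a neonatal record whose
death count (9,218.75/yr) is implied from its published dollar losses
rather than independently reported — it is marked as such and excluded
from exact death-count reproduction. One record (the childhood-malaria
row) keeps a note that its quoted period (2010–2015) differs from the
underlying estimate's stated span (2010–2014); nothing downstream
depends on the choice. CSV serialization writes floats via `repr` and
reads them with round-trip precision so write→read is bit-exact,
including negative and absent bounds.

## Synthetic data generator

`generate_estimates` emulates the record structure the pipeline assumes:
per study, a true attributable fraction drawn from Beta(2, 8) (centred
near 0.2, the dengue-like regime) and a true baseline burden from a
lognormal with median 20,000 deaths/yr and log-sd 0.5 (a half order of
magnitude across studies). Each study reports a central estimate drawn
from a mean-unbiased reporting distribution — Beta with mean equal to
the true fraction (concentration 400, sd ≈ 0.02 near 0.2) and a
mean-corrected lognormal (log-sd 0.1) for the burden — and publishes the
exact 2.5/97.5 percentiles of that distribution as its 95% interval.
Mean-unbiased reporting is what makes the parameter-recovery regression
(recovered monetized losses on true generating products, slope
estimated through the origin) have expectation exactly 1; the test
tolerance is 3 heteroskedasticity-robust standard errors, since the
multiplicative noise scales residual variance with the truth squared.
A single seeded generator drives each run in a fixed order (per study:
true fraction, true baseline, reported fraction, reported baseline), so
identical configs produce byte-identical output files.

What the generator does *not* emulate: dependence between fraction and
burden, heterogeneous interval asymmetries, reporting selection effects,
or the underlying climate counterfactuals. Passing recovery tests show
the pipeline's arithmetic is faithful under the stated statistical
structure, not that real attribution studies satisfy that structure.

## Numerical choices

- Rounding is half-away-from-zero everywhere a value is reported
  (person counts to integers, VSL to 0.1 million, money to one decimal
  at scale); internal arithmetic is never rounded. No published value
  distinguishes half-up from half-even except ties the convention
  handles (e.g. the malaria upper bound 19,422.5 → 19,423).
- Study periods are inclusive integer year spans; "1991–2018" is 28
  years. Single-year studies are start = end.
- Degenerate inputs: zero or negative baseline prevalence, non-positive
  GDP or VSL inputs, inverted interval bounds and cumulative records
  without a period are validation errors, raised at construction by the
  record models, not at use.

## Problem sizes

The reproduction surface is desk-scale (a few dozen records) and runs in
milliseconds. Stochastic checks use 100,000 Monte Carlo samples for the
quantile oracle and 200 synthetic studies for parameter recovery —
enough for standard errors well below the tolerances they are tested
against.

## Known limitations

- Valuation covers mortality only: no morbidity, healthcare-system or
  wider societal costs, no discounting, no per-country VSL.
- The endpoint convention's conservatism under independence is
  quantified but not corrected; the package reports what the synthesis
  convention produces.
- Block totals inherit the sources' conventions (central-only, printed
  overrides); an endpoint-summed interval on totals is computable from
  the primitives but intentionally not part of the reproduction output.
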