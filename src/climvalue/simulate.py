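"""Synthetic attribution databases and a Monte Carlo propagation oracle.

Two jobs live here. ``generate_estimates`` fabricates study records with
the same statistical anatomy the pipeline assumes of real ones: each
synthetic study has a true attributable fraction and a true baseline
death burden, reports a noisy central estimate of each, and publishes a
95% interval equal to the exact 2.5/97.5 percentiles of its reporting
distribution. Because the generating truths are retained, recovery tests
can regress pipeline output against them.

``mc_propagate`` is the statistical oracle for the endpoint-pairing
convention. The pipeline forms the interval of a product by pairing the
factors' own interval endpoints (low x low, high x high); the oracle
instead samples the factors independently and takes empirical percentiles
of the product. For a product of genuinely uncertain independent factors
the endpoint interval is conservative (wider); when one factor is
constant the transform is monotone and the two intervals coincide.
Sampling order is fixed (per study: true fraction, true baseline,
reported fraction, reported baseline) so a seed pins the output bytes.
"""

from __future__ import annotations

import math
from typing import List, Literal, Tuple, Union

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .estimates import AttributionEstimate
from .extrapolate import AttributableFractionInput
from .intervals import IntervalValue, StudyPeriod

__all__ = [
    "BetaSpec",
    "TruncNormSpec",
    "LogNormalSpec",
    "PointMassSpec",
    "GeneratorConfig",
    "SyntheticStudy",
    "MCPropagationResult",
    "generate_estimates",
    "mc_propagate",
]


class BetaSpec(BaseModel):
    """Beta(a, b) on [0, 1] — natural support for attributable fractions."""

    kind: Literal["beta"] = "beta"
    a: float = Field(gt=0)
    b: float = Field(gt=0)

    def frozen(self):
        return stats.beta(self.a, self.b)


class TruncNormSpec(BaseModel):
    """Normal(mu, sigma) truncated to [low, high]."""

    kind: Literal["truncnorm"] = "truncnorm"
    mu: float
    sigma: float = Field(gt=0)
    low: float = 0.0
    high: float = 1.0

    @model_validator(mode="after")
    def _check_support(self) -> "TruncNormSpec":
        if self.low >= self.high:
            raise ValueError(f"empty truncation interval [{self.low}, {self.high}]")
        return self

    def frozen(self):
        a = (self.low - self.mu) / self.sigma
        b = (self.high - self.mu) / self.sigma
        return stats.truncnorm(a, b, loc=self.mu, scale=self.sigma)


class LogNormalSpec(BaseModel):
    """Lognormal with log-mean mu and log-sd sigma — heavy-tailed positive
    burdens (baseline deaths)."""

    kind: Literal["lognormal"] = "lognormal"
    mu: float
    sigma: float = Field(gt=0)

    def frozen(self):
        return stats.lognorm(s=self.sigma, scale=math.exp(self.mu))


class PointMassSpec(BaseModel):
    """A degenerate distribution: every sample and quantile equals ``value``."""

    kind: Literal["point"] = "point"
    value: float

    def frozen(self):  # scipy has no point mass; emulate the two calls we use
        value = self.value

        class _Point:
            def rvs(self, size, random_state):
                return np.full(size, value)

            def ppf(self, q):
                return np.full_like(np.asarray(q, dtype=float), value)

        return _Point()


DistributionSpec = Union[BetaSpec, TruncNormSpec, LogNormalSpec, PointMassSpec]
FractionSpec = Union[BetaSpec, TruncNormSpec, PointMassSpec]


class GeneratorConfig(BaseModel):
    """Study-database generator settings.

    Defaults emulate a vector-borne-disease-like literature: attributable
    fractions centred near 0.2 with realistic spread (Beta(2, 8)), and
    baseline burdens lognormal around 20,000 deaths/yr with a half-order-
    of-magnitude spread (log-sd 0.5) — the scale of the dengue route.
    Reporting noise (the gap between a study's central estimate and the
    generating truth) is mean-unbiased by construction: fractions are
    reported through a Beta distribution with mean equal to the true
    fraction (concentration 400 gives sd ~0.02 near f=0.2), burdens
    through a mean-corrected lognormal with 10% log-sd.
    """

    n_studies: int = Field(ge=1)
    seed: int
    fraction_distribution: FractionSpec = BetaSpec(a=2.0, b=8.0)
    baseline_deaths_distribution: LogNormalSpec = LogNormalSpec(
        mu=math.log(20_000.0), sigma=0.5
    )
    fraction_reporting_concentration: float = Field(default=400.0, gt=0)
    deaths_reporting_log_sd: float = Field(default=0.1, gt=0)
    period_range: Tuple[int, int] = (1990, 2020)
    ci_level: float = 0.95

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        if self.period_range[0] > self.period_range[1]:
            raise ValueError(f"empty period range {self.period_range}")
        if self.ci_level != 0.95:
            raise ValueError("generator emits 95% intervals only")
        return self


class SyntheticStudy(BaseModel):
    """A generated record together with its generating truths."""

    estimate: AttributionEstimate
    fraction_input: AttributableFractionInput
    true_fraction: float
    true_baseline_deaths: float

    model_config = {"frozen": True}

    @property
    def true_attributable_deaths(self) -> float:
        return self.true_fraction * self.true_baseline_deaths


def _reporting_fraction_dist(true_fraction: float, concentration: float):
    # Beta with mean exactly the true fraction: reported centrals are
    # unbiased, which is what makes the recovery regression slope 1
    f = min(max(true_fraction, 1e-6), 1.0 - 1e-6)
    return stats.beta(f * concentration, (1.0 - f) * concentration)


def _reporting_deaths_dist(true_deaths: float, log_sd: float):
    # log-mean shifted by -sigma^2/2 so the mean (not the median) equals
    # the true burden; same unbiasedness rationale as the fraction
    return LogNormalSpec(
        mu=math.log(true_deaths) - 0.5 * log_sd**2, sigma=log_sd
    ).frozen()


def generate_estimates(config: GeneratorConfig) -> List[SyntheticStudy]:
    """Generate ``n_studies`` synthetic attribution records.

    Per study: draw the true fraction and baseline, then a reported
    central for each from its reporting distribution; the published
    interval is that distribution's exact 2.5/97.5 percentiles. The
    record's death count is the endpoint-paired product of the two
    reported intervals, exactly as the pipeline would compute it.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    q = (1.0 - config.ci_level) / 2.0
    frac_truth_dist = config.fraction_distribution.frozen()
    base_truth_dist = config.baseline_deaths_distribution.frozen()
    studies: List[SyntheticStudy] = []
    for i in range(config.n_studies):
        true_f = float(frac_truth_dist.rvs(size=1, random_state=rng)[0])
        true_b = float(base_truth_dist.rvs(size=1, random_state=rng)[0])
        f_rep = _reporting_fraction_dist(true_f, config.fraction_reporting_concentration)
        b_rep = _reporting_deaths_dist(true_b, config.deaths_reporting_log_sd)
        f_central = float(f_rep.rvs(size=1, random_state=rng)[0])
        b_central = float(b_rep.rvs(size=1, random_state=rng)[0])
        f_lo, f_hi = (float(f_rep.ppf(p)) for p in (q, 1.0 - q))
        b_lo, b_hi = (float(b_rep.ppf(p)) for p in (q, 1.0 - q))
        # reported central can fall outside the truth-centred percentile
        # band; widen to keep the record a valid interval
        fraction = IntervalValue(
            central=f_central,
            lower=min(f_lo, f_central),
            upper=max(f_hi, f_central),
            bound_kind="ci95",
        )
        baseline = IntervalValue(
            central=b_central,
            lower=min(b_lo, b_central),
            upper=max(b_hi, b_central),
            bound_kind="ci95",
        )
        frac_input = AttributableFractionInput(
            fraction=fraction, baseline_deaths_annual=baseline
        )
        start = int(rng.integers(config.period_range[0], config.period_range[1] + 1))
        estimate = AttributionEstimate(
            study_label=f"synthetic-{i:03d}",
            cause="Synthetic cause",
            region="synthetic",
            period=StudyPeriod(start_year=start, end_year=start),
            deaths=fraction.multiply(baseline),
            deaths_basis="annual",
            estimate_type="attribution",
            collection="synthetic",
            notes=f"true_fraction={true_f!r} true_baseline={true_b!r}",
        )
        studies.append(
            SyntheticStudy(
                estimate=estimate,
                fraction_input=frac_input,
                true_fraction=true_f,
                true_baseline_deaths=true_b,
            )
        )
    return studies


class MCPropagationResult(BaseModel):
    """Empirical product interval vs the endpoint-paired one."""

    quantile_interval: IntervalValue
    endpoint_interval: IntervalValue
    n_samples: int = Field(ge=1000)
    seed: int

    model_config = {"frozen": True}


def mc_propagate(
    fraction_dist: DistributionSpec,
    baseline_dist: DistributionSpec,
    n_samples: int = 100_000,
    seed: int = 0,
) -> MCPropagationResult:
    """Sample the product of two independent factors and compare intervals.

    ``quantile_interval`` holds the empirical median and 2.5/97.5
    percentiles of the sampled product; ``endpoint_interval`` pairs each
    factor's own exact percentiles (median x median, q2.5 x q2.5,
    q97.5 x q97.5) — the pipeline's convention under an independence
    assumption it does not make.
    """
    if n_samples < 1000:
        raise ValueError("oracle use requires n_samples >= 1000")
    rng = np.random.default_rng(seed)
    f_dist = fraction_dist.frozen()
    b_dist = baseline_dist.frozen()
    f = np.asarray(f_dist.rvs(size=n_samples, random_state=rng), dtype=float)
    b = np.asarray(b_dist.rvs(size=n_samples, random_state=rng), dtype=float)
    product = f * b
    lo, med, hi = np.percentile(product, [2.5, 50.0, 97.5])
    quantile = IntervalValue(central=float(med), lower=float(lo), upper=float(hi))
    endpoint = IntervalValue(
        central=float(f_dist.ppf(0.5)) * float(b_dist.ppf(0.5)),
        lower=float(f_dist.ppf(0.025)) * float(b_dist.ppf(0.025)),
        upper=float(f_dist.ppf(0.975)) * float(b_dist.ppf(0.975)),
    )
    return MCPropagationResult(
        quantile_interval=quantile,
        endpoint_interval=endpoint,
        n_samples=n_samples,
        seed=seed,
    )
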