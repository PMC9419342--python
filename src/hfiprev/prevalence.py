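"""Prevalence estimators for a fully penetrant autosomal-recessive disease.

Three estimators operate on carrier screens and population allele counts:

* **Method 1 — carrier frequency.** With carrier frequency ``f`` observed in
  a screened cohort, a random couple is carrier x carrier with probability
  ``f**2`` and their child is affected with probability ``f**2 / 4``
  (Hardy-Weinberg random mating, recessive inheritance).
* **Method 2 — sex-stratified couples.** Same risk computed from the male
  and female carrier frequencies separately:
  ``(c_m/n_m) * (c_f/n_f) / 4``. Coincides with Method 1 whenever the two
  sex strata carry at the same rate.
* **Method 3 — Bayesian allele-count posterior.** Each undiagnosed carrier
  contributes one pathogenic allele among the cohort's ``2N`` typed
  alleles. With ``c`` pathogenic alleles out of ``n`` the posterior on the
  pathogenic allele frequency ``q`` is ``Beta(c, n - c)`` (Haldane prior,
  the default) or ``Beta(c + 1/2, n - c + 1/2)`` (Jeffreys). The reported
  point prevalence is the posterior mean of ``q**2``; the credible interval
  is the central posterior interval of ``q**2``, available both in closed
  form (squared Beta quantiles) and by Monte-Carlo sampling.

Estimates display in the clinical "1 in X" convention with the denominator
truncated toward zero, so the display never overstates the risk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .panel_io import PopulationAFRecord

__all__ = [
    "CohortCarrierCounts",
    "PrevalenceEstimate",
    "Ratio",
    "format_one_in",
    "carrier_frequency",
    "couple_carrier_risk",
    "estimate_method1_hw",
    "estimate_method2_sex_stratified",
    "estimate_method3_bayesian",
    "estimate_from_population_allele_counts",
    "average_estimates",
]

_METHODS = {
    "carrier_frequency",
    "permutation_combination",
    "bayesian",
    "population_allele_counts",
    "average",
}


@dataclass(frozen=True)
class CohortCarrierCounts:
    """Sex-stratified carrier counts for one screened cohort.

    Individuals already diagnosed with the disease (and their relatives)
    are excluded *before* these counts are formed; every counted carrier is
    an unaffected heterozygote.
    """

    n_total: int
    n_male: int
    n_female: int
    carriers_male: int
    carriers_female: int

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if self.n_male + self.n_female > self.n_total:
            # strict equality is not required: screened cohorts may contain
            # individuals of unrecorded sex, so the strata may undercount
            raise ValueError(
                f"n_male + n_female cannot exceed n_total "
                f"({self.n_male} + {self.n_female} > {self.n_total})"
            )
        if not 0 <= self.carriers_male <= self.n_male:
            raise ValueError("carriers_male out of range [0, n_male]")
        if not 0 <= self.carriers_female <= self.n_female:
            raise ValueError("carriers_female out of range [0, n_female]")

    @property
    def carriers_total(self) -> int:
        return self.carriers_male + self.carriers_female

    @property
    def pathogenic_alleles(self) -> tuple[int, int]:
        """(carrier alleles, total alleles): one pathogenic allele per
        carrier among 2N typed alleles."""
        return self.carriers_total, 2 * self.n_total


def format_one_in(p: float) -> str:
    """Display a probability as ``1/X`` with X = floor(1/p).

    Truncation toward zero (not rounding) is the reporting convention: a
    carrier frequency of 1/342.93 prints as ``1/342``. Values of 1/p within
    1e-9 relative of an integer are snapped to it so exact rationals are
    not mangled by floating-point noise.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"probability must be in (0, 1], got {p}")
    d = 1.0 / p
    nearest = round(d)
    if nearest > 0 and abs(d - nearest) < 1e-9 * max(1.0, nearest):
        return f"1/{nearest}"
    return f"1/{math.floor(d)}"


def _display(p: float) -> str:
    return "0" if p == 0.0 else format_one_in(p)


class Ratio(NamedTuple):
    """A probability with its 1-in-X display string."""

    value: float
    display: str


@dataclass(frozen=True)
class PrevalenceEstimate:
    """A method-tagged prevalence probability with optional credible interval.

    ``ci_low``/``ci_high`` are the analytic central-interval endpoints;
    ``mc_ci_low``/``mc_ci_high`` carry the Monte-Carlo counterparts when a
    sampling pass was run (they must agree with the analytic ones and are
    kept for diagnostics).
    """

    method: str
    prevalence: float
    ci_low: float | None = None
    ci_high: float | None = None
    mc_ci_low: float | None = None
    mc_ci_high: float | None = None

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown method tag {self.method!r}")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence must be in [0, 1], got {self.prevalence}")
        if (self.ci_low is None) != (self.ci_high is None):
            raise ValueError("ci_low and ci_high must be given together")
        if self.ci_low is not None:
            if not 0.0 <= self.ci_low <= self.prevalence <= self.ci_high <= 1.0:
                raise ValueError(
                    "credible interval must satisfy "
                    "0 <= ci_low <= prevalence <= ci_high <= 1"
                )

    @property
    def display(self) -> str:
        return _display(self.prevalence)

    @property
    def ci_display(self) -> str | None:
        """Interval in the ``(1/X_low ~ 1/X_high)`` convention: the *low*
        prevalence bound has the larger denominator and prints first."""
        if self.ci_low is None:
            return None
        return f"({_display(self.ci_low)} ~ {_display(self.ci_high)})"


def carrier_frequency(counts: CohortCarrierCounts) -> Ratio:
    """Observed P/LP carrier frequency, carriers_total / n_total."""
    p = counts.carriers_total / counts.n_total
    return Ratio(p, _display(p))


def couple_carrier_risk(counts: CohortCarrierCounts) -> Ratio:
    """Probability a random couple is carrier x carrier: f**2."""
    f = counts.carriers_total / counts.n_total
    return Ratio(f * f, _display(f * f))


def estimate_method1_hw(counts: CohortCarrierCounts) -> PrevalenceEstimate:
    """Hardy-Weinberg estimate from the pooled carrier frequency: f**2 / 4."""
    f = counts.carriers_total / counts.n_total
    return PrevalenceEstimate(method="carrier_frequency", prevalence=f * f / 4.0)


def estimate_method2_sex_stratified(counts: CohortCarrierCounts) -> PrevalenceEstimate:
    """Couple risk from sex-specific carrier frequencies.

    Probability that a random male carrier x random female carrier couple
    is drawn, times the 1/4 chance their child inherits both pathogenic
    alleles.
    """
    if counts.n_male < 1 or counts.n_female < 1:
        raise ValueError("both sex strata must be non-empty")
    fm = counts.carriers_male / counts.n_male
    ff = counts.carriers_female / counts.n_female
    return PrevalenceEstimate(method="permutation_combination", prevalence=fm * ff / 4.0)


def _beta_params(carrier_alleles: int, total_alleles: int, prior: str) -> tuple[float, float]:
    if prior == "haldane":
        if not 0 < carrier_alleles < total_alleles:
            raise ValueError(
                "the Haldane prior Beta(c, n-c) is degenerate at c=0 or c=n; "
                "use prior='jeffreys' for boundary counts"
            )
        return float(carrier_alleles), float(total_alleles - carrier_alleles)
    if prior == "jeffreys":
        return carrier_alleles + 0.5, total_alleles - carrier_alleles + 0.5
    raise ValueError(f"unknown prior {prior!r}; expected 'haldane' or 'jeffreys'")


def estimate_method3_bayesian(
    carrier_alleles: int,
    total_alleles: int,
    mc_samples: int = 100_000,
    seed: int = 0,
    alpha_level: float = 0.05,
    prior: str = "haldane",
) -> PrevalenceEstimate:
    """Posterior prevalence from pathogenic-allele counts.

    Parameters
    ----------
    carrier_alleles
        Pathogenic alleles observed (one per unaffected carrier when the
        counts come from a carrier screen).
    total_alleles
        Total typed alleles (2N for a diploid cohort of N individuals).
    mc_samples
        Monte-Carlo draws for the sampled credible interval (>= 1000). The
        point estimate and the reported interval are analytic and therefore
        deterministic; the MC interval is attached for cross-checking.
    seed
        Seed for the Monte-Carlo stream.
    alpha_level
        1 - credible level; 0.05 gives the central 95% interval.
    prior
        ``"haldane"`` (Beta(0,0), posterior Beta(c, n-c); default) or
        ``"jeffreys"`` (Beta(1/2, 1/2)). Haldane requires 0 < c < n.

    Notes
    -----
    The point estimate is the posterior mean of the prevalence q**2,
    ``E[q^2] = a(a+1) / ((a+b)(a+b+1))`` for a Beta(a, b) posterior — not
    the squared posterior mean of q, which is biased low by the posterior
    variance.
    """
    if carrier_alleles < 0 or total_alleles < 1:
        raise ValueError("need carrier_alleles >= 0 and total_alleles >= 1")
    if carrier_alleles > total_alleles:
        raise ValueError("carrier_alleles cannot exceed total_alleles")
    if mc_samples < 1000:
        raise ValueError("mc_samples must be >= 1000")
    a, b = _beta_params(carrier_alleles, total_alleles, prior)

    point = a * (a + 1.0) / ((a + b) * (a + b + 1.0))
    q_lo = stats.beta.ppf(alpha_level / 2.0, a, b)
    q_hi = stats.beta.ppf(1.0 - alpha_level / 2.0, a, b)

    rng = np.random.default_rng(seed)
    q = rng.beta(a, b, size=mc_samples)
    mc_lo, mc_hi = np.quantile(q * q, [alpha_level / 2.0, 1.0 - alpha_level / 2.0])

    return PrevalenceEstimate(
        method="bayesian",
        prevalence=float(point),
        ci_low=float(q_lo**2),
        ci_high=float(q_hi**2),
        mc_ci_low=float(mc_lo),
        mc_ci_high=float(mc_hi),
    )


def estimate_from_population_allele_counts(
    records: Sequence[PopulationAFRecord],
    mc_samples: int = 100_000,
    seed: int = 0,
    alpha_level: float = 0.05,
    prior: str = "jeffreys",
) -> PrevalenceEstimate:
    """Panel-wide prevalence for one population from per-variant AC/AN.

    Each variant gets an independent Beta posterior on its allele frequency
    (Jeffreys by default so untyped-but-recorded AC=0 variants contribute a
    proper prior mass); the total pathogenic allele frequency is the sum
    ``q = sum_i q_i`` and the prevalence is ``q**2`` under random mating.
    The point estimate is the deterministic ``(sum_i E[q_i])**2``; the
    credible interval comes from Monte-Carlo quantiles of ``q**2``.
    """
    if not records:
        raise ValueError("records must be non-empty")
    pops = {r.population for r in records}
    if len(pops) != 1:
        raise ValueError(f"records span multiple populations: {sorted(pops)}")
    if mc_samples < 1000:
        raise ValueError("mc_samples must be >= 1000")

    ab = [_beta_params(r.allele_count, r.allele_number, prior) for r in records]
    means = np.array([a / (a + b) for a, b in ab])
    point = float(means.sum() ** 2)

    rng = np.random.default_rng(seed)
    q = np.zeros(mc_samples)
    for a, b in ab:
        q += rng.beta(a, b, size=mc_samples)
    lo, hi = np.quantile(q * q, [alpha_level / 2.0, 1.0 - alpha_level / 2.0])
    # MC-quantile interval may not bracket the analytic point for very
    # skewed posteriors; clamp to preserve the interval invariant.
    lo = min(float(lo), point)
    hi = max(float(hi), point)

    return PrevalenceEstimate(
        method="population_allele_counts",
        prevalence=point,
        ci_low=lo,
        ci_high=hi,
        mc_ci_low=lo,
        mc_ci_high=hi,
    )


def average_estimates(estimates: Iterable[PrevalenceEstimate]) -> PrevalenceEstimate:
    """Arithmetic mean of prevalence *probabilities* across methods.

    The mean is taken on the probability scale, never on the 1-in-X
    denominators (a mean of denominators would be a harmonic-mean
    probability and would overweight the smallest estimates).
    """
    probs = [e.prevalence for e in estimates]
    if not probs:
        raise ValueError("need at least one estimate to average")
    return PrevalenceEstimate(method="average", prevalence=float(np.mean(probs)))
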