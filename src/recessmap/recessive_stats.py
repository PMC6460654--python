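"""Allele-frequency arithmetic and the homozygote-depletion test.

A recessive sterile (or lethal) allele at frequency q leaves a telltale
signature in a fertile cohort of N animals: heterozygous carriers are common
but homozygotes are missing, although N*q^2 are expected under Hardy-
Weinberg proportions. The probability of seeing as few homozygotes as
observed is computed either from the exact binomial distribution
Binomial(N, q^2) or from its Poisson(N*q^2) approximation.

Small-proportion fertility outcomes (insemination and IVF success) are
summarised with exact binomial confidence intervals and compared with
Fisher's exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

DEPLETION_METHODS = ("binomial_exact", "poisson")


@dataclass(frozen=True)
class CarrierCounts:
    n_het: int
    n_hom: int
    n_total: int

    def __post_init__(self) -> None:
        if min(self.n_het, self.n_hom, self.n_total) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_het + self.n_hom > self.n_total:
            raise ValueError("carriers cannot outnumber scored animals")


@dataclass(frozen=True)
class DepletionResult:
    q: float
    expected_hom: float
    observed_hom: int
    p_zero: float
    method: str


@dataclass(frozen=True)
class ProportionSummary:
    k: int
    n: int
    proportion: float
    ci_low: float
    ci_high: float


def allele_frequency(counts: CarrierCounts) -> float:
    """q = (n_het + 2 n_hom) / (2 n_total)."""
    if counts.n_total == 0:
        raise ValueError("allele frequency undefined for an empty cohort")
    return (counts.n_het + 2 * counts.n_hom) / (2 * counts.n_total)


def expected_homozygotes(q: float, n: int) -> float:
    """Hardy-Weinberg expectation N*q^2."""
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    return n * q * q


def zero_homozygote_pvalue(
    q: float, n: int, observed: int = 0, method: str = "binomial_exact"
) -> DepletionResult:
    """P(X <= observed) homozygotes under HWE sampling.

    ``binomial_exact``: X ~ Binomial(n, q^2) (default; the exact sampling
    distribution of homozygote counts). ``poisson``: X ~ Poisson(n*q^2).
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    if observed > n:
        raise ValueError("observed homozygotes cannot exceed cohort size")
    expected = n * q * q
    if method == "binomial_exact":
        p = float(stats.binom.cdf(observed, n, q * q))
    elif method == "poisson":
        p = float(stats.poisson.cdf(observed, expected))
    else:
        raise ValueError(
            f"unknown depletion method {method!r}; choose from {DEPLETION_METHODS}"
        )
    return DepletionResult(
        q=q, expected_hom=expected, observed_hom=observed, p_zero=p, method=method
    )


def recurrence_denominator(q: float) -> float:
    """X in the "1 in X" expected rate of homozygotes, X = 1/q^2.

    Returns ``math.inf`` for q = 0 (no homozygote ever expected).
    """
    if q < 0 or q > 1:
        raise ValueError("q must be in [0, 1]")
    if q == 0:
        return math.inf
    return 1.0 / (q * q)


def proportion_summary(k: int, n: int, confidence: float = 0.95) -> ProportionSummary:
    """k/n with a two-sided exact (Clopper-Pearson) binomial interval."""
    if n <= 0:
        raise ValueError("proportion undefined for n = 0")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=confidence, method="exact")
    return ProportionSummary(
        k=k, n=n, proportion=k / n, ci_low=float(ci.low), ci_high=float(ci.high)
    )


@dataclass(frozen=True)
class TwoProportionResult:
    p_value: float
    odds_ratio: float  # conditional MLE; nan/inf when a margin is zero


def two_proportion_exact_test(k1: int, n1: int, k2: int, n2: int) -> TwoProportionResult:
    """Fisher exact two-sided test on [[k1, n1-k1], [k2, n2-k2]]."""
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    if min(min(row) for row in table) < 0:
        raise ValueError("invalid 2x2 counts")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    try:
        or_res = stats.contingency.odds_ratio(table, kind="conditional")
        odds = float(or_res.statistic)
    except ValueError:
        odds = math.nan
    return TwoProportionResult(p_value=float(p), odds_ratio=odds)


# ---------------------------------------------------------------------------
# display renderings (raw values are always retained; these follow the
# reporting precisions used for cohort summaries)
# ---------------------------------------------------------------------------

def render_frequency_percent(q: float) -> float:
    """Allele/haplotype frequency as a percentage at one decimal (0.0249 -> 2.5)."""
    return round(100.0 * q, 1)


def render_proportion_percent(p: float) -> float:
    """Proportion as percent: integer above 1%, one decimal below (0.009375 -> 0.9)."""
    pct = 100.0 * p
    return float(round(pct)) if pct >= 1.0 else round(pct, 1)


def render_expected_homozygotes(expected: float) -> int:
    return round(expected)


def render_recurrence(q: float) -> str:
    x = recurrence_denominator(q)
    if math.isinf(x):
        return "homozygotes not expected (q = 0)"
    return f"1 in {round(x)}"


def interval_length_mb(start_bp: int, end_bp: int) -> float:
    """Inclusive interval length in Mb, rounded to 2 decimals for reporting."""
    if end_bp < start_bp:
        raise ValueError("end_bp must be >= start_bp")
    return round((end_bp - start_bp + 1) / 1e6, 2)
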