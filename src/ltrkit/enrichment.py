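"""Exact-test statistics behind every reported enrichment number.

Implements the two-sided Fisher exact test (summing, over the margin
class of the observed 2x2 table, every table whose hypergeometric
probability does not exceed the observed one -- the convention of the
mainstream exact-test implementations), enrichment ratios as observed
vs expected percentages, set-vs-set differential comparisons, the
upper-tail hypergeometric overlap test, and the log(p)*z combined
score used by rank-based enrichment platforms.

Category enrichment against a gene universe follows the construction
that reproduces the published tables: the observed in-category count
among linked genes is tested against the expected-by-chance count for
the same number of linked genes at the universe's category prevalence.
"""

from __future__ import annotations

import decimal
import math
from dataclasses import dataclass
from typing import Collection, Sequence

import numpy as np
from scipy import stats

from .types import ContingencyResult, LTRKitError, ValidationError

__all__ = [
    "fisher_two_sided",
    "fisher_margin_class",
    "enrichment_ratio",
    "category_enrichment",
    "category_enrichment_from_counts",
    "expected_count",
    "DifferentialComparison",
    "differential_comparison",
    "hypergeometric_overlap",
    "combined_score",
    "benjamini_hochberg",
    "round_half_up",
]

# relative slack when comparing table probabilities, absorbing float
# round-off in the hypergeometric pmf (same convention as R / scipy)
_REL_EPS = 1e-7


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as the published tables do.

    Works on the shortest decimal representation of ``x`` so that values
    printed as exact ties (e.g. 1.005) round up despite binary round-off.
    """
    quantum = decimal.Decimal(1).scaleb(-ndigits)
    return float(
        decimal.Decimal(repr(float(x))).quantize(
            quantum, rounding=decimal.ROUND_HALF_UP
        )
    )


def fisher_margin_class(r1: int, r2: int, c1: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Fisher p-values for every table with the given margins.

    Returns the feasible values of the top-left cell ``a`` and the
    corresponding p-values, computed by summing hypergeometric
    probabilities not exceeding each table's own.
    """
    if min(r1, r2, c1) < 0 or c1 > r1 + r2:
        raise ValidationError("inconsistent margins")
    n = r1 + r2
    a_lo = max(0, c1 - r2)
    a_hi = min(r1, c1)
    ks = np.arange(a_lo, a_hi + 1)
    if n == 0:
        return ks, np.ones(1)
    pmf = stats.hypergeom.pmf(ks, n, r1, c1)
    order = np.argsort(pmf, kind="stable")
    csum = np.cumsum(pmf[order])
    # p[i] = sum of pmf over tables with pmf <= pmf[i]*(1+eps)
    idx = np.searchsorted(pmf[order], pmf * (1 + _REL_EPS), side="right")
    pvals = np.minimum(csum[idx - 1], 1.0)
    return ks, pvals


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact test p-value for the table [[a, b], [c, d]]."""
    for v in (a, b, c, d):
        if v < 0:
            raise ValidationError("contingency cells must be non-negative")
    if a + b + c + d == 0:
        raise ValidationError("at least one margin must be nonzero")
    ks, pvals = fisher_margin_class(a + b, c + d, a + c)
    return float(pvals[np.searchsorted(ks, a)])


def enrichment_ratio(
    obs_k: int, obs_n: int, exp_k: int, exp_n: int
) -> tuple[float, float, float]:
    """Observed %, expected %, and their ratio (full precision)."""
    if obs_n <= 0 or exp_n <= 0:
        raise ValidationError("denominators must be positive")
    observed_pct = 100.0 * obs_k / obs_n
    expected_pct = 100.0 * exp_k / exp_n
    if expected_pct == 0:
        raise ValidationError("expected percentage is zero; enrichment undefined")
    return observed_pct, expected_pct, observed_pct / expected_pct


def expected_count(n_linked: int, n_category: int, n_universe: int) -> int:
    """Expected-by-chance in-category count among ``n_linked`` genes."""
    return int(math.floor(n_linked * n_category / n_universe + 0.5))


def category_enrichment_from_counts(
    k: int, n: int, category_total: int, universe_size: int,
    method: str = "universe",
) -> ContingencyResult:
    """Category enrichment from bare counts.

    ``k`` in-category genes among ``n`` linked genes, against a category
    of ``category_total`` genes in a universe of ``universe_size``.

    Two table constructions are supported.  ``method="universe"`` is the
    standard contingency partition of the whole universe,
    ``[[k, n-k], [K-k, N-n-K+k]]`` -- a properly calibrated exact test.
    ``method="expected_count"`` compares the observed in-category count
    against the expected-by-chance count for an equally sized linked set,
    ``[[k, n-k], [e, n-e]]`` with ``e = round(n*K/N)``; this is the
    construction behind the published enrichment tables, and is
    conservative because the expected column carries no sampling
    variance.  Percentages and the enrichment ratio are identical under
    both methods.
    """
    if method not in ("universe", "expected_count"):
        raise ValueError(f"unknown method {method!r}")
    if k > n or category_total > universe_size or n > universe_size:
        raise ValidationError("inconsistent counts")
    if k > category_total:
        raise ValidationError("in-category linked count exceeds the category size")
    observed_pct, expected_pct, enr = enrichment_ratio(
        k, n, category_total, universe_size
    )
    if method == "universe":
        c = category_total - k
        d = universe_size - n - category_total + k
    else:
        c = expected_count(n, category_total, universe_size)
        d = n - c
    p = fisher_two_sided(k, n - k, c, d)
    return ContingencyResult(
        a=k,
        b=n - k,
        c=c,
        d=d,
        observed_pct=observed_pct,
        expected_pct=expected_pct,
        enrichment=enr,
        p_two_sided=p,
    )


def category_enrichment(
    linked_genes: Collection[str],
    category_genes: Collection[str],
    universe: Collection[str],
    method: str = "universe",
) -> ContingencyResult:
    """Enrichment of a gene category among locus-linked genes.

    See :func:`category_enrichment_from_counts` for the two table
    constructions; genes outside the universe are rejected for the
    linked set and ignored for the category.
    """
    universe_set = set(universe)
    linked = set(linked_genes)
    if not linked <= universe_set:
        outside = sorted(linked - universe_set)[:5]
        raise ValidationError(f"linked genes outside the universe, e.g. {outside}")
    category = set(category_genes) & universe_set
    k = len(linked & category)
    n = len(linked)
    if n == 0:
        raise ValidationError("empty linked set")
    return category_enrichment_from_counts(
        k, n, len(category), len(universe_set), method=method
    )


@dataclass(frozen=True)
class DifferentialComparison:
    """Fisher comparison of in-category fractions between two gene sets."""

    k_a: int
    n_a: int
    k_b: int
    n_b: int
    p_two_sided: float

    def __post_init__(self) -> None:
        if self.k_a > self.n_a or self.k_b > self.n_b:
            raise ValidationError("k must not exceed n")

    @property
    def pct_a(self) -> float:
        return 100.0 * self.k_a / self.n_a

    @property
    def pct_b(self) -> float:
        return 100.0 * self.k_b / self.n_b

    @property
    def table(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return ((self.k_a, self.n_a - self.k_a), (self.k_b, self.n_b - self.k_b))


def differential_comparison(
    k_a: int, n_a: int, k_b: int, n_b: int
) -> DifferentialComparison:
    if k_a > n_a or k_b > n_b:
        raise ValidationError("k must not exceed n")
    p = fisher_two_sided(k_a, n_a - k_a, k_b, n_b - k_b)
    return DifferentialComparison(k_a, n_a, k_b, n_b, p)


def hypergeometric_overlap(
    size_a: int, size_b: int, overlap: int, universe_size: int
) -> float:
    """Upper-tail probability of >= ``overlap`` shared genes by chance."""
    if overlap > min(size_a, size_b) or max(size_a, size_b) > universe_size:
        raise ValidationError("inconsistent set sizes")
    if min(size_a, size_b, overlap) < 0:
        raise ValidationError("sizes must be non-negative")
    return float(stats.hypergeom.sf(overlap - 1, universe_size, size_a, size_b))


def combined_score(p: float, z: float) -> float:
    """Combined enrichment score c = ln(p) * z."""
    if not 0.0 < p <= 1.0:
        raise ValidationError("p must be in (0, 1]")
    if not math.isfinite(z):
        raise ValidationError("z must be finite")
    return math.log(p) * z


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (utility)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out
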