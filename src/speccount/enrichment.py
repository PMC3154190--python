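"""Category over-representation analysis for the analytical groups.

Given a sample of protein/gene identifiers and an annotation of categories
(GO biological processes, KEGG pathways, or any user-supplied sets) over a
reference universe of size N, each category of size K observed k times in a
sample of size n is scored by

* the **ratio of enrichment** R = k / (n·K/N) — observed members over the
  number expected if the sample were drawn uniformly from the universe;
* the exact **hypergeometric upper-tail p-value** P(X ≥ k);
* the **Benjamini–Hochberg** adjusted p-value across all categories tested.

A category is significant when the adjusted p is below alpha (default 0.05)
and at least ``min_k`` (default 2) sample members fall in it. Output is
ordered by descending ratio, the convention used when plotting the most
enriched categories first.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .records import AnnotationSet, EnrichmentResult

logger = logging.getLogger(__name__)

__all__ = [
    "assign_categories",
    "ratio_of_enrichment",
    "hypergeom_pvalue",
    "bh_adjust",
    "filter_categories",
    "enrich",
]


def assign_categories(
    sample_ids: Iterable[str], annotation: AnnotationSet
) -> tuple[dict[str, tuple[int, int, int, int]], int]:
    """Per-category (k, n, K, N) contingency parameters for one sample.

    Duplicate sample identifiers are collapsed; identifiers absent from the
    universe are dropped with a logged count. Returns the parameter map and
    the number of dropped identifiers.
    """
    sample = set(sample_ids)
    if not sample:
        raise ValueError("empty sample")
    in_universe = sample & annotation.universe
    n_dropped = len(sample) - len(in_universe)
    if n_dropped:
        logger.info(
            "%d sample identifier(s) absent from the universe were dropped",
            n_dropped,
        )
    n = len(in_universe)
    N = int(annotation.universe_size)
    params = {
        cid: (len(in_universe & members), n, len(members), N)
        for cid, members in annotation.categories.items()
    }
    return params, n_dropped


def ratio_of_enrichment(k: int, n: int, K: int, N: int) -> float:
    """Observed category members over the count expected from the universe.

    R = k / (n·K/N); equivalently (k/n)/(K/N). R > 1 means the category is
    over-represented in the sample relative to its universe frequency.
    """
    if n <= 0 or K <= 0 or N <= 0:
        raise ValueError("n, K and N must be positive")
    expected = n * K / N
    return k / expected


def hypergeom_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Exact upper-tail P(X ≥ k), X ~ Hypergeometric(N, K, n).

    The probability of observing at least k category members when drawing n
    identifiers without replacement from a universe of N containing K
    members. Computed by exact pmf summation (scipy survival function); no
    normal approximation.
    """
    if not (0 <= k <= min(n, K)) or n > N or K > N or min(n, K, N) < 0:
        raise ValueError(
            f"inconsistent hypergeometric parameters k={k} n={n} K={K} N={N}"
        )
    # sf(k-1) = P(X >= k)
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adj(i) = min over j ≥ i (rank order) of p(j)·m/j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def filter_categories(
    results: Sequence[EnrichmentResult],
    alpha: float = 0.05,
    min_k: int = 2,
) -> list[EnrichmentResult]:
    """Significant categories, sorted by descending ratio of enrichment.

    Significance requires an adjusted p strictly below ``alpha`` and at
    least ``min_k`` sample members in the category.
    """
    for res in results:
        res.significant = res.p_adjusted < alpha and res.k >= min_k
    kept = [r for r in results if r.significant]
    kept.sort(key=lambda r: (-r.ratio, r.category_id))
    return kept


def enrich(
    sample_ids: Iterable[str],
    annotation: AnnotationSet,
    alpha: float = 0.05,
    min_k: int = 2,
) -> list[EnrichmentResult]:
    """Full over-representation analysis of one sample.

    Returns every category's result (sorted by descending ratio) with
    p-values BH-adjusted across all categories tested and significance
    flags set; use :func:`filter_categories` or the ``significant`` field
    to restrict to hits.
    """
    params, _ = assign_categories(sample_ids, annotation)
    ids = sorted(params)
    results = []
    for cid in ids:
        k, n, K, N = params[cid]
        results.append(
            EnrichmentResult(
                category_id=cid,
                name=annotation.name_of(cid),
                k=k,
                n=n,
                K=K,
                N=N,
                expected=n * K / N,
                ratio=ratio_of_enrichment(k, n, K, N),
                p_value=hypergeom_pvalue(k, n, K, N),
            )
        )
    adjusted = bh_adjust([r.p_value for r in results])
    for res, p_adj in zip(results, adjusted):
        res.p_adjusted = p_adj
        res.significant = p_adj < alpha and res.k >= min_k
    results.sort(key=lambda r: (-r.ratio, r.category_id))
    return results
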