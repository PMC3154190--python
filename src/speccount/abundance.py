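"""Two-condition spectral-count comparison.

Partitions proteins by presence (exclusive to either condition vs shared),
computes log2 fold changes B/A for shared proteins, derives significance
cutoffs as mean ± 1 sample SD of the shared fold-change distribution, checks
loading balance via the coefficient of variance of per-condition spectral
totals, and applies the abundance-window and protein-family filters that
define the four analytical groups handed to enrichment:

    group 1 — exclusive to condition A
    group 2 — shared, significantly decreased in B, inside the count window
    group 3 — shared, significantly increased in B, inside the count window
    group 4 — exclusive to condition B

Exclusive proteins bypass the count window; family-excluded proteins (by
default immunoglobulins and hemoglobins, which dominate spectra without
being informative here) appear in no group.

Cutoffs are computed over *all* shared proteins, before the abundance
window is applied; the window then restricts which changed proteins enter
the analytical groups.
"""

from __future__ import annotations

import math
import statistics
from typing import Iterable, Optional, Sequence

from ._rounding import round_half_up
from .exceptions import MalformedInputError
from .records import (
    DECREASED,
    EXCLUSIVE_A,
    EXCLUSIVE_B,
    INCREASED,
    NOT_APPLICABLE,
    SHARED,
    UNCHANGED,
    FoldChangeRecord,
    LoadingSummary,
    ProteinGroup,
    ThresholdPair,
)

__all__ = [
    "records_from_groups",
    "classify_presence",
    "log2_fold_change",
    "significance_thresholds",
    "classify_change",
    "loading_cv",
    "abundance_window_filter",
    "exclude_families",
    "make_analytical_groups",
    "quantify",
    "DEFAULT_EXCLUDED_FAMILIES",
]

DEFAULT_EXCLUDED_FAMILIES = ("immunoglobulin", "hemoglobin")


def records_from_groups(groups: Iterable[ProteinGroup]) -> list[FoldChangeRecord]:
    """Turn decoy-free protein groups into fold-change records."""
    return [
        FoldChangeRecord(
            accession=g.representative,
            description=g.description,
            count_A=g.count_A,
            count_B=g.count_B,
        )
        for g in groups
    ]


def classify_presence(
    records: Sequence[FoldChangeRecord],
) -> dict[str, int]:
    """Label each record exclusive_A / exclusive_B / shared, in place.

    Returns the partition sizes; the three classes always sum to the input
    size. A record with zero counts in both conditions cannot exist after
    identification and is rejected.
    """
    counts = {EXCLUSIVE_A: 0, EXCLUSIVE_B: 0, SHARED: 0}
    for rec in records:
        if rec.count_A == 0 and rec.count_B == 0:
            raise MalformedInputError(
                f"{rec.accession}: zero spectra in both conditions"
            )
        if rec.count_B == 0:
            rec.presence_class = EXCLUSIVE_A
        elif rec.count_A == 0:
            rec.presence_class = EXCLUSIVE_B
        else:
            rec.presence_class = SHARED
            rec.log2fc = log2_fold_change(rec.count_A, rec.count_B)
        counts[rec.presence_class] += 1
    return counts


def log2_fold_change(count_a: int, count_b: int) -> float:
    """log2(count_B / count_A), defined only when both counts are positive.

    No pseudocount is applied: proteins with a zero count are exclusives by
    construction and are handled by the presence partition instead.
    """
    if count_a <= 0 or count_b <= 0:
        raise ValueError(
            "log2 fold change requires positive counts in both conditions; "
            "zero-count proteins belong to the presence partition"
        )
    return math.log2(count_b / count_a)


def significance_thresholds(
    records_or_values: Sequence,
) -> ThresholdPair:
    """Mean ± 1 sample SD cutoffs over the shared log2 fold changes.

    Accepts fold-change records (shared ones contribute their ``log2fc``) or
    a bare sequence of floats. Sample SD uses the n−1 denominator.
    """
    values = _shared_log2fcs(records_or_values)
    if len(values) < 2:
        raise ValueError(
            "need at least two shared proteins to estimate fold-change cutoffs"
        )
    return ThresholdPair(
        mean_fc=statistics.fmean(values),
        sd_fc=statistics.stdev(values),
    )


def _shared_log2fcs(records_or_values: Sequence) -> list[float]:
    values: list[float] = []
    for item in records_or_values:
        if isinstance(item, FoldChangeRecord):
            if item.log2fc is not None:
                values.append(item.log2fc)
        else:
            values.append(float(item))
    return values


def classify_change(
    record: FoldChangeRecord, thresholds: ThresholdPair
) -> str:
    """Classify one shared protein against the fold-change cutoffs.

    Strictly greater than the upper cutoff → increased; strictly less than
    the lower cutoff → decreased; boundary values are unchanged. Exclusive
    proteins get ``not_applicable``.
    """
    if record.log2fc is None:
        record.change_class = NOT_APPLICABLE
    elif record.log2fc > thresholds.upper:
        record.change_class = INCREASED
    elif record.log2fc < thresholds.lower:
        record.change_class = DECREASED
    else:
        record.change_class = UNCHANGED
    return record.change_class


def loading_cv(total_a: int, total_b: int) -> LoadingSummary:
    """Coefficient of variance of the two per-condition spectral totals.

    A loading control: near-equal totals (CV on the order of 1%) show that
    fold changes reflect biology rather than sample loading. Uses the
    sample SD (n−1 denominator over the two totals); reported value rounded
    half-up to two decimals.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("per-condition totals must be positive")
    mean = (total_a + total_b) / 2.0
    sd = statistics.stdev([float(total_a), float(total_b)])
    raw = 100.0 * sd / mean
    return LoadingSummary(
        total_A=total_a,
        total_B=total_b,
        cv_percent=round_half_up(raw, 2),
        cv_percent_raw=raw,
    )


def abundance_window_filter(
    records: Sequence[FoldChangeRecord], low: int = 25, high: int = 300
) -> list[FoldChangeRecord]:
    """Flag shared records inside the total-spectra window (inclusive).

    Shared proteins outside [low, high] total spectra are excluded from the
    analytical groups — very low counts are unreliable and very abundant
    proteins sit within the unchanged band anyway. Exclusive proteins are
    always retained regardless of total spectral count.
    """
    if low > high:
        raise ValueError("window lower bound exceeds upper bound")
    for rec in records:
        if rec.presence_class == SHARED:
            rec.in_window = low <= rec.total <= high
        else:
            rec.in_window = True
    return list(records)


def exclude_families(
    records: Sequence[FoldChangeRecord],
    patterns: Sequence[str] = DEFAULT_EXCLUDED_FAMILIES,
) -> list[FoldChangeRecord]:
    """Flag records whose description matches an excluded protein family.

    Matching is a case-insensitive substring test against each pattern.
    """
    lowered = [p.lower() for p in patterns]
    for rec in records:
        desc = rec.description.lower()
        rec.family_excluded = any(p in desc for p in lowered)
    return list(records)


def make_analytical_groups(
    records: Sequence[FoldChangeRecord],
    thresholds: Optional[ThresholdPair] = None,
) -> dict[str, list[FoldChangeRecord]]:
    """Split filtered records into the four disjoint analytical groups.

    If ``thresholds`` is given, change classes are (re)assigned first.
    Family-excluded records appear in no group; shared changed records must
    also lie inside the abundance window.
    """
    if thresholds is not None:
        for rec in records:
            classify_change(rec, thresholds)
    groups: dict[str, list[FoldChangeRecord]] = {
        EXCLUSIVE_A: [],
        DECREASED: [],
        INCREASED: [],
        EXCLUSIVE_B: [],
    }
    for rec in records:
        if rec.family_excluded:
            continue
        if rec.presence_class == EXCLUSIVE_A:
            groups[EXCLUSIVE_A].append(rec)
        elif rec.presence_class == EXCLUSIVE_B:
            groups[EXCLUSIVE_B].append(rec)
        elif rec.change_class in (INCREASED, DECREASED) and rec.in_window:
            groups[rec.change_class].append(rec)
    return groups


def quantify(
    groups: Sequence[ProteinGroup],
    window: tuple[int, int] = (25, 300),
    excluded_families: Sequence[str] = DEFAULT_EXCLUDED_FAMILIES,
) -> tuple[
    list[FoldChangeRecord],
    dict[str, int],
    ThresholdPair,
    LoadingSummary,
    dict[str, list[FoldChangeRecord]],
]:
    """Run the full quantitation stage on decoy-free protein groups.

    Returns the labelled records, the presence partition sizes, the
    fold-change cutoffs, the loading summary, and the four analytical
    groups.
    """
    records = records_from_groups(groups)
    partition = classify_presence(records)
    thresholds = significance_thresholds(records)
    loading = loading_cv(
        sum(r.count_A for r in records), sum(r.count_B for r in records)
    )
    abundance_window_filter(records, *window)
    exclude_families(records, excluded_families)
    analytical = make_analytical_groups(records, thresholds)
    return records, partition, thresholds, loading, analytical
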