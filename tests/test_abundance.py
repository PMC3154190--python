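"""Presence partition, fold-change statistics, filters, analytical groups."""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from speccount import (
    FoldChangeRecord,
    ThresholdPair,
    abundance_window_filter,
    classify_change,
    classify_presence,
    exclude_families,
    loading_cv,
    log2_fold_change,
    make_analytical_groups,
    significance_thresholds,
)
from speccount.exceptions import MalformedInputError
from speccount._rounding import round_half_up


def rec(count_a, count_b, accession="P1", description=""):
    return FoldChangeRecord(
        accession=accession, description=description,
        count_A=count_a, count_B=count_b,
    )


# ---------------------------------------------------------------------------
# presence partition

@pytest.mark.parametrize(
    "count_a,count_b,expected",
    [(5, 0, "exclusive_A"), (0, 7, "exclusive_B"), (3, 4, "shared")],
)
def test_presence_classes(count_a, count_b, expected):
    records = [rec(count_a, count_b)]
    counts = classify_presence(records)
    assert records[0].presence_class == expected
    assert counts[expected] == 1


def test_presence_rejects_double_zero():
    with pytest.raises(MalformedInputError):
        classify_presence([rec(0, 0)])


def test_partition_sums_to_input_size(default_quantified):
    partition = default_quantified["partition"]
    assert sum(partition.values()) == len(default_quantified["records"])
    assert (
        sum(partition.values())
        == default_quantified["ident"].n_after_decoy_removal
    )


# ---------------------------------------------------------------------------
# log2 fold change

@pytest.mark.parametrize(
    "count_a,count_b,expected",
    [(4, 8, 1.0), (13, 13, 0.0), (8, 1, -3.0)],
)
def test_log2_fold_change_values(count_a, count_b, expected):
    assert log2_fold_change(count_a, count_b) == pytest.approx(expected)


def test_log2_fold_change_refuses_zero_counts():
    with pytest.raises(ValueError, match="presence"):
        log2_fold_change(0, 5)


# ---------------------------------------------------------------------------
# significance thresholds

def test_published_mean_and_sd_give_published_cutoffs():
    # two points at mean +/- sd/sqrt(2) realize mean 0.128, sample SD 0.997
    offset = 0.997 / math.sqrt(2)
    thresholds = significance_thresholds([0.128 - offset, 0.128 + offset])
    assert round_half_up(thresholds.mean_fc, 3) == 0.128
    assert round_half_up(thresholds.sd_fc, 3) == 0.997
    assert round_half_up(thresholds.lower, 3) == -0.869
    assert round_half_up(thresholds.upper, 3) == 1.125


def test_degenerate_distribution_has_zero_sd():
    thresholds = significance_thresholds([0.5, 0.5, 0.5])
    assert thresholds.sd_fc == 0.0
    assert thresholds.lower == thresholds.upper == 0.5


def test_two_point_thresholds_match_direct_formula():
    thresholds = significance_thresholds([-1.0, 1.0])
    assert thresholds.mean_fc == 0.0
    assert thresholds.sd_fc == pytest.approx(math.sqrt(2))
    assert thresholds.lower == pytest.approx(-math.sqrt(2))
    assert thresholds.upper == pytest.approx(math.sqrt(2))


def test_thresholds_require_two_shared_records():
    with pytest.raises(ValueError):
        significance_thresholds([0.5])


@given(
    values=st.lists(
        st.floats(min_value=-6, max_value=6, allow_nan=False),
        min_size=2, max_size=50,
    )
)
@settings(derandomize=True, deadline=None, max_examples=60)
def test_threshold_symmetry(values):
    thresholds = significance_thresholds(values)
    assert thresholds.upper - thresholds.mean_fc == pytest.approx(
        thresholds.mean_fc - thresholds.lower
    )
    assert thresholds.upper - thresholds.mean_fc == pytest.approx(thresholds.sd_fc)


# ---------------------------------------------------------------------------
# change classification

@pytest.mark.parametrize(
    "log2fc,expected",
    [(2.0, "increased"), (0.128, "unchanged"), (1.125, "unchanged"),
     (-0.869, "unchanged"), (-2.0, "decreased")],
)
def test_change_classes_with_published_cutoffs(log2fc, expected):
    thresholds = ThresholdPair(mean_fc=0.128, sd_fc=0.997)
    record = rec(1, 1)
    record.presence_class = "shared"
    record.log2fc = log2fc
    assert classify_change(record, thresholds) == expected


def test_exclusive_record_change_is_not_applicable():
    record = rec(5, 0)
    classify_presence([record])
    assert classify_change(record, ThresholdPair(0.0, 1.0)) == "not_applicable"


def test_classification_counts_swap_under_condition_relabeling():
    counts = [(4, 40), (40, 4), (10, 11), (30, 29), (7, 70), (3, 3)]
    records = [rec(a, b, accession=f"P{i}") for i, (a, b) in enumerate(counts)]
    classify_presence(records)
    thresholds = significance_thresholds(records)
    for r in records:
        classify_change(r, thresholds)
    swapped = [rec(b, a, accession=f"P{i}") for i, (a, b) in enumerate(counts)]
    classify_presence(swapped)
    thresholds_swapped = significance_thresholds(swapped)
    assert thresholds_swapped.mean_fc == pytest.approx(-thresholds.mean_fc)
    for r in swapped:
        classify_change(r, thresholds_swapped)
    n_inc = sum(r.change_class == "increased" for r in records)
    n_dec = sum(r.change_class == "decreased" for r in records)
    assert sum(r.change_class == "decreased" for r in swapped) == n_inc
    assert sum(r.change_class == "increased" for r in swapped) == n_dec


# ---------------------------------------------------------------------------
# loading CV

def test_published_totals_give_published_cv():
    summary = loading_cv(35637, 35009)
    assert summary.cv_percent == 1.26


def test_equal_totals_give_zero_cv():
    assert loading_cv(4242, 4242).cv_percent == 0.00


def test_cv_matches_direct_sample_sd_evaluation():
    # sd([100, 200]) = 70.71..., mean 150 -> 47.14%
    assert loading_cv(100, 200).cv_percent == 47.14


# ---------------------------------------------------------------------------
# filters

def test_window_excludes_low_and_high_shared_but_never_exclusives():
    low = rec(12, 12)        # total 24: below
    edge = rec(13, 12)       # total 25: boundary inclusive
    high = rec(150, 151)     # total 301: above
    exclusive = rec(0, 5)    # exclusive_B, tiny: retained regardless
    records = [low, edge, high, exclusive]
    classify_presence(records)
    abundance_window_filter(records, 25, 300)
    assert not low.in_window
    assert edge.in_window
    assert not high.in_window
    assert exclusive.in_window


@pytest.mark.parametrize(
    "description,excluded",
    [
        ("Immunoglobulin heavy chain", True),
        ("Hemoglobin subunit beta", True),
        ("Cathepsin B", False),
    ],
)
def test_family_exclusion_is_case_insensitive_substring(description, excluded):
    record = rec(5, 5, description=description)
    exclude_families([record])
    assert record.family_excluded is excluded


# ---------------------------------------------------------------------------
# analytical groups

def test_analytical_groups_are_disjoint_and_complete():
    records = [
        rec(5, 0, "exA"),
        rec(0, 5, "exB"),
        rec(100, 4, "down"),     # log2fc -4.6
        rec(4, 100, "up"),       # log2fc +4.6
        rec(50, 52, "flat"),
        rec(4, 90, "ig", description="immunoglobulin kappa"),
        rec(400, 4000, "huge"),  # changed but outside the window
    ]
    classify_presence(records)
    thresholds = ThresholdPair(mean_fc=0.0, sd_fc=1.0)
    abundance_window_filter(records, 25, 300)
    exclude_families(records)
    groups = make_analytical_groups(records, thresholds)
    assert [r.accession for r in groups["exclusive_A"]] == ["exA"]
    assert [r.accession for r in groups["exclusive_B"]] == ["exB"]
    assert [r.accession for r in groups["decreased"]] == ["down"]
    assert [r.accession for r in groups["increased"]] == ["up"]
    assigned = [r.accession for recs in groups.values() for r in recs]
    assert len(assigned) == len(set(assigned))
    assert "flat" not in assigned and "ig" not in assigned and "huge" not in assigned


def test_planted_differentials_recovered_with_high_sensitivity(default_quantified):
    """Planted 2.5-log2 effects land in the increased/decreased sets."""
    truth = default_quantified["truth"]
    records = default_quantified["records"]
    up = truth.of_class("shared_up")
    down = truth.of_class("shared_down")
    increased = {r.accession for r in records if r.change_class == "increased"}
    decreased = {r.accession for r in records if r.change_class == "decreased"}
    recovered = len(up & increased) + len(down & decreased)
    assert recovered / (len(up) + len(down)) >= 0.90
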