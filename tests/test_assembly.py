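"""Protein assembly: decoys, evidence graph, parsimony, FDR."""

from __future__ import annotations

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from speccount import (
    apply_min_peptides,
    assemble,
    build_peptide_protein_graph,
    collapse_indistinguishable,
    compute_fdr,
    generate_decoy_database,
    parsimony_cover,
    remove_decoys,
    ProteinGroup,
)
from speccount.exceptions import MalformedInputError

from conftest import psm


# ---------------------------------------------------------------------------
# decoy database

@pytest.mark.parametrize(
    "record,expected",
    [
        (("P1", "PEPTIDE"), ("REV_P1", "EDITPEP")),
        (("P2", "A"), ("REV_P2", "A")),
    ],
)
def test_decoy_is_prefixed_full_reversal(record, expected):
    assert generate_decoy_database([record]) == [expected]


def test_decoy_database_preserves_order_and_cardinality():
    records = [("P1", "AAK"), ("P2", "CCR"), ("P3", "DDK")]
    decoys = generate_decoy_database(records)
    assert [d[0] for d in decoys] == ["REV_P1", "REV_P2", "REV_P3"]
    assert len(decoys) == 3


def test_decoy_database_rejects_empty_sequence_naming_accession():
    with pytest.raises(MalformedInputError, match="P9"):
        generate_decoy_database([("P9", "")])


# ---------------------------------------------------------------------------
# evidence graph

def test_graph_counts_spectra_per_condition():
    graph = build_peptide_protein_graph(
        [psm("s1", "PEP", {"A1"}, "A"), psm("s2", "PEP", {"A1"}, "A")]
    )
    assert graph.peptide_to_proteins == {"PEP": frozenset({"A1"})}
    assert graph.peptide_counts["PEP"] == {"A": 2}


def test_graph_unions_accessions_across_psms():
    graph = build_peptide_protein_graph(
        [psm("s1", "PEP", {"A1"}, "A"), psm("s2", "PEP", {"A2"}, "A")]
    )
    assert graph.peptide_to_proteins["PEP"] == frozenset({"A1", "A2"})


def test_graph_of_empty_input_is_empty():
    graph = build_peptide_protein_graph([])
    assert graph.peptide_to_proteins == {}
    assert graph.peptide_counts == {}


# ---------------------------------------------------------------------------
# indistinguishable collapse

def _graph(*psms_):
    return build_peptide_protein_graph(list(psms_))


def test_identical_evidence_collapses_to_one_group():
    graph = _graph(
        psm("s1", "PEPA", {"A1", "A2"}, "A"),
        psm("s2", "PEPB", {"A1", "A2"}, "A"),
    )
    groups = collapse_indistinguishable(graph)
    assert len(groups) == 1
    assert groups[0].members == frozenset({"A1", "A2"})
    assert groups[0].representative == "A1"


def test_distinct_evidence_stays_separate():
    graph = _graph(
        psm("s1", "PEPA", {"A1", "A2"}, "A"),
        psm("s2", "PEPB", {"A2"}, "A"),
    )
    groups = collapse_indistinguishable(graph)
    assert len(groups) == 2


def test_collapse_of_empty_graph_is_empty():
    assert collapse_indistinguishable(_graph()) == []


# ---------------------------------------------------------------------------
# parsimony cover

def test_cover_discards_subsumed_protein():
    # p1 -> {A, B}, p2 -> {A}, p3 -> {C}: minimal cover is {A, C}; B is
    # subsumed (its only peptide is explained by A)
    graph = _graph(
        psm("s1", "PEP1", {"A", "B"}, "X"),
        psm("s2", "PEP2", {"A"}, "X"),
        psm("s3", "PEP3", {"C"}, "X"),
    )
    groups = parsimony_cover(collapse_indistinguishable(graph), graph, "X", "Y")
    assert sorted(g.representative for g in groups) == ["A", "C"]


def test_disjoint_evidence_retains_all_proteins():
    graph = _graph(
        psm("s1", "PEP1", {"A"}, "X"),
        psm("s2", "PEP2", {"B"}, "X"),
    )
    groups = parsimony_cover(collapse_indistinguishable(graph), graph, "X", "Y")
    assert sorted(g.representative for g in groups) == ["A", "B"]


def test_single_protein_explains_all_peptides():
    graph = _graph(
        psm("s1", "PEP1", {"A"}, "X"),
        psm("s2", "PEP2", {"A"}, "X"),
    )
    groups = parsimony_cover(collapse_indistinguishable(graph), graph, "X", "Y")
    assert len(groups) == 1
    assert groups[0].count_A == 2


def test_shared_peptide_counts_credited_to_every_selected_group():
    graph = _graph(
        psm("s1", "PEPS", {"A", "B"}, "X"),
        psm("s2", "PEPA", {"A"}, "X"),
        psm("s3", "PEPB", {"B"}, "Y"),
    )
    groups = parsimony_cover(collapse_indistinguishable(graph), graph, "X", "Y")
    by_rep = {g.representative: g for g in groups}
    assert by_rep["A"].count_A == 2  # PEPS + PEPA
    assert by_rep["B"].count_A == 1 and by_rep["B"].count_B == 1


def _random_instance(rng: random.Random):
    n_prot = rng.randint(2, 12)
    n_pep = rng.randint(n_prot, 20)
    psms_ = []
    for j in range(n_pep):
        owners = rng.sample(range(n_prot), rng.randint(1, min(3, n_prot)))
        for c in range(rng.randint(1, 3)):
            psms_.append(
                psm(f"s{j}_{c}", f"PEP{j:02d}", {f"A{i:02d}" for i in owners},
                    "X" if c % 2 == 0 else "Y")
            )
    return psms_


def _exact_min_cover_size(pre_groups, all_peptides):
    """Exhaustive minimal set cover by bitmask enumeration."""
    pep_index = {p: i for i, p in enumerate(sorted(all_peptides))}
    full = (1 << len(pep_index)) - 1
    masks = []
    for g in pre_groups:
        m = 0
        for p in g.peptides:
            m |= 1 << pep_index[p]
        masks.append(m)
    for size in range(1, len(masks) + 1):
        for combo in itertools.combinations(masks, size):
            acc = 0
            for m in combo:
                acc |= m
            if acc == full:
                return size
    raise AssertionError("no cover found")


def test_greedy_cover_is_minimal_on_small_random_instances():
    """Greedy parsimony matches the exhaustive minimal cover (sampled)."""
    rng = random.Random(20110810)
    for _ in range(200):
        psms_ = _random_instance(rng)
        graph = build_peptide_protein_graph(psms_)
        pre = collapse_indistinguishable(graph)
        selected = parsimony_cover(pre, graph, "X", "Y")
        exact = _exact_min_cover_size(pre, set(graph.peptide_to_proteins))
        assert len(selected) == exact


def test_selected_groups_explain_every_peptide_and_conserve_counts():
    rng = random.Random(7)
    for _ in range(50):
        psms_ = _random_instance(rng)
        graph = build_peptide_protein_graph(psms_)
        selected = parsimony_cover(
            collapse_indistinguishable(graph), graph, "X", "Y"
        )
        covered = set().union(*(g.peptides for g in selected))
        assert covered == set(graph.peptide_to_proteins)
        credited = sum(g.total for g in selected)
        assert credited >= len(psms_)
        shared_between_selected = any(
            sum(1 for g in selected if p in g.peptides) > 1
            for p in graph.peptide_to_proteins
        )
        if not shared_between_selected:
            assert credited == len(psms_)


def test_assembly_is_invariant_under_psm_permutation():
    rng = random.Random(11)
    psms_ = _random_instance(rng)
    reference = parsimony_cover(
        collapse_indistinguishable(build_peptide_protein_graph(psms_)),
        build_peptide_protein_graph(psms_), "X", "Y",
    )
    for _ in range(5):
        shuffled = psms_[:]
        rng.shuffle(shuffled)
        graph = build_peptide_protein_graph(shuffled)
        groups = parsimony_cover(collapse_indistinguishable(graph), graph, "X", "Y")
        assert groups == reference


# ---------------------------------------------------------------------------
# min-peptide filter

def _group(rep, peptides, count_a=1, count_b=1, decoy=False):
    return ProteinGroup(
        representative=rep, members=frozenset({rep}),
        peptides=frozenset(peptides), count_A=count_a, count_B=count_b,
        is_decoy=decoy,
    )


def test_min_peptides_boundary_is_inclusive():
    one = _group("P1", {"p1"})
    two = _group("P2", {"p1", "p2"})
    assert apply_min_peptides([one, two], 2) == [two]
    assert apply_min_peptides([one, two], 1) == [one, two]


# ---------------------------------------------------------------------------
# FDR and decoy removal

def test_fdr_doubling_rule_reproduces_published_rate():
    groups = [_group(f"P{i}", {"a", "b"}) for i in range(2814)]
    groups += [_group(f"REV_P{i}", {"c", "d"}, decoy=True) for i in range(11)]
    summary = compute_fdr(groups)
    assert summary.n_total_groups == 2825
    assert summary.n_decoy_groups == 11
    assert summary.fdr_percent == 0.78
    assert summary.n_after_decoy_removal == 2814
    assert not summary.exceeds_max


def test_fdr_zero_decoys_and_exact_threshold():
    assert compute_fdr([_group(f"P{i}", {"a", "b"}) for i in range(100)]).fdr_percent == 0.0
    groups = [_group(f"P{i}", {"a", "b"}) for i in range(195)]
    groups += [_group(f"REV_{i}", {"c", "d"}, decoy=True) for i in range(5)]
    summary = compute_fdr(groups, max_fdr_percent=5.0)
    assert summary.fdr_percent == 5.00
    assert not summary.exceeds_max  # 5.00 does not exceed max 5.0


def test_fdr_of_empty_list_is_zero_with_warning(caplog):
    import logging

    with caplog.at_level(logging.WARNING, logger="speccount.assembly"):
        summary = compute_fdr([])
    assert summary.fdr_percent == 0.0
    assert any("empty" in rec.message for rec in caplog.records)


@given(
    n_targets=st.integers(min_value=1, max_value=300),
    n_decoys=st.integers(min_value=0, max_value=50),
)
@settings(derandomize=True, deadline=None, max_examples=60)
def test_fdr_never_decreases_when_a_decoy_is_added(n_targets, n_decoys):
    groups = [_group(f"P{i}", {"a", "b"}) for i in range(n_targets)]
    groups += [_group(f"REV_{i}", {"c", "d"}, decoy=True) for i in range(n_decoys)]
    before = compute_fdr(groups)
    groups.append(_group("REV_NEW", {"e", "f"}, decoy=True))
    after = compute_fdr(groups)
    assert after.fdr_percent_raw >= before.fdr_percent_raw
    assert before.n_after_decoy_removal == len(remove_decoys(groups[:-1]))


def test_remove_decoys_examples():
    targets = [_group(f"P{i}", {"a", "b"}) for i in range(4)]
    decoys = [_group("REV_1", {"c", "d"}, decoy=True)]
    assert remove_decoys(targets + decoys) == targets
    assert remove_decoys(targets) == targets
    assert remove_decoys(decoys) == []


def test_mixed_target_decoy_group_counts_as_target():
    graph = _graph(
        psm("s1", "PEP1", {"P1", "REV_P2"}, "X", decoys={"REV_P2"}),
        psm("s2", "PEP2", {"P1", "REV_P2"}, "X", decoys={"REV_P2"}),
    )
    groups = parsimony_cover(collapse_indistinguishable(graph), graph, "X", "Y")
    assert len(groups) == 1
    assert not groups[0].is_decoy


def test_assemble_end_to_end_on_constructed_input():
    psms_ = [
        psm("s1", "PEPA", {"P1"}, "X"),
        psm("s2", "PEPB", {"P1"}, "X"),
        psm("s3", "PEPC", {"P2"}, "Y"),  # one peptide only: filtered out
        psm("s4", "PEPD", {"REV_P3"}, "X", decoys={"REV_P3"}),
        psm("s5", "PEPE", {"REV_P3"}, "Y", decoys={"REV_P3"}),
    ]
    groups, summary = assemble(psms_, condition_a="X", condition_b="Y")
    assert summary.n_total_groups == 2
    assert summary.n_decoy_groups == 1
    assert summary.fdr_percent == 100.0  # 2*1/2
    assert summary.exceeds_max
    assert [g.representative for g in remove_decoys(groups)] == ["P1"]
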