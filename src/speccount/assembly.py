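"""Parsimonious protein assembly from peptide-spectrum matches.

Implements the IDPicker-style path from a PSM table to a minimal,
FDR-controlled list of protein groups:

1. build the bipartite peptide→protein evidence graph with per-condition
   spectral counts (:func:`build_peptide_protein_graph`);
2. collapse proteins with identical peptide evidence into indistinguishable
   pre-groups (:func:`collapse_indistinguishable`);
3. greedily select a minimal set of groups explaining every peptide,
   discarding subsumed proteins (:func:`parsimony_cover`);
4. apply the minimum-distinct-peptide filter (:func:`apply_min_peptides`);
5. estimate the protein-level false discovery rate from reversed-decoy hits
   with the doubling rule FDR = 2·D/T (:func:`compute_fdr`) and remove decoy
   groups (:func:`remove_decoys`).

:func:`assemble` chains the five steps.
"""

from __future__ import annotations

import heapq
import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from ._rounding import round_half_up
from .exceptions import MalformedInputError
from .records import DECOY_PREFIX, IdentificationSummary, ProteinGroup, PSMRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PeptideProteinGraph",
    "generate_decoy_database",
    "build_peptide_protein_graph",
    "collapse_indistinguishable",
    "parsimony_cover",
    "apply_min_peptides",
    "compute_fdr",
    "remove_decoys",
    "assemble",
]


def generate_decoy_database(
    protein_records: Sequence[tuple[str, str]],
) -> list[tuple[str, str]]:
    """Reverse every protein sequence to build a decoy database.

    Each input ``(accession, sequence)`` yields ``("REV_" + accession,
    reversed sequence)``, preserving input order. Searching targets and
    decoys together lets decoy hits estimate the false discovery rate.
    """
    decoys = []
    for accession, sequence in protein_records:
        if not sequence:
            raise MalformedInputError(
                f"protein {accession!r} has an empty sequence"
            )
        decoys.append((DECOY_PREFIX + accession, sequence[::-1]))
    return decoys


@dataclass
class PeptideProteinGraph:
    """Bipartite peptide→protein evidence with per-condition spectral counts.

    ``peptide_to_proteins`` maps each distinct peptide sequence to the union
    of accessions over all PSMs containing it; ``peptide_counts`` maps
    ``peptide -> {condition: n_spectra}``.
    """

    peptide_to_proteins: dict[str, frozenset[str]] = field(default_factory=dict)
    peptide_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    decoy_flags: dict[str, bool] = field(default_factory=dict)
    conditions: tuple[str, ...] = ()
    descriptions: dict[str, str] = field(default_factory=dict)

    def peptide_total(self, peptide: str) -> int:
        return sum(self.peptide_counts.get(peptide, {}).values())

    def protein_to_peptides(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for peptide, accessions in self.peptide_to_proteins.items():
            for acc in accessions:
                out.setdefault(acc, set()).add(peptide)
        return {acc: frozenset(peps) for acc, peps in out.items()}


def build_peptide_protein_graph(
    psms: Iterable[PSMRecord],
    descriptions: Optional[dict[str, str]] = None,
) -> PeptideProteinGraph:
    """Aggregate PSMs into the peptide→protein graph with spectral counts."""
    pep_prot: dict[str, set[str]] = {}
    pep_counts: dict[str, dict[str, int]] = {}
    decoy_flags: dict[str, bool] = {}
    conditions: set[str] = set()
    for psm in psms:
        pep_prot.setdefault(psm.peptide, set()).update(psm.accessions)
        cond_counts = pep_counts.setdefault(psm.peptide, {})
        cond_counts[psm.condition] = cond_counts.get(psm.condition, 0) + 1
        conditions.add(psm.condition)
        for acc in psm.accessions:
            flag = bool(psm.is_decoy_map[acc])
            if decoy_flags.setdefault(acc, flag) != flag:
                raise MalformedInputError(
                    f"accession {acc!r} has inconsistent decoy flags"
                )
    return PeptideProteinGraph(
        peptide_to_proteins={p: frozenset(a) for p, a in pep_prot.items()},
        peptide_counts=pep_counts,
        decoy_flags=decoy_flags,
        conditions=tuple(sorted(conditions)),
        descriptions=dict(descriptions or {}),
    )


@dataclass
class PreGroup:
    """Accessions sharing identical distinct-peptide evidence."""

    representative: str
    members: frozenset[str]
    peptides: frozenset[str]


def collapse_indistinguishable(graph: PeptideProteinGraph) -> list[PreGroup]:
    """Merge accessions whose distinct-peptide sets are identical.

    Proteins indistinguishable by their identified peptides are reported as
    one group under the lexicographically smallest accession.
    """
    by_evidence: dict[frozenset[str], set[str]] = {}
    for acc, peptides in graph.protein_to_peptides().items():
        by_evidence.setdefault(peptides, set()).add(acc)
    groups = [
        PreGroup(
            representative=min(members),
            members=frozenset(members),
            peptides=peptides,
        )
        for peptides, members in by_evidence.items()
    ]
    groups.sort(key=lambda g: g.representative)
    return groups


#: Components with at most this many candidate groups are solved exactly.
EXACT_COMPONENT_LIMIT = 16


def parsimony_cover(
    pre_groups: Sequence[PreGroup],
    graph: PeptideProteinGraph,
    condition_a: Optional[str] = None,
    condition_b: Optional[str] = None,
    exact_limit: int = EXACT_COMPONENT_LIMIT,
) -> list[ProteinGroup]:
    """Minimal set cover of peptides by protein groups.

    The peptide-protein graph decomposes into connected components (in
    practice small, since most proteins carry private peptides). Each
    component with at most ``exact_limit`` candidate groups is solved by
    exhaustive minimal cover — so the reported list is provably minimal
    there — with ties among minimal covers broken by larger total spectral
    count, then lexicographically smallest representatives. Larger
    components fall back to greedy selection (most uncovered peptides
    first, same tie-breaks). Groups whose peptides end up fully covered by
    selected groups are discarded (subsumed proteins). Every peptide's
    per-condition spectral counts are credited in full to every selected
    group containing it.
    """
    if condition_a is None or condition_b is None:
        condition_a, condition_b = _resolve_conditions(
            graph.conditions, condition_a, condition_b
        )

    totals = {
        g.representative: sum(graph.peptide_total(p) for p in g.peptides)
        for g in pre_groups
    }
    selected: list[PreGroup] = []
    for component in _connected_components(pre_groups):
        if len(component) <= exact_limit:
            selected.extend(_exact_component_cover(component, totals))
        else:
            selected.extend(_greedy_component_cover(component, totals))

    result = []
    for g in selected:
        count_a = sum(
            graph.peptide_counts.get(p, {}).get(condition_a, 0) for p in g.peptides
        )
        count_b = sum(
            graph.peptide_counts.get(p, {}).get(condition_b, 0) for p in g.peptides
        )
        result.append(
            ProteinGroup(
                representative=g.representative,
                members=g.members,
                peptides=g.peptides,
                count_A=count_a,
                count_B=count_b,
                is_decoy=all(graph.decoy_flags.get(m, False) for m in g.members),
                description=graph.descriptions.get(g.representative, ""),
            )
        )
    result.sort(key=lambda g: g.representative)
    return result


def _connected_components(pre_groups: Sequence[PreGroup]) -> list[list[PreGroup]]:
    """Partition groups into components connected by shared peptides."""
    by_peptide: dict[str, list[int]] = {}
    for i, g in enumerate(pre_groups):
        for p in g.peptides:
            by_peptide.setdefault(p, []).append(i)
    parent = list(range(len(pre_groups)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for indices in by_peptide.values():
        root = find(indices[0])
        for i in indices[1:]:
            parent[find(i)] = root
    components: dict[int, list[PreGroup]] = {}
    for i, g in enumerate(pre_groups):
        components.setdefault(find(i), []).append(g)
    # deterministic order: by smallest representative in each component
    ordered = sorted(components.values(), key=lambda c: min(g.representative for g in c))
    for component in ordered:
        component.sort(key=lambda g: g.representative)
    return ordered


def _exact_component_cover(
    component: list[PreGroup], totals: dict[str, int]
) -> list[PreGroup]:
    """Exhaustive minimal cover of one component (deterministic tie-break)."""
    peptides = sorted(set().union(*(g.peptides for g in component)))
    pep_index = {p: i for i, p in enumerate(peptides)}
    full = (1 << len(peptides)) - 1
    masks = []
    for g in component:
        mask = 0
        for p in g.peptides:
            mask |= 1 << pep_index[p]
        masks.append(mask)
    for size in range(1, len(component) + 1):
        best: Optional[tuple[int, tuple[str, ...], tuple[int, ...]]] = None
        for combo in itertools.combinations(range(len(component)), size):
            covered = 0
            for i in combo:
                covered |= masks[i]
            if covered != full:
                continue
            key = (
                -sum(totals[component[i].representative] for i in combo),
                tuple(component[i].representative for i in combo),
                combo,
            )
            if best is None or key < best:
                best = key
        if best is not None:
            return [component[i] for i in best[2]]
    raise AssertionError("component has no cover")  # pragma: no cover


def _greedy_component_cover(
    component: list[PreGroup], totals: dict[str, int]
) -> list[PreGroup]:
    """Lazy-heap greedy cover: coverage gain only shrinks as peptides get
    covered, so a popped entry with a stale gain can be re-pushed without
    breaking greedy order."""
    uncovered: set[str] = set().union(*(g.peptides for g in component))
    by_rep = {g.representative: g for g in component}
    heap: list[tuple[int, int, str, int]] = []
    for g in component:
        heapq.heappush(
            heap,
            (-len(g.peptides), -totals[g.representative], g.representative,
             len(g.peptides)),
        )
    selected: list[PreGroup] = []
    while uncovered and heap:
        _, neg_total, rep, stamped_gain = heapq.heappop(heap)
        group = by_rep[rep]
        gain = len(group.peptides & uncovered)
        if gain == 0:
            continue
        if gain != stamped_gain:
            heapq.heappush(heap, (-gain, neg_total, rep, gain))
            continue
        selected.append(group)
        uncovered -= group.peptides
    return selected


def _resolve_conditions(
    observed: tuple[str, ...],
    condition_a: Optional[str],
    condition_b: Optional[str],
) -> tuple[str, str]:
    if condition_a is not None and condition_b is not None:
        return condition_a, condition_b
    if len(observed) > 2:
        raise MalformedInputError(
            f"more than two condition labels present: {observed}"
        )
    labels = list(observed) + ["", ""]
    return labels[0], labels[1]


def apply_min_peptides(
    groups: Sequence[ProteinGroup], min_distinct: int = 2
) -> list[ProteinGroup]:
    """Keep only groups identified by at least ``min_distinct`` peptides."""
    if min_distinct < 1:
        raise ValueError("min_distinct must be >= 1")
    return [g for g in groups if g.n_peptides >= min_distinct]


def compute_fdr(
    groups: Sequence[ProteinGroup], max_fdr_percent: float = 5.0
) -> IdentificationSummary:
    """Protein-level FDR by the target-decoy doubling rule.

    FDR% = 100 · 2·D / T, where D is the number of decoy groups and T the
    total number of groups: a decoy hit implies an equally likely false
    target hit, so the decoy count is doubled. The reported value is rounded
    half-up to two decimals; the threshold check uses full precision.
    """
    total = len(groups)
    n_decoy = sum(1 for g in groups if g.is_decoy)
    if total == 0:
        logger.warning("computing FDR of an empty identification list")
        raw = 0.0
    else:
        raw = 100.0 * 2.0 * n_decoy / total
    return IdentificationSummary(
        n_total_groups=total,
        n_decoy_groups=n_decoy,
        fdr_percent=round_half_up(raw, 2),
        fdr_percent_raw=raw,
        n_after_decoy_removal=total - n_decoy,
        max_fdr_percent=max_fdr_percent,
        exceeds_max=raw > max_fdr_percent,
    )


def remove_decoys(groups: Sequence[ProteinGroup]) -> list[ProteinGroup]:
    """Drop decoy groups from the identification list."""
    return [g for g in groups if not g.is_decoy]


def assemble(
    psms: Iterable[PSMRecord],
    min_distinct_peptides: int = 2,
    max_fdr_percent: float = 5.0,
    condition_a: Optional[str] = None,
    condition_b: Optional[str] = None,
    descriptions: Optional[dict[str, str]] = None,
) -> tuple[list[ProteinGroup], IdentificationSummary]:
    """Full assembly: graph → collapse → parsimony → filters → FDR.

    Returns the group list *with decoys still present* alongside the
    identification summary; call :func:`remove_decoys` (or use the pipeline)
    for the target-only list.
    """
    graph = build_peptide_protein_graph(psms, descriptions=descriptions)
    pre_groups = collapse_indistinguishable(graph)
    groups = parsimony_cover(pre_groups, graph, condition_a, condition_b)
    n_before = len(groups)
    groups = apply_min_peptides(groups, min_distinct_peptides)
    logger.info(
        "assembly: %d pre-groups -> %d covered -> %d with >=%d peptides",
        len(pre_groups), n_before, len(groups), min_distinct_peptides,
    )
    summary = compute_fdr(groups, max_fdr_percent)
    return groups, summary
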