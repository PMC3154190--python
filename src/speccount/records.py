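"""Core record types shared across the pipeline stages.

The pipeline moves through three in-memory currencies:

* :class:`PSMRecord` — one identified spectrum, linking a peptide sequence to
  the candidate proteins it matches under one of two condition labels.
* :class:`ProteinGroup` — a parsimony-resolved protein identification with its
  distinct-peptide evidence and per-condition spectral counts.
* :class:`FoldChangeRecord` — per-protein quantitation used by the
  differential-abundance and enrichment stages.

All types are plain frozen-ish dataclasses; table I/O lives in
:mod:`speccount.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .exceptions import MalformedInputError

#: Class labels for the presence partition of a two-condition comparison.
EXCLUSIVE_A = "exclusive_A"
EXCLUSIVE_B = "exclusive_B"
SHARED = "shared"

#: Change-class labels for shared proteins.
INCREASED = "increased"
DECREASED = "decreased"
UNCHANGED = "unchanged"
NOT_APPLICABLE = "not_applicable"

#: Prefix marking reversed-decoy accessions.
DECOY_PREFIX = "REV_"


@dataclass
class PSMRecord:
    """One peptide-spectrum match.

    Parameters
    ----------
    spectrum_id:
        Opaque identifier, unique within a condition.
    peptide:
        Upper-case amino-acid sequence (at least one residue).
    accessions:
        Non-empty set of candidate protein accessions for this peptide.
    condition:
        Condition label (e.g. ``"67NR"`` or ``"4T1"``).
    is_decoy_map:
        Per-accession decoy flag; must cover every accession.
    """

    spectrum_id: str
    peptide: str
    accessions: frozenset[str]
    condition: str
    is_decoy_map: Mapping[str, bool]

    def __post_init__(self) -> None:
        self.accessions = frozenset(self.accessions)
        if not self.peptide:
            raise MalformedInputError(
                f"PSM {self.spectrum_id!r}: empty peptide sequence"
            )
        if not self.accessions:
            raise MalformedInputError(
                f"PSM {self.spectrum_id!r}: no matched accessions"
            )
        missing = self.accessions - set(self.is_decoy_map)
        if missing:
            raise MalformedInputError(
                f"PSM {self.spectrum_id!r}: missing decoy flag for "
                f"{sorted(missing)}"
            )


@dataclass
class ProteinGroup:
    """A parsimony-resolved protein group with its spectral-count evidence.

    ``members`` share identical distinct-peptide evidence and are reported
    under the lexicographically smallest accession. A group is a decoy iff
    *all* members are decoys; mixed groups count as targets.
    """

    representative: str
    members: frozenset[str]
    peptides: frozenset[str]
    count_A: int
    count_B: int
    is_decoy: bool
    description: str = ""

    @property
    def total(self) -> int:
        return self.count_A + self.count_B

    @property
    def n_peptides(self) -> int:
        return len(self.peptides)

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        self.peptides = frozenset(self.peptides)
        if not self.members:
            raise MalformedInputError("protein group with no members")
        if self.representative not in self.members:
            raise MalformedInputError(
                f"representative {self.representative!r} not among members"
            )
        if self.count_A < 0 or self.count_B < 0:
            raise MalformedInputError(
                f"group {self.representative!r}: negative spectral count"
            )


@dataclass
class IdentificationSummary:
    """Target-decoy bookkeeping for an assembled identification list.

    ``fdr_percent`` is the reported value, rounded half-up to two decimals;
    ``fdr_percent_raw`` keeps full precision (used for threshold checks).
    """

    n_total_groups: int
    n_decoy_groups: int
    fdr_percent: float
    fdr_percent_raw: float
    n_after_decoy_removal: int
    max_fdr_percent: float
    exceeds_max: bool

    def __post_init__(self) -> None:
        assert self.n_decoy_groups <= self.n_total_groups
        assert (
            self.n_after_decoy_removal
            == self.n_total_groups - self.n_decoy_groups
        )
        assert self.fdr_percent >= 0.0


@dataclass
class FoldChangeRecord:
    """Per-protein two-condition quantitation.

    ``log2fc`` is defined only for shared proteins (both counts positive);
    exclusive proteins carry ``None`` and change class ``not_applicable``.
    """

    accession: str
    description: str
    count_A: int
    count_B: int
    presence_class: str = ""
    log2fc: Optional[float] = None
    change_class: str = NOT_APPLICABLE
    in_window: bool = True
    family_excluded: bool = False

    @property
    def total(self) -> int:
        return self.count_A + self.count_B

    @property
    def is_shared(self) -> bool:
        return self.count_A > 0 and self.count_B > 0


@dataclass
class ThresholdPair:
    """Mean ± 1 SD significance cutoffs on the shared log2 fold changes.

    Stored at full precision so that ``upper - mean == mean - lower == sd``
    holds exactly; rounding (half-up, 3 decimals) happens at reporting time.
    """

    mean_fc: float
    sd_fc: float

    @property
    def lower(self) -> float:
        return self.mean_fc - self.sd_fc

    @property
    def upper(self) -> float:
        return self.mean_fc + self.sd_fc

    def __post_init__(self) -> None:
        if self.sd_fc < 0:
            raise ValueError("standard deviation must be non-negative")


@dataclass
class LoadingSummary:
    """Per-condition total spectra and their coefficient of variance."""

    total_A: int
    total_B: int
    cv_percent: float
    cv_percent_raw: float


@dataclass
class AnnotationSet:
    """Category → members mapping over a stated reference universe.

    The universe is the identifier space against which over-representation is
    judged (the stand-in for "the genome"); ``universe_size`` may exceed the
    number of annotated identifiers to model unannotated background genes.
    """

    categories: dict[str, frozenset[str]]
    universe: frozenset[str]
    category_names: dict[str, str] = field(default_factory=dict)
    universe_size: Optional[int] = None

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe)
        self.categories = {
            cid: frozenset(members) for cid, members in self.categories.items()
        }
        if self.universe_size is None:
            self.universe_size = len(self.universe)
        for cid, members in self.categories.items():
            if not members:
                raise MalformedInputError(f"category {cid!r} is empty")
            if len(members) > self.universe_size:
                raise MalformedInputError(
                    f"category {cid!r} larger than the universe"
                )

    def name_of(self, category_id: str) -> str:
        return self.category_names.get(category_id, category_id)


@dataclass
class EnrichmentResult:
    """Over-representation statistics for one category in one sample."""

    category_id: str
    name: str
    k: int
    n: int
    K: int
    N: int
    expected: float
    ratio: float
    p_value: float
    p_adjusted: float = float("nan")
    significant: bool = False
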