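"""Readers and writers for the pipeline's plain-text interchange formats.

All tables are UTF-8, tab-separated with a header row and LF line endings:

* PSM table: ``spectrum_id  peptide  accessions  condition  decoy_flags``
  with accessions semicolon-joined and decoy flags semicolon-joined 0/1 in
  the same order.
* Protein-group report: ``representative  members  n_peptides  count_A
  count_B  total  is_decoy  description``.
* Fold-change table: one row per protein with counts, log2fc, presence and
  change classes and filter flags; thresholds/loading go to a JSON sidecar.
* Annotation: either long-form TSV (``category_id  category_name
  member_id``) or GMT (``category<TAB>description<TAB>member...``).
* Enrichment report: one row per category with k, n, K, N, expected,
  ratio, p, adjusted p, significance.

FASTA goes through Biopython.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import MalformedInputError
from .records import (
    AnnotationSet,
    EnrichmentResult,
    FoldChangeRecord,
    LoadingSummary,
    ProteinGroup,
    PSMRecord,
    ThresholdPair,
)
from ._rounding import round_half_up

PathLike = Union[str, Path]

PSM_COLUMNS = ["spectrum_id", "peptide", "accessions", "condition", "decoy_flags"]
GROUP_COLUMNS = [
    "representative", "members", "n_peptides",
    "count_A", "count_B", "total", "is_decoy", "description",
]
FOLDCHANGE_COLUMNS = [
    "accession", "description", "count_A", "count_B", "total",
    "log2fc", "presence_class", "change_class", "in_window", "family_excluded",
]
ENRICHMENT_COLUMNS = [
    "category_id", "name", "k", "n", "K", "N",
    "expected", "ratio", "p_value", "p_adjusted", "significant",
]


# ---------------------------------------------------------------------------
# PSM tables

def write_psm_table(psms: Iterable[PSMRecord], path: PathLike) -> None:
    rows = []
    for psm in psms:
        accs = sorted(psm.accessions)
        rows.append(
            {
                "spectrum_id": psm.spectrum_id,
                "peptide": psm.peptide,
                "accessions": ";".join(accs),
                "condition": psm.condition,
                "decoy_flags": ";".join(
                    "1" if psm.is_decoy_map[a] else "0" for a in accs
                ),
            }
        )
    pd.DataFrame(rows, columns=PSM_COLUMNS).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_psm_table(path: PathLike) -> list[PSMRecord]:
    df = _read_tsv(path, PSM_COLUMNS)
    psms = []
    for row in df.itertuples(index=False):
        accs = str(row.accessions).split(";")
        flags = str(row.decoy_flags).split(";")
        if len(accs) != len(flags):
            raise MalformedInputError(
                f"{path}: accession/decoy-flag arity mismatch for "
                f"spectrum {row.spectrum_id!r}"
            )
        psms.append(
            PSMRecord(
                spectrum_id=str(row.spectrum_id),
                peptide=str(row.peptide),
                accessions=frozenset(accs),
                condition=str(row.condition),
                is_decoy_map={a: f == "1" for a, f in zip(accs, flags)},
            )
        )
    return psms


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(
    records: Sequence[tuple[str, str]],
    path: PathLike,
    descriptions: Optional[dict[str, str]] = None,
) -> None:
    descriptions = descriptions or {}
    seq_records = [
        SeqRecord(Seq(seq), id=acc, description=descriptions.get(acc, ""))
        for acc, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path: PathLike) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_fasta_descriptions(path: PathLike) -> dict[str, str]:
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        out[rec.id] = desc
    return out


# ---------------------------------------------------------------------------
# Protein groups

def write_protein_groups(groups: Iterable[ProteinGroup], path: PathLike) -> None:
    rows = [
        {
            "representative": g.representative,
            "members": ";".join(sorted(g.members)),
            "n_peptides": g.n_peptides,
            "count_A": g.count_A,
            "count_B": g.count_B,
            "total": g.total,
            "is_decoy": int(g.is_decoy),
            "description": g.description,
        }
        for g in groups
    ]
    pd.DataFrame(rows, columns=GROUP_COLUMNS).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_protein_groups(path: PathLike) -> list[ProteinGroup]:
    df = _read_tsv(path, GROUP_COLUMNS[:-1])  # description optional
    groups = []
    for row in df.itertuples(index=False):
        groups.append(
            ProteinGroup(
                representative=str(row.representative),
                members=frozenset(str(row.members).split(";")),
                # peptide identities are not persisted in the report; keep
                # the arity so n_peptides survives a round trip
                peptides=frozenset(
                    f"peptide_{i}" for i in range(int(row.n_peptides))
                ),
                count_A=int(row.count_A),
                count_B=int(row.count_B),
                is_decoy=bool(int(row.is_decoy)),
                description=str(getattr(row, "description", ""))
                if not pd.isna(getattr(row, "description", ""))
                else "",
            )
        )
    return groups


# ---------------------------------------------------------------------------
# Fold-change table and sidecar

def write_fold_changes(
    records: Iterable[FoldChangeRecord], path: PathLike
) -> None:
    rows = [
        {
            "accession": r.accession,
            "description": r.description,
            "count_A": r.count_A,
            "count_B": r.count_B,
            "total": r.total,
            "log2fc": "" if r.log2fc is None else repr(r.log2fc),
            "presence_class": r.presence_class,
            "change_class": r.change_class,
            "in_window": int(r.in_window),
            "family_excluded": int(r.family_excluded),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=FOLDCHANGE_COLUMNS).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_fold_changes(path: PathLike) -> list[FoldChangeRecord]:
    df = _read_tsv(path, FOLDCHANGE_COLUMNS)
    out = []
    for row in df.itertuples(index=False):
        log2fc = None if pd.isna(row.log2fc) or row.log2fc == "" else float(row.log2fc)
        out.append(
            FoldChangeRecord(
                accession=str(row.accession),
                description="" if pd.isna(row.description) else str(row.description),
                count_A=int(row.count_A),
                count_B=int(row.count_B),
                presence_class=str(row.presence_class),
                log2fc=log2fc,
                change_class=str(row.change_class),
                in_window=bool(int(row.in_window)),
                family_excluded=bool(int(row.family_excluded)),
            )
        )
    return out


def write_quant_sidecar(
    thresholds: ThresholdPair,
    loading: LoadingSummary,
    partition: dict[str, int],
    path: PathLike,
) -> None:
    payload = {
        "fold_change": {
            "mean": thresholds.mean_fc,
            "sd": thresholds.sd_fc,
            "lower": thresholds.lower,
            "upper": thresholds.upper,
            "lower_reported": round_half_up(thresholds.lower, 3),
            "upper_reported": round_half_up(thresholds.upper, 3),
        },
        "loading": {
            "total_A": loading.total_A,
            "total_B": loading.total_B,
            "cv_percent": loading.cv_percent,
        },
        "presence_partition": dict(partition),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# Annotations

def read_annotation(
    path: PathLike, universe_size: Optional[int] = None
) -> AnnotationSet:
    """Read a long-form annotation TSV or a GMT file (sniffed by header)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.rstrip("\n").split("\t")[:3] == ["category_id", "category_name", "member_id"]:
        return _read_annotation_tsv(path, universe_size)
    return _read_annotation_gmt(path, universe_size)


def _read_annotation_tsv(
    path: Path, universe_size: Optional[int]
) -> AnnotationSet:
    df = _read_tsv(path, ["category_id", "category_name", "member_id"])
    categories: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for row in df.itertuples(index=False):
        cid = str(row.category_id)
        categories.setdefault(cid, set()).add(str(row.member_id))
        names[cid] = str(row.category_name)
    return _make_annotation(categories, names, universe_size)


def _read_annotation_gmt(
    path: Path, universe_size: Optional[int]
) -> AnnotationSet:
    categories: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise MalformedInputError(
                f"{path}: GMT line needs category, description and >=1 member"
            )
        cid, desc, *members = fields
        categories[cid] = set(members)
        names[cid] = desc
    return _make_annotation(categories, names, universe_size)


def _make_annotation(
    categories: dict[str, set[str]],
    names: dict[str, str],
    universe_size: Optional[int],
) -> AnnotationSet:
    universe: set[str] = set().union(*categories.values()) if categories else set()
    return AnnotationSet(
        categories={c: frozenset(m) for c, m in categories.items()},
        universe=frozenset(universe),
        category_names=names,
        universe_size=universe_size,
    )


def write_annotation(annotation: AnnotationSet, path: PathLike) -> None:
    rows = []
    for cid in sorted(annotation.categories):
        for member in sorted(annotation.categories[cid]):
            rows.append(
                {
                    "category_id": cid,
                    "category_name": annotation.name_of(cid),
                    "member_id": member,
                }
            )
    pd.DataFrame(rows, columns=["category_id", "category_name", "member_id"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# Enrichment reports

def write_enrichment_report(
    results: Iterable[EnrichmentResult], path: PathLike
) -> None:
    rows = [
        {
            "category_id": r.category_id,
            "name": r.name,
            "k": r.k,
            "n": r.n,
            "K": r.K,
            "N": r.N,
            "expected": repr(r.expected),
            "ratio": repr(r.ratio),
            "p_value": repr(r.p_value),
            "p_adjusted": repr(r.p_adjusted),
            "significant": int(r.significant),
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_enrichment_report(path: PathLike) -> pd.DataFrame:
    return _read_tsv(path, ENRICHMENT_COLUMNS)


# ---------------------------------------------------------------------------

def _read_tsv(path: PathLike, required_columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                         na_values=[])
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise MalformedInputError(f"{path}: not a readable TSV: {exc}") from exc
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise MalformedInputError(f"{path}: missing column(s) {missing}")
    return df
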