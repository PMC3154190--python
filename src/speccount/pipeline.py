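"""End-to-end orchestration: assembly → quantitation → enrichment.

:func:`run_full_pipeline` chains every stage on file inputs, writes all
stage outputs (TSV/JSON) plus a run manifest with parameters, version,
seed and input checksums, and returns the in-memory results. The summary
report prints the headline numbers of a run: identification totals and
FDR, presence partition, fold-change cutoffs, changed counts, loading CV,
and the top enriched categories per analytical group.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

from ._version import __version__
from ._rounding import round_half_up
from .abundance import DEFAULT_EXCLUDED_FAMILIES, quantify
from .assembly import assemble, remove_decoys
from .enrichment import enrich
from .exceptions import FdrExceededError
from .records import (
    DECREASED,
    EXCLUSIVE_A,
    EXCLUSIVE_B,
    INCREASED,
    SHARED,
    AnnotationSet,
    EnrichmentResult,
    FoldChangeRecord,
    IdentificationSummary,
    LoadingSummary,
    ProteinGroup,
    ThresholdPair,
)
from . import io as sio

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_full_pipeline", "summary_report",
           "changed_percent"]

#: Analytical group labels in reporting order.
GROUP_ORDER = (EXCLUSIVE_A, DECREASED, INCREASED, EXCLUSIVE_B)


@dataclass
class PipelineConfig:
    """All knobs of a full run; defaults follow the standard workflow."""

    psm_path: Union[str, Path, None] = None
    fasta_path: Union[str, Path, None] = None
    annotation_path: Union[str, Path, None] = None
    out_dir: Union[str, Path] = "speccount_out"
    condition_a: str = "67NR"
    condition_b: str = "4T1"
    min_distinct_peptides: int = 2
    max_fdr_percent: float = 5.0
    fail_on_fdr: bool = False
    window: tuple[int, int] = (25, 300)
    exclusion_patterns: tuple[str, ...] = DEFAULT_EXCLUDED_FAMILIES
    alpha: float = 0.05
    min_category_k: int = 2
    universe_size: Optional[int] = None
    seed: int = 0

    def validate(self) -> None:
        if self.min_distinct_peptides < 1:
            raise ValueError("min_distinct_peptides must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.window[0] > self.window[1]:
            raise ValueError("abundance window is inverted")
        if self.max_fdr_percent < 0:
            raise ValueError("max_fdr_percent must be non-negative")


@dataclass
class PipelineResult:
    groups_with_decoys: list[ProteinGroup]
    identification: IdentificationSummary
    groups: list[ProteinGroup]
    records: list[FoldChangeRecord]
    partition: dict[str, int]
    thresholds: ThresholdPair
    loading: LoadingSummary
    analytical_groups: dict[str, list[FoldChangeRecord]]
    enrichment: dict[str, list[EnrichmentResult]] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    @property
    def n_changed(self) -> int:
        return sum(
            1 for r in self.records if r.change_class in (INCREASED, DECREASED)
        )


def changed_percent(n_changed: int, n_identified: int) -> float:
    """Share of the identified proteome flagged as changed, in percent."""
    if n_identified <= 0:
        raise ValueError("n_identified must be positive")
    return 100.0 * n_changed / n_identified


def run_full_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage on the configured inputs and write all outputs."""
    config.validate()
    psm_path = Path(config.psm_path) if config.psm_path else None
    if psm_path is None or not psm_path.exists():
        raise FileNotFoundError(f"PSM table not found: {config.psm_path}")

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    psms = sio.read_psm_table(psm_path)
    descriptions = (
        sio.read_fasta_descriptions(config.fasta_path)
        if config.fasta_path
        else None
    )
    logger.info("assembly: %d PSMs in", len(psms))
    groups_all, ident = assemble(
        psms,
        min_distinct_peptides=config.min_distinct_peptides,
        max_fdr_percent=config.max_fdr_percent,
        condition_a=config.condition_a,
        condition_b=config.condition_b,
        descriptions=descriptions,
    )
    logger.info(
        "assembly: %d groups out (%d decoys, FDR %.2f%%)",
        ident.n_total_groups, ident.n_decoy_groups, ident.fdr_percent,
    )
    if ident.exceeds_max and config.fail_on_fdr:
        raise FdrExceededError(
            f"identification FDR {ident.fdr_percent:.2f}% exceeds the "
            f"configured maximum {config.max_fdr_percent:.2f}%"
        )
    groups = remove_decoys(groups_all)
    logger.info("decoy removal: %d groups in, %d out", len(groups_all), len(groups))

    records, partition, thresholds, loading, analytical = quantify(
        groups,
        window=config.window,
        excluded_families=config.exclusion_patterns,
    )
    assert sum(partition.values()) == len(groups)
    logger.info(
        "partition: %d exclusive_A / %d shared / %d exclusive_B",
        partition[EXCLUSIVE_A], partition[SHARED], partition[EXCLUSIVE_B],
    )

    result = PipelineResult(
        groups_with_decoys=groups_all,
        identification=ident,
        groups=groups,
        records=records,
        partition=partition,
        thresholds=thresholds,
        loading=loading,
        analytical_groups=analytical,
    )

    annotation: Optional[AnnotationSet] = None
    if config.annotation_path:
        annotation = sio.read_annotation(
            config.annotation_path, universe_size=config.universe_size
        )
        for label in GROUP_ORDER:
            sample = [r.accession for r in analytical[label]]
            if not any(s in annotation.universe for s in sample):
                if sample:
                    logger.warning(
                        "enrichment[%s]: no sample identifier in the "
                        "annotation universe; skipping", label,
                    )
                result.enrichment[label] = []
                continue
            result.enrichment[label] = enrich(
                sample, annotation, alpha=config.alpha, min_k=config.min_category_k
            )
            logger.info(
                "enrichment[%s]: %d categories, %d significant",
                label, len(result.enrichment[label]),
                sum(r.significant for r in result.enrichment[label]),
            )

    _write_outputs(config, result, out_dir)
    return result


def _write_outputs(
    config: PipelineConfig, result: PipelineResult, out_dir: Path
) -> None:
    sio.write_protein_groups(result.groups_with_decoys, out_dir / "protein_groups.tsv")
    sio.write_fold_changes(result.records, out_dir / "fold_changes.tsv")
    sio.write_quant_sidecar(
        result.thresholds, result.loading, result.partition,
        out_dir / "quantitation.json",
    )
    ident = result.identification
    (out_dir / "identification.json").write_text(
        json.dumps(
            {
                "n_total_groups": ident.n_total_groups,
                "n_decoy_groups": ident.n_decoy_groups,
                "fdr_percent": ident.fdr_percent,
                "n_after_decoy_removal": ident.n_after_decoy_removal,
                "max_fdr_percent": ident.max_fdr_percent,
                "exceeds_max": ident.exceeds_max,
            },
            indent=2,
        )
        + "\n"
    )
    for label, recs in result.analytical_groups.items():
        (out_dir / f"group_{label}.txt").write_text(
            "".join(f"{r.accession}\n" for r in recs)
        )
    for label, results in result.enrichment.items():
        sio.write_enrichment_report(results, out_dir / f"enrichment_{label}.tsv")
    result.manifest = _build_manifest(config, result)
    (out_dir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True) + "\n"
    )
    (out_dir / "summary.txt").write_text(summary_report(result) + "\n")


def _build_manifest(config: PipelineConfig, result: PipelineResult) -> dict:
    params = asdict(config)
    for key in ("psm_path", "fasta_path", "annotation_path", "out_dir"):
        if params[key] is not None:
            params[key] = str(params[key])
    checksums = {}
    for key in ("psm_path", "fasta_path", "annotation_path"):
        value = getattr(config, key)
        if value and Path(value).exists():
            checksums[key] = hashlib.sha256(Path(value).read_bytes()).hexdigest()
    return {
        "package": "speccount",
        "version": __version__,
        "seed": config.seed,
        "parameters": params,
        "input_sha256": checksums,
        "counts": {
            "n_total_groups": result.identification.n_total_groups,
            "n_after_decoy_removal": result.identification.n_after_decoy_removal,
            "partition": result.partition,
            "analytical_groups": {
                label: len(recs)
                for label, recs in result.analytical_groups.items()
            },
        },
    }


def summary_report(result: PipelineResult, top: int = 5) -> str:
    """Human-readable run summary; every number mirrors a stage output."""
    ident = result.identification
    part = result.partition
    lines = [
        "== identification ==",
        f"protein groups: {ident.n_total_groups} "
        f"(decoys: {ident.n_decoy_groups})",
        f"FDR {ident.fdr_percent:.2f}% (max {ident.max_fdr_percent:.2f}%)",
        f"after decoy removal: {ident.n_after_decoy_removal}",
        "== presence partition ==",
        f"{EXCLUSIVE_A}: {part[EXCLUSIVE_A]}  shared: {part[SHARED]}  "
        f"{EXCLUSIVE_B}: {part[EXCLUSIVE_B]}",
        f"partition sums to identifications: "
        f"{sum(part.values()) == ident.n_after_decoy_removal}",
        "== fold change ==",
        f"mean {result.thresholds.mean_fc:.3f}  SD {result.thresholds.sd_fc:.3f}",
        f"cutoffs: < {round_half_up(result.thresholds.lower, 3):.3f} "
        f"or > {round_half_up(result.thresholds.upper, 3):.3f}",
        f"changed: {result.n_changed} of {ident.n_after_decoy_removal} "
        f"({round_half_up(changed_percent(result.n_changed, ident.n_after_decoy_removal)):.0f}%)",
        "== loading ==",
        f"total spectra: {result.loading.total_A} vs {result.loading.total_B} "
        f"(CV {result.loading.cv_percent:.2f}%)",
        "== analytical groups ==",
    ]
    for label in GROUP_ORDER:
        lines.append(f"{label}: {len(result.analytical_groups[label])} proteins")
    if result.enrichment:
        lines.append("== enrichment (top categories by ratio) ==")
        for label in GROUP_ORDER:
            results = result.enrichment.get(label, [])
            significant = [r for r in results if r.significant]
            if not significant:
                lines.append(f"[{label}] no significant categories")
                continue
            for r in significant[:top]:
                lines.append(
                    f"[{label}] {r.name}: ratio {r.ratio:.2f} "
                    f"(k={r.k}, adj p={r.p_adjusted:.3g})"
                )
    return "\n".join(lines)
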