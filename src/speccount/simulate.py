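"""Synthetic PSM tables, protein databases, and annotation sets.

The generator emulates the statistical structure of a two-condition
label-free spectral-counting experiment so that assembly, quantitation and
enrichment can be exercised end to end with known ground truth:

* two conditions with near-equal total spectra (loading CV ≈ 1%),
* per-protein expected counts drawn log-normally, with realized totals
  spanning roughly 2 up to the low thousands,
* a presence structure with small exclusive fractions on either side,
* a shared-protein log2 fold-change distribution with non-zero mean and
  unit-scale SD, made of biological scatter plus Poisson counting noise,
* planted differential proteins at a configurable log2 effect,
* a small reversed-decoy contamination,
* occasional peptide sharing between proteins (creating indistinguishable
  and subsumable cases for the parsimony stage).

Counts are Poisson draws around the per-condition expectations; shared
proteins are clamped to at least one spectrum per condition and every
protein receives at least two distinct observed peptides, so the emitted
PSM table is always consistent with the declared ground truth (consistency
is checked on every emission).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .records import AnnotationSet, DECOY_PREFIX, PSMRecord

__all__ = [
    "SimulationConfig",
    "SimulatedProtein",
    "GroundTruth",
    "PlantedCategory",
    "simulate_proteome",
    "simulate_psm_table",
    "simulate_annotation",
    "write_ground_truth",
]

_RESIDUES = np.array(list("ACDEFGHILMNPQSTVWY"))  # body residues; K/R terminal


@dataclass
class SimulationConfig:
    """Generator settings; the defaults are the package's study conditions.

    Abundance: per-condition expected spectra are LogNormal(3.0, 1.0)
    (median ≈ 20 per condition, realized totals ranging from the clamp
    floor of 2 up to the low thousands at larger n). Biological scatter:
    null shared proteins get a log2 effect ~ Normal(0.128, 0.25); the mean
    Poisson log2-ratio noise at this abundance contributes ≈ 0.35 variance,
    so the null SD is ≈ 0.64 and, with 10% planted ±2.5 effects, the
    realized fold-change SD is ≈ 1 — the unit-scale target. Exclusive
    fractions 0.015 / 0.055 mirror a small unique-to-A cohort and a larger
    unique-to-B cohort. Loading imbalance targets a CV of 1.26e-2 between
    expected condition totals (realized CV carries Poisson jitter that
    shrinks with experiment size); since totals are dominated by abundant
    proteins, a nonzero mean log2 ratio under near-equal loading requires
    the null effects to anticorrelate slightly with abundance, which the
    generator plants (the most abundant proteins sit at or below the mean
    fold change).
    """

    n_proteins: int = 200
    n_decoy_contaminants: int = 2
    n_family_contaminants: int = 2
    peptides_per_protein: tuple[int, int] = (4, 12)
    peptide_length: tuple[int, int] = (7, 25)
    peptide_sharing_prob: float = 0.02
    abundance_log_mean: float = 3.0
    abundance_log_sigma: float = 1.0
    frac_exclusive_A: float = 0.015
    frac_exclusive_B: float = 0.055
    frac_differential: float = 0.10
    effect_size_log2: float = 2.5
    baseline_log2fc_mean: float = 0.128
    baseline_log2fc_sd: float = 0.25
    loading_imbalance_cv: float = 0.0126
    condition_a: str = "67NR"
    condition_b: str = "4T1"
    # annotation generation
    n_background_ids: int = 800
    n_categories: int = 20
    category_size_range: tuple[int, int] = (10, 80)
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        for name in ("frac_exclusive_A", "frac_exclusive_B", "frac_differential",
                     "peptide_sharing_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.frac_exclusive_A + self.frac_exclusive_B > 1.0:
            raise ValueError("exclusive fractions exceed 1")
        if self.peptides_per_protein[0] < 2:
            raise ValueError("each protein needs at least 2 peptides")
        if self.loading_imbalance_cv < 0 or self.loading_imbalance_cv >= math.sqrt(2):
            raise ValueError("loading_imbalance_cv out of range")


@dataclass
class SimulatedProtein:
    accession: str
    description: str
    peptides: list[str]

    @property
    def sequence(self) -> str:
        return "".join(self.peptides)


@dataclass
class GroundTruth:
    """Per-protein truth for the emitted PSM table.

    ``true_class`` is one of exclusive_A / exclusive_B / shared_null /
    shared_up / shared_down / decoy; ``true_log2_effect`` is the planted
    log2 B-over-A effect (NaN for exclusives and decoys). ``planted_categories``
    maps category ids to whether enrichment was planted.
    """

    true_class: dict[str, str] = field(default_factory=dict)
    true_log2_effect: dict[str, float] = field(default_factory=dict)
    planted_categories: dict[str, bool] = field(default_factory=dict)

    def of_class(self, *classes: str) -> set[str]:
        return {a for a, c in self.true_class.items() if c in classes}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "accession": acc,
                "true_class": cls,
                "true_log2_effect": self.true_log2_effect.get(acc, float("nan")),
            }
            for acc, cls in sorted(self.true_class.items())
        ]
        return pd.DataFrame(rows, columns=["accession", "true_class", "true_log2_effect"])


def write_ground_truth(truth: GroundTruth, path: Union[str, Path]) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Proteome

def simulate_proteome(config: SimulationConfig) -> list[SimulatedProtein]:
    """Random tryptic-style proteome with optional peptide sharing.

    Each protein is a concatenation of K/R-terminated random peptides.
    With probability ``peptide_sharing_prob`` a peptide is also copied into
    another protein, creating homology-like shared evidence.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_proteins
    width = max(4, len(str(n)))
    proteins = []
    for i in range(n):
        n_pep = int(rng.integers(config.peptides_per_protein[0],
                                 config.peptides_per_protein[1] + 1))
        peptides = [_random_peptide(rng, config.peptide_length) for _ in range(n_pep)]
        proteins.append(
            SimulatedProtein(
                accession=f"P{i:0{width}d}",
                description=f"Synthetic protein {i}",
                peptides=peptides,
            )
        )
    # family contaminants get recognizable descriptions
    family_names = ["Immunoglobulin heavy chain (synthetic)",
                    "Hemoglobin subunit beta (synthetic)"]
    for j in range(min(config.n_family_contaminants, n)):
        proteins[n - 1 - j].description = family_names[j % 2] + f" {j}"
    # peptide sharing: copy peptides into a second protein
    if n > 1 and config.peptide_sharing_prob > 0:
        for i, prot in enumerate(proteins):
            for pep in list(prot.peptides):
                if rng.random() < config.peptide_sharing_prob:
                    j = int(rng.integers(0, n - 1))
                    if j >= i:
                        j += 1
                    if pep not in proteins[j].peptides:
                        proteins[j].peptides.append(pep)
    return proteins


def _random_peptide(rng: np.random.Generator, length_range: tuple[int, int]) -> str:
    length = int(rng.integers(length_range[0], length_range[1] + 1))
    body = "".join(rng.choice(_RESIDUES, size=length - 1))
    terminal = "K" if rng.random() < 0.5 else "R"
    return body + terminal


# ---------------------------------------------------------------------------
# PSM table

def simulate_psm_table(
    config: SimulationConfig,
    proteome: Optional[Sequence[SimulatedProtein]] = None,
) -> tuple[list[PSMRecord], GroundTruth]:
    """Emit a ground-truthed PSM table for the configured experiment."""
    config.validate()
    if proteome is None:
        proteome = simulate_proteome(config)
    rng = np.random.default_rng([config.seed, 1])
    n = len(proteome)

    # peptide ownership decides which proteins can be exclusives: a protein
    # sharing a peptide with another would inherit cross-condition spectra,
    # so exclusive classes are drawn from fully-private proteins only
    owners_precheck: dict[str, int] = {}
    for prot in proteome:
        for pep in prot.peptides:
            owners_precheck[pep] = owners_precheck.get(pep, 0) + 1
    fully_private = [
        i for i, prot in enumerate(proteome)
        if all(owners_precheck[p] == 1 for p in prot.peptides)
    ]

    # --- assign true classes
    n_a = int(round(config.frac_exclusive_A * n))
    n_b = int(round(config.frac_exclusive_B * n))
    private_order = rng.permutation(len(fully_private))
    exclusive_pool = [fully_private[int(i)] for i in private_order]
    n_a = min(n_a, len(exclusive_pool))
    n_b = min(n_b, max(0, len(exclusive_pool) - n_a))
    idx_a = set(exclusive_pool[:n_a])
    idx_b = set(exclusive_pool[n_a:n_a + n_b])
    rest = [i for i in range(n) if i not in idx_a and i not in idx_b]
    rest_order = rng.permutation(len(rest))
    shared_idx = [rest[int(i)] for i in rest_order]
    n_diff = int(round(config.frac_differential * len(shared_idx)))
    diff_idx = shared_idx[:n_diff]
    classes: dict[int, str] = {}
    effects: dict[int, float] = {}
    for pos, i in enumerate(diff_idx):
        up = pos % 2 == 0
        classes[i] = "shared_up" if up else "shared_down"
        effects[i] = config.baseline_log2fc_mean + (
            config.effect_size_log2 if up else -config.effect_size_log2
        )
    # --- per-protein base abundance (needed for the abundance tilt below)
    base = rng.lognormal(config.abundance_log_mean, config.abundance_log_sigma, size=n)

    # Null biological effects carry a small abundance anticorrelation: with
    # near-equal condition totals (dominated by abundant proteins) a nonzero
    # unweighted mean log2 ratio can only exist if abundant proteins sit at
    # or below the mean — the tilt b is chosen so the abundance-weighted
    # mean matches the loading target while the unweighted mean stays at
    # baseline_log2fc_mean. For LogNormal(mu, sigma) abundances the
    # weighted-minus-unweighted gap of log2(abundance) is sigma^2 / ln 2.
    c = config.loading_imbalance_cv
    r_target = (math.sqrt(2) - c) / (math.sqrt(2) + c)
    gap = config.abundance_log_sigma ** 2 / math.log(2)
    tilt = (
        (config.baseline_log2fc_mean - math.log2(r_target)) / gap
        if gap > 0 else 0.0
    )
    log2_base = np.log2(base)
    centered = log2_base - log2_base.mean()
    for i in shared_idx[n_diff:]:
        classes[i] = "shared_null"
        effects[i] = float(
            config.baseline_log2fc_mean
            - tilt * centered[i]
            + rng.normal(0.0, config.baseline_log2fc_sd)
        )
    for i in idx_a:
        classes[int(i)] = "exclusive_A"
    for i in idx_b:
        classes[int(i)] = "exclusive_B"

    # --- per-condition expectations
    lam_a = np.zeros(n)
    lam_b = np.zeros(n)
    for i in range(n):
        cls = classes[i]
        if cls == "exclusive_A":
            lam_a[i] = base[i]
        elif cls == "exclusive_B":
            lam_b[i] = base[i]
        else:
            e = effects[i]
            lam_a[i] = base[i] * 2.0 ** (-e / 2.0)
            lam_b[i] = base[i] * 2.0 ** (e / 2.0)

    # scale condition-B expectations so expected totals hit the target CV:
    # for two totals, CV = sqrt(2)(1-r)/(1+r) with r = total_B/total_A
    c = config.loading_imbalance_cv
    r_target = (math.sqrt(2) - c) / (math.sqrt(2) + c)
    if lam_b.sum() > 0:
        lam_b *= r_target * lam_a.sum() / lam_b.sum()

    # --- draw counts (shared clamped to >=1 per condition, exclusives >=2)
    count_a = np.zeros(n, dtype=int)
    count_b = np.zeros(n, dtype=int)
    for i in range(n):
        cls = classes[i]
        if cls == "exclusive_A":
            count_a[i] = max(2, int(rng.poisson(lam_a[i])))
        elif cls == "exclusive_B":
            count_b[i] = max(2, int(rng.poisson(lam_b[i])))
        else:
            count_a[i] = max(1, int(rng.poisson(lam_a[i])))
            count_b[i] = max(1, int(rng.poisson(lam_b[i])))

    # --- peptide -> accession map over targets (+ decoys below)
    peptide_owners: dict[str, set[str]] = {}
    for prot in proteome:
        for pep in prot.peptides:
            peptide_owners.setdefault(pep, set()).add(prot.accession)
    private: dict[str, list[str]] = {
        prot.accession: [p for p in prot.peptides if len(peptide_owners[p]) == 1]
        for prot in proteome
    }

    # --- emit PSMs
    psms: list[PSMRecord] = []
    scan_counter = {config.condition_a: 0, config.condition_b: 0}

    def emit(peptide: str, condition: str) -> None:
        scan_counter[condition] += 1
        owners = sorted(peptide_owners[peptide])
        psms.append(
            PSMRecord(
                spectrum_id=f"{condition}_{scan_counter[condition]:06d}",
                peptide=peptide,
                accessions=frozenset(owners),
                condition=condition,
                is_decoy_map={a: a.startswith(DECOY_PREFIX) for a in owners},
            )
        )

    for i, prot in enumerate(proteome):
        total = int(count_a[i] + count_b[i])
        if total == 0:
            continue
        # anchors guarantee >=2 distinct observed peptides, preferring
        # peptides private to this protein so parsimony can recover it
        pool = private[prot.accession] if len(private[prot.accession]) >= 2 else prot.peptides
        anchor_idx = rng.choice(len(pool), size=2, replace=False)
        choices = [pool[int(anchor_idx[0])], pool[int(anchor_idx[1])]]
        if total > 2:
            extra = rng.integers(0, len(prot.peptides), size=total - 2)
            choices.extend(prot.peptides[int(j)] for j in extra)
        perm = rng.permutation(total)
        shuffled = [choices[int(j)] for j in perm]
        for pep in shuffled[: count_a[i]]:
            emit(pep, config.condition_a)
        for pep in shuffled[count_a[i]:]:
            emit(pep, config.condition_b)

    # --- decoy contaminants: 2 peptides x 1 spectrum each
    truth = GroundTruth()
    for j in range(config.n_decoy_contaminants):
        acc = f"{DECOY_PREFIX}X{j:04d}"
        cond = config.condition_a if j % 2 == 0 else config.condition_b
        for _ in range(2):
            pep = _random_peptide(rng, config.peptide_length)
            while pep in peptide_owners:
                pep = _random_peptide(rng, config.peptide_length)
            peptide_owners[pep] = {acc}
            emit(pep, cond)
        truth.true_class[acc] = "decoy"
        truth.true_log2_effect[acc] = float("nan")

    for i, prot in enumerate(proteome):
        truth.true_class[prot.accession] = classes[i]
        truth.true_log2_effect[prot.accession] = effects.get(i, float("nan"))

    _validate_consistency(psms, truth, config)
    return psms, truth


def _validate_consistency(
    psms: Sequence[PSMRecord], truth: GroundTruth, config: SimulationConfig
) -> None:
    """Ground truth must match the emitted table (checked on every emission)."""
    seen: dict[str, set[str]] = {}
    for psm in psms:
        for acc in psm.accessions:
            seen.setdefault(acc, set()).add(psm.condition)
    for acc, cls in truth.true_class.items():
        conds = seen.get(acc, set())
        if cls == "exclusive_A" and config.condition_b in conds:
            raise AssertionError(f"{acc}: exclusive_A protein has B spectra")
        if cls == "exclusive_B" and config.condition_a in conds:
            raise AssertionError(f"{acc}: exclusive_B protein has A spectra")
        if cls.startswith("shared") and conds != {config.condition_a, config.condition_b}:
            raise AssertionError(f"{acc}: shared protein not seen in both conditions")


# ---------------------------------------------------------------------------
# Annotation

@dataclass
class PlantedCategory:
    """A category to over-represent in a chosen target id set."""

    category_id: str
    name: str
    size: int
    target_ids: frozenset[str]
    multiplier: float = 1.0


def simulate_annotation(
    config: SimulationConfig,
    proteome: Sequence[SimulatedProtein],
    planted_categories: Sequence[PlantedCategory] = (),
) -> tuple[AnnotationSet, GroundTruth]:
    """Annotation sets over a universe of simulated proteins plus background.

    Random categories draw members uniformly from the universe; planted
    categories weight their target identifiers by ``multiplier``, creating
    known over-representation for recovery tests (multiplier 1 plants
    nothing and serves as a null input).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    protein_ids = [p.accession for p in proteome]
    background = [f"BG{i:05d}" for i in range(config.n_background_ids)]
    universe = np.array(protein_ids + background)

    categories: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    truth = GroundTruth()
    for i in range(config.n_categories):
        size = int(rng.integers(config.category_size_range[0],
                                config.category_size_range[1] + 1))
        members = rng.choice(universe, size=size, replace=False)
        cid = f"CAT{i:03d}"
        categories[cid] = frozenset(str(m) for m in members)
        names[cid] = f"random category {i}"
        truth.planted_categories[cid] = False
    for planted in planted_categories:
        weights = np.where(
            np.isin(universe, sorted(planted.target_ids)), planted.multiplier, 1.0
        )
        weights = weights / weights.sum()
        members = rng.choice(universe, size=planted.size, replace=False, p=weights)
        categories[planted.category_id] = frozenset(str(m) for m in members)
        names[planted.category_id] = planted.name
        truth.planted_categories[planted.category_id] = planted.multiplier > 1.0

    annotation = AnnotationSet(
        categories=categories,
        universe=frozenset(str(u) for u in universe),
        category_names=names,
    )
    return annotation, truth
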