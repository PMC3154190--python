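"""Shared fixtures: small constructed inputs and a cached default simulation."""

from __future__ import annotations

import pytest

from speccount import (
    PSMRecord,
    SimulationConfig,
    assemble,
    quantify,
    remove_decoys,
    simulate_proteome,
    simulate_psm_table,
)


def psm(spectrum_id, peptide, accessions, condition, decoys=()):
    """Terse PSMRecord constructor for tests."""
    return PSMRecord(
        spectrum_id=spectrum_id,
        peptide=peptide,
        accessions=frozenset(accessions),
        condition=condition,
        is_decoy_map={a: a in decoys for a in accessions},
    )


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()  # seed 0, 200 proteins: the study conditions


@pytest.fixture(scope="session")
def default_simulation(default_config):
    """Proteome + PSM table + ground truth at the generator defaults."""
    proteome = simulate_proteome(default_config)
    psms, truth = simulate_psm_table(default_config, proteome)
    return default_config, proteome, psms, truth


@pytest.fixture(scope="session")
def default_quantified(default_simulation):
    """Full assembly + quantitation of the default simulation."""
    config, proteome, psms, truth = default_simulation
    groups, ident = assemble(
        psms, condition_a=config.condition_a, condition_b=config.condition_b
    )
    targets = remove_decoys(groups)
    records, partition, thresholds, loading, analytical = quantify(targets)
    return {
        "config": config,
        "truth": truth,
        "groups": groups,
        "ident": ident,
        "targets": targets,
        "records": records,
        "partition": partition,
        "thresholds": thresholds,
        "loading": loading,
        "analytical": analytical,
    }
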