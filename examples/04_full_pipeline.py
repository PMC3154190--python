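"""The full workflow on files: simulate -> assemble -> quantify -> enrich.

Writes a synthetic experiment (PSM table, FASTA, annotation) to a
temporary directory, runs the complete pipeline on those files, and
prints the run summary. Equivalent shell session:

    speccount simulate --out exp --n-proteins 150 --seed 2
    speccount run --psm exp/psms.tsv --fasta exp/proteins.fasta \
        --annotation exp/annotation.tsv --out run
    speccount summarize run
"""

import tempfile
from pathlib import Path

from speccount import (
    PipelineConfig,
    SimulationConfig,
    run_full_pipeline,
    simulate_annotation,
    simulate_proteome,
    simulate_psm_table,
    summary_report,
)
from speccount import io as sio

workdir = Path(tempfile.mkdtemp())
config = SimulationConfig(n_proteins=150, seed=2)
proteome = simulate_proteome(config)
psms, truth = simulate_psm_table(config, proteome)
annotation, _ = simulate_annotation(config, proteome)
sio.write_psm_table(psms, workdir / "psms.tsv")
sio.write_fasta(
    [(p.accession, p.sequence) for p in proteome],
    workdir / "proteins.fasta",
    descriptions={p.accession: p.description for p in proteome},
)
sio.write_annotation(annotation, workdir / "annotation.tsv")

result = run_full_pipeline(
    PipelineConfig(
        psm_path=workdir / "psms.tsv",
        fasta_path=workdir / "proteins.fasta",
        annotation_path=workdir / "annotation.tsv",
        out_dir=workdir / "run",
        seed=config.seed,
    )
)
print(summary_report(result))
print(f"\nstage outputs in {workdir / 'run'}:")
for path in sorted((workdir / "run").iterdir()):
    print(" ", path.name)
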