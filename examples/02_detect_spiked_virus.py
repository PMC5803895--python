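"""Spike a replicating virus into the transcriptome and detect it.

A replicating RNA virus leaves transcripts but no genomic copy; the triage
decision tree therefore escalates a transcriptome-only RNA-virus hit to
PUTATIVE_VIRUS and the report flips to CONTAMINATION_SUSPECTED with a
nonzero exit semantics (exit code 3 in the CLI).
"""

from viroscreen import PipelineConfig, run_pipeline, VpdDatabase
from viroscreen.synthdata import (
    make_host_genome,
    make_host_transcripts,
    make_toy_vpd,
    plant_element,
    template_bundle,
)

templates = template_bundle()
genome = make_host_genome(n_contigs=4, mean_len=4000, gc=0.4, seed=2)
transcripts = make_host_transcripts(genome, n=6, seed=2)

# the virus transcript encodes a protein at 70% identity to the database's
# rhabdovirus L entry - distant enough that nucleotide search would miss it
genome, viral_tx, truth = plant_element(
    genome, "VIRUS", templates, {"target_identity": 0.7}, seed=2
)

vpd = VpdDatabase(entries=make_toy_vpd())
report = run_pipeline(
    PipelineConfig(genome=genome, transcriptome=transcripts + viral_tx,
                   vpd=vpd)
)

print(f"summary: {report.summary}")
for v in report.putative_viruses():
    h = v.best_viral_hit
    print(f"  suspected: {h.query_id} on {v.contig_id} "
          f"(E={h.e_value:.2g}, {h.pct_identity:.0f}% aa identity)")
# The verdict names the closest database protein; the E-value and identity
# quantify how confidently the contig encodes a viral-like protein.
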