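# viroscreen

Adventitious-virus screening of cell-substrate sequencing data by translated
homology search against a compact, curated viral protein database.

## The problem

Cell lines used to produce biologicals (vaccines, recombinant proteins) must
be shown to be free of adventitious viruses. Read-level screens (mapping or
nucleotide BLAST against viral databases) are sensitive for *known* viruses
but miss divergent ones, need heavy compute, and require a clean host
reference genome for read subtraction. An alternative is to search
*assemblies* — genome and transcriptome contigs — with a translated search
(protein query vs all six reading frames of each contig, TBLASTN semantics)
using a compact viral protein database (VPD) covering viral taxonomic
diversity. Protein-level search sees homology that nucleotide search cannot,
and a few thousand curated queries keep the whole screen fast on a desktop.

The catch: insect (and other eukaryotic) genomes are full of sequences that
*legitimately* encode virus-like proteins — Maverick/Polinton DNA
transposons (ATPase, integrase, protease, DNA polymerase B, capsid-like
ORFs), errantiviruses (insect LTR retroelements with a retroviral-style
*gag*/*pol*/*env* architecture), R1 LINEs carrying superfamily-1 helicase
domains acquired from (+)ssRNA viruses, and endogenous viral elements (EVEs)
— fragments of RNA viruses fossilised in the genome. A screen that cannot
tell these from a replicating virus is useless. `viroscreen` implements the
whole decision procedure:

1. **Search**: seed-and-extend translated search with Karlin–Altschul
   statistics — bit = (λS − ln K)/ln 2, E = m·n·2^(−bit), BLOSUM62 with
   affine gaps 11/1 (λ = 0.267, K = 0.041), E < 0.1 reporting threshold.
2. **Differential homology**: regions whose best host-protein alignment
   beats the best viral alignment by ≥ 20 orders of magnitude in E-value
   are host genes.
3. **Element architecture**: contigs are scanned for Maverick (≥ 5 hallmark
   ORF roles), errantivirus (LTR pair + intact gag/pol/env with signal
   peptide, basic cleavage site and C-terminal transmembrane helix in env)
   and R1-LINE (ORF2 with RT core followed by a C-terminal SF1-helicase
   domain) architectures.
4. **EVE calling**: a hit from an RNA virus with no DNA stage that is
   nevertheless present in the *genome* assembly, flanked by ≥ 200 nt of
   host sequence, is an EVE — with nonsense/frameshift interruption counts
   and RPKM when reads are supplied.
5. **Verdict**: anything that survives 1–4 with E < 0.1 is a
   PUTATIVE_VIRUS and flips the report to CONTAMINATION_SUSPECTED.

The package also provides VPD construction/curation (one representative
virus per family; automatic purge of viral proteins with close cellular
homologs), a toy de Bruijn assembler and read simulator for sensitivity
experiments, read mapping + RPKM, and protein phylogenetics (progressive
alignment, Kimura/JTT distances, neighbor joining, Newick output) to back
"clusters with transposons, not with viruses" arguments.

## Worked example

```python
from viroscreen import PipelineConfig, run_pipeline, VpdDatabase
from viroscreen.synthdata import (
    make_host_genome, make_host_transcripts, make_toy_vpd,
    plant_element, template_bundle,
)

templates = template_bundle()
genome = make_host_genome(n_contigs=4, mean_len=4000, gc=0.4, seed=2)
transcripts = make_host_transcripts(genome, n=6, seed=2)
genome, viral_tx, _ = plant_element(           # spike a replicating virus
    genome, "VIRUS", templates, {"target_identity": 0.7}, seed=2)

vpd = VpdDatabase(entries=make_toy_vpd())
report = run_pipeline(PipelineConfig(
    genome=genome, transcriptome=transcripts + viral_tx, vpd=vpd))
print(report.summary)
for v in report.putative_viruses():
    h = v.best_viral_hit
    print(h.query_id, v.contig_id, f"E={h.e_value:.2g}",
          f"{h.pct_identity:.0f}% id")
```

prints

```
CONTAMINATION_SUSPECTED
tpl_rhabdo_L virus_tx_2 E=1.6e-266 70% id
```

The spiked transcript encodes a protein only 70% identical to the closest
database entry — far below what nucleotide search needs — yet the
translated search pins it with an overwhelming E-value, and because the
sequence is present in the transcriptome but absent from the genome (an RNA
virus has no DNA stage), triage escalates it to PUTATIVE_VIRUS. The
`examples/` directory has one script per capability: clean-screen,
spiked-virus, transposon annotation, EVE quantitation, the read-count
sensitivity curve, and VPD curation + phylogeny.

A thin CLI wraps the same pipeline (`viroscreen run … -o outdir`, exit code
0 = CLEAN, 3 = CONTAMINATION_SUSPECTED), with subcommands `simulate`,
`search`, `annotate`, `assemble`, `build-vpd` and `report`.

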