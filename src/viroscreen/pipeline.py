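"""End-to-end contamination screen: search -> annotate -> triage -> report.

Stages, in order: optional VPD curation; translated search of the genome
assembly; translated search of the transcriptome assembly; element
annotation of hit-bearing contigs; triage of every significant hit; optional
read mapping with RPKM for EVEs; report. The run is deterministic given the
configuration and seed, and all intermediates are written as plain text.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from .elements import ElementAnnotation, annotate_elements, elements_to_bed
from .motifs import motif_library
from .quant import map_reads, rpkm
from .search import Hsp, ScoringScheme, hsps_to_table, tblastn_search
from .seqio import FastqRead, SequenceRecord, read_fasta, read_fastq, Alphabet
from .triage import TriageContext, TriageVerdict, Verdict, triage_hits
from .vpd import VpdDatabase, purge_cellular_homologs, read_vpd

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genome: list[SequenceRecord] | str
    transcriptome: list[SequenceRecord] | str
    vpd: VpdDatabase | tuple[str, str]
    host_proteome: list[SequenceRecord] | str | None = None
    reads: list[FastqRead] | str | None = None
    curate_vpd: bool = False
    e_cutoff: float = 0.1
    delta_log10: float = 20.0
    min_host_flank: int = 200
    min_orf_aa: int = 100
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.e_cutoff <= 0 or self.e_cutoff > 10:
            raise ValueError("e_cutoff must be in (0, 10]")
        if self.delta_log10 <= 0:
            raise ValueError("delta_log10 must be positive")


@dataclass
class ContaminationReport:
    summary: str                       # CLEAN or CONTAMINATION_SUSPECTED
    verdicts: list[TriageVerdict]
    eve_rows: list[dict]
    elements: list[ElementAnnotation]
    genome_hits: list[Hsp]
    transcriptome_hits: list[Hsp]
    expected_read_context: dict | None = None
    stage_seconds: dict = field(default_factory=dict)

    @property
    def contaminated(self) -> bool:
        return self.summary == "CONTAMINATION_SUSPECTED"

    def putative_viruses(self) -> list[TriageVerdict]:
        return [v for v in self.verdicts if v.verdict is Verdict.PUTATIVE_VIRUS]

    def summary_dict(self) -> dict:
        counts: dict[str, int] = {}
        for v in self.verdicts:
            counts[v.verdict.value] = counts.get(v.verdict.value, 0) + 1
        return {
            "summary": self.summary,
            "verdict_counts": counts,
            "n_genome_hits": len(self.genome_hits),
            "n_transcriptome_hits": len(self.transcriptome_hits),
            "suspected_viruses": sorted(
                {v.best_viral_hit.query_id for v in self.putative_viruses()}
            ),
            "eve_count": len(self.eve_rows),
        }


def _load_records(x, alphabet=Alphabet.NUCLEOTIDE) -> list[SequenceRecord]:
    if isinstance(x, str) or isinstance(x, Path):
        return read_fasta(x, alphabet=alphabet)
    return list(x)


def run_pipeline(config: PipelineConfig) -> ContaminationReport:
    """Execute the full screen; see module docstring for the stage order."""
    timings: dict[str, float] = {}
    t0 = time.time()
    genome = _load_records(config.genome)
    transcriptome = _load_records(config.transcriptome)
    vpd = (
        config.vpd if isinstance(config.vpd, VpdDatabase)
        else read_vpd(*config.vpd)
    )
    host = (
        _load_records(config.host_proteome, Alphabet.PROTEIN)
        if config.host_proteome is not None else []
    )
    reads = (
        read_fastq(config.reads) if isinstance(config.reads, (str, Path))
        else (list(config.reads) if config.reads is not None else None)
    )
    scheme = ScoringScheme.blosum62()
    timings["load"] = time.time() - t0

    t0 = time.time()
    if config.curate_vpd and host:
        vpd = purge_cellular_homologs(vpd, host)
        log.info("VPD curation removed %d entries", len(vpd.removal_log))
    queries = vpd.records()
    timings["curate"] = time.time() - t0

    t0 = time.time()
    genome_hits = tblastn_search(
        queries, genome, scheme, e_cutoff=config.e_cutoff
    )
    timings["search_genome"] = time.time() - t0
    t0 = time.time()
    tx_hits = tblastn_search(
        queries, transcriptome, scheme, e_cutoff=config.e_cutoff
    )
    timings["search_transcriptome"] = time.time() - t0

    t0 = time.time()
    library = motif_library()
    hit_contigs = sorted({h.subject_id for h in genome_hits})
    genome_by_id = {r.id: r for r in genome}
    tx_by_id = {r.id: r for r in transcriptome}
    elements: dict[str, list[ElementAnnotation]] = {}
    for cid in hit_contigs:
        anns = annotate_elements(
            cid, genome_by_id[cid].residues, library, config.min_orf_aa
        )
        if anns:
            elements[cid] = anns
    timings["annotate"] = time.time() - t0

    t0 = time.time()
    ctx = TriageContext(
        genome=genome_by_id,
        transcriptome=tx_by_id,
        viral_refs=queries,
        host_refs=host,
        viral_meta=vpd.meta_by_protein(),
        elements=elements,
        e_cutoff=config.e_cutoff,
        delta_threshold=config.delta_log10,
        min_host_flank=config.min_host_flank,
        scheme=scheme,
    )
    verdicts = triage_hits(genome_hits, "genome", ctx)
    verdicts += triage_hits(tx_hits, "transcriptome", ctx)
    timings["triage"] = time.time() - t0

    t0 = time.time()
    eve_rows = []
    eve_features: list[SequenceRecord] = []
    seen_regions: list[tuple[str, int, int]] = []
    for v in sorted(
        (v for v in verdicts if v.eve_call is not None),
        key=lambda v: (v.eve_call.contig_id, v.eve_call.region),
    ):
        s_, e_ = v.eve_call.region
        if any(c == v.eve_call.contig_id and s_ < hi_ and lo_ < e_
               for c, lo_, hi_ in seen_regions):
            continue  # same genomic EVE seen via genome and transcriptome
        seen_regions.append((v.eve_call.contig_id, s_, e_))
        contig = genome_by_id[v.eve_call.contig_id]
        s, e = v.eve_call.region
        eve_features.append(
            SequenceRecord(f"EVE_{v.eve_call.contig_id}_{s}_{e}",
                           contig.residues[s:e])
        )
        eve_rows.append({
            "eve": f"{v.eve_call.closest_virus} {v.eve_call.closest_protein}-like",
            "contig": v.eve_call.contig_id,
            "region": [s, e],
            "length_bp": e - s,
            "nonsense_mutations": v.eve_call.nonsense_count,
            "frameshift_mutations": v.eve_call.frameshift_count,
            "genome_present": True,
            "transcriptome_present": v.eve_call.transcriptome_present,
            "rpkm": None,
            "reads_mapped": None,
        })
    if reads and eve_features:
        counts, _ = map_reads(reads, eve_features)
        total = max(1, len(reads))
        for row, feat in zip(eve_rows, eve_features):
            row["reads_mapped"] = counts[feat.id]
            row["rpkm"] = round(
                rpkm(counts[feat.id], len(feat.residues), total).rpkm, 3
            )
    timings["quantify"] = time.time() - t0

    n_putative = sum(
        1 for v in verdicts if v.verdict is Verdict.PUTATIVE_VIRUS
    )
    report = ContaminationReport(
        summary="CONTAMINATION_SUSPECTED" if n_putative else "CLEAN",
        verdicts=verdicts,
        eve_rows=eve_rows,
        elements=[a for anns in elements.values() for a in anns],
        genome_hits=genome_hits,
        transcriptome_hits=tx_hits,
        stage_seconds={k: round(v, 3) for k, v in timings.items()},
    )
    if config.output_dir:
        write_report(report, config.output_dir)
    return report


def verdicts_to_tsv(verdicts: list[TriageVerdict]) -> str:
    lines = ["contig_id\tregion_start\tregion_end\tverdict\tbest_viral_hit\t"
             "e_value\tdelta_log10_e\tevidence"]
    for v in verdicts:
        delta = "" if v.delta_log10_e is None else f"{v.delta_log10_e:.2f}"
        lines.append(
            f"{v.contig_id}\t{v.region[0] + 1}\t{v.region[1]}\t"
            f"{v.verdict.value}\t{v.best_viral_hit.query_id}\t"
            f"{v.best_viral_hit.e_value:.3g}\t{delta}\t"
            f"{'; '.join(v.evidence)}"
        )
    return "\n".join(lines) + "\n"


def write_report(report: ContaminationReport, output_dir: str | Path) -> None:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    hsps_to_table(report.genome_hits).to_csv(
        out / "hits_genome.tsv", sep="\t", index=False
    )
    hsps_to_table(report.transcriptome_hits).to_csv(
        out / "hits_transcriptome.tsv", sep="\t", index=False
    )
    (out / "verdicts.tsv").write_text(verdicts_to_tsv(report.verdicts))
    (out / "elements.bed").write_text(elements_to_bed(report.elements))
    (out / "eves.json").write_text(json.dumps(report.eve_rows, indent=1))
    (out / "report.json").write_text(
        json.dumps(report.summary_dict(), indent=1, sort_keys=True)
    )
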