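"""Viral protein database (VPD) construction and curation.

A compact VPD keeps translated searches fast and interpretable: one (ideally
whole-genome-sequenced 'type') virus per family, plus user-listed
must-include viruses such as agents known to infect the host species.
Curation then removes viral proteins with close cellular homologs - the
proteins that would otherwise drag host genes into every screen: polymerase,
kinase, phosphatase, apoptosis-inhibitor, superoxide-dismutase, protease,
nuclease, ubiquitin-ligase and zinc/ring-finger domain carriers. Removal is
automated here: a protein is purged when its best alignment against the host
proteome reaches an E-value threshold, or when it matches the packaged
cellular-domain blocklist; every removal is logged with machine-checkable
evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .motifs import MotifDefinition, annotate_motifs, cellular_blocklist
from .search import ScoringScheme, evalue, smith_waterman_protein
from .seqio import Alphabet, SequenceRecord, read_fasta, write_fasta

log = logging.getLogger(__name__)

BALTIMORE_MATERIAL = {
    "I": "dsDNA", "II": "ssDNA", "III": "dsRNA", "IV": "plus_ssRNA",
    "V": "minus_ssRNA", "VI": "ssRNA_RT", "VII": "dsDNA_RT",
}

#: genome materials with no DNA stage in the replication cycle
RNA_NO_DNA_STAGE = {"plus_ssRNA", "minus_ssRNA", "dsRNA"}


@dataclass
class ViralProteinEntry:
    protein_id: str
    virus: str
    family: str
    baltimore_group: str
    genome_material: str
    whole_genome_type_virus: bool
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")
        expected = BALTIMORE_MATERIAL.get(self.baltimore_group)
        if expected is not None and expected != self.genome_material:
            raise ValueError(
                f"{self.protein_id}: genome material {self.genome_material} "
                f"inconsistent with Baltimore group {self.baltimore_group}"
            )

    def as_record(self) -> SequenceRecord:
        return SequenceRecord(
            self.protein_id, self.sequence,
            description=f"{self.virus} ({self.family})",
            alphabet=Alphabet.PROTEIN,
        )


@dataclass
class VpdDatabase:
    entries: list[ViralProteinEntry]
    provenance: str = ""
    removal_log: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.protein_id for e in self.entries]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate protein ids in VPD: {dup}")

    def __len__(self) -> int:
        return len(self.entries)

    def records(self) -> list[SequenceRecord]:
        return [e.as_record() for e in self.entries]

    def meta_by_protein(self) -> dict[str, ViralProteinEntry]:
        return {e.protein_id: e for e in self.entries}


def select_representatives(
    proteins: list[ViralProteinEntry],
    must_include_viruses: set[str] | frozenset[str] = frozenset(),
) -> VpdDatabase:
    """Retain the proteins of one representative virus per family.

    Within a family a whole-genome-sequenced type virus is preferred;
    otherwise the first (by name) virus with complete metadata. Viruses on
    the must-include list are always retained regardless of deduplication.
    """
    by_family: dict[str, dict[str, list[ViralProteinEntry]]] = {}
    for p in proteins:
        if not p.family:
            raise ValueError(f"{p.protein_id}: missing family metadata")
        by_family.setdefault(p.family, {}).setdefault(p.virus, []).append(p)
    keep: list[ViralProteinEntry] = []
    for family in sorted(by_family):
        viruses = by_family[family]
        if not viruses:
            raise ValueError(f"family {family} has no candidate viruses")
        typed = sorted(
            v for v, ps in viruses.items() if ps[0].whole_genome_type_virus
        )
        chosen = typed[0] if typed else sorted(viruses)[0]
        wanted = {chosen} | (set(viruses) & set(must_include_viruses))
        for v in sorted(wanted):
            keep.extend(viruses[v])
    return VpdDatabase(
        entries=keep,
        provenance=(
            f"representatives of {len(by_family)} families"
            + (f"; must-include: {sorted(must_include_viruses)}"
               if must_include_viruses else "")
        ),
    )


def purge_cellular_homologs(
    vpd: VpdDatabase,
    host_proteome: list[SequenceRecord],
    e_threshold: float = 1e-10,
    blocklist: list[MotifDefinition] | None = None,
    scheme: ScoringScheme | None = None,
) -> VpdDatabase:
    """Remove viral proteins with close cellular homologs.

    An entry is removed iff its best protein-protein alignment against the
    host proteome has E <= ``e_threshold``, or it matches any motif of the
    cellular-domain blocklist. Conservation: |kept| + |removed| = |input|.
    Idempotent by construction.
    """
    if not host_proteome:
        raise ValueError("host proteome must be non-empty")
    if e_threshold <= 0:
        raise ValueError("e_threshold must be positive")
    blocklist = blocklist if blocklist is not None else cellular_blocklist()
    scheme = scheme or ScoringScheme.blosum62()
    n_host = sum(len(r.residues) for r in host_proteome)
    kept: list[ViralProteinEntry] = []
    removals: list[tuple[str, str, str]] = list(vpd.removal_log)
    for entry in vpd.entries:
        motif_hits = annotate_motifs(entry.sequence, blocklist)
        if motif_hits:
            h = motif_hits[0]
            removals.append(
                (entry.protein_id, "BLOCKLIST_DOMAIN",
                 f"{h.name} at aa {h.start + 1}-{h.end}")
            )
            continue
        best_e, best_host = None, None
        for host in host_proteome:
            hsp = smith_waterman_protein(
                entry.sequence, host.residues, scheme,
                query_id=entry.protein_id, subject_id=host.id,
            )
            if hsp is None:
                continue
            _, e = evalue(hsp.raw_score, len(entry.sequence), n_host, scheme)
            if best_e is None or e < best_e:
                best_e, best_host = e, host.id
        if best_e is not None and best_e <= e_threshold:
            removals.append(
                (entry.protein_id, "CLOSE_HOST_HOMOLOG",
                 f"best host hit {best_host} E={best_e:.3g}")
            )
            continue
        kept.append(entry)
    return VpdDatabase(
        entries=kept,
        provenance=vpd.provenance + f"; purged at E<={e_threshold:g} + blocklist",
        removal_log=removals,
    )


# ---------------------------------------------------------------------------
# TSV sidecar I/O (FASTA headers cannot carry the metadata reliably)
# ---------------------------------------------------------------------------

_META_COLS = ["protein_id", "virus", "family", "baltimore_group",
              "genome_material", "type_flag"]


def write_vpd(vpd: VpdDatabase, fasta_path: str | Path, meta_path: str | Path,
              removal_log_path: str | Path | None = None) -> None:
    write_fasta(vpd.records(), fasta_path)
    with open(meta_path, "w") as fh:
        fh.write("\t".join(_META_COLS) + "\n")
        for e in vpd.entries:
            fh.write(
                f"{e.protein_id}\t{e.virus}\t{e.family}\t{e.baltimore_group}"
                f"\t{e.genome_material}\t{int(e.whole_genome_type_virus)}\n"
            )
    if removal_log_path is not None:
        with open(removal_log_path, "w") as fh:
            fh.write("protein_id\treason\tevidence\n")
            for pid, reason, evidence in vpd.removal_log:
                fh.write(f"{pid}\t{reason}\t{evidence}\n")


def read_vpd(fasta_path: str | Path, meta_path: str | Path) -> VpdDatabase:
    records = {
        r.id: r for r in read_fasta(fasta_path, alphabet=Alphabet.PROTEIN)
    }
    entries = []
    with open(meta_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _META_COLS:
            raise ValueError(f"unexpected VPD metadata columns: {header}")
        for line in fh:
            pid, virus, family, group, material, flag = line.rstrip("\n").split("\t")
            if pid not in records:
                raise ValueError(f"metadata row {pid} has no FASTA record")
            entries.append(
                ViralProteinEntry(
                    pid, virus, family, group, material, bool(int(flag)),
                    records[pid].residues,
                )
            )
    return VpdDatabase(entries=entries, provenance=f"read from {fasta_path}")
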