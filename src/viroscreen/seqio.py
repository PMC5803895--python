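"""Sequence I/O, translation, six-frame coordinate mapping and ORF calling.

Internally every coordinate is 0-based, half-open, on the forward strand of
the contig. Human-readable reports convert to 1-based inclusive at the edge.
Nucleotide records are restricted to the {A, C, G, T, N} alphabet: other
IUPAC ambiguity codes are mapped to N on read (with a logged warning), since
translated homology search treats all ambiguity identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable

log = logging.getLogger(__name__)

NT_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_FRAMES = (1, 2, 3, -1, -2, -3)


class Alphabet(str, Enum):
    NUCLEOTIDE = "NUCLEOTIDE"
    PROTEIN = "PROTEIN"


@dataclass
class SequenceRecord:
    """A named sequence with an explicit alphabet tag."""

    id: str
    residues: str
    description: str = ""
    alphabet: Alphabet = Alphabet.NUCLEOTIDE

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class OrfCall:
    """A maximal ATG-to-stop open reading frame on either strand.

    ``start``/``end`` are forward-strand nucleotide coordinates covering the
    start codon through the stop codon (when a stop is present). ``aa_seq``
    excludes the terminal stop.
    """

    contig_id: str
    strand: str  # '+' or '-'
    start: int
    end: int
    frame: int
    aa_seq: str
    has_internal_stop: bool = False
    partial: bool = False  # no stop codon before the contig edge

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0 or self.end <= self.start:
            raise ValueError("ORF interval must be a positive multiple of 3")

    @property
    def aa_len(self) -> int:
        return len(self.aa_seq)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def _clean_nt(seq: str, rec_id: str) -> str:
    s = seq.upper()
    if not set(s) <= NT_ALPHABET:
        bad = sorted(set(s) - NT_ALPHABET)
        log.warning(
            "record %s: ambiguity codes %s mapped to N", rec_id, "".join(bad)
        )
        s = "".join(c if c in NT_ALPHABET else "N" for c in s)
    return s


def read_fasta(
    path: str | Path, alphabet: Alphabet = Alphabet.NUCLEOTIDE
) -> list[SequenceRecord]:
    """Read FASTA records. Duplicate ids and empty records are errors."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r} in {path}")
        if alphabet is Alphabet.NUCLEOTIDE:
            seq = _clean_nt(seq, rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, seq, desc, alphabet))
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, wrap: int = 60
) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), wrap):
                fh.write(rec.residues[i : i + wrap] + "\n")


@dataclass
class FastqRead:
    id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.id!r}: sequence and quality lengths differ"
            )


def read_fastq(path: str | Path) -> list[FastqRead]:
    """Read 4-line FASTQ (Sanger Phred+33). Truncated records are errors."""
    reads = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            q = "".join(
                chr(33 + v) for v in rec.letter_annotations["phred_quality"]
            )
            reads.append(FastqRead(rec.id, str(rec.seq).upper(), q))
    return reads


def read_fastq_pairs(
    r1_path: str | Path, r2_path: str | Path
) -> list[tuple[FastqRead, FastqRead]]:
    r1 = read_fastq(r1_path)
    r2 = read_fastq(r2_path)
    if len(r1) != len(r2):
        raise ValueError(
            f"paired FASTQ record counts differ: {len(r1)} vs {len(r2)}"
        )
    return list(zip(r1, r2))


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------

def _build_codon_table() -> dict[str, str]:
    table = dict(CodonTable.unambiguous_dna_by_id[1].forward_table)
    for stop in CodonTable.unambiguous_dna_by_id[1].stop_codons:
        table[stop] = "*"
    return table


CODON_TABLE = _build_codon_table()


def reverse_complement(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]


def translate(nt: str, frame: int = 1) -> str:
    """Translate one reading frame with the standard genetic code.

    Codons containing N (or any non-ACGT character) become 'X'; stop codons
    are rendered '*'; a trailing partial codon is dropped. Negative frames
    translate the reverse complement.
    """
    if frame not in VALID_FRAMES:
        raise ValueError(f"invalid frame {frame}; expected one of {VALID_FRAMES}")
    s = nt.upper()
    if frame < 0:
        s = reverse_complement(s)
    offset = abs(frame) - 1
    out = []
    for i in range(offset, len(s) - 2, 3):
        out.append(CODON_TABLE.get(s[i : i + 3], "X"))
    return "".join(out)


@dataclass
class FrameTranslation:
    frame: int
    protein: str
    nt_len: int

    def aa_to_nt(self, aa_index: int) -> tuple[int, int]:
        """Forward-strand nucleotide interval of the codon at ``aa_index``."""
        if not 0 <= aa_index < len(self.protein):
            raise IndexError(aa_index)
        off = abs(self.frame) - 1
        if self.frame > 0:
            start = off + 3 * aa_index
            return start, start + 3
        end = self.nt_len - off - 3 * aa_index
        return end - 3, end

    def aa_span_to_nt(self, aa_start: int, aa_end: int) -> tuple[int, int]:
        """Forward-strand interval covering aa indices [aa_start, aa_end)."""
        if aa_end <= aa_start:
            raise ValueError("empty span")
        off = abs(self.frame) - 1
        if self.frame > 0:
            return off + 3 * aa_start, off + 3 * aa_end
        return self.nt_len - off - 3 * aa_end, self.nt_len - off - 3 * aa_start


def six_frame(nt: str) -> list[FrameTranslation]:
    """All six frame translations with coordinate maps."""
    if len(nt) < 3:
        raise ValueError("sequence shorter than one codon")
    return [FrameTranslation(f, translate(nt, f), len(nt)) for f in VALID_FRAMES]


# ---------------------------------------------------------------------------
# ORF calling
# ---------------------------------------------------------------------------

def find_orfs(
    nt: str, min_aa_len: int = 30, contig_id: str = "", require_stop: bool = False
) -> list[OrfCall]:
    """All maximal ATG-to-stop ORFs on both strands, sorted by start.

    An ORF running off the contig edge without a stop codon is reported with
    ``partial=True`` unless ``require_stop`` is set.
    """
    if min_aa_len < 1:
        raise ValueError("min_aa_len must be >= 1")
    s = nt.upper()
    n = len(s)
    orfs: list[OrfCall] = []
    for frame in VALID_FRAMES:
        prot = translate(s, frame)
        strand = "+" if frame > 0 else "-"
        seg_start = 0  # aa index of first codon after previous stop
        i = 0
        L = len(prot)
        while seg_start < L:
            stop = prot.find("*", seg_start)
            seg_end = stop if stop != -1 else L
            m = prot.find("M", seg_start, seg_end)
            if m != -1 and seg_end - m >= min_aa_len:
                partial = stop == -1
                if not (require_stop and partial):
                    aa_seq = prot[m:seg_end]
                    # codon interval incl. stop codon when present
                    last = seg_end if partial else seg_end + 1
                    off = abs(frame) - 1
                    if frame > 0:
                        start_nt = off + 3 * m
                        end_nt = off + 3 * last
                    else:
                        end_nt = n - off - 3 * m
                        start_nt = n - off - 3 * last
                    orfs.append(
                        OrfCall(
                            contig_id=contig_id,
                            strand=strand,
                            start=start_nt,
                            end=end_nt,
                            frame=frame,
                            aa_seq=aa_seq,
                            has_internal_stop=False,
                            partial=partial,
                        )
                    )
            if stop == -1:
                break
            seg_start = stop + 1
            i += 1
    orfs.sort(key=lambda o: (o.start, o.end, o.frame))
    return orfs
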