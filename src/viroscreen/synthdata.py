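"""Seeded generator of toy host genomes/transcriptomes with planted viruses,
endogenous viral elements and virus-like transposons, plus read simulation.

Everything is deterministic per seed. Template proteins are synthetic: they
are built around the packaged motif consensi (Walker A/B, DDE integrase,
adenain triad, PLA2, family-B polymerase core, RT core, SF1 helicase) with
background residues drawn from average amino-acid frequencies, so the suite
runs with zero network access. The templates emulate the *architecture* of
real elements, not their sequences: motif spans are protected when a
template is diverged to a target identity, mirroring the strong conservation
of catalytic residues in real families.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .motifs import motif_library
from .search import ROBINSON_FREQS
from .seqio import (
    Alphabet,
    CODON_TABLE,
    FastqRead,
    SequenceRecord,
    reverse_complement,
)
from .vpd import ViralProteinEntry

_AA = list(ROBINSON_FREQS)
_AA_P = np.array([ROBINSON_FREQS[a] for a in _AA])
_AA_P = _AA_P / _AA_P.sum()

_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in sorted(CODON_TABLE.items()):
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
STOP_CODONS = _CODONS_BY_AA["*"]

from Bio.Align import substitution_matrices as _subs

_B62 = _subs.load("BLOSUM62")


def _rng(seed: int, *salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *salt]))


def _rand_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_AA, size=n, p=_AA_P))


def _rand_nt(rng: np.random.Generator, n: int, gc: float = 0.4) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform synonymous codon choice; no stop codons inside."""
    return "".join(
        _CODONS_BY_AA[aa][rng.integers(len(_CODONS_BY_AA[aa]))]
        for aa in protein
    )


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

@dataclass
class ProteinTemplate:
    id: str
    sequence: str
    protected: list[tuple[int, int]] = field(default_factory=list)

    def protected_mask(self) -> np.ndarray:
        m = np.zeros(len(self.sequence), dtype=bool)
        for s, e in self.protected:
            m[s:e] = True
        return m


def _with_motifs(
    rng: np.random.Generator,
    total_len: int,
    inserts: list[tuple[int, str]],
    name: str,
) -> ProteinTemplate:
    """Random-background protein with motif consensi planted at offsets."""
    seq = list(_rand_protein(rng, total_len))
    protected = []
    for off, consensus in inserts:
        seq[off : off + len(consensus)] = list(consensus)
        protected.append((off, off + len(consensus)))
    return ProteinTemplate(name, "".join(seq), protected)


def _consensus(name: str) -> str:
    for m in motif_library():
        if m.name == name:
            return m.consensus
    raise KeyError(name)


def _env_template(rng: np.random.Generator, name: str = "tpl_env") -> ProteinTemplate:
    """env-like protein: N-terminal signal peptide, internal basic cleavage
    site, C-terminal transmembrane stretch."""
    hydros = list("LIVFA")
    n = 400
    seq = list(_rand_protein(rng, n))
    signal = ["M"] + [hydros[rng.integers(5)] for _ in range(11)]
    seq[0:12] = signal
    cleav_at = n - 80
    seq[cleav_at : cleav_at + 4] = list("RQKR")
    tm_at = n - 40
    seq[tm_at : tm_at + 19] = [hydros[rng.integers(5)] for _ in range(19)]
    return ProteinTemplate(
        name, "".join(seq),
        [(0, 12), (cleav_at, cleav_at + 4), (tm_at, tm_at + 19)],
    )


def template_bundle() -> dict[str, ProteinTemplate]:
    """Deterministic synthetic template proteins for every element class."""
    rng = _rng(0xC0FFEE)
    t: dict[str, ProteinTemplate] = {}
    # Maverick hallmark roles
    t["tpl_ATP"] = _with_motifs(
        rng, 350, [(60, _consensus("WALKER_A")), (140, _consensus("WALKER_B"))],
        "tpl_ATP",
    )
    t["tpl_INT"] = _with_motifs(
        rng, 320, [(50, _consensus("INTEGRASE_DDE")), (280, _consensus("CHROMO"))],
        "tpl_INT",
    )
    t["tpl_PRO"] = _with_motifs(rng, 150, [(30, _consensus("ADENAIN_TRIAD"))], "tpl_PRO")
    t["tpl_POLB"] = _with_motifs(rng, 1100, [(700, _consensus("POLB_CORE"))], "tpl_POLB")
    t["tpl_CAP"] = _with_motifs(rng, 260, [(30, _consensus("PLA2_CATALYTIC"))], "tpl_CAP")
    for k, ln in (("tpl_ORF2", 180), ("tpl_ORF6", 160), ("tpl_ORF7", 220), ("tpl_ORF8", 150)):
        t[k] = ProteinTemplate(k, _rand_protein(rng, ln))
    # errantivirus
    t["tpl_gag"] = ProteinTemplate("tpl_gag", _rand_protein(rng, 450))
    t["tpl_pol"] = _with_motifs(
        rng, 900, [(150, _consensus("RT_CORE")), (450, _consensus("INTEGRASE_DDE"))],
        "tpl_pol",
    )
    t["tpl_env"] = _env_template(rng)
    # R1 LINE
    t["tpl_r1_orf1"] = ProteinTemplate("tpl_r1_orf1", _rand_protein(rng, 350))
    t["tpl_r1_orf2"] = _with_motifs(
        rng, 1000, [(250, _consensus("RT_CORE")), (730, _consensus("SF1_HELICASE"))],
        "tpl_r1_orf2",
    )
    # toy viral proteins for the VPD and for virus/EVE planting
    for k, ln in (
        ("tpl_rhabdo_N", 430), ("tpl_rhabdo_P", 300), ("tpl_rhabdo_G", 500),
        ("tpl_rhabdo_L", 650), ("tpl_denso_NS1", 400), ("tpl_ifla_rep", 550),
        ("tpl_bunya_N", 250),
    ):
        t[k] = ProteinTemplate(k, _rand_protein(rng, ln))
    return t


def make_toy_vpd() -> list[ViralProteinEntry]:
    """A compact synthetic viral protein set covering several Baltimore
    groups, used as the search query set in tests and examples."""
    t = template_bundle()
    rows = [
        ("tpl_rhabdo_N", "Toy rhabdovirus", "Rhabdoviridae", "V", "minus_ssRNA"),
        ("tpl_rhabdo_P", "Toy rhabdovirus", "Rhabdoviridae", "V", "minus_ssRNA"),
        ("tpl_rhabdo_G", "Toy rhabdovirus", "Rhabdoviridae", "V", "minus_ssRNA"),
        ("tpl_rhabdo_L", "Toy rhabdovirus", "Rhabdoviridae", "V", "minus_ssRNA"),
        ("tpl_denso_NS1", "Toy densovirus", "Parvoviridae", "II", "ssDNA"),
        ("tpl_ifla_rep", "Toy iflavirus", "Iflaviridae", "IV", "plus_ssRNA"),
        ("tpl_bunya_N", "Toy bunyavirus", "Phenuiviridae", "V", "minus_ssRNA"),
    ]
    return [
        ViralProteinEntry(
            protein_id=pid, virus=virus, family=family, baltimore_group=grp,
            genome_material=mat, whole_genome_type_virus=True,
            sequence=t[pid].sequence,
        )
        for pid, virus, family, grp, mat in rows
    ]


# ---------------------------------------------------------------------------
# Divergence
# ---------------------------------------------------------------------------

def mutate_protein(
    template: ProteinTemplate | str,
    target_identity: float,
    seed: int,
    protect_motifs: bool = True,
) -> str:
    """Substitute residues at random unprotected positions until the overall
    identity is within +-2% of the target. Replacement residues are
    BLOSUM62-weighted (softmax of the substitution row, original excluded)."""
    if not 0 < target_identity <= 1:
        raise ValueError("target_identity must be in (0, 1]")
    if isinstance(template, str):
        template = ProteinTemplate("anon", template)
    rng = _rng(seed, 11)
    seq = list(template.sequence)
    n = len(seq)
    mask = template.protected_mask() if protect_motifs else np.zeros(n, bool)
    free = np.flatnonzero(~mask)
    n_changes = int(round((1 - target_identity) * n))
    n_changes = min(n_changes, len(free))
    positions = rng.choice(free, size=n_changes, replace=False)
    alphabet = list(_B62.alphabet[:20])
    for p in positions:
        orig = seq[p]
        if orig not in alphabet:
            continue
        row = np.array([_B62[orig, a] for a in alphabet], dtype=float)
        row[alphabet.index(orig)] = -np.inf
        w = np.exp(row / 2.0)
        w /= w.sum()
        seq[p] = alphabet[rng.choice(len(alphabet), p=w)]
    return "".join(seq)


def mutate_coding(
    template_protein: ProteinTemplate | str, target_identity: float, seed: int
) -> tuple[str, str]:
    """(diverged protein, encoding nucleotide sequence)."""
    prot = mutate_protein(template_protein, target_identity, seed)
    nt = back_translate(prot, _rng(seed, 12))
    return prot, nt


# ---------------------------------------------------------------------------
# Host genome
# ---------------------------------------------------------------------------

def make_host_genome(
    n_contigs: int, mean_len: int, gc: float = 0.4, seed: int = 0
) -> list[SequenceRecord]:
    """i.i.d. host contigs at the given GC content, deterministic per seed."""
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = _rng(seed, 1)
    recs = []
    for i in range(n_contigs):
        length = int(rng.integers(int(0.8 * mean_len), int(1.2 * mean_len) + 1))
        recs.append(
            SequenceRecord(f"host_contig_{i + 1}", _rand_nt(rng, length, gc))
        )
    return recs


def make_host_transcripts(
    genome: Sequence[SequenceRecord], n: int, mean_len: int = 1200, seed: int = 0
) -> list[SequenceRecord]:
    """Host transcripts sampled as windows of genome contigs."""
    rng = _rng(seed, 2)
    out = []
    for i in range(n):
        c = genome[rng.integers(len(genome))]
        ln = min(len(c.residues), int(rng.integers(int(0.6 * mean_len), int(1.4 * mean_len))))
        start = int(rng.integers(0, len(c.residues) - ln + 1))
        out.append(SequenceRecord(f"host_tx_{i + 1}", c.residues[start : start + ln]))
    return out


# ---------------------------------------------------------------------------
# Planting
# ---------------------------------------------------------------------------

@dataclass
class PlantedElement:
    element_class: str
    contig_id: str
    span: tuple[int, int]          # genome span; (-1, -1) for free virus
    template_id: str
    target_identity: float
    interruptions: tuple[int, int] = (0, 0)  # (nonsense, frameshift)
    transcribed: bool = False
    transcript_ids: list[str] = field(default_factory=list)


@dataclass
class GroundTruth:
    seed: int
    planted: list[PlantedElement] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        planted = [
            PlantedElement(
                element_class=p["element_class"], contig_id=p["contig_id"],
                span=tuple(p["span"]), template_id=p["template_id"],
                target_identity=p["target_identity"],
                interruptions=tuple(p["interruptions"]),
                transcribed=p["transcribed"],
                transcript_ids=list(p["transcript_ids"]),
            )
            for p in d["planted"]
        ]
        return cls(seed=d["seed"], planted=planted, config=d["config"])


#: stop codons in-frame with the following ORF, so the called ORF begins at
#: the gene's own ATG rather than an upstream ATG in the spacer
_STOP_CASSETTE = "TAATAGTGA"


def _orf_nt(protein: str, rng: np.random.Generator) -> str:
    body = back_translate(protein, rng)
    if not protein.startswith("M"):
        body = "ATG" + body
    return _STOP_CASSETTE + body + STOP_CODONS[rng.integers(len(STOP_CODONS))]


def _apply_interruptions(
    orf_nt: str, nonsense: int, frameshift: int, rng: np.random.Generator
) -> str:
    """Plant nonsense codons and single-nt deletions inside an ORF body."""
    s = orf_nt
    n_codons = len(s) // 3
    if nonsense:
        picks = sorted(
            rng.choice(np.arange(n_codons // 4, 3 * n_codons // 4),
                       size=nonsense, replace=False)
        )
        chars = list(s)
        for c in picks:
            chars[3 * c : 3 * c + 3] = list("TAA")
        s = "".join(chars)
    for k in range(frameshift):
        cut = int(len(s) * (k + 1) / (frameshift + 1.5))
        s = s[:cut] + s[cut + 1 :]
    return s


def _insert(
    genome: list[SequenceRecord], element_nt: str, rng: np.random.Generator,
    min_flank: int = 300,
) -> tuple[str, tuple[int, int]]:
    """Insert an element into a random contig keeping host flanks."""
    candidates = [
        (i, r) for i, r in enumerate(genome)
        if len(r.residues) >= 2 * min_flank
    ]
    if not candidates:
        raise ValueError("genome contigs too short for planting")
    i, rec = candidates[rng.integers(len(candidates))]
    pos = int(rng.integers(min_flank, len(rec.residues) - min_flank + 1))
    new = rec.residues[:pos] + element_nt + rec.residues[pos:]
    genome[i] = SequenceRecord(rec.id, new, rec.description, rec.alphabet)
    return rec.id, (pos, pos + len(element_nt))


def plant_element(
    genome: list[SequenceRecord],
    element_class: str,
    templates: dict[str, ProteinTemplate] | None = None,
    params: dict | None = None,
    seed: int = 0,
) -> tuple[list[SequenceRecord], list[SequenceRecord], PlantedElement]:
    """Plant one element; returns (genome', new transcripts, truth entry).

    Classes: EVE, VIRUS, MAVERICK, ERRANTIVIRUS, R1_LINE. The genome list is
    copied, never modified in place.
    """
    templates = templates or template_bundle()
    params = dict(params or {})
    genome = list(genome)
    rng = _rng(seed, 3, zlib.crc32(element_class.encode()) % (2 ** 16))
    identity = float(params.get("target_identity", 0.75))
    transcripts: list[SequenceRecord] = []

    if element_class == "EVE":
        tpl_id = params.get("template_id", "tpl_rhabdo_N")
        frag_aa = int(params.get("fragment_aa", 160))
        nonsense, frameshift = params.get("interruptions", (0, 0))
        transcribed = bool(params.get("transcribed", True))
        prot = mutate_protein(templates[tpl_id], identity, seed)
        if frag_aa < len(prot):
            off = int(rng.integers(0, len(prot) - frag_aa + 1))
            prot = prot[off : off + frag_aa]
        nt = _orf_nt(prot, rng)
        nt = _apply_interruptions(nt, nonsense, frameshift, rng)
        contig_id, span = _insert(genome, nt, rng)
        tx_ids = []
        if transcribed:
            tx_id = f"eve_tx_{seed}"
            transcripts.append(SequenceRecord(tx_id, nt))
            tx_ids = [tx_id]
        truth = PlantedElement(
            "EVE", contig_id, span, tpl_id, identity,
            (int(nonsense), int(frameshift)), transcribed, tx_ids,
        )
        return genome, transcripts, truth

    if element_class == "VIRUS":
        tpl_id = params.get("template_id", "tpl_rhabdo_L")
        prot = mutate_protein(templates[tpl_id], identity, seed)
        mrna = (
            _rand_nt(rng, 30) + _orf_nt(prot, rng) + _rand_nt(rng, 40)
        )
        tx_id = f"virus_tx_{seed}"
        transcripts.append(SequenceRecord(tx_id, mrna))
        truth = PlantedElement(
            "VIRUS", "", (-1, -1), tpl_id, identity, (0, 0), True, [tx_id]
        )
        return genome, transcripts, truth

    if element_class == "MAVERICK":
        lineage = int(params.get("lineage", 1))
        order = ["tpl_ATP", "tpl_ORF2", "tpl_INT", "tpl_CAP", "tpl_PRO",
                 "tpl_ORF6", "tpl_ORF7", "tpl_ORF8", "tpl_POLB"]
        parts = []
        for tpl_id in order:
            prot = mutate_protein(templates[tpl_id], identity, seed + zlib.crc32(tpl_id.encode()) % 997)
            orf = _orf_nt(prot, rng)
            if tpl_id == "tpl_POLB" and lineage == 2:
                orf = reverse_complement(orf)
            parts.append(orf)
            if tpl_id != order[-1]:
                parts.append(_rand_nt(rng, int(rng.integers(60, 121))))
        element = "".join(parts)
        contig_id, span = _insert(genome, element, rng)
        truth = PlantedElement(
            "MAVERICK", contig_id, span, f"maverick_lineage{lineage}",
            identity, (0, 0),
        )
        return genome, transcripts, truth

    if element_class == "ERRANTIVIRUS":
        nonsense, frameshift = params.get("interruptions", (0, 0))
        ltr = _rand_nt(rng, int(params.get("ltr_len", 300)))
        parts = [ltr, _rand_nt(rng, 80)]
        for tpl_id in ("tpl_gag", "tpl_pol", "tpl_env"):
            prot = mutate_protein(templates[tpl_id], identity, seed + zlib.crc32(tpl_id.encode()) % 997)
            orf = _orf_nt(prot, rng)
            if tpl_id == "tpl_env":
                orf = _apply_interruptions(orf, nonsense, frameshift, rng)
            parts.append(orf)
            parts.append(_rand_nt(rng, 180))
        parts.append(_rand_nt(rng, 55))
        parts.append(ltr)
        element = "".join(parts)
        contig_id, span = _insert(genome, element, rng)
        truth = PlantedElement(
            "ERRANTIVIRUS", contig_id, span, "errantivirus", identity,
            (int(nonsense), int(frameshift)),
        )
        return genome, transcripts, truth

    if element_class == "R1_LINE":
        parts = []
        for tpl_id in ("tpl_r1_orf1", "tpl_r1_orf2"):
            prot = mutate_protein(templates[tpl_id], identity, seed + zlib.crc32(tpl_id.encode()) % 997)
            parts.append(_orf_nt(prot, rng))
            parts.append(_rand_nt(rng, 30))
        element = "".join(parts[:-1])
        contig_id, span = _insert(genome, element, rng)
        truth = PlantedElement(
            "R1_LINE", contig_id, span, "r1_line", identity, (0, 0)
        )
        return genome, transcripts, truth

    raise ValueError(f"unknown element class {element_class!r}")


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    sources: Sequence[SequenceRecord],
    n: int | None = None,
    coverage: float | None = None,
    read_len: int = 150,
    paired: bool = False,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[FastqRead] | list[tuple[FastqRead, FastqRead]]:
    """Uniform-start read simulation (2 x 150 paired-end semantics when
    ``paired``); substitution errors at ``error_rate``; deterministic per
    seed."""
    if n is None and coverage is None:
        raise ValueError("give n or coverage")
    total = sum(len(s.residues) for s in sources)
    if n is None:
        n = int(round(coverage * total / (read_len * (2 if paired else 1))))
    rng = _rng(seed, 4)
    usable = [s for s in sources if len(s.residues) >= read_len]
    if not usable and n > 0:
        raise ValueError("read length exceeds every source length")
    weights = np.array([len(s.residues) - read_len + 1 for s in usable], float)
    weights /= weights.sum()
    out = []
    frag_len = int(2.6 * read_len)
    for i in range(n):
        src = usable[rng.choice(len(usable), p=weights)]
        seq = src.residues
        if paired and len(seq) >= frag_len:
            start = int(rng.integers(0, len(seq) - frag_len + 1))
            frag = seq[start : start + frag_len]
            r1 = _maybe_err(frag[:read_len], error_rate, rng)
            r2 = _maybe_err(reverse_complement(frag)[:read_len], error_rate, rng)
            out.append(
                (FastqRead(f"read_{i + 1}/1", r1, "I" * read_len),
                 FastqRead(f"read_{i + 1}/2", r2, "I" * read_len))
            )
        else:
            start = int(rng.integers(0, len(seq) - read_len + 1))
            r = _maybe_err(seq[start : start + read_len], error_rate, rng)
            out.append(FastqRead(f"read_{i + 1}", r, "I" * read_len))
    return out


def _maybe_err(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < error_rate:
            chars[i] = rng.choice([c for c in "ACGT" if c != chars[i]])
    return "".join(chars)
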