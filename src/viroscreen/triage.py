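"""Hit triage: the decision procedure that separates adventitious viruses
from look-alikes.

Every translated-search hit with E < 0.1 is assigned exactly one verdict, in
fixed precedence order:

1. HOST - host reference proteins align tens of orders of magnitude better
   than the best viral protein (differential homology).
2. TRANSPOSON_* - the region overlaps an annotated Maverick, errantivirus or
   R1-LINE element; virus-like proteins inside transposons do not indicate
   contamination.
3. EVE - the hit derives from an RNA virus with no DNA replication stage yet
   the region is present in the *genome* assembly with host flanks: it must
   be an endogenous viral element, not a replicating virus.
4. PUTATIVE_VIRUS - a significant viral hit that survives 1-3; notably an
   RNA-virus hit present in the transcriptome but absent from the genome.
5. UNRESOLVED - anything else.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum

import edlib

from .elements import ElementAnnotation, ElementClass
from .motifs import MotifDefinition, MotifHit, annotate_motifs, motif_library
from .search import Hsp, ScoringScheme, evalue, smith_waterman_protein, tblastn_search
from .seqio import SequenceRecord, reverse_complement, translate
from .vpd import RNA_NO_DNA_STAGE, ViralProteinEntry

log = logging.getLogger(__name__)

E_FLOOR = 1e-300  # floor before log10 to avoid -inf


class Verdict(str, Enum):
    HOST = "HOST"
    EVE = "EVE"
    TRANSPOSON_MAVERICK = "TRANSPOSON_MAVERICK"
    TRANSPOSON_ERRANTIVIRUS = "TRANSPOSON_ERRANTIVIRUS"
    TRANSPOSON_R1_LINE = "TRANSPOSON_R1_LINE"
    PUTATIVE_VIRUS = "PUTATIVE_VIRUS"
    UNRESOLVED = "UNRESOLVED"


_ELEMENT_VERDICT = {
    ElementClass.MAVERICK: Verdict.TRANSPOSON_MAVERICK,
    ElementClass.ERRANTIVIRUS: Verdict.TRANSPOSON_ERRANTIVIRUS,
    ElementClass.LTR_RETROTRANSPOSON: Verdict.TRANSPOSON_ERRANTIVIRUS,
    ElementClass.R1_LINE: Verdict.TRANSPOSON_R1_LINE,
}


@dataclass
class TriageVerdict:
    contig_id: str
    region: tuple[int, int]
    verdict: Verdict
    best_viral_hit: Hsp
    best_host_hit: Hsp | None = None
    delta_log10_e: float | None = None
    evidence: list[str] = field(default_factory=list)
    eve_call: "EveCall | None" = None


@dataclass
class EveCall:
    contig_id: str
    region: tuple[int, int]
    closest_virus: str
    closest_protein: str
    genome_present: bool = True   # definitional: every EVE is genomic
    transcriptome_present: bool = False
    nonsense_count: int = 0
    frameshift_count: int = 0
    rpkm: float | None = None
    reads_mapped: int | None = None


@dataclass
class TriageContext:
    """Everything classify_hit needs besides the hit itself."""

    genome: dict[str, SequenceRecord]
    transcriptome: dict[str, SequenceRecord]
    viral_refs: list[SequenceRecord]
    host_refs: list[SequenceRecord]
    viral_meta: dict[str, ViralProteinEntry]
    elements: dict[str, list[ElementAnnotation]] = field(default_factory=dict)
    e_cutoff: float = 0.1
    delta_threshold: float = 20.0
    min_host_flank: int = 200
    scheme: ScoringScheme | None = None

    def __post_init__(self) -> None:
        if self.scheme is None:
            self.scheme = ScoringScheme.blosum62()


# ---------------------------------------------------------------------------
# Differential homology
# ---------------------------------------------------------------------------

def delta_log10_e(e_viral: float, e_host: float) -> float:
    return math.log10(max(e_viral, E_FLOOR)) - math.log10(max(e_host, E_FLOOR))


def differential_homology(
    region_aa: str,
    viral_refs: list[SequenceRecord],
    host_refs: list[SequenceRecord],
    delta_threshold: float = 20.0,
    scheme: ScoringScheme | None = None,
) -> tuple[str, float | None, Hsp | None]:
    """HOST when host proteins beat the best viral protein by
    >= ``delta_threshold`` orders of magnitude in E-value; VIRAL_LIKE
    otherwise. Returns (component, delta, best host hsp)."""
    scheme = scheme or ScoringScheme.blosum62()
    if not host_refs:
        return "VIRAL_LIKE", None, None

    def best_e(refs: list[SequenceRecord]) -> tuple[float, Hsp | None]:
        n_db = sum(len(r.residues) for r in refs)
        best, best_hsp = math.inf, None
        for ref in refs:
            hsp = smith_waterman_protein(
                region_aa, ref.residues, scheme, subject_id=ref.id
            )
            if hsp is None:
                continue
            _, e = evalue(hsp.raw_score, len(region_aa), n_db, scheme)
            if e < best:
                best, best_hsp = e, hsp
        return best, best_hsp

    e_viral, _ = best_e(viral_refs)
    e_host, host_hsp = best_e(host_refs)
    if not math.isfinite(e_host) or e_host > 10:
        return "VIRAL_LIKE", None, None
    if not math.isfinite(e_viral):
        return "HOST", math.inf, host_hsp
    delta = delta_log10_e(e_viral, e_host)
    return ("HOST" if delta >= delta_threshold else "VIRAL_LIKE"), delta, host_hsp


# ---------------------------------------------------------------------------
# Sequence presence / location helpers
# ---------------------------------------------------------------------------

def locate_in_db(
    region_nt: str,
    records: dict[str, SequenceRecord] | list[SequenceRecord],
    max_divergence: float = 0.10,
) -> tuple[str, int, int] | None:
    """Best near-exact location of a nucleotide region in a sequence set
    (either strand), or None. Infix alignment via edlib."""
    if isinstance(records, dict):
        records = list(records.values())
    best = None
    limit = int(max_divergence * len(region_nt))
    for rec in records:
        for probe in (region_nt, reverse_complement(region_nt)):
            res = edlib.align(probe, rec.residues, task="locations", mode="HW", k=limit)
            if res["editDistance"] == -1:
                continue
            dist = res["editDistance"]
            if best is None or dist < best[0]:
                s, e = res["locations"][0]
                best = (dist, rec.id, s, e + 1)
    if best is None:
        return None
    return best[1], best[2], best[3]


def present_in_db(
    region_nt: str,
    records: dict[str, SequenceRecord] | list[SequenceRecord],
    max_divergence: float = 0.10,
) -> bool:
    return locate_in_db(region_nt, records, max_divergence) is not None


# ---------------------------------------------------------------------------
# Interruption counting
# ---------------------------------------------------------------------------

def count_interruptions(
    genomic_region: str,
    reference_protein: SequenceRecord,
    scheme: ScoringScheme | None = None,
) -> tuple[int, int]:
    """(nonsense_count, frameshift_count) of a viral ORF relic.

    Nonsense mutations are internal stop codons within the aligned span in
    the hit frame (stops inside HSP alignments plus stops in the same-frame
    gaps between chained HSPs). Frameshifts are frame transitions among
    chained co-linear HSPs of the reference on the region.
    """
    scheme = scheme or ScoringScheme.blosum62()
    region = SequenceRecord("region", genomic_region)
    hsps = tblastn_search(
        [reference_protein], [region], scheme, e_cutoff=10.0
    )
    if not hsps:
        return 0, 0
    strand = 1 if hsps[0].frame > 0 else -1
    same = sorted(
        (h for h in hsps if (1 if h.frame > 0 else -1) == strand),
        key=lambda h: h.q_start,
    )
    chained: list[Hsp] = []
    for h in same:
        if not chained:
            chained.append(h)
            continue
        prev = chained[-1]
        q_ok = h.q_start >= prev.q_start and h.q_end >= prev.q_end
        s_ok = (h.s_start >= prev.s_start) if strand > 0 else (h.s_end <= prev.s_end)
        if q_ok and s_ok:
            chained.append(h)
    nonsense = sum(h.s_aln.count("*") for h in chained)
    frameshift = sum(
        1 for a, b in zip(chained, chained[1:]) if a.frame != b.frame
    )
    # stops in the same-frame gap between consecutive chained HSPs
    for a, b in zip(chained, chained[1:]):
        if a.frame != b.frame:
            continue
        if strand > 0:
            gap_lo, gap_hi = a.s_end, b.s_start
        else:
            gap_lo, gap_hi = b.s_end, a.s_start
        if gap_hi - gap_lo <= 0:
            continue
        sub = genomic_region[gap_lo:gap_hi]
        if strand < 0:
            sub = reverse_complement(sub)
        # keep the codon phase of the flanking HSPs
        nonsense += translate(sub, 1).count("*") if len(sub) >= 3 else 0
    return nonsense, frameshift


def _resolve_source(subject_id: str, ctx: TriageContext, hint: str) -> str:
    in_g = subject_id in ctx.genome
    in_t = subject_id in ctx.transcriptome
    if in_g and in_t:
        return hint
    if in_g:
        return "genome"
    if in_t:
        return "transcriptome"
    raise KeyError(f"subject {subject_id!r} in neither assembly")


def _region_protein(
    hit: Hsp, region: tuple[int, int], subject: SequenceRecord,
    pad: int = 450,
) -> str:
    """Translation of the hit's reading frame over the region expanded by
    ``pad`` nt each side - the predicted protein the differential-homology
    comparison is run on (a conserved host gene aligns to host references
    far beyond the viral-domain HSP)."""
    s = subject.residues
    n = len(s)
    a = max(0, region[0] - pad)
    b = min(n, region[1] + pad)
    sub = s[a:b]
    f = hit.frame
    if f == 0:
        return hit.s_aln.replace("-", "")
    if f > 0:
        off = ((f - 1) - a) % 3
        prot = translate(sub, off + 1)
    else:
        off = ((-f - 1) - (n - b)) % 3
        prot = translate(sub, -(off + 1))
    return prot.replace("*", "X")


# ---------------------------------------------------------------------------
# EVE calling
# ---------------------------------------------------------------------------

def call_eve(
    hit: Hsp,
    hit_source: str,  # "genome" or "transcriptome"
    ctx: TriageContext,
    region: tuple[int, int] | None = None,
) -> EveCall | None:
    """EVE iff the hit's virus has an RNA genome with no DNA stage AND the
    region is present in the genome assembly with >= min_host_flank nt of
    non-viral sequence on at least one side."""
    meta = ctx.viral_meta.get(hit.query_id)
    if meta is None or meta.genome_material not in RNA_NO_DNA_STAGE:
        return None
    region = region or (hit.s_start, hit.s_end)
    hit_source = _resolve_source(hit.subject_id, ctx, hit_source)
    if hit_source == "genome":
        contig = ctx.genome[hit.subject_id]
        loc = (hit.subject_id, region[0], region[1])
    else:
        tx = ctx.transcriptome[hit.subject_id]
        region_nt = tx.residues[region[0] : region[1]]
        loc = locate_in_db(region_nt, ctx.genome)
        if loc is None:
            return None  # transcriptome-only: escalates to PUTATIVE_VIRUS
        contig = ctx.genome[loc[0]]
    left_flank = loc[1]
    right_flank = len(contig.residues) - loc[2]
    if max(left_flank, right_flank) < ctx.min_host_flank:
        return None
    region_nt = contig.residues[loc[1] : loc[2]]
    tx_present = present_in_db(region_nt, ctx.transcriptome) if ctx.transcriptome else False
    ref = next(
        (r for r in ctx.viral_refs if r.id == hit.query_id), None
    )
    nonsense = frameshift = 0
    if ref is not None:
        pad = 60
        sub = contig.residues[max(0, loc[1] - pad) : loc[2] + pad]
        nonsense, frameshift = count_interruptions(sub, ref, ctx.scheme)
    return EveCall(
        contig_id=loc[0],
        region=(loc[1], loc[2]),
        closest_virus=meta.virus,
        closest_protein=meta.protein_id,
        genome_present=True,
        transcriptome_present=tx_present,
        nonsense_count=nonsense,
        frameshift_count=frameshift,
    )


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_hit(
    hit: Hsp, hit_source: str, ctx: TriageContext,
    region: tuple[int, int] | None = None,
) -> TriageVerdict:
    """One verdict per hit region, first match wins (see module docstring)."""
    region = region or (hit.s_start, hit.s_end)
    hit_source = _resolve_source(hit.subject_id, ctx, hit_source)
    evidence: list[str] = [
        f"best viral hit {hit.query_id} E={hit.e_value:.3g} "
        f"({hit.pct_identity:.0f}% id over {hit.aligned_len} aa)"
    ]
    subject = (ctx.genome if hit_source == "genome"
               else ctx.transcriptome)[hit.subject_id]
    region_aa = _region_protein(hit, region, subject)

    # 1. differential homology vs host references
    if ctx.host_refs:
        component, delta, host_hsp = differential_homology(
            region_aa, ctx.viral_refs, ctx.host_refs,
            ctx.delta_threshold, ctx.scheme,
        )
        if component == "HOST":
            evidence.append(
                f"host protein {host_hsp.subject_id if host_hsp else '?'} "
                f"better by {delta:.1f} orders of magnitude"
            )
            return TriageVerdict(
                hit.subject_id, region, Verdict.HOST, hit, host_hsp, delta,
                evidence,
            )
    else:
        component, delta, host_hsp = "VIRAL_LIKE", None, None
        evidence.append("no host refs")

    # 2. element annotations
    anns = ctx.elements.get(hit.subject_id, [])
    for ann in anns:
        if ann.element_class in _ELEMENT_VERDICT and ann.overlaps(*region):
            evidence.append(
                f"region inside {ann.element_class.value} "
                f"[{ann.start}, {ann.end})"
            )
            return TriageVerdict(
                hit.subject_id, region, _ELEMENT_VERDICT[ann.element_class],
                hit, host_hsp, delta, evidence,
            )

    # 3. EVE
    eve = call_eve(hit, hit_source, ctx, region)
    if eve is not None:
        evidence.append(
            f"RNA-virus relic present in genome with host flanks; "
            f"transcribed={eve.transcriptome_present}"
        )
        return TriageVerdict(
            hit.subject_id, region, Verdict.EVE, hit, host_hsp, delta,
            evidence, eve_call=eve,
        )

    # 4. putative adventitious virus
    if hit.e_value < ctx.e_cutoff:
        meta = ctx.viral_meta.get(hit.query_id)
        if meta is not None and meta.genome_material in RNA_NO_DNA_STAGE \
                and hit_source == "transcriptome":
            evidence.append(
                "RNA-virus hit present in transcriptome, absent from genome"
            )
        elif hit_source == "genome":
            evidence.append("viral hit without host flanks in genome")
        return TriageVerdict(
            hit.subject_id, region, Verdict.PUTATIVE_VIRUS, hit, host_hsp,
            delta, evidence,
        )

    return TriageVerdict(
        hit.subject_id, region, Verdict.UNRESOLVED, hit, host_hsp, delta,
        evidence + ["no rule matched"],
    )


def cluster_hits(hsps: list[Hsp]) -> list[tuple[str, int, int, list[Hsp]]]:
    """Group hits on one subject by >= 1 nt overlap into regions."""
    by_subject: dict[str, list[Hsp]] = {}
    for h in hsps:
        by_subject.setdefault(h.subject_id, []).append(h)
    regions = []
    for subject in sorted(by_subject):
        hits = sorted(by_subject[subject], key=lambda h: (h.s_start, h.s_end))
        cur: list[Hsp] = []
        lo = hi = 0
        for h in hits:
            if cur and h.s_start < hi:
                cur.append(h)
                hi = max(hi, h.s_end)
            else:
                if cur:
                    regions.append((subject, lo, hi, cur))
                cur, lo, hi = [h], h.s_start, h.s_end
        if cur:
            regions.append((subject, lo, hi, cur))
    return regions


def triage_hits(
    hsps: list[Hsp], hit_source: str, ctx: TriageContext
) -> list[TriageVerdict]:
    """Cluster hits into regions and classify each region once, using its
    most significant hit as the representative. Totality: every hit with
    E < cutoff belongs to exactly one region and verdict."""
    verdicts = []
    for subject, lo, hi, hits in cluster_hits(hsps):
        best = min(hits, key=lambda h: (h.e_value, -h.raw_score))
        v = classify_hit(best, hit_source, ctx, region=(lo, hi))
        if len(hits) > 1:
            v.evidence.append(f"region merges {len(hits)} HSPs")
        verdicts.append(v)
    return verdicts
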