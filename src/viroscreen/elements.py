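"""Architecture classifiers for virus-like mobile elements.

Three element families that routinely produce viral-protein hits in insect
genomes are recognised by their ORF architecture rather than by homology
alone:

* Maverick/Polinton: a giant DNA transposon carrying 6-10 ORFs of which five
  hallmark roles (ATPase, integrase, adenain-like protease, family-B DNA
  polymerase, capsid-like/PLA2) must co-occur.
* errantivirus: an insect LTR retroelement with gag, pol (RT + integrase)
  and a third env-like ORF carrying a signal sequence, a C-terminal
  transmembrane stretch and a basic cleavage site; without the env ORF the
  element is called a plain LTR retrotransposon.
* R1 LINE: a non-LTR element whose second ORF carries an RT core followed by
  a superfamily-1 helicase domain in its C-terminal third.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import edlib

from .motifs import MotifDefinition, MotifHit, annotate_motifs, motif_library
from .seqio import OrfCall, find_orfs, reverse_complement

log = logging.getLogger(__name__)


class ElementClass(str, Enum):
    MAVERICK = "MAVERICK"
    ERRANTIVIRUS = "ERRANTIVIRUS"
    R1_LINE = "R1_LINE"
    LTR_RETROTRANSPOSON = "LTR_RETROTRANSPOSON"
    PARTIAL = "PARTIAL"


MAVERICK_HALLMARKS = ("ATP", "INT", "PRO", "POLB", "CAP")


@dataclass
class ElementAnnotation:
    contig_id: str
    start: int
    end: int
    element_class: ElementClass
    orfs: list[tuple[OrfCall, str]] = field(default_factory=list)  # (orf, role)
    intact: bool = True
    evidence: list[str] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return self.start, self.end

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end

    def as_bed_row(self) -> tuple:
        hallmark = sum(1 for _, r in self.orfs if r in MAVERICK_HALLMARKS)
        strand = self.orfs[0][0].strand if self.orfs else "+"
        return (self.contig_id, self.start, self.end,
                self.element_class.value, hallmark, strand)


@dataclass
class LtrPair:
    left: tuple[int, int]
    right: tuple[int, int]
    pct_identity: float
    same_orientation: bool = True


@dataclass
class EnvFeatures:
    has_signal_seq: bool = False
    has_cterm_tm: bool = False
    has_basic_cleavage: bool = False
    signal_pos: tuple[int, int] | None = None
    tm_pos: tuple[int, int] | None = None
    cleavage_pos: tuple[int, int] | None = None

    @property
    def all_present(self) -> bool:
        return self.has_signal_seq and self.has_cterm_tm and self.has_basic_cleavage


# Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}


def _hydropathy_windows(aa: str, window: int, threshold: float):
    """Yield (start, end) of windows whose mean Kyte-Doolittle value exceeds
    the threshold."""
    vals = [KYTE_DOOLITTLE.get(c, 0.0) for c in aa]
    for i in range(0, len(vals) - window + 1):
        if sum(vals[i : i + window]) / window > threshold:
            yield (i, i + window)


def env_features(
    aa: str,
    hydro_threshold: float = 1.6,
    signal_window: int = 8,
    signal_region: int = 30,
    tm_window: int = 19,
    tm_region: int = 60,
) -> EnvFeatures:
    """Structural features of an env-like membrane fusion protein.

    Signal sequence: a hydrophobic window (mean KD > threshold over
    ``signal_window`` residues) within the first ``signal_region`` residues.
    C-terminal TM: a hydrophobic window of ``tm_window`` residues within the
    last ``tm_region``. Basic cleavage site: R-X-(K/R)-R, or >= 3 basic
    residues in any 5-residue window, located N-terminal of the TM.
    """
    if len(aa) < 100:
        raise ValueError("env feature scan requires a protein of >= 100 aa")
    aa = aa.upper()
    feats = EnvFeatures()
    for s, e in _hydropathy_windows(aa[:signal_region], signal_window, hydro_threshold):
        feats.has_signal_seq = True
        feats.signal_pos = (s, e)
        break
    tail_off = max(0, len(aa) - tm_region)
    for s, e in _hydropathy_windows(aa[tail_off:], tm_window, hydro_threshold):
        feats.has_cterm_tm = True
        feats.tm_pos = (tail_off + s, tail_off + e)
        break
    limit = feats.tm_pos[0] if feats.tm_pos else len(aa)
    import re

    m = re.search("R.[KR]R", aa[:limit])
    if m:
        feats.has_basic_cleavage = True
        feats.cleavage_pos = (m.start(), m.end())
    else:
        basics = [c in "KR" for c in aa[:limit]]
        for i in range(len(basics) - 4):
            if sum(basics[i : i + 5]) >= 3:
                feats.has_basic_cleavage = True
                feats.cleavage_pos = (i, i + 5)
                break
    return feats


# ---------------------------------------------------------------------------
# LTR detection
# ---------------------------------------------------------------------------

def detect_ltrs(
    contig: str,
    min_len: int = 150,
    min_identity: float = 90.0,
    max_element_span: int = 12000,
    anchor_k: int = 11,
) -> LtrPair | None:
    """Best same-orientation direct repeat pair of an LTR element.

    Shared k-mer anchors on a common diagonal delimit candidate repeats; the
    two copies are then aligned (edlib, global) to score identity. Returns
    the pair maximising length x identity, or None.
    """
    s = contig.upper()
    n = len(s)
    if n < 2 * min_len:
        return None
    pos: dict[str, list[int]] = {}
    for i in range(n - anchor_k + 1):
        pos.setdefault(s[i : i + anchor_k], []).append(i)
    # diagonal -> anchor start positions of the left copy
    diags: dict[int, list[int]] = {}
    for plist in pos.values():
        if len(plist) < 2 or len(plist) > 50:
            continue
        for a in range(len(plist)):
            for b in range(a + 1, len(plist)):
                d = plist[b] - plist[a]
                if min_len <= d <= max_element_span:
                    diags.setdefault(d, []).append(plist[a])
    if not diags:
        return None
    # merge nearby diagonals (indel wobble)
    keys = sorted(diags)
    clusters: list[list[int]] = []
    cur = [keys[0]]
    for k in keys[1:]:
        if k - cur[-1] <= 20:
            cur.append(k)
        else:
            clusters.append(cur)
            cur = [k]
    clusters.append(cur)
    best: LtrPair | None = None
    best_key = -1.0
    for cluster in clusters:
        d0 = int(round(sum(cluster) / len(cluster)))
        positions = sorted({a for d in cluster for a in diags[d]})
        # dense anchor runs isolate the actual repeat block from stray
        # chance anchors on nearby diagonals
        runs: list[list[int]] = [[positions[0]]]
        for p in positions[1:]:
            if p - runs[-1][-1] <= 50:
                runs[-1].append(p)
            else:
                runs.append([p])
        for run in runs:
            lo = run[0]
            hi = run[-1] + anchor_k
            if hi - lo < min_len:
                pad = (min_len - (hi - lo) + 1) // 2
                lo = max(0, lo - pad)
                hi = min(n, hi + pad)
            hi = min(hi, lo + d0)  # copies must not overlap
            if hi - lo < min_len:
                continue
            r_lo = lo + d0
            right_seq = s[r_lo : r_lo + (hi - lo)]
            if r_lo < hi or len(right_seq) < min_len:
                continue
            left_seq = s[lo:hi]
            res = edlib.align(left_seq, right_seq, task="distance", mode="NW")
            aln_len = max(len(left_seq), len(right_seq))
            ident = 100.0 * (aln_len - res["editDistance"]) / aln_len
            if ident < min_identity:
                continue
            key = (hi - lo) * ident
            if key > best_key:
                best_key = key
                best = LtrPair(
                    left=(lo, hi),
                    right=(r_lo, r_lo + len(right_seq)),
                    pct_identity=round(ident, 2),
                )
    return best


# ---------------------------------------------------------------------------
# Role assignment from motif content
# ---------------------------------------------------------------------------

def _orf_motifs(orf: OrfCall, library) -> set[str]:
    return {h.name for h in annotate_motifs(orf.aa_seq, library)}


def _assign_roles(
    orfs: list[OrfCall], library
) -> tuple[dict[str, OrfCall], list[str]]:
    """Best hallmark-role assignment per ORF; conflicts keep the ORF with
    more motif evidence (then the longer ORF) and are logged."""
    evidence: list[str] = []
    claims: dict[str, list[tuple[int, int, OrfCall]]] = {}
    for orf in orfs:
        names = _orf_motifs(orf, library)
        role_scores: dict[str, int] = {}
        if "WALKER_A" in names and "WALKER_B" in names:
            role_scores["ATP"] = 2
        if "INTEGRASE_DDE" in names:
            role_scores["INT"] = 1 + ("CHROMO" in names)
        if "ADENAIN_TRIAD" in names:
            role_scores["PRO"] = 1
        if "POLB_CORE" in names:
            role_scores["POLB"] = 1
        if "PLA2_CATALYTIC" in names:
            role_scores["CAP"] = 1
        for role, score in role_scores.items():
            claims.setdefault(role, []).append((score, orf.aa_len, orf))
    # global greedy assignment: strongest evidence first, one role per ORF
    flat = [
        (score, aa_len, role, orf)
        for role, cands in claims.items()
        for score, aa_len, orf in cands
    ]
    flat.sort(key=lambda t: (-t[0], -t[1], t[2], t[3].start))
    roles: dict[str, OrfCall] = {}
    taken: set[int] = set()
    for score, aa_len, role, orf in flat:
        if role in roles or id(orf) in taken:
            continue
        roles[role] = orf
        taken.add(id(orf))
    for role, cands in claims.items():
        if len(cands) > 1:
            evidence.append(
                f"role {role}: {len(cands)} candidate ORFs, kept the one at "
                f"{roles[role].start if role in roles else '?'}"
            )
    return roles, evidence


def classify_maverick(
    orfs: list[OrfCall],
    library: list[MotifDefinition] | None = None,
    window: int = 25000,
) -> ElementAnnotation | None:
    """Maverick/Polinton call: >= 5 hallmark roles co-occurring in a window.

    Fewer than five (but at least two) hallmark roles yield a PARTIAL
    annotation. The orientation of the POLB ORF relative to the others is
    recorded (lineage-1: same strand; lineage-2: opposite strand).
    """
    if not orfs:
        return None
    library = library if library is not None else motif_library()
    roles, evidence = _assign_roles(orfs, library)
    hall = {r: o for r, o in roles.items() if r in MAVERICK_HALLMARKS}
    if len(hall) < 2:
        return None
    starts = [o.start for o in hall.values()]
    ends = [o.end for o in hall.values()]
    if max(ends) - min(starts) > window:
        evidence.append("hallmark ORFs exceed the co-occurrence window")
        return None
    contig_id = orfs[0].contig_id
    role_list = sorted(hall.items(), key=lambda kv: kv[1].start)
    annotated = [(o, r) for r, o in role_list]
    if len(hall) < 5:
        return ElementAnnotation(
            contig_id, min(starts), max(ends), ElementClass.PARTIAL,
            annotated, True,
            evidence + [f"only {len(hall)}/5 hallmark roles present"],
        )
    span_lo, span_hi = min(starts), max(ends)
    in_window = [o for o in orfs if o.start >= span_lo and o.end <= span_hi]
    n_orfs = len(in_window)
    if not 6 <= n_orfs <= 10:
        evidence.append(f"total ORF count {n_orfs} outside the typical 6-10")
    other_strands = {o.strand for r, o in hall.items() if r != "POLB"}
    if len(other_strands) == 1 and hall["POLB"].strand not in other_strands:
        evidence.append("lineage-2 orientation: POLB on the opposite strand")
    else:
        evidence.append("lineage-1 orientation: all hallmark ORFs co-oriented")
    return ElementAnnotation(
        contig_id, span_lo, span_hi, ElementClass.MAVERICK,
        annotated, True, evidence + [f"{n_orfs} ORFs in element span"],
    )


def classify_errantivirus(
    contig: str,
    orfs: list[OrfCall],
    ltr: LtrPair | None = None,
    library: list[MotifDefinition] | None = None,
    min_gag_aa: int = 200,
) -> ElementAnnotation | None:
    """Errantivirus call: ordered gag / pol / env ORFs, LTRs when present.

    pol requires RT core + integrase motifs; env requires all three
    membrane-fusion features. gag is positional: a large ORF upstream of pol
    without pol/env evidence. Without an env-like ORF the element is a
    LTR_RETROTRANSPOSON, never an errantivirus. ``intact`` is False when a
    role is carried by a chain of interrupted ORF fragments.
    """
    if not orfs:
        return None
    library = library if library is not None else motif_library()
    lo, hi = (ltr.left[0], ltr.right[1]) if ltr else (0, len(contig))
    inside = [o for o in orfs if o.start >= lo and o.end <= hi]
    if not inside:
        return None
    contig_id = orfs[0].contig_id
    merged = _merge_interrupted(inside)
    pol = env = gag = None
    pol_chain = env_chain = gag_chain = None
    for chain in merged:
        aa = "".join(o.aa_seq for o in chain)
        names = {h.name for h in annotate_motifs(aa, library)}
        if pol is None and "RT_CORE" in names and "INTEGRASE_DDE" in names:
            pol, pol_chain = chain[0], chain
            continue
        if env is None and len(aa) >= 100:
            feats = env_features(aa)
            if feats.all_present:
                env, env_chain = chain[0], chain
                continue
    for chain in merged:
        aa_len = sum(o.aa_len for o in chain)
        if chain[0] in (pol, env):
            continue
        if aa_len >= min_gag_aa and (pol is None or chain[0].start < pol.start):
            if gag is None or chain[0].start < gag.start:
                gag, gag_chain = chain[0], chain
    if not (gag and pol):
        return None
    evidence = []
    if ltr:
        evidence.append(
            f"LTR pair {ltr.left}-{ltr.right} at {ltr.pct_identity}% identity"
        )
    if env is None or not (gag.start < pol.start < env.start):
        if env is not None:
            return None
        roles = [(gag, "GAG"), (pol, "POL")]
        return ElementAnnotation(
            contig_id, min(gag.start, pol.start), max(gag.end, pol.end),
            ElementClass.LTR_RETROTRANSPOSON, roles, True,
            evidence + ["no env-like ORF: typical LTR retrotransposon"],
        )
    intact = all(len(c) == 1 for c in (gag_chain, pol_chain, env_chain))
    if not intact:
        evidence.append("role ORF interrupted by stop/frameshift")
    roles = [(gag, "GAG"), (pol, "POL"), (env, "ENV")]
    start = ltr.left[0] if ltr else gag.start
    end = ltr.right[1] if ltr else env.end
    return ElementAnnotation(
        contig_id, start, end, ElementClass.ERRANTIVIRUS, roles, intact,
        evidence + ["intact gag/pol/env" if intact else "interrupted ORFs"],
    )


def _merge_interrupted(
    orfs: list[OrfCall], max_gap_nt: int = 150, max_overlap_nt: int = 90
) -> list[list[OrfCall]]:
    """Chain consecutive same-strand ORF fragments into candidate interrupted
    genes.

    A nonsense mutation splits a gene into two same-frame ORFs separated by
    a few nt; a frameshift yields a downstream fragment in a different frame
    that may slightly overlap or trail the first. Fragments are chained when
    the gap is within [-max_overlap_nt, max_gap_nt]. A chain of length 1 is
    an intact ORF.
    """
    chains: list[list[OrfCall]] = []
    by_strand: dict[str, list[OrfCall]] = {"+": [], "-": []}
    for o in sorted(orfs, key=lambda o: o.start):
        by_strand[o.strand].append(o)
    for strand, lst in by_strand.items():
        cur: list[OrfCall] = []
        for o in lst:
            if cur and -max_overlap_nt <= o.start - cur[-1].end <= max_gap_nt:
                cur.append(o)
            else:
                if cur:
                    chains.append(cur)
                cur = [o]
        if cur:
            chains.append(cur)
    chains.sort(key=lambda c: c[0].start)
    return chains


def classify_r1_line(
    orfs: list[OrfCall],
    library: list[MotifDefinition] | None = None,
    cterm_fraction: float = 0.60,
    max_orf_gap: int = 2000,
) -> ElementAnnotation | None:
    """R1 LINE call: two-ORF architecture with an ORF2 carrying an RT core
    followed by SF1-helicase motifs in its C-terminal third. No LTRs are
    required (non-LTR element)."""
    if not orfs:
        return None
    library = library if library is not None else motif_library()
    contig_id = orfs[0].contig_id
    for orf2 in sorted(orfs, key=lambda o: -o.aa_len):
        hits = annotate_motifs(orf2.aa_seq, library)
        rt = [h for h in hits if h.name == "RT_CORE"]
        hel = [h for h in hits if h.name == "SF1_HELICASE"]
        if not rt or not hel:
            continue
        cterm = [h for h in hel if h.start >= cterm_fraction * orf2.aa_len]
        if not cterm:
            continue
        if not any(h.start < cterm[0].start for h in rt):
            continue
        # upstream companion ORF on the same strand
        if orf2.strand == "+":
            partners = [
                o for o in orfs
                if o is not orf2 and o.strand == "+"
                and o.end <= orf2.start and orf2.start - o.end <= max_orf_gap
            ]
        else:
            partners = [
                o for o in orfs
                if o is not orf2 and o.strand == "-"
                and o.start >= orf2.end and o.start - orf2.end <= max_orf_gap
            ]
        if not partners:
            continue
        orf1 = max(partners, key=lambda o: o.aa_len)
        lo = min(orf1.start, orf2.start)
        hi = max(orf1.end, orf2.end)
        return ElementAnnotation(
            contig_id, lo, hi, ElementClass.R1_LINE,
            [(orf1, "ORF1"), (orf2, "ORF2")], True,
            [
                f"RT core at aa {rt[0].start}, SF1 helicase at aa "
                f"{cterm[0].start}/{orf2.aa_len}",
            ],
        )
    return None


# ---------------------------------------------------------------------------
# Contig-level orchestration
# ---------------------------------------------------------------------------

def annotate_elements(
    contig_id: str,
    contig: str,
    library: list[MotifDefinition] | None = None,
    min_orf_aa: int = 100,
    ltr_params: dict | None = None,
) -> list[ElementAnnotation]:
    """Scan one contig for Maverick, errantivirus and R1 LINE architectures."""
    library = library if library is not None else motif_library()
    orfs = find_orfs(contig, min_aa_len=min_orf_aa, contig_id=contig_id)
    if not orfs:
        return []
    out: list[ElementAnnotation] = []
    mav = classify_maverick(orfs, library)
    if mav and mav.element_class is ElementClass.MAVERICK:
        out.append(mav)
    ltr = detect_ltrs(contig, **(ltr_params or {}))
    erv = classify_errantivirus(contig, orfs, ltr, library)
    if erv:
        out.append(erv)
    r1 = classify_r1_line(orfs, library)
    if r1:
        out.append(r1)
    if not out and mav:  # PARTIAL maverick only if nothing stronger
        out.append(mav)
    return out


def elements_to_bed(annotations: list[ElementAnnotation]) -> str:
    lines = []
    for a in annotations:
        c, s, e, name, score, strand = a.as_bed_row()
        lines.append(f"{c}\t{s}\t{e}\t{name}\t{score}\t{strand}")
    return "\n".join(lines) + ("\n" if lines else "")
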