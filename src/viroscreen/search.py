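"""Translated homology search: protein queries against six-frame translations.

The engine follows the classic seed-and-extend design: 3-mer neighborhood
words seed ungapped X-drop extensions, and extensions that reach a trigger
score are refined by banded affine-gap (Gotoh) local alignment. Significance
uses Karlin-Altschul statistics: bit = (lambda*S - ln K)/ln 2 and
E = m*n*2**(-bit) with m the query length in residues and n the summed
nucleotide length of the subject set. Gapped searches use the published
BLOSUM62 / gap 11,1 constants (lambda = 0.267, K = 0.041); raw m and n are
used rather than length-adjusted effective sizes, so absolute E-values are
slightly conservative relative to production BLAST.

A full Smith-Waterman (Gotoh) aligner is included as the exact local-alignment
oracle the seeded engine is validated against. A gap of length g costs
gap_open + gap_extend * g.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import SequenceRecord, six_frame

log = logging.getLogger(__name__)

NEG = -(10 ** 9)

#: Robinson & Robinson amino-acid background frequencies (order ARNDCQEGHILKMFPSTWYV)
ROBINSON_FREQS = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}

STANDARD_AA = "ARNDCQEGHILKMFPSTWYV"


@dataclass
class ScoringScheme:
    """Substitution matrix plus affine gap costs and Karlin-Altschul constants."""

    matrix: np.ndarray            # square, indexed by ``alphabet``
    alphabet: str
    gap_open: int = 11
    gap_extend: int = 1
    lambda_: float = 0.267        # gapped BLOSUM62 11/1
    K: float = 0.041

    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if self.matrix.shape != (len(self.alphabet), len(self.alphabet)):
            raise ValueError("matrix shape inconsistent with alphabet")
        self._index = {c: i for i, c in enumerate(self.alphabet)}
        if self.matrix.max() <= 0:
            raise ValueError("scoring matrix must have a positive entry")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")

    @classmethod
    def blosum62(
        cls, gap_open: int = 11, gap_extend: int = 1, stop_penalty: int = -15
    ) -> "ScoringScheme":
        """BLOSUM62 with stop-codon columns set to ``stop_penalty`` so local
        alignments split at in-frame stops instead of bridging them on
        marginal downstream matches (stop runs then surface as distinct
        chained HSPs, which is what interruption counting relies on)."""
        m = substitution_matrices.load("BLOSUM62")
        mat = np.array(m, dtype=np.int64)
        alphabet = str(m.alphabet)
        star = alphabet.index("*")
        mat[star, :] = stop_penalty
        mat[:, star] = stop_penalty
        mat[star, star] = 1
        return cls(mat, alphabet, gap_open, gap_extend)

    def encode(self, seq: str) -> np.ndarray:
        x_idx = self._index.get("X", 0)
        return np.fromiter(
            (self._index.get(c, x_idx) for c in seq.upper()),
            dtype=np.int64,
            count=len(seq),
        )

    def score(self, a: str, b: str) -> int:
        return int(self.matrix[self._index.get(a, self._index.get("X", 0)),
                               self._index.get(b, self._index.get("X", 0))])


@dataclass
class Hsp:
    """One high-scoring pair.

    For translated searches ``s_start``/``s_end`` are forward-strand
    nucleotide coordinates and ``frame`` is in {+-1, +-2, +-3}; for plain
    protein-protein alignment ``frame`` is 0 and subject coordinates are in
    residues.
    """

    query_id: str
    subject_id: str
    frame: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    raw_score: int
    bit_score: float
    e_value: float
    pct_identity: float
    aligned_len: int
    q_aln: str = ""
    s_aln: str = ""

    def as_row(self) -> dict:
        """1-based inclusive coordinates for tabular reports."""
        return {
            "query_id": self.query_id,
            "subject_id": self.subject_id,
            "pct_identity": round(self.pct_identity, 2),
            "aligned_len": self.aligned_len,
            "q_start": self.q_start + 1,
            "q_end": self.q_end,
            "s_start": self.s_start + 1,
            "s_end": self.s_end,
            "frame": self.frame,
            "bit_score": round(self.bit_score, 2),
            "e_value": self.e_value,
        }


# ---------------------------------------------------------------------------
# Karlin-Altschul statistics
# ---------------------------------------------------------------------------

def lambda_ungapped(
    matrix: np.ndarray | ScoringScheme,
    background: dict[str, float] | None = None,
    tol: float = 1e-9,
) -> float:
    """Unique positive root of sum_ij p_i p_j exp(lambda*s_ij) = 1 by bisection."""
    if isinstance(matrix, ScoringScheme):
        scheme = matrix
        aas = [c for c in STANDARD_AA if c in scheme._index]
        idx = [scheme._index[c] for c in aas]
        sub = scheme.matrix[np.ix_(idx, idx)].astype(float)
        bg = background or ROBINSON_FREQS
        p = np.array([bg[c] for c in aas], dtype=float)
    else:
        sub = np.asarray(matrix, dtype=float)
        if background is None:
            raise ValueError("background frequencies required for a bare matrix")
        p = np.asarray(list(background.values()), dtype=float)
    p = p / p.sum()
    pp = np.outer(p, p)
    if (pp * sub).sum() >= 0:
        raise ValueError("expected score under background must be negative")
    if sub.max() <= 0:
        raise ValueError("matrix has no positive score")

    def f(lam: float) -> float:
        return float((pp * np.exp(lam * sub)).sum()) - 1.0

    lo, hi = 1e-6, 1.0
    while f(hi) < 0:
        hi *= 2
        if hi > 100:
            raise ValueError("no positive root found")
    while hi - lo > 1e-12:
        mid = 0.5 * (lo + hi)
        v = f(mid)
        if abs(v) < tol:
            return mid
        if v < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def evalue(
    raw_score: float, m: int, n: int, scheme: ScoringScheme
) -> tuple[float, float]:
    """(bit score, E-value) for a raw score against an m x n search space."""
    if m < 1 or n < 1:
        raise ValueError("search space dimensions must be >= 1")
    bit = (scheme.lambda_ * raw_score - math.log(scheme.K)) / math.log(2)
    e = m * n * 2.0 ** (-bit)
    return bit, e


# ---------------------------------------------------------------------------
# Smith-Waterman (Gotoh) oracle
# ---------------------------------------------------------------------------

def _sw_matrix(qi: np.ndarray, si: np.ndarray, scheme: ScoringScheme) -> np.ndarray:
    """Full local-alignment score matrix H (int64, shape (m+1, n+1)).

    Row-vectorized Gotoh: within a row, the gap-from-left term E is a prefix
    maximum of H0 + extend*j, which is exact for affine costs because a path
    that re-opens a gap immediately after closing one is always dominated by
    the single longer gap.
    """
    m, n = len(qi), len(si)
    go, ge = scheme.gap_open, scheme.gap_extend
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    F = np.full(n + 1, NEG, dtype=np.int64)
    jj = np.arange(1, n + 1, dtype=np.int64)
    for i in range(1, m + 1):
        sub = scheme.matrix[qi[i - 1], si]
        F[1:] = np.maximum(H[i - 1, 1:] - go - ge, F[1:] - ge)
        diag = H[i - 1, :-1] + sub
        H0 = np.maximum(np.maximum(diag, F[1:]), 0)
        # E[j] = max_{k<j} H[i,k] - go - ge*(j-k); H[i,0] = 0
        A = np.empty(n + 1, dtype=np.int64)
        A[0] = 0
        A[1:] = H0 + ge * jj
        np.maximum.accumulate(A, out=A)
        E = A[:-1] - go - ge * jj
        H[i, 1:] = np.maximum(H0, E)
    return H


def _sw_traceback(
    H: np.ndarray, qi: np.ndarray, si: np.ndarray, scheme: ScoringScheme,
    i: int, j: int,
) -> tuple[int, int, list[tuple[int, int]]]:
    """Walk back from (i, j); tie-break order diagonal > up > left."""
    go, ge = scheme.gap_open, scheme.gap_extend
    path: list[tuple[int, int]] = []
    while i > 0 and j > 0 and H[i, j] > 0:
        v = H[i, j]
        if v == H[i - 1, j - 1] + scheme.matrix[qi[i - 1], si[j - 1]]:
            path.append((i - 1, j - 1))
            i, j = i - 1, j - 1
            continue
        moved = False
        for g in range(1, i + 1):  # vertical gap (query consumed)
            if v == H[i - g, j] - go - ge * g:
                for t in range(g):
                    path.append((i - 1 - t, -1))
                i -= g
                moved = True
                break
        if moved:
            continue
        for g in range(1, j + 1):  # horizontal gap
            if v == H[i, j - g] - go - ge * g:
                for t in range(g):
                    path.append((-1, j - 1 - t))
                j -= g
                moved = True
                break
        if not moved:  # pragma: no cover - recurrence is exhaustive
            raise RuntimeError("traceback failed")
    return i, j, path[::-1]


def smith_waterman_protein(
    query: str | SequenceRecord,
    subject: str | SequenceRecord,
    scheme: ScoringScheme | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
) -> Hsp | None:
    """Optimal local alignment of two proteins under affine gaps.

    Returns None when no positive-scoring alignment exists. Deterministic:
    the first maximal cell in row-major order is chosen, and traceback ties
    resolve diagonal > up > left.
    """
    scheme = scheme or ScoringScheme.blosum62()
    if isinstance(query, SequenceRecord):
        query_id, query = query.id, query.residues
    if isinstance(subject, SequenceRecord):
        subject_id, subject = subject.id, subject.residues
    qi, si = scheme.encode(query), scheme.encode(subject)
    if len(qi) == 0 or len(si) == 0:
        return None
    H = _sw_matrix(qi, si, scheme)
    best = int(H.max())
    if best <= 0:
        return None
    bi, bj = np.unravel_index(int(H.argmax()), H.shape)
    i0, j0, path = _sw_traceback(H, qi, si, scheme, int(bi), int(bj))
    q_aln, s_aln, ident = _path_to_alignment(path, query, subject)
    bit, e = evalue(best, len(query), len(subject), scheme)
    return Hsp(
        query_id=query_id, subject_id=subject_id, frame=0,
        q_start=i0, q_end=int(bi), s_start=j0, s_end=int(bj),
        raw_score=best, bit_score=bit, e_value=e,
        pct_identity=100.0 * ident / len(path), aligned_len=len(path),
        q_aln=q_aln, s_aln=s_aln,
    )


def _path_to_alignment(
    path: list[tuple[int, int]], query: str, subject: str
) -> tuple[str, str, int]:
    q_aln, s_aln, ident = [], [], 0
    for qi_, sj_ in path:
        qc = query[qi_] if qi_ >= 0 else "-"
        sc = subject[sj_] if sj_ >= 0 else "-"
        q_aln.append(qc)
        s_aln.append(sc)
        if qc == sc and qc != "-":
            ident += 1
    return "".join(q_aln), "".join(s_aln), ident


# ---------------------------------------------------------------------------
# Banded Gotoh (used by the seeded engine)
# ---------------------------------------------------------------------------

def _banded_sw(
    qi: np.ndarray, si: np.ndarray, scheme: ScoringScheme,
    diag: int, half_width: int,
) -> tuple[int, int, int, list[tuple[int, int]], bool]:
    """Local Gotoh alignment restricted to the band |j - i - diag| <= half_width.

    Returns (score, end_i, end_j, path, touched_edge); ``touched_edge`` is
    True when the optimal path runs along a band boundary, signalling the
    caller to widen the band. Band column b = j - i - diag + half_width; the
    diagonal predecessor keeps b, vertical uses b+1, horizontal b-1. H rows
    are zero-initialised (= the local-alignment boundary) and E/F rows are
    -inf, which makes out-of-range predecessors exact.
    """
    m, n = len(qi), len(si)
    go, ge = scheme.gap_open, scheme.gap_extend
    w = 2 * half_width + 1
    H = np.zeros((m + 1, w), dtype=np.int64)
    E = np.full((m + 1, w), NEG, dtype=np.int64)
    F = np.full((m + 1, w), NEG, dtype=np.int64)
    mat = scheme.matrix
    best, bi, bj = 0, 0, 0
    for i in range(1, m + 1):
        jlo = max(1, i + diag - half_width)
        jhi = min(n, i + diag + half_width)
        for j in range(jlo, jhi + 1):
            b = j - i - diag + half_width
            d = H[i - 1, b] + mat[qi[i - 1], si[j - 1]]
            f = max(H[i - 1, b + 1] - go - ge, F[i - 1, b + 1] - ge) if b + 1 < w else NEG
            e = max(H[i, b - 1] - go - ge, E[i, b - 1] - ge) if b >= 1 else NEG
            F[i, b] = f
            E[i, b] = e
            h = max(0, int(d), e, f)
            H[i, b] = h
            if h > best:
                best, bi, bj = h, i, j
    if best <= 0:
        return 0, 0, 0, [], False
    path: list[tuple[int, int]] = []
    touched = False
    i, j = bi, bj
    state = "H"
    while i > 0 and j > 0:
        b = j - i - diag + half_width
        if b in (0, w - 1):
            touched = True
        if state == "H":
            v = H[i, b]
            if v == 0:
                break
            if v == H[i - 1, b] + mat[qi[i - 1], si[j - 1]]:
                path.append((i - 1, j - 1))
                i, j = i - 1, j - 1
            elif v == F[i, b]:
                state = "F"
            elif v == E[i, b]:
                state = "E"
            else:  # pragma: no cover - recurrence is exhaustive
                raise RuntimeError("banded traceback failed")
        elif state == "F":
            path.append((i - 1, -1))
            if b + 1 < w and F[i, b] == F[i - 1, b + 1] - ge:
                i -= 1
            else:
                i -= 1
                state = "H"
        else:  # state == "E"
            path.append((-1, j - 1))
            if b >= 1 and E[i, b] == E[i, b - 1] - ge:
                j -= 1
            else:
                j -= 1
                state = "H"
    path.reverse()
    return best, bi, bj, path, touched


# ---------------------------------------------------------------------------
# Seeded translated search
# ---------------------------------------------------------------------------

def _neighborhood(
    word: tuple[int, int, int], scheme: ScoringScheme, threshold: int,
    std_idx: np.ndarray, cache: dict,
) -> list[tuple[int, int, int]]:
    if word in cache:
        return cache[word]
    a, b, c = word
    sa = scheme.matrix[a, std_idx]
    sb = scheme.matrix[b, std_idx]
    sc = scheme.matrix[c, std_idx]
    total = sa[:, None, None] + sb[None, :, None] + sc[None, None, :]
    hits = np.argwhere(total >= threshold)
    out = [
        (int(std_idx[x]), int(std_idx[y]), int(std_idx[z])) for x, y, z in hits
    ]
    cache[word] = out
    return out


def _ungapped_xdrop(
    qi: np.ndarray, si: np.ndarray, qpos: int, spos: int,
    scheme: ScoringScheme, x_drop: int, word: int = 3,
) -> tuple[int, int, int]:
    """Extend a seed without gaps; returns (score, q_start, q_end)."""
    mat = scheme.matrix
    score = 0
    for k in range(word):
        score += mat[qi[qpos + k], si[spos + k]]
    # right
    best = score
    cur = score
    qe = qpos + word
    se = spos + word
    best_qe = qe
    while qe < len(qi) and se < len(si):
        cur += mat[qi[qe], si[se]]
        if cur > best:
            best, best_qe = cur, qe + 1
        if best - cur > x_drop:
            break
        qe += 1
        se += 1
    # left
    cur = best
    qs = qpos
    ss = spos
    best_qs = qs
    while qs > 0 and ss > 0:
        cur += mat[qi[qs - 1], si[ss - 1]]
        if cur > best:
            best, best_qs = cur, qs - 1
        if best - cur > x_drop:
            break
        qs -= 1
        ss -= 1
    return int(best), best_qs, best_qe


def tblastn_search(
    queries: Sequence[SequenceRecord],
    subjects: Sequence[SequenceRecord],
    scheme: ScoringScheme | None = None,
    seed_word: int = 3,
    seed_threshold: int = 11,
    x_drop: int = 20,
    e_cutoff: float = 0.1,
    band_half_width: int = 30,
    gap_trigger: int = 40,
) -> list[Hsp]:
    """Protein queries vs six-frame translations of nucleotide subjects.

    HSPs with E < ``e_cutoff`` are returned sorted by ascending E-value;
    overlapping same-frame HSPs of one query/subject pair are merged keeping
    the best score. Subject coordinates are forward-strand nucleotides.
    """
    if not queries or not subjects:
        raise ValueError("need at least one query and one subject")
    scheme = scheme or ScoringScheme.blosum62()
    n_total = sum(len(s.residues) for s in subjects)
    std_idx = np.array([scheme._index[c] for c in STANDARD_AA], dtype=np.int64)
    std_set = set(int(v) for v in std_idx)

    # word -> [(query index, qpos)] over all neighborhood words
    word_index: dict[tuple[int, int, int], list[tuple[int, int]]] = {}
    q_enc: list[np.ndarray] = []
    ncache: dict = {}
    for iq, q in enumerate(queries):
        qi = scheme.encode(q.residues)
        q_enc.append(qi)
        for p in range(0, len(qi) - seed_word + 1):
            w = tuple(int(v) for v in qi[p : p + seed_word])
            if not all(v in std_set for v in w):
                continue
            for nb in _neighborhood(w, scheme, seed_threshold, std_idx, ncache):
                word_index.setdefault(nb, []).append((iq, p))

    hsps: list[Hsp] = []
    for subj in subjects:
        if len(subj.residues) < 3:
            log.warning("subject %s shorter than one codon; skipped", subj.id)
            continue
        for ft in six_frame(subj.residues):
            prot = ft.protein
            if not prot:
                continue
            si = scheme.encode(prot)
            # collect seeds per query
            seeds: dict[int, list[tuple[int, int]]] = {}
            for sp in range(0, len(si) - seed_word + 1):
                w = tuple(int(v) for v in si[sp : sp + seed_word])
                if w not in word_index:
                    continue
                for iq, qp in word_index[w]:
                    seeds.setdefault(iq, []).append((qp, sp))
            for iq, seedlist in seeds.items():
                qi = q_enc[iq]
                m = len(qi)
                covered: dict[int, int] = {}  # diag -> s end already extended
                done_regions: list[tuple[int, int, int, int]] = []
                frame_hsps: list[tuple[int, int, int, list[tuple[int, int]]]] = []
                for qp, sp in sorted(seedlist, key=lambda t: (t[1] - t[0], t[1])):
                    diag = sp - qp
                    if covered.get(diag, -1) >= sp:
                        continue
                    if any(
                        qlo <= qp < qhi and slo <= sp < shi
                        for qlo, qhi, slo, shi in done_regions
                    ):
                        continue
                    score, qs, qe = _ungapped_xdrop(
                        qi, si, qp, sp, scheme, x_drop, seed_word
                    )
                    covered[diag] = sp + (qe - qp)
                    if score < gap_trigger:
                        continue
                    hw = band_half_width
                    while True:
                        gscore, bi, bj, path, touched = _banded_sw(
                            qi, si, scheme, diag, hw
                        )
                        if not touched or hw >= max(m, len(si)):
                            break
                        hw *= 2
                    if not path:
                        continue
                    q_idxs = [p[0] for p in path if p[0] >= 0]
                    s_idxs = [p[1] for p in path if p[1] >= 0]
                    done_regions.append(
                        (min(q_idxs), max(q_idxs) + 1, min(s_idxs), max(s_idxs) + 1)
                    )
                    frame_hsps.append((gscore, bi, bj, path))
                # dedupe by subject interval, keep best score
                kept: list[tuple[int, int, int, list[tuple[int, int]]]] = []
                for cand in sorted(frame_hsps, key=lambda t: -t[0]):
                    cs = [p[1] for p in cand[3] if p[1] >= 0]
                    if not cs:
                        continue
                    c_lo, c_hi = min(cs), max(cs) + 1
                    overlap = False
                    for k in kept:
                        ks = [p[1] for p in k[3] if p[1] >= 0]
                        k_lo, k_hi = min(ks), max(ks) + 1
                        if c_lo < k_hi and k_lo < c_hi:
                            overlap = True
                            break
                    if not overlap:
                        kept.append(cand)
                for gscore, bi, bj, path in kept:
                    bit, e = evalue(gscore, m, n_total, scheme)
                    if e >= e_cutoff:
                        continue
                    q_aln, s_aln, ident = _path_to_alignment(
                        path, queries[iq].residues, prot
                    )
                    q_idxs = [p[0] for p in path if p[0] >= 0]
                    s_idxs = [p[1] for p in path if p[1] >= 0]
                    aa_s, aa_e = min(s_idxs), max(s_idxs) + 1
                    nt_s, nt_e = ft.aa_span_to_nt(aa_s, aa_e)
                    hsps.append(
                        Hsp(
                            query_id=queries[iq].id,
                            subject_id=subj.id,
                            frame=ft.frame,
                            q_start=min(q_idxs),
                            q_end=max(q_idxs) + 1,
                            s_start=nt_s,
                            s_end=nt_e,
                            raw_score=int(gscore),
                            bit_score=bit,
                            e_value=e,
                            pct_identity=100.0 * ident / len(path),
                            aligned_len=len(path),
                            q_aln=q_aln,
                            s_aln=s_aln,
                        )
                    )
    hsps.sort(
        key=lambda h: (h.e_value, h.query_id, h.subject_id, h.s_start, h.frame)
    )
    return hsps


def hsps_to_table(hsps: Iterable[Hsp]):
    """Tabular hit report (1-based inclusive coordinates)."""
    import pandas as pd

    return pd.DataFrame([h.as_row() for h in hsps])
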