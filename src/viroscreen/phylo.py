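"""Protein alignment, distance matrices, neighbor-joining trees and Newick
output - the machinery behind "does this virus-like protein cluster with
transposons or with viruses?" arguments.

Distances default to the Kimura-corrected p-distance
d = -ln(1 - p - p^2/5); the Jones-Taylor-Thornton (JTT) model is available
as a maximum-likelihood alternative. The JTT transition model is
reconstructed from the packaged JTT log-odds table: the published table
prints log10 relatedness odds at 250 PAMs, so the equilibrium frequencies
are recovered as the Perron eigenvector of the odds matrix and the rate
matrix follows from the matrix logarithm of the implied transition matrix.
The reconstruction is approximate (the published table is rounded to one
decimal) but preserves the model's exchangeability structure, which is what
the qualitative clustering claims rest on.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices
from scipy.linalg import expm, logm
from scipy.optimize import minimize_scalar

from .search import ScoringScheme
from .seqio import SequenceRecord

log = logging.getLogger(__name__)

KIMURA_P_CAP = 0.85
KIMURA_D_CAP = 10.0


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape inconsistent with labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if not np.all(np.isfinite(self.d)) or np.any(self.d < 0):
            raise ValueError("distances must be finite and non-negative")

    def to_phylip(self) -> str:
        lines = [f"    {len(self.labels)}"]
        for lab, row in zip(self.labels, self.d):
            name = lab[:10].ljust(10)
            lines.append(name + "  " + "  ".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Progressive alignment
# ---------------------------------------------------------------------------

def _nw_profile(
    prof_a: list[str], prof_b: list[str], scheme: ScoringScheme,
    gap: int = 8,
) -> tuple[list[str], list[str]]:
    """Global profile-profile alignment (linear gap penalty, sum-of-pairs
    column scores). Each profile is a list of equal-length aligned rows."""
    la, lb = len(prof_a[0]), len(prof_b[0])
    cols_a = [[row[i] for row in prof_a] for i in range(la)]
    cols_b = [[row[i] for row in prof_b] for i in range(lb)]

    def col_score(ca: list[str], cb: list[str]) -> float:
        tot = cnt = 0
        for x in ca:
            for y in cb:
                if x == "-" or y == "-":
                    tot -= 1
                else:
                    tot += scheme.score(x, y)
                cnt += 1
        return tot / cnt

    S = np.zeros((la + 1, lb + 1))
    S[:, 0] = -gap * np.arange(la + 1)
    S[0, :] = -gap * np.arange(lb + 1)
    ptr = np.zeros((la + 1, lb + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    ptr[1:, 0] = 1
    ptr[0, 1:] = 2
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            d = S[i - 1, j - 1] + col_score(cols_a[i - 1], cols_b[j - 1])
            u = S[i - 1, j] - gap
            l = S[i, j - 1] - gap
            best = max(d, u, l)
            S[i, j] = best
            ptr[i, j] = 0 if best == d else (1 if best == u else 2)
    # traceback
    out_a: list[list[str]] = [[] for _ in prof_a]
    out_b: list[list[str]] = [[] for _ in prof_b]
    i, j = la, lb
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 0 and i > 0 and j > 0:
            for r, row in enumerate(prof_a):
                out_a[r].append(row[i - 1])
            for r, row in enumerate(prof_b):
                out_b[r].append(row[j - 1])
            i, j = i - 1, j - 1
        elif p == 1 and i > 0 or (j == 0 and i > 0):
            for r, row in enumerate(prof_a):
                out_a[r].append(row[i - 1])
            for r in range(len(prof_b)):
                out_b[r].append("-")
            i -= 1
        else:
            for r in range(len(prof_a)):
                out_a[r].append("-")
            for r, row in enumerate(prof_b):
                out_b[r].append(row[j - 1])
            j -= 1
    return (["".join(reversed(r)) for r in out_a],
            ["".join(reversed(r)) for r in out_b])


def progressive_align(
    seqs: list[SequenceRecord] | list[str],
    scheme: ScoringScheme | None = None,
) -> list[str]:
    """Progressive multiple alignment: UPGMA guide tree on pairwise-identity
    distances, profiles merged by global DP. Rows are returned in input
    order; every input residue appears in the output."""
    scheme = scheme or ScoringScheme.blosum62()
    strings = [s.residues if isinstance(s, SequenceRecord) else s for s in seqs]
    n = len(strings)
    if n < 2:
        raise ValueError("progressive alignment needs >= 2 sequences")
    # pairwise identity distances from pairwise global alignments
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = _nw_profile([strings[i]], [strings[j]], scheme)
            ra, rb = a[0], b[0]
            matches = sum(1 for x, y in zip(ra, rb) if x == y and x != "-")
            shared = sum(1 for x, y in zip(ra, rb) if x != "-" and y != "-")
            p = 1 - matches / shared if shared else 1.0
            D[i, j] = D[j, i] = p
    # UPGMA merge order via scipy
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    Z = linkage(squareform(D, checks=False), method="average")
    profiles: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [strings[i]]) for i in range(n)
    }
    for step, (a, b, _, _) in enumerate(Z):
        ia, ib = int(a), int(b)
        idx_a, prof_a = profiles.pop(ia)
        idx_b, prof_b = profiles.pop(ib)
        na, nb = _nw_profile(prof_a, prof_b, scheme)
        profiles[n + step] = (idx_a + idx_b, na + nb)
    order, rows = profiles.popitem()[1]
    out = [""] * n
    for idx, row in zip(order, rows):
        out[idx] = row
    return out


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _pairwise_p(msa: list[str], i: int, j: int) -> float:
    shared = diffs = 0
    for x, y in zip(msa[i], msa[j]):
        if x == "-" or y == "-":
            continue
        shared += 1
        if x != y:
            diffs += 1
    return diffs / shared if shared else 1.0


def kimura_distance(p: float) -> float:
    """Kimura's correction for protein p-distance, capped at 10.0 when the
    formula's domain ends (p >= 0.85)."""
    if p >= KIMURA_P_CAP:
        log.warning("p-distance %.3f beyond Kimura domain; capped", p)
        return KIMURA_D_CAP
    return -math.log(1.0 - p - p * p / 5.0)


@lru_cache(maxsize=1)
def _jtt_model() -> tuple[np.ndarray, np.ndarray]:
    """(equilibrium frequencies, rate matrix scaled to 1 sub/site) from the
    packaged JTT log-odds table."""
    tab = substitution_matrices.load("JONES")
    S = np.array(tab, dtype=float)
    odds = np.power(10.0, S)  # relatedness odds at 250 PAMs
    w, v = np.linalg.eig(odds)
    k = int(np.argmax(w.real))
    f = np.abs(v[:, k].real)
    f = f / f.sum()
    P250 = odds * f[None, :]          # P[i, j] = f_j * odds_ij
    P250 = P250 / P250.sum(axis=1, keepdims=True)
    Q = logm(P250).real / 250.0
    Q[Q < 0] = np.where(np.eye(20, dtype=bool), Q, 0.0)[Q < 0]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -float(np.dot(f, np.diag(Q)))
    return f, Q / rate


def jtt_distance(msa_i: str, msa_j: str) -> float:
    """Maximum-likelihood pairwise distance under the JTT model by scalar
    optimization of the aligned-pair likelihood."""
    f, Q = _jtt_model()
    alpha = "ARNDCQEGHILKMFPSTWYV"
    idx = {c: i for i, c in enumerate(alpha)}
    pairs: dict[tuple[int, int], int] = {}
    for x, y in zip(msa_i, msa_j):
        if x in idx and y in idx:
            pairs[(idx[x], idx[y])] = pairs.get((idx[x], idx[y]), 0) + 1
    if not pairs:
        return 0.0
    if all(i == j for i, j in pairs):
        return 0.0

    def nll(t: float) -> float:
        P = expm(Q * t)
        ll = 0.0
        for (i, j), c in pairs.items():
            ll += c * math.log(max(f[i] * P[i, j], 1e-300))
        return -ll

    res = minimize_scalar(nll, bounds=(1e-6, 20.0), method="bounded")
    return float(res.x)


def protein_distance(
    msa: list[str], labels: list[str] | None = None, model: str = "KIMURA"
) -> DistanceMatrix:
    """Distance matrix over the rows of an alignment (shared non-gap
    columns). Models: KIMURA (default) or JTT."""
    if len(msa) < 2:
        raise ValueError("need >= 2 aligned rows")
    if len({len(r) for r in msa}) != 1:
        raise ValueError("rows must be aligned (equal length)")
    if model not in ("KIMURA", "JTT"):
        raise ValueError(f"unknown model {model!r}")
    n = len(msa)
    labels = labels or [f"seq{i + 1}" for i in range(n)]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if model == "KIMURA":
                d = kimura_distance(_pairwise_p(msa, i, j))
            else:
                d = jtt_distance(msa[i], msa[j])
            D[i, j] = D[j, i] = d
    log.info("distance model: %s", model)
    return DistanceMatrix(labels, D)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class UnrootedTree:
    """Unrooted tree as an adjacency map; binary except one central
    trifurcation (or the 2-leaf edge case)."""

    adjacency: dict[int, list[tuple[int, float]]]
    leaf_labels: dict[int, str]
    notes: list[str] = field(default_factory=list)

    @property
    def leaves(self) -> list[str]:
        return [self.leaf_labels[k] for k in sorted(self.leaf_labels)]

    def path_length(self, a: str, b: str) -> float:
        name_to_id = {v: k for k, v in self.leaf_labels.items()}
        start, goal = name_to_id[a], name_to_id[b]
        stack = [(start, 0.0, -1)]
        while stack:
            node, dist, prev = stack.pop()
            if node == goal:
                return dist
            for nxt, w in self.adjacency[node]:
                if nxt != prev:
                    stack.append((nxt, dist + w, node))
        raise ValueError(f"no path {a} -> {b}")


def neighbor_joining(dm: DistanceMatrix) -> UnrootedTree:
    """Classical neighbor joining (Saitou-Nei with standard branch-length
    formulas). On an additive matrix the generating tree is recovered
    exactly. Ties in the Q criterion break by the smallest label pair;
    negative branch-length estimates are clamped to zero with a note."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    D = {(i, j): dm.d[i, j] for i in range(n) for j in range(n)}
    active = list(range(n))
    adjacency: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n)}
    leaf_labels = dict(enumerate(dm.labels))
    node_label = {i: dm.labels[i] for i in range(n)}
    notes: list[str] = []
    next_id = n

    def connect(a: int, b: int, w: float) -> None:
        if w < 0:
            notes.append(f"negative branch {w:.4g} clamped to 0")
            w = 0.0
        adjacency[a].append((b, w))
        adjacency[b].append((a, w))

    while len(active) > 3:
        r = {i: sum(D[(i, k)] for k in active if k != i) for i in active}
        m = len(active)
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                i, j = active[ai], active[bi]
                q = (m - 2) * D[(i, j)] - r[i] - r[j]
                pair_key = tuple(sorted((node_label[i], node_label[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand < best:
                    best = cand
        _, _, i, j = best
        u = next_id
        next_id += 1
        adjacency[u] = []
        node_label[u] = f"node{u}"
        li = 0.5 * D[(i, j)] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[(i, j)] - li
        connect(u, i, li)
        connect(u, j, lj)
        for k in active:
            if k in (i, j):
                continue
            D[(u, k)] = D[(k, u)] = 0.5 * (D[(i, k)] + D[(j, k)] - D[(i, j)])
        D[(u, u)] = 0.0
        active = [k for k in active if k not in (i, j)] + [u]
    a, b, c = active
    center = next_id
    adjacency[center] = []
    node_label[center] = f"node{center}"
    la = 0.5 * (D[(a, b)] + D[(a, c)] - D[(b, c)])
    lb = 0.5 * (D[(a, b)] + D[(b, c)] - D[(a, c)])
    lc = 0.5 * (D[(a, c)] + D[(b, c)] - D[(a, b)])
    connect(center, a, la)
    connect(center, b, lb)
    connect(center, c, lc)
    return UnrootedTree(adjacency, leaf_labels, notes)


def _quote_label(label: str) -> str:
    if any(c in label for c in " ()[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: UnrootedTree) -> str:
    """Newick text with branch lengths, printed from the central internal
    node (round-trip parseable; labels with spaces are quoted)."""
    internal = [k for k in tree.adjacency if k not in tree.leaf_labels]
    root = max(internal) if internal else max(tree.adjacency)

    def render(node: int, prev: int) -> str:
        children = [(n, w) for n, w in tree.adjacency[node] if n != prev]
        if not children and node in tree.leaf_labels:
            return _quote_label(tree.leaf_labels[node])
        parts = [f"{render(n, node)}:{w:.6f}" for n, w in children]
        return "(" + ",".join(parts) + ")"

    return render(root, -1) + ";"
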