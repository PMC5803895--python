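"""Read mapping, RPKM, assembly statistics, a toy de Bruijn assembler, and
the read-count sensitivity analysis.

The assembler is deliberately minimal: unitigs (maximal non-branching paths)
of a strand-specific de Bruijn graph, with contigs below the length floor or
supported by a single read discarded. Requiring two overlapping reads per
contig is what gives the method its characteristic detection threshold: a
transcript sampled by only a handful of reads assembles - and is therefore
detectable by translated search - only once read starts begin to overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np
import pandas as pd

from .search import ScoringScheme, tblastn_search
from .seqio import FastqRead, SequenceRecord, reverse_complement

log = logging.getLogger(__name__)


@dataclass
class RpkmRecord:
    feature_id: str
    feature_len: int
    reads_mapped: int
    total_mapped_reads: int
    rpkm: float


@dataclass
class AssemblyStats:
    n_contigs: int
    total_bases: int
    max_len: int
    min_len: int
    n50: int
    pct_n: float


def rpkm(reads_mapped: int, feature_len: int, total_mapped_reads: int,
         feature_id: str = "") -> RpkmRecord:
    """Reads per kilobase of feature per million mapped reads."""
    if feature_len < 1:
        raise ValueError("feature_len must be >= 1")
    if total_mapped_reads < 1:
        raise ValueError("total_mapped_reads must be >= 1")
    value = reads_mapped / (feature_len / 1000.0) / (total_mapped_reads / 1e6)
    return RpkmRecord(feature_id, feature_len, reads_mapped,
                      total_mapped_reads, value)


def assembly_stats(contigs: Sequence[SequenceRecord]) -> AssemblyStats:
    if not contigs:
        raise ValueError("need at least one contig")
    lengths = sorted((len(c.residues) for c in contigs), reverse=True)
    total = sum(lengths)
    acc = 0
    n50 = lengths[-1]
    for L in lengths:
        acc += L
        if acc >= total / 2:
            n50 = L
            break
    n_count = sum(c.residues.upper().count("N") for c in contigs)
    return AssemblyStats(
        n_contigs=len(lengths), total_bases=total, max_len=lengths[0],
        min_len=lengths[-1], n50=n50, pct_n=100.0 * n_count / total,
    )


# ---------------------------------------------------------------------------
# Read mapping
# ---------------------------------------------------------------------------

def map_reads(
    reads: Sequence[FastqRead],
    references: Sequence[SequenceRecord],
    min_identity: float = 95.0,
    seed_k: int = 21,
    min_read_fraction: float = 0.80,
) -> tuple[dict[str, int], dict[str, str | None]]:
    """Assign each read to the reference it aligns to at >= ``min_identity``
    over >= ``min_read_fraction`` of its length (either strand); candidate
    references are found by shared ``seed_k``-mers, ties broken by k-mer
    count then lexicographic reference id. Returns (per-reference counts,
    per-read assignment; None = unmapped)."""
    index: dict[str, set[str]] = {}
    for ref in references:
        s = ref.residues.upper()
        for i in range(len(s) - seed_k + 1):
            index.setdefault(s[i : i + seed_k], set()).add(ref.id)
    by_id = {r.id: r.residues.upper() for r in references}
    counts = {r.id: 0 for r in references}
    assign: dict[str, str | None] = {}
    for read in reads:
        seq = read.seq.upper()
        if len(seq) < seed_k:
            assign[read.id] = None
            continue
        shared: dict[str, int] = {}
        probes = (seq, reverse_complement(seq))
        for probe in probes:
            for i in range(len(probe) - seed_k + 1):
                for rid in index.get(probe[i : i + seed_k], ()):
                    shared[rid] = shared.get(rid, 0) + 1
        best_rid = None
        max_dist = int(round(len(seq) * (1 - min_identity / 100.0)))
        cands = sorted(shared, key=lambda r: (-shared[r], r))
        for rid in cands:
            ok = False
            for probe in probes:
                res = edlib.align(probe, by_id[rid], task="distance",
                                  mode="HW", k=max_dist)
                if res["editDistance"] != -1:
                    ok = True
                    break
            if ok:
                best_rid = rid
                break
        assign[read.id] = best_rid
        if best_rid is not None:
            counts[best_rid] += 1
    return counts, assign


# ---------------------------------------------------------------------------
# Toy de Bruijn assembler
# ---------------------------------------------------------------------------

def mini_assemble(
    reads: Sequence[FastqRead | SequenceRecord | str],
    k: int = 31,
    min_contig: int = 100,
    min_read_support: int = 2,
) -> list[SequenceRecord]:
    """Strand-specific de Bruijn unitig assembler.

    Contigs are maximal non-branching paths over the k-mer set of the reads;
    contigs shorter than ``min_contig`` or supported by fewer than
    ``min_read_support`` distinct reads are discarded. Deterministic given
    the (order-independent) k-mer set.
    """
    seqs: list[tuple[int, str]] = []
    for i, r in enumerate(reads):
        s = r if isinstance(r, str) else (r.seq if isinstance(r, FastqRead) else r.residues)
        seqs.append((i, s.upper()))
    support: dict[str, set[int]] = {}
    for rid, s in seqs:
        for i in range(len(s) - k + 1):
            support.setdefault(s[i : i + k], set()).add(rid)
    if not support:
        return []
    out_edges: dict[str, set[str]] = {}
    in_deg: dict[str, int] = {}
    nodes: set[str] = set()
    for kmer in support:
        u, v = kmer[:-1], kmer[1:]
        nodes.update((u, v))
        if v not in out_edges.setdefault(u, set()) :
            out_edges[u].add(v)
            in_deg[v] = in_deg.get(v, 0) + 1
    in_deg = {n: in_deg.get(n, 0) for n in nodes}
    out_deg = {n: len(out_edges.get(n, ())) for n in nodes}

    def is_branch(n: str) -> bool:
        return in_deg[n] != 1 or out_deg[n] != 1

    visited: set[tuple[str, str]] = set()
    unitigs: list[str] = []

    def walk(u: str, v: str) -> None:
        if (u, v) in visited:
            return
        visited.add((u, v))
        path = [u, v]
        while not is_branch(path[-1]):
            nxt = next(iter(out_edges[path[-1]]))
            if (path[-1], nxt) in visited:
                break
            visited.add((path[-1], nxt))
            path.append(nxt)
        unitigs.append(path[0] + "".join(p[-1] for p in path[1:]))

    for u in sorted(nodes):
        if is_branch(u):
            for v in sorted(out_edges.get(u, ())):
                walk(u, v)
    for u in sorted(nodes):  # remaining simple cycles
        for v in sorted(out_edges.get(u, ())):
            if (u, v) not in visited:
                walk(u, v)

    contigs = []
    for seq in unitigs:
        if len(seq) < min_contig:
            continue
        readset: set[int] = set()
        for i in range(len(seq) - k + 1):
            readset |= support.get(seq[i : i + k], set())
        if len(readset) < min_read_support:
            continue
        contigs.append(seq)
    contigs.sort(key=lambda s: (-len(s), s))
    return [
        SequenceRecord(f"contig_{i + 1}", s) for i, s in enumerate(contigs)
    ]


# ---------------------------------------------------------------------------
# Expected read-count scaling & sensitivity
# ---------------------------------------------------------------------------

def expected_viral_reads(
    ref_mapped: int, ref_total: float, new_total: float
) -> tuple[float, int]:
    """Scale a reference experiment's viral read count to a new sequencing
    depth: ref_mapped * new_total / ref_total, (unrounded, rounded)."""
    if ref_mapped < 0 or ref_total <= 0 or new_total <= 0:
        raise ValueError("inputs must be positive")
    exact = ref_mapped * new_total / ref_total
    return exact, int(round(exact))


def sensitivity_experiment(
    transcript: SequenceRecord,
    vpd_records: Sequence[SequenceRecord],
    n_values: Sequence[int],
    replicates: int = 20,
    seed: int = 1,
    read_len: int = 150,
    k: int = 31,
    e_cutoff: float = 0.1,
    scheme: ScoringScheme | None = None,
) -> tuple[pd.DataFrame, int | None]:
    """Detection rate of a virus-like transcript versus read count.

    For each N: sample N error-free reads uniformly from the transcript,
    assemble with the de Bruijn mini-assembler, search contigs against the
    viral protein set; success = any HSP with E < cutoff. The empirical rate
    is smoothed by a running maximum (detection cannot get worse with more
    reads) before the >= 0.5 threshold lookup. Returns (table, min N)."""
    from .synthdata import simulate_reads  # local import to avoid a cycle

    scheme = scheme or ScoringScheme.blosum62()
    n_values = sorted(n_values)
    rows = []
    for n in n_values:
        hits = 0
        for rep in range(replicates):
            rep_seed = (seed * 100003 + n * 1009 + rep) % (2 ** 31)
            if n == 0:
                continue
            reads = simulate_reads(
                [transcript], n=n, read_len=read_len, seed=rep_seed
            )
            contigs = mini_assemble(reads, k=k)
            if not contigs:
                continue
            found = tblastn_search(
                list(vpd_records), contigs, scheme, e_cutoff=e_cutoff
            )
            if found:
                hits += 1
        rows.append({"n_reads": n, "detection_rate": hits / replicates})
    table = pd.DataFrame(rows)
    table["smoothed_rate"] = table["detection_rate"].cummax()
    hit_rows = table[table["smoothed_rate"] >= 0.5]
    min_n = int(hit_rows["n_reads"].iloc[0]) if len(hit_rows) else None
    return table, min_n
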