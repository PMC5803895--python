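"""Packaged protein motif library: a deterministic, offline surrogate for
conserved-domain annotation.

Each motif is a position-constrained residue pattern (a restricted regular
expression over the amino-acid alphabet) read off the conserved blocks of the
domain families relevant to virus-like mobile elements (Walker A/B, the
integrase DDE triad, the adenain catalytic triad, PLA2, family-B polymerase,
RT core, SF1 helicase, chromo) plus a blocklist of ubiquitous cellular
domains used during viral-protein-database curation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources


@dataclass(frozen=True)
class MotifDefinition:
    name: str
    pattern: str
    consensus: str
    note: str = ""
    min_matches: int = 1

    def compiled(self) -> re.Pattern:
        return re.compile(self.pattern)


@dataclass(frozen=True)
class MotifHit:
    name: str
    start: int  # aa offset, 0-based
    end: int    # half-open


def _load(fname: str) -> list[MotifDefinition]:
    text = (
        resources.files("viroscreen").joinpath("data").joinpath(fname).read_text()
    )
    out = []
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        name, pattern, consensus, note = line.split("\t")
        out.append(MotifDefinition(name, pattern, consensus, note))
    return out


def motif_library() -> list[MotifDefinition]:
    """Domain motifs used for element-role assignment and hit triage."""
    return _load("motifs.tsv")


def cellular_blocklist() -> list[MotifDefinition]:
    """Cellular-domain motifs whose presence disqualifies a viral protein
    from the curated database (polymerases, kinases, phosphatases, apoptosis
    inhibitors, superoxide dismutases, proteases, nucleases, ubiquitin
    ligases, zinc/ring fingers)."""
    return _load("blocklist.tsv")


def annotate_motifs(
    aa_seq: str, library: list[MotifDefinition] | None = None
) -> list[MotifHit]:
    """All motif matches with positions; overlapping matches are all
    reported. Deterministic: scanned left to right, library order."""
    library = library if library is not None else motif_library()
    seq = aa_seq.upper()
    hits: list[MotifHit] = []
    for motif in library:
        rx = motif.compiled()
        for pos in range(len(seq)):
            m = rx.match(seq, pos)
            if m:
                hits.append(MotifHit(motif.name, pos, m.end()))
    return hits
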