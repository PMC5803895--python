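# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `viroscreen`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Translated search engine

Protein queries are compared against all six reading-frame translations of
nucleotide contigs (TBLASTN semantics). The engine is the classic
seed-and-extend design:

* **Seeding.** Every query 3-mer is expanded into its neighborhood — all
  3-mers whose BLOSUM62 score against it is ≥ 11 (one-hit seeding). Subject
  frames are scanned against this word index. One-hit seeding trades speed
  for sensitivity, the right trade at the desk scales this package targets.
* **Ungapped extension.** Each seed is extended in both directions with an
  X-drop of 20; extensions scoring below a gap trigger of 40 (raw) are
  discarded. This is what keeps chance seeds in host sequence cheap.
* **Gapped extension.** Surviving extensions are refined by banded
  affine-gap (Gotoh) local alignment around the seed diagonal, band
  half-width 30, doubled automatically whenever the optimal path touches
  the band edge. Overlapping same-frame HSPs keep the best score.
* **Statistics.** bit = (λS − ln K)/ln 2 and E = m·n·2^(−bit), with m the
  query length (aa) and n the summed subject length (nt). Gapped BLOSUM62
  11/1 constants λ = 0.267, K = 0.041. Raw (not length-adjusted) m and n
  are used, so absolute E-values are slightly conservative relative to
  production BLAST; all thresholds in the package are calibrated on this
  same convention. The ungapped λ solver (bisection on
  Σ pᵢpⱼ e^{λs} = 1 to |f| < 1e-9, Robinson–Robinson backgrounds) is
  exposed separately and is validated against closed forms.
* **Stop codons.** Frame translations keep `*`; the search scheme sets
  stop columns to −15 so local alignments split at in-frame stops rather
  than bridging them on marginal downstream matches. Interruption counting
  (below) depends on this: a nonsense mutation surfaces as two chained
  same-frame HSPs, a frameshift as chained HSPs in different frames.
* **Oracle.** A full Smith–Waterman–Gotoh aligner (vectorised per row; the
  gap-from-left term is an exact prefix-maximum because re-opening a gap
  immediately after closing one is dominated under affine costs) serves as
  the engine's validation oracle. The suite checks, on constructed
  instances whose optimal alignment contains an exact seed word, that the
  seeded engine's score equals the oracle's and never exceeds it; the
  oracle itself is cross-checked against an independent optimal aligner.

A gap of length g costs open + extend·g (11 + g by default), matching the
convention the published gapped constants were fitted under.

## Hit triage

Every region with a hit at E < 0.1 receives exactly one verdict, first
match wins:

1. **HOST.** The region's reading frame, expanded by 450 nt each side, is
   translated and aligned (Smith–Waterman) against host and viral reference
   proteins. If the best host E-value beats the best viral E-value by
   ≥ 20 orders of magnitude (Δlog₁₀E ≥ 20, E-values floored at 1e-300), the
   region is a conserved host gene. The expansion matters: a host gene's
   conserved domain can match a viral protein closely, and only the full
   predicted protein separates the two hypotheses. The threshold 20
   formalises "tens of orders of magnitude" as the smallest plural tens;
   it is configurable.
2. **TRANSPOSON_*.** Region overlaps a Maverick, errantivirus/LTR, or
   R1-LINE annotation (below).
3. **EVE.** The hit's source virus has an RNA genome with no DNA stage
   (+ssRNA, −ssRNA, dsRNA — not the RT classes), and the region is present
   in the *genome* assembly with ≥ 200 nt of host sequence on at least one
   flank. The flank requirement is the package's explicit, testable
   surrogate for "integrated, not a co-assembled viral contig".
   Transcriptome hits are located in the genome by near-exact (≤ 10%
   divergence) infix alignment. Interruption counts: nonsense = in-frame
   stops inside the chained alignment span (including same-frame inter-HSP
   gaps), frameshift = frame transitions along the chain.
4. **PUTATIVE_VIRUS.** A significant viral hit surviving 1–3 — notably any
   RNA-virus hit present in the transcriptome but absent from the genome,
   or a genomic viral hit without host flanks.
5. **UNRESOLVED.** Surfaced, never silently dropped.

Hits are clustered into regions by ≥ 1 nt overlap; this can in principle
merge adjacent elements, which is surfaced in the evidence chain rather
than adjudicated.

## Element classifiers

* **Maverick/Polinton**: ≥ 5 of the hallmark roles {ATP (Walker A+B), INT
  (DDE integrase, chromo domain as secondary evidence), PRO (adenain-like
  triad), POLB (family-B polymerase motif C), CAP (PLA2)} co-occurring
  within 25 kb. Role evidence comes from the packaged motif library; roles
  are assigned by a global greedy match (strongest evidence first, one role
  per ORF), so an ORF with two motif families cannot starve another role.
  2–4 roles yield PARTIAL. The POLB orientation relative to the other ORFs
  distinguishes the two lineage patterns (co-oriented vs opposite-strand).
  The classifier accepts PLA2-style capsid evidence because the elements
  this package models carry a parvovirus-VP1-like CAP rather than the
  classical PY protein.
* **Errantivirus**: ordered gag (positional: large upstream ORF), pol
  (RT core + integrase motifs), env (all three membrane-fusion features)
  between detected LTRs when present; LTRs strengthen but are not required
  when all three role ORFs are intact. Without an env ORF the call is
  LTR_RETROTRANSPOSON, never errantivirus. Same-strand ORF fragments with
  gaps in [−90, +150] nt are chained as one interrupted gene; `intact`
  requires single-fragment roles.
* **env features** (Kyte–Doolittle hydropathy): signal = mean > 1.6 over an
  8-aa window within the first 30 residues; C-terminal TM = mean > 1.6 over
  a 19-aa window within the last 60; basic cleavage = R-X-(K/R)-R or ≥ 3
  basic residues in a 5-aa window, N-terminal of the TM. Standard window
  sizes/threshold; all configurable.
* **LTR detection**: shared 11-mer anchors grouped by diagonal (±20 for
  indel wobble), dense anchor runs (gaps ≤ 50 nt) delimit candidate
  repeats, copies must not overlap, identity scored by global edit-distance
  alignment. Defaults: length ≥ 150, identity ≥ 90%, span ≤ 12 kb; best
  pair by length × identity.
* **R1 LINE**: a two-ORF architecture where ORF2 carries an RT core
  followed by SF1-helicase motifs starting in its C-terminal third
  (threshold 0.6 of the ORF length, so a domain at 0.7 of a 1000-aa ORF
  qualifies and an N-terminal copy never does). No LTRs required.

## Motif library

The conserved-domain annotation a networked pipeline gets from an online
domain database is replaced by a packaged library of position-constrained
residue patterns (restricted regular expressions) for the domains the
classifiers need: Walker A/B, DDE integrase triad, adenain triad, PLA2,
POLB motif C, RT core (LPQG…YxDD), SF1 helicase (motifs I/II/VI), chromo;
plus a curation blocklist of ubiquitous cellular domains (polymerase,
kinase, phosphatase, BIR, Cu/Zn SOD, serine protease, PD-(D/E)xK nuclease,
RING, C2H2). Patterns were written around each family's published anchor
residues with spacing ranges wide enough for real diversity yet anchored
enough that a random 300-aa protein matches any given pattern with
probability ≪ 1. Every pattern matches its own consensus (tested). Only
domain *labels* are needed downstream, which is why a motif surrogate
suffices.

## VPD construction and curation

`select_representatives` keeps one virus per family (whole-genome 'type'
viruses preferred, ties by name for determinism) plus user-listed
must-include viruses. `purge_cellular_homologs` removes an entry when its
best Smith–Waterman alignment against the host proteome reaches E ≤ 1e-10,
or when it matches the cellular-domain blocklist; every removal is logged
with machine-checkable evidence, the operation is conservative
(|kept| + |removed| = |input|) and idempotent. The E threshold automates
what is in practice a manual curation judgement; it is configurable and
recorded in the removal log.

## Quantitation and the sensitivity experiment

* **Read mapping**: shared 21-mers nominate references; a read maps at
  ≥ 95% identity over ≥ 80% of its length (edit-distance, either strand);
  ties break by shared-k-mer count then reference id.
* **RPKM** = reads / (len/1000) / (total/1e6), exactly.
* **Mini-assembler**: strand-specific de Bruijn unitigs (k = 31); contigs
  below 100 nt or supported by fewer than two distinct reads are discarded.
  The two-read rule is the load-bearing choice: it makes "a few reads fail,
  ten reads succeed" reproducible, because detection requires overlapping
  read starts, not just coverage.
* **Sensitivity experiment**: for each N, sample N error-free 150 bp reads
  uniformly (seeded), assemble, search against the VPD; success = any HSP
  with E < 0.1. Rates over 20 replicates are smoothed by a running maximum
  (detection cannot degrade with more reads) before the ≥ 0.5 threshold
  lookup. Error-free reads are the default because the threshold argument
  is about coverage geometry, not sequencing error; an error-rate option
  exists. The absolute threshold is assembler-dependent, which is why the
  claim defended is an upper bound (≤ 10 reads), not an equality.
* **expected_viral_reads** scales a reference experiment's viral read count
  to a new sequencing depth (ref_mapped × new_total / ref_total).

## Phylogenetics

Progressive alignment: UPGMA guide tree on pairwise-identity distances,
profile-profile merges by global DP with sum-of-pairs column scores and a
linear gap penalty of 8 — deliberately simple; the package's phylogenetic
claims are qualitative clustering, not branch-length inference. Distances:
Kimura's protein correction d = −ln(1 − p − p²/5) by default, capped at
10.0 where the formula's domain ends (p ≥ 0.85); optionally a
Jones–Taylor–Thornton maximum-likelihood distance. The JTT transition model
is reconstructed from the packaged JTT log-odds table (equilibrium
frequencies as the Perron eigenvector of the odds matrix; rate matrix via
the matrix logarithm of the implied 250-PAM transition matrix, scaled to
one substitution/site). The published table is rounded to one decimal, so
this reconstruction is approximate; it preserves the exchangeability
structure that qualitative clustering rests on, and Kimura remains the
default. Neighbor joining is the classical algorithm with standard
branch-length formulas; Q-criterion ties break by the lexicographically
smallest label pair, negative branch estimates are clamped to zero with a
logged note, and on additive matrices the generating tree is recovered to
< 1e-9 (tested, and cross-checked against an independent NJ
implementation). Newick output quotes labels containing spaces and
round-trips through a standard parser.

## Synthetic data

The generator emulates the *decision-relevant structure* of real screening
data: i.i.d. host contigs at a chosen GC; planted elements built from
synthetic template proteins constructed around the packaged motif consensi;
uniform-start error-free reads (2×150 paired-end semantics available).
Divergence to a target identity substitutes BLOSUM62-weighted residues at
exactly round((1−t)·L) positions — landing within ±2% of the target by
construction — while protecting motif spans, mirroring catalytic-residue
conservation in real families. Planted ORFs are preceded by a 9-nt in-frame
stop cassette so called ORFs start at the gene ATG and ground-truth spans
are exact. EVEs get ≥ 200 nt host flanks and optional nonsense (TAA codon
replacement) and frameshift (single-nt deletion) edits; viruses exist only
as transcripts; Mavericks place POLB last (opposite strand for lineage 2);
errantiviruses carry identical 300-nt LTR copies.

What the generator does *not* emulate — repeat families, splicing,
sequencing error profiles, uneven coverage, assembly artifacts, real
phylogenetic signal — bounds what passing tests show: they validate the
decision procedure and its statistics, not performance on real cell-line
data, for which the database, host proteome and thresholds would need
real-world inputs.

## Problem sizes and determinism

The test suite and the acceptance script run on synthetic datasets of a few
tens of kilobases with a seven-protein database — sizes chosen so the full
suite completes in minutes on one CPU while still exercising every decision
path at meaningful replicate counts (50 seeds per element class, 20 clean
replicates, 200 oracle instances). All randomness flows from explicit
seeds through `numpy` SeedSequences; pipeline reruns with the same
configuration and seed reproduce reports byte-identically (tested).

## Known limitations

* No composition-based statistics and no low-complexity masking; borderline
  hits in biased sequence may score optimistically. Off by default and
  documented rather than silently applied.
* E-values use raw search-space sizes (see above).
* The assembler is strand-specific and single-k; it is a sensitivity-model
  instrument, not a production assembler.
* The errantivirus Ψ packaging signal is not detected (no operational
  definition exists to implement).
* Host/viral reference sets are user-supplied FASTA; no taxonomy service or
  remote database access is used anywhere.
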