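"""Motif annotation and the hit-triage decision procedure."""

import math

import pytest

from viroscreen.elements import annotate_elements
from viroscreen.motifs import annotate_motifs, motif_library
from viroscreen.search import tblastn_search
from viroscreen.seqio import Alphabet, SequenceRecord
from viroscreen.synthdata import (
    _orf_nt,
    _rng,
    back_translate,
    make_host_genome,
    make_host_transcripts,
    mutate_protein,
    plant_element,
)
from viroscreen.triage import (
    TriageContext,
    Verdict,
    classify_hit,
    count_interruptions,
    delta_log10_e,
    differential_homology,
    triage_hits,
)

from conftest import random_protein


class TestAnnotateMotifs:
    def test_walker_a_found_at_planted_offset(self, rng):
        lib = motif_library()
        walker = next(m.consensus for m in lib if m.name == "WALKER_A")
        seq = random_protein(rng, 73) + walker + random_protein(rng, 50)
        hits = [h for h in annotate_motifs(seq, lib) if h.name == "WALKER_A"]
        assert any(h.start == 73 for h in hits)

    def test_homopolymer_has_no_hits(self):
        assert annotate_motifs("A" * 300) == []

    def test_sf1_helicase_cterminal_in_template(self, templates):
        seq = templates["tpl_r1_orf2"].sequence
        hits = [
            h for h in annotate_motifs(seq) if h.name == "SF1_HELICASE"
        ]
        assert hits and hits[0].start > 700


class TestDifferentialHomology:
    def test_rule_arithmetic(self):
        assert delta_log10_e(1e-6, 1e-40) == pytest.approx(34)
        assert delta_log10_e(1e-30, 1e-35) == pytest.approx(5)
        # zero E-values floored, not -inf
        assert math.isfinite(delta_log10_e(0.0, 1e-10))

    def test_host_verdict_when_host_much_better(self, rng):
        region = random_protein(rng, 120)
        host = [SequenceRecord("hostP", region, alphabet=Alphabet.PROTEIN)]
        viral = [SequenceRecord(
            "viralP",
            region[:30] + random_protein(rng, 90),
            alphabet=Alphabet.PROTEIN,
        )]
        comp, delta, hsp = differential_homology(region, viral, host)
        assert comp == "HOST"
        assert delta >= 20
        assert hsp.subject_id == "hostP"

    def test_viral_like_when_no_host_hit(self, rng):
        region = random_protein(rng, 100)
        viral = [SequenceRecord("v", region, alphabet=Alphabet.PROTEIN)]
        host = [SequenceRecord("h", random_protein(rng, 100),
                               alphabet=Alphabet.PROTEIN)]
        comp, delta, _ = differential_homology(region, viral, host)
        assert comp == "VIRAL_LIKE"

    def test_close_call_stays_viral_like(self, rng):
        # host only slightly better than viral: below the 20-order threshold
        region = random_protein(rng, 150)
        viral = [SequenceRecord("v", region[:140], alphabet=Alphabet.PROTEIN)]
        host = [SequenceRecord("h", region, alphabet=Alphabet.PROTEIN)]
        comp, delta, _ = differential_homology(region, viral, host)
        assert delta is not None and delta < 20
        assert comp == "VIRAL_LIKE"

    def test_empty_host_refs_is_viral_like(self, rng):
        region = random_protein(rng, 100)
        comp, delta, hsp = differential_homology(region, [], [])
        assert comp == "VIRAL_LIKE" and delta is None and hsp is None


class TestCountInterruptions:
    def _region(self, templates, nonsense=0, frameshift=0, seed=4):
        from viroscreen.synthdata import _apply_interruptions

        rng = _rng(seed, 21)
        prot = mutate_protein(templates["tpl_rhabdo_N"], 0.8, seed)
        orf = _orf_nt(prot, rng)
        orf = _apply_interruptions(orf, nonsense, frameshift, rng)
        ref = SequenceRecord("ref", templates["tpl_rhabdo_N"].sequence,
                             alphabet=Alphabet.PROTEIN)
        return orf, ref

    def test_intact_orf_zero_zero(self, templates):
        region, ref = self._region(templates)
        assert count_interruptions(region, ref) == (0, 0)

    def test_single_nonsense_codon_counted(self, templates):
        region, ref = self._region(templates, nonsense=1)
        n, f = count_interruptions(region, ref)
        assert (n, f) == (1, 0)

    def test_single_nt_deletion_counted_as_frameshift(self, templates):
        region, ref = self._region(templates, frameshift=1)
        n, f = count_interruptions(region, ref)
        assert f == 1 and n == 0


def _context(genome, transcriptome, toy_vpd, host_refs=()):
    return TriageContext(
        genome={r.id: r for r in genome},
        transcriptome={r.id: r for r in transcriptome},
        viral_refs=toy_vpd.records(),
        host_refs=list(host_refs),
        viral_meta=toy_vpd.meta_by_protein(),
    )


@pytest.fixture(scope="module")
def eve_dataset(templates):
    genome = make_host_genome(3, 6000, 0.4, seed=61)
    genome, tx, truth = plant_element(
        genome, "EVE", templates,
        {"target_identity": 0.7, "transcribed": True}, seed=61,
    )
    return genome, tx, truth


class TestClassifyHit:
    def test_eve_verdict_for_genomic_rna_virus_relic(
        self, eve_dataset, toy_vpd
    ):
        genome, tx, truth = eve_dataset
        ctx = _context(genome, tx, toy_vpd)
        hits = tblastn_search(toy_vpd.records(), genome)
        assert hits
        verdicts = triage_hits(hits, "genome", ctx)
        assert [v.verdict for v in verdicts] == [Verdict.EVE]
        eve = verdicts[0].eve_call
        assert eve.genome_present and eve.transcriptome_present
        assert eve.closest_virus == "Toy rhabdovirus"

    def test_transcriptome_only_hit_is_putative_virus(
        self, toy_vpd, templates
    ):
        genome = make_host_genome(3, 6000, 0.4, seed=62)
        _, vtx, _ = plant_element(
            genome, "VIRUS", templates, {"target_identity": 0.7}, seed=62
        )
        ctx = _context(genome, vtx, toy_vpd)
        hits = tblastn_search(toy_vpd.records(), vtx)
        verdicts = triage_hits(hits, "transcriptome", ctx)
        assert verdicts
        assert all(v.verdict is Verdict.PUTATIVE_VIRUS for v in verdicts)
        assert any("absent from genome" in e
                   for v in verdicts for e in v.evidence)

    def test_hit_inside_element_annotation_is_transposon(
        self, toy_vpd, templates
    ):
        genome = make_host_genome(3, 9000, 0.4, seed=63)
        genome, _, truth = plant_element(
            genome, "MAVERICK", templates, {"target_identity": 0.75}, seed=63
        )
        contig = next(r for r in genome if r.id == truth.contig_id)
        ctx = _context(genome, [], toy_vpd)
        ctx.elements = {
            contig.id: annotate_elements(contig.id, contig.residues)
        }
        # fabricate a viral hit inside the element span by searching with
        # the element's own POLB-bearing region translated
        hits = tblastn_search(toy_vpd.records(), genome, e_cutoff=10.0)
        if not hits:  # random homology may be absent; plant a real one
            prot = mutate_protein(templates["tpl_rhabdo_G"], 0.8, 63)
            mid = (truth.span[0] + truth.span[1]) // 2
            s = contig.residues
            s2 = s[:mid] + back_translate(prot, _rng(63, 5)) + s[mid:]
            genome = [r if r.id != contig.id else
                      SequenceRecord(r.id, s2) for r in genome]
            ctx = _context(genome, [], toy_vpd)
            ctx.elements = {
                contig.id: annotate_elements(
                    contig.id,
                    next(r.residues for r in genome if r.id == contig.id),
                )
            }
            hits = tblastn_search(toy_vpd.records(), genome)
        verdicts = triage_hits(hits, "genome", ctx)
        inside = [
            v for v in verdicts
            if v.region[0] >= truth.span[0] - 50
            and v.region[1] <= truth.span[1] + len(v.region) + 2000
        ]
        assert any(
            v.verdict is Verdict.TRANSPOSON_MAVERICK for v in inside
        )

    def test_host_like_hit_classified_host(self, toy_vpd, rng):
        # a region identical to a host protein, weakly similar to a viral one
        region_prot = random_protein(rng, 150)
        host_ref = SequenceRecord("hostP", region_prot,
                                  alphabet=Alphabet.PROTEIN)
        contig = SequenceRecord(
            "c1", back_translate(region_prot, _rng(64, 6))
        )
        viral_q = SequenceRecord(
            "viralQ", region_prot[:40] + random_protein(rng, 110),
            alphabet=Alphabet.PROTEIN,
        )
        from viroscreen.vpd import ViralProteinEntry, VpdDatabase

        vpd = VpdDatabase(entries=[ViralProteinEntry(
            "viralQ", "v", "f", "V", "minus_ssRNA", True, viral_q.residues
        )])
        ctx = _context([contig], [], vpd, host_refs=[host_ref])
        hits = tblastn_search([viral_q], [contig])
        assert hits
        verdicts = triage_hits(hits, "genome", ctx)
        assert verdicts[0].verdict is Verdict.HOST
        assert verdicts[0].delta_log10_e >= 20

    def test_totality_and_order_invariance(self, eve_dataset, toy_vpd):
        genome, tx, truth = eve_dataset
        ctx = _context(genome, tx, toy_vpd)
        hits = tblastn_search(toy_vpd.records(), genome + tx)
        v1 = triage_hits(hits, "genome", ctx)
        v2 = triage_hits(list(reversed(hits)), "genome", ctx)
        key = lambda vs: sorted(
            (v.contig_id, v.region, v.verdict.value) for v in vs
        )
        assert key(v1) == key(v2)
        # every significant hit falls in exactly one region
        n_in_regions = sum(
            1 for h in hits for v in v1
            if h.subject_id == v.contig_id
            and v.region[0] <= h.s_start and h.s_end <= v.region[1]
        )
        assert n_in_regions == len(hits)
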