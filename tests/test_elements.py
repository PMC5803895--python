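"""Element architecture classifiers: Maverick, errantivirus, R1 LINE."""

import numpy as np
import pytest

from viroscreen.elements import (
    ElementClass,
    annotate_elements,
    classify_errantivirus,
    classify_maverick,
    classify_r1_line,
    detect_ltrs,
    env_features,
)
from viroscreen.seqio import find_orfs, reverse_complement
from viroscreen.synthdata import (
    _rand_nt,
    _rng,
    make_host_genome,
    plant_element,
    template_bundle,
)

from conftest import random_nt


class TestEnvFeatures:
    def test_template_env_has_all_features(self, templates):
        f = env_features(templates["tpl_env"].sequence)
        assert f.all_present
        assert f.signal_pos[0] < 30
        assert f.tm_pos[0] >= len(templates["tpl_env"].sequence) - 60
        assert f.cleavage_pos[0] < f.tm_pos[0]

    def test_featureless_protein_all_false(self):
        f = env_features("S" * 200)
        assert not (f.has_signal_seq or f.has_cterm_tm or f.has_basic_cleavage)
        assert f.signal_pos is None and f.tm_pos is None

    def test_tm_not_cterminal_rejected(self):
        # hydrophobic stretch at position 10 only: counts as signal, not TM
        seq = "S" * 10 + "LLLLLLLLLLLLLLLLLLL" + "S" * 171
        f = env_features(seq)
        assert not f.has_cterm_tm

    def test_short_protein_is_error(self):
        with pytest.raises(ValueError):
            env_features("M" * 99)


class TestDetectLtrs:
    def test_exact_terminal_repeats(self, rng):
        ltr = random_nt(rng, 300)
        contig = ltr + random_nt(rng, 4000) + ltr
        pair = detect_ltrs(contig)
        assert pair is not None
        assert pair.pct_identity == 100.0
        assert pair.left == (0, 300) or pair.left[0] < 50
        assert pair.same_orientation

    def test_no_repeats_none(self, rng):
        assert detect_ltrs(random_nt(rng, 3000)) is None

    def test_diverged_repeats_need_lower_threshold(self, rng):
        ltr = random_nt(rng, 300)
        mutated = list(ltr)
        picks = rng.choice(300, size=45, replace=False)  # 85% identity
        for p in picks:
            mutated[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[p]]
        contig = ltr + random_nt(rng, 3000) + "".join(mutated)
        assert detect_ltrs(contig, min_identity=90) is None
        pair = detect_ltrs(contig, min_identity=80)
        assert pair is not None and 80 <= pair.pct_identity < 90

    def test_identity_symmetric_under_revcomp(self, rng):
        ltr = random_nt(rng, 200)
        contig = ltr + random_nt(rng, 2500) + ltr
        a = detect_ltrs(contig)
        b = detect_ltrs(reverse_complement(contig))
        assert a is not None and b is not None
        assert a.pct_identity == b.pct_identity


def _planted_contig(cls, seed, identity=0.75, **params):
    templates = template_bundle()
    genome = make_host_genome(3, 9000, 0.4, seed=seed)
    params = {"target_identity": identity, **params}
    genome, _, truth = plant_element(genome, cls, templates, params, seed=seed)
    contig = next(r for r in genome if r.id == truth.contig_id)
    return contig, truth


class TestMaverick:
    def test_lineage1_same_strand(self):
        contig, truth = _planted_contig("MAVERICK", 21, lineage=1)
        orfs = find_orfs(contig.residues, 100, contig.id)
        ann = classify_maverick(orfs)
        assert ann.element_class is ElementClass.MAVERICK
        assert any("lineage-1" in e for e in ann.evidence)
        roles = {r for _, r in ann.orfs}
        assert roles == {"ATP", "INT", "PRO", "POLB", "CAP"}

    def test_lineage2_polb_opposite_strand(self):
        contig, truth = _planted_contig("MAVERICK", 22, lineage=2)
        orfs = find_orfs(contig.residues, 100, contig.id)
        ann = classify_maverick(orfs)
        assert ann.element_class is ElementClass.MAVERICK
        assert any("lineage-2" in e for e in ann.evidence)
        polb = next(o for o, r in ann.orfs if r == "POLB")
        others = [o for o, r in ann.orfs if r != "POLB"]
        assert all(o.strand != polb.strand for o in others)

    def test_three_hallmarks_is_partial(self, templates):
        parts = []
        rng = _rng(5, 55)
        from viroscreen.synthdata import _orf_nt

        for tpl in ("tpl_ATP", "tpl_INT", "tpl_PRO"):
            parts.append(_orf_nt(templates[tpl].sequence, rng))
            parts.append(_rand_nt(rng, 80))
        contig = _rand_nt(rng, 400) + "".join(parts) + _rand_nt(rng, 400)
        orfs = find_orfs(contig, 100, "c")
        ann = classify_maverick(orfs)
        assert ann is not None
        assert ann.element_class is ElementClass.PARTIAL


class TestErrantivirus:
    def test_intact_element_with_ltrs(self):
        contig, truth = _planted_contig("ERRANTIVIRUS", 31)
        ltr = detect_ltrs(contig.residues)
        orfs = find_orfs(contig.residues, 100, contig.id)
        ann = classify_errantivirus(contig.residues, orfs, ltr)
        assert ann.element_class is ElementClass.ERRANTIVIRUS
        assert ann.intact
        assert [r for _, r in ann.orfs] == ["GAG", "POL", "ENV"]
        assert (ann.start, ann.end) == truth.span

    def test_env_internal_stop_not_intact(self):
        contig, truth = _planted_contig(
            "ERRANTIVIRUS", 32, interruptions=(1, 0)
        )
        ltr = detect_ltrs(contig.residues)
        orfs = find_orfs(contig.residues, 100, contig.id)
        ann = classify_errantivirus(contig.residues, orfs, ltr)
        assert ann.element_class is ElementClass.ERRANTIVIRUS
        assert not ann.intact

    def test_gag_pol_only_is_ltr_retrotransposon(self, templates):
        from viroscreen.synthdata import _orf_nt

        rng = _rng(6, 66)
        ltr = _rand_nt(rng, 300)
        parts = [ltr, _rand_nt(rng, 80)]
        for tpl in ("tpl_gag", "tpl_pol"):
            parts.append(_orf_nt(templates[tpl].sequence, rng))
            parts.append(_rand_nt(rng, 180))
        parts.append(ltr)
        contig = _rand_nt(rng, 350) + "".join(parts) + _rand_nt(rng, 350)
        ltr_pair = detect_ltrs(contig)
        orfs = find_orfs(contig, 100, "c")
        ann = classify_errantivirus(contig, orfs, ltr_pair)
        assert ann is not None
        assert ann.element_class is ElementClass.LTR_RETROTRANSPOSON


class TestR1Line:
    def test_planted_architecture_recognised(self):
        contig, truth = _planted_contig("R1_LINE", 41)
        orfs = find_orfs(contig.residues, 100, contig.id)
        ann = classify_r1_line(orfs)
        assert ann.element_class is ElementClass.R1_LINE
        assert [r for _, r in ann.orfs] == ["ORF1", "ORF2"]

    def test_helicase_in_nterminal_third_rejected(self, templates, rng):
        from viroscreen.motifs import motif_library
        from viroscreen.synthdata import (
            _orf_nt,
            _rand_protein,
            _with_motifs,
            _consensus,
        )

        g = _rng(7, 77)
        bad_orf2 = _with_motifs(
            g, 1000,
            [(620, _consensus("RT_CORE")), (120, _consensus("SF1_HELICASE"))],
            "bad",
        )
        parts = [
            _orf_nt(templates["tpl_r1_orf1"].sequence, g),
            _rand_nt(g, 30),
            _orf_nt(bad_orf2.sequence, g),
        ]
        contig = _rand_nt(g, 400) + "".join(parts) + _rand_nt(g, 400)
        orfs = find_orfs(contig, 100, "c")
        assert classify_r1_line(orfs) is None

    def test_single_orf_rt_only_rejected(self, templates):
        from viroscreen.synthdata import _orf_nt

        g = _rng(8, 88)
        contig = (
            _rand_nt(g, 400)
            + _orf_nt(templates["tpl_pol"].sequence, g)
            + _rand_nt(g, 400)
        )
        orfs = find_orfs(contig, 100, "c")
        assert classify_r1_line(orfs) is None


class TestContigOrchestration:
    def test_annotations_independent_of_record_order(self):
        contig, truth = _planted_contig("MAVERICK", 51)
        a = annotate_elements(contig.id, contig.residues)
        b = annotate_elements(contig.id, contig.residues)
        assert [(x.element_class, x.start, x.end) for x in a] == [
            (x.element_class, x.start, x.end) for x in b
        ]

    def test_no_elements_on_plain_host_sequence(self):
        genome = make_host_genome(1, 8000, 0.4, seed=9)
        anns = annotate_elements("c", genome[0].residues)
        assert all(a.element_class is ElementClass.PARTIAL for a in anns) or not anns
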