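"""Intron phases, domain-to-genome mapping, PR/VQR typing."""

import numpy as np
import pytest

from wrkyscan import synthetic
from wrkyscan.domain_scan import scan_domains
from wrkyscan.gene_structure import (domains_without_typed_intron,
                                     exon_count, intron_phases,
                                     intron_type_tallies, map_domain_to_cds,
                                     residue_span, residues_to_genomic,
                                     type_domain_introns)
from wrkyscan.genome_io import TranscriptModel


def _two_exon(offset: int, rest: int = 30) -> TranscriptModel:
    """Transcript whose single intron sits after `offset` coding nt."""
    total = offset + rest
    assert total % 3 == 0
    e1 = (1, offset)
    e2 = (offset + 101, offset + 100 + rest)
    return TranscriptModel("t", "g", "c", "+", exons=[e1, e2],
                           cds=[e1, e2])


class TestPhases:
    @pytest.mark.parametrize("offset,phase", [(6, 0), (7, 1), (8, 2)])
    def test_phase_examples(self, offset, phase):
        rest = (3 - offset % 3) % 3 + 30
        recs = intron_phases(_two_exon(offset, rest))
        assert [r.phase for r in recs] == [phase]
        assert recs[0].coding_offset == offset

    def test_interrupted_residue_and_context(self):
        protein = "MARVQR"
        recs = intron_phases(_two_exon(8, 13), protein)
        assert recs[0].interrupted_residue == protein[8 // 3]
        recs0 = intron_phases(_two_exon(6, 15), protein)
        assert recs0[0].following_context == protein[2:5]

    def test_utr_intron_not_in_cds(self):
        # intron between a 5' UTR exon and the coding exon
        t = TranscriptModel("t", "g", "c", "+",
                            exons=[(1, 50), (151, 300)],
                            cds=[(151, 300)], partial=True)
        recs = intron_phases(t)
        assert len(recs) == 1 and not recs[0].in_cds

    def test_exon_count(self):
        assert exon_count(_two_exon(6, 15)) == 2
        t = TranscriptModel("t", "g", "c", "+", [(1, 30)], [(1, 30)])
        assert exon_count(t) == 1

    def test_intron_count_is_exons_minus_one(self, rng):
        for _ in range(20):
            prot, _ = synthetic.gen_protein("IIc", rng)
            plans = [synthetic.IntronPlanItem("plain", offset=int(o))
                     for o in sorted(rng.choice(
                         np.arange(1, 3 * len(prot)), 3, replace=False))]
            loc = synthetic.gen_locus(prot, plans, rng)
            t = TranscriptModel("t", "g", "c", "+", loc.exons_plus,
                                loc.exons_plus)
            assert len(intron_phases(t)) == exon_count(t) - 1


class TestDomainMapping:
    def test_single_exon_closed_form(self):
        # residues 10-60 (1-based incl.) in a CDS starting at 101: nt
        # offsets 27..179 -> genomic 128..280
        t = TranscriptModel("t", "g", "c", "+", [(101, 400)], [(101, 400)])
        ivs = residues_to_genomic(t, 9, 60)
        assert ivs == [(128, 280)]

    def test_minus_strand_mirror(self):
        t = TranscriptModel("t", "g", "c", "-", [(101, 400)], [(101, 400)])
        ivs = residues_to_genomic(t, 9, 60)
        assert ivs == [(221, 373)]
        assert sum(e - s + 1 for s, e in ivs) == 3 * 51

    def test_exon_junction_split_lengths(self):
        # 51 residues crossing one junction: interval lengths sum to 153
        t = _two_exon(90, 210)
        ivs = residues_to_genomic(t, 9, 60)
        assert len(ivs) == 2
        assert sum(e - s + 1 for s, e in ivs) == 3 * 51

    @pytest.mark.parametrize("strand", "+-")
    def test_per_residue_oracle(self, strand, rng):
        """Block mapping equals independent residue-by-residue mapping."""
        prot, truth = synthetic.gen_protein("IId", rng)
        plans = [synthetic.IntronPlanItem("plain", offset=int(o))
                 for o in sorted(rng.choice(np.arange(1, 3 * len(prot)),
                                            4, replace=False))]
        loc = synthetic.gen_locus(prot, plans, rng, strand=strand)
        exons = (loc.exons_plus if strand == "+" else loc.exons_plus[::-1])
        t = TranscriptModel("t", "g", "c", strand, list(exons), list(exons))
        # per-nucleotide oracle: enumerate genomic positions of the CDS in
        # translation order
        order = []
        for s, e in t.cds:
            rngpos = range(s, e + 1) if strand == "+" else range(e, s - 1, -1)
            order.extend(rngpos)
        a, b = truth.domain_spans[0]
        expected = sorted(order[3 * a: 3 * b])
        d = [x for x in scan_domains(prot) if x.complete][0]
        ivs = map_domain_to_cds(d, t)
        got = sorted(p for s, e in ivs for p in range(s, e + 1))
        assert got == expected


class TestTyping:
    def _typed(self, label, plan_kind, seed, phase=None):
        rng = np.random.default_rng(seed)
        prot, truth = synthetic.gen_protein(label, rng)
        hstart = truth.heptamers[0]["start"]
        if plan_kind == "PR":
            plan = synthetic.IntronPlanItem("PR", residue=hstart + 1,
                                            phase=phase or 2)
        else:
            plan = synthetic.IntronPlanItem("VQR", residue=hstart + 7)
        loc = synthetic.gen_locus(prot, [plan], rng)
        t = TranscriptModel("t", "g", "c", "+", loc.exons_plus,
                            loc.exons_plus)
        recs = intron_phases(t, prot)
        spans = [residue_span(d) for d in scan_domains(prot)]
        return type_domain_introns(recs, spans, prot), truth

    def test_phase2_pr(self):
        recs, _ = self._typed("IIc", "PR", 0)
        assert [(r.type, r.phase) for r in recs] == [("PR", 2)]
        assert recs[0].interrupted_residue == "R"

    def test_phase1_pr(self):
        recs, _ = self._typed("IIe", "PR", 1, phase=1)
        assert [(r.type, r.phase) for r in recs] == [("PR", 1)]

    def test_phase0_vqr(self):
        recs, _ = self._typed("IIa", "VQR", 2)
        assert [(r.type, r.phase) for r in recs] == [("VQR", 0)]
        assert recs[0].following_context == "VQR"

    def test_out_of_domain_introns_untyped(self, rng):
        prot, truth = synthetic.gen_protein("IId", rng)
        a, b = truth.domain_spans[0]
        off = 3 * b + 30 + 2  # phase-2 position well past the domain
        loc = synthetic.gen_locus(
            prot, [synthetic.IntronPlanItem("plain", offset=off)], rng)
        t = TranscriptModel("t", "g", "c", "+", loc.exons_plus,
                            loc.exons_plus)
        recs = intron_phases(t, prot)
        spans = [residue_span(d) for d in scan_domains(prot)]
        type_domain_introns(recs, spans, prot)
        assert recs[0].type == "none" and not recs[0].within_domain

    def test_strand_mirror_invariance(self):
        seed = 9
        results = []
        for strand in "+-":
            rng = np.random.default_rng(seed)
            prot, truth = synthetic.gen_protein("IIb", rng)
            plan = synthetic.IntronPlanItem(
                "VQR", residue=truth.heptamers[0]["start"] + 7)
            loc = synthetic.gen_locus(prot, [plan],
                                      np.random.default_rng(seed),
                                      strand=strand)
            exons = (loc.exons_plus if strand == "+"
                     else loc.exons_plus[::-1])
            t = TranscriptModel("t", "g", "c", strand, list(exons),
                                list(exons))
            recs = intron_phases(t, prot)
            spans = [residue_span(d) for d in scan_domains(prot)]
            type_domain_introns(recs, spans, prot)
            results.append([(r.coding_offset, r.phase, r.type)
                            for r in recs])
        assert results[0] == results[1]

    def test_tallies_and_untyped_domains(self):
        recs, truth = self._typed("IIc", "PR", 4)
        assert intron_type_tallies(recs) == {"PR": 1, "VQR": 0, "none": 0}
        spans = [tuple(s) for s in truth.domain_spans]
        assert domains_without_typed_intron(spans, recs) == 0
        assert domains_without_typed_intron(spans, []) == 1
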