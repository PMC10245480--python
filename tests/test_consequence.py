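"""Consequence calling: positional classes, codon effects, oracle agreement."""

import numpy as np
import pytest

from txeffect.consequence import (
    ConsequenceCall,
    NoCallError,
    annotate_all,
    call_consequence,
)
from txeffect.models import GenomeRef, OrfModel, TranscriptModel, Variant, reverse_complement
from txeffect.orf import translate

from conftest import ENGINE_TO_ORACLE, oracle_coding_effect, random_coding_transcript

BASES = "ACGT"


def make_gene(strand="+"):
    """Two-exon transcript with a full-CDS ORF on a hand-built contig.

    Spliced layout (200 nt): 30 nt 5'UTR, 120 nt CDS (ATG + 38 codons
    scaffold), 3 nt stop is inside the CDS span, 50 nt 3'UTR.
    """
    utr5 = "C" * 30
    cds = "ATG" + "AAA" * 37 + "GAA" + "TAA"  # M + K*37 + E, stop
    utr3 = "G" * 50
    spliced = utr5 + cds + utr3
    exon_len1 = 80
    pieces = [spliced[:exon_len1], spliced[exon_len1:]]
    intron = "T" * 40  # no GT/AG needed: splice terms are positional
    if strand == "+":
        contig = "A" * 10 + pieces[0] + intron + pieces[1] + "A" * 10
        exons = [(10, 10 + exon_len1), (130, 130 + len(pieces[1]))]
    else:
        contig = (
            "A" * 10
            + reverse_complement(pieces[1])
            + intron
            + reverse_complement(pieces[0])
            + "A" * 10
        )
        e2 = (10, 10 + len(pieces[1]))
        e1 = (e2[1] + 40, e2[1] + 40 + exon_len1)
        exons = [e2, e1]
    g = GenomeRef({"chrT": contig})
    t = TranscriptModel("tx1", "gene1", "chrT", strand, exons)
    assert t.spliced_sequence(g) == spliced
    orf = OrfModel(
        "tx1", 30, 30 + len(cds), 0.95, translate(cds[:-3]), True,
        cds_blocks=t.tx_span_to_blocks(30, 30 + len(cds)), orf_id="tx1.orf0",
    )
    return g, t, orf


def snv_at(t, g, pos0, alt=None):
    ref = g.fetch(t.contig, pos0, pos0 + 1)
    if alt is None:
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
    return Variant(t.contig, pos0 + 1, ref, alt)


class TestPositionalClasses:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_deep_intron(self, strand):
        g, t, orf = make_gene(strand)
        (intron_s, intron_e) = t.introns[0]
        mid = (intron_s + intron_e) // 2
        call = call_consequence(snv_at(t, g, mid), t, orf, g)
        assert call.terms == {"intron_variant"}

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_splice_donor_acceptor_region(self, strand):
        g, t, orf = make_gene(strand)
        s, e = t.introns[0]
        donor = s if strand == "+" else e - 1
        acceptor = e - 1 if strand == "+" else s
        step = 1 if strand == "+" else -1
        assert call_consequence(snv_at(t, g, donor), t, orf, g).terms == {
            "splice_donor_variant"
        }
        assert call_consequence(snv_at(t, g, donor + step), t, orf, g).terms == {
            "splice_donor_variant"
        }
        assert call_consequence(snv_at(t, g, acceptor), t, orf, g).terms == {
            "splice_acceptor_variant"
        }
        assert call_consequence(
            snv_at(t, g, donor + 4 * step), t, orf, g
        ).terms == {"splice_region_variant"}

    def test_exonic_splice_region_co_assigned(self):
        g, t, orf = make_gene("+")
        last_exon1 = t.exons[0][1] - 1  # CDS base adjacent to the junction
        call = call_consequence(snv_at(t, g, last_exon1), t, orf, g)
        assert "splice_region_variant" in call.terms
        assert call.terms & {"missense_variant", "synonymous_variant", "stop_gained"}

    def test_utrs(self):
        g, t, orf = make_gene("+")
        five = call_consequence(snv_at(t, g, t.tx_to_genome(5)), t, orf, g)
        three = call_consequence(snv_at(t, g, t.tx_to_genome(190)), t, orf, g)
        assert five.terms == {"5_prime_UTR_variant"}
        assert three.terms == {"3_prime_UTR_variant"}

    def test_noncoding_transcript(self):
        g, t, _ = make_gene("+")
        call = call_consequence(snv_at(t, g, t.tx_to_genome(100)), t, None, g)
        assert call.terms == {"non_coding_transcript_exon_variant"}

    def test_upstream_downstream_and_intergenic(self):
        g, t, orf = make_gene("+")
        left = snv_at(t, g, 2)
        right = snv_at(t, g, len(g.contigs["chrT"]) - 2)
        assert call_consequence(left, t, orf, g).terms == {"upstream_gene_variant"}
        assert call_consequence(right, t, orf, g).terms == {"downstream_gene_variant"}
        far = call_consequence(left, t, orf, g, window=1)
        assert far.terms == {"intergenic_variant"}
        # on the minus strand the sides swap
        g2, t2, orf2 = make_gene("-")
        assert call_consequence(snv_at(t2, g2, 2), t2, orf2, g2).terms == {
            "downstream_gene_variant"
        }

    def test_contig_mismatch_is_no_call(self):
        g, t, orf = make_gene("+")
        with pytest.raises(NoCallError):
            call_consequence(Variant("chrX", 50, "A", "G"), t, orf, g)


class TestCodingSnvs:
    def test_stop_gained_from_lysine_codon(self):
        g, t, orf = make_gene("+")
        # codon 2 is AAA (K); A>T at its first base gives TAA (stop)
        pos0 = t.tx_to_genome(33)
        call = call_consequence(Variant("chrT", pos0 + 1, "A", "T"), t, orf, g)
        assert call.terms == {"stop_gained"}
        assert call.aa_change == ("K", 2, "*")

    def test_start_lost_m_to_t(self):
        g, t, orf = make_gene("+")
        pos0 = t.tx_to_genome(31)  # middle base of the initiator ATG
        call = call_consequence(Variant("chrT", pos0 + 1, "T", "C"), t, orf, g)
        assert call.terms == {"start_lost"}
        assert call.aa_change == ("M", 1, "T")

    def test_synonymous_third_base(self):
        g, t, orf = make_gene("+")
        pos0 = t.tx_to_genome(35)  # third base of AAA; A>G keeps lysine
        call = call_consequence(Variant("chrT", pos0 + 1, "A", "G"), t, orf, g)
        assert call.terms == {"synonymous_variant"}
        assert call.aa_change is None

    def test_missense(self):
        g, t, orf = make_gene("+")
        pos0 = t.tx_to_genome(33)
        call = call_consequence(Variant("chrT", pos0 + 1, "A", "G"), t, orf, g)
        assert call.terms == {"missense_variant"}
        assert call.aa_change == ("K", 2, "E")

    def test_stop_lost_and_stop_retained(self):
        g, t, orf = make_gene("+")
        stop_first = t.tx_to_genome(orf.tx_end - 3)
        lost = call_consequence(Variant("chrT", stop_first + 1, "T", "C"), t, orf, g)
        assert lost.terms == {"stop_lost"}
        retained = call_consequence(
            Variant("chrT", t.tx_to_genome(orf.tx_end - 1) + 1, "A", "G"), t, orf, g
        )
        assert retained.terms == {"stop_retained_variant"}

    def test_incomplete_orf_never_loses_stop(self):
        g, t, orf = make_gene("+")
        open_orf = OrfModel(
            "tx1", orf.tx_start, orf.tx_end, 0.9,
            translate(t.spliced_sequence(g)[orf.tx_start:orf.tx_end - 3]),
            False, cds_blocks=orf.cds_blocks, orf_id="tx1.orf0",
        )
        pos0 = t.tx_to_genome(orf.tx_end - 3)
        call = call_consequence(Variant("chrT", pos0 + 1, "T", "C"), t, open_orf, g)
        assert "stop_lost" not in call.terms


class TestIndels:
    def test_frameshift(self):
        g, t, orf = make_gene("+")
        pos0 = t.tx_to_genome(60)
        ref = g.fetch("chrT", pos0, pos0 + 2)
        call = call_consequence(Variant("chrT", pos0 + 1, ref, ref[0]), t, orf, g)
        assert "frameshift_variant" in call.terms

    def test_inframe_deletion(self):
        g, t, orf = make_gene("+")
        pos0 = t.tx_to_genome(59)
        ref = g.fetch("chrT", pos0, pos0 + 4)
        call = call_consequence(Variant("chrT", pos0 + 1, ref, ref[0]), t, orf, g)
        assert call.terms == {"inframe_deletion"}

    def test_inframe_insertion(self):
        g, t, orf = make_gene("+")
        pos0 = t.tx_to_genome(59)
        ref = g.fetch("chrT", pos0, pos0 + 1)
        call = call_consequence(
            Variant("chrT", pos0 + 1, ref, ref + "GGG"), t, orf, g
        )
        assert call.terms == {"inframe_insertion"}

    def test_deletion_of_initiator_co_assigns_start_lost(self):
        g, t, orf = make_gene("+")
        anchor = t.tx_to_genome(orf.tx_start) - 1  # base before the ATG
        ref = g.fetch("chrT", anchor, anchor + 4)
        call = call_consequence(Variant("chrT", anchor + 1, ref, ref[0]), t, orf, g)
        assert call.terms == {"inframe_deletion", "start_lost"}


class TestOracleEquivalence:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_random_cds_snvs_match_mutate_and_translate(self, strand):
        rng = np.random.default_rng(42 if strand == "+" else 43)
        checked = 0
        while checked < 300:
            g, t, orf = random_coding_transcript(rng, strand)
            for _ in range(10):
                tx = int(rng.integers(orf.tx_start, orf.tx_end))
                pos0 = t.tx_to_genome(tx)
                ref = g.fetch(t.contig, pos0, pos0 + 1)
                alt = BASES[int(rng.integers(0, 4))]
                if alt == ref:
                    continue
                v = Variant(t.contig, pos0 + 1, ref, alt)
                call = call_consequence(v, t, orf, g)
                coding = [x for x in call.terms if x in ENGINE_TO_ORACLE]
                assert len(coding) == 1, call.terms
                expected = oracle_coding_effect(g, t, orf, pos0, alt)
                assert ENGINE_TO_ORACLE[coding[0]] == expected
                checked += 1

    def test_strand_symmetry(self):
        """Mirroring the locus (revcomp genome, flipped strand and
        coordinates) leaves every consequence term unchanged."""
        rng = np.random.default_rng(77)
        for _ in range(60):
            g, t, orf = random_coding_transcript(rng, "+")
            L = len(g.contigs[t.contig])
            gm = GenomeRef({t.contig: reverse_complement(g.contigs[t.contig])})
            tm = TranscriptModel(
                t.transcript_id, t.gene_id, t.contig, "-",
                [(L - e, L - s) for s, e in t.exons],
            )
            om = OrfModel(
                orf.transcript_id, orf.tx_start, orf.tx_end,
                orf.coding_probability, orf.protein, orf.has_stop,
                cds_blocks=tm.tx_span_to_blocks(orf.tx_start, orf.tx_end),
                orf_id=orf.orf_id,
            )
            pos0 = int(rng.integers(0, L))
            ref = g.fetch(t.contig, pos0, pos0 + 1)
            alt = BASES[int(rng.integers(0, 4))]
            if alt == ref:
                continue
            call = call_consequence(Variant(t.contig, pos0 + 1, ref, alt), t, orf, g)
            mcall = call_consequence(
                Variant(
                    t.contig, L - pos0, reverse_complement(ref),
                    reverse_complement(alt),
                ),
                tm, om, gm,
            )
            assert call.terms == mcall.terms


class TestAnnotateAll:
    def test_counts_and_fallbacks(self):
        g, t, orf = make_gene("+")
        t2 = TranscriptModel("tx2", "gene1", "chrT", "+", [list(t.exons)[0]],
                             novelty="novel", source="custom")
        orf_map = {"tx1": [orf], "tx2": []}
        v_in = snv_at(t, g, t.tx_to_genome(100))
        v_out = Variant("chr9", 5, "A", "G")
        calls = annotate_all(
            [v_in, v_out],
            {"custom": ([t, t2], orf_map), "reference": ([t], {"tx1": [orf]})},
            g,
        )
        # v_in: 2 custom calls (tx1 with orf, tx2 without) + 1 reference;
        # v_out: one intergenic call per source
        assert len(calls) == 5
        for v in (v_in, v_out):
            for src in ("custom", "reference"):
                assert any(
                    c.variant.key() == v.key() and c.source == src for c in calls
                )
        assert all(c.terms for c in calls)

    def test_transcript_with_k_orfs_yields_k_calls(self):
        g, t, orf = make_gene("+")
        orf2 = OrfModel(
            "tx1", orf.tx_start + 3, orf.tx_end, 0.5, orf.protein[1:],
            True, cds_blocks=t.tx_span_to_blocks(orf.tx_start + 3, orf.tx_end),
            orf_id="tx1.orf1",
        )
        v = snv_at(t, g, t.tx_to_genome(100))
        calls = annotate_all(
            [v], {"custom": ([t], {"tx1": [orf, orf2]}),
                  "reference": ([], {})}, g
        )
        assert sum(c.source == "custom" for c in calls) == 2
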