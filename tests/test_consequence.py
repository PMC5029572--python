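"""Consequence annotation on the packaged worked-example fixtures.

Includes a brute-force oracle that fully translates both isoform CDSes with
Biopython and diffs the peptides, independent of the annotation path.
"""

import pytest
from Bio.Seq import Seq

from crypticsplice.acceptor_features import classify_pair
from crypticsplice.consequence import (
    amplicon_lengths,
    annotate_consequence,
    nmd_rule,
)
from crypticsplice.fixtures import ABCB7_PRIMERS
from crypticsplice.genome_io import spliced_sequence
from crypticsplice.synthetic_data import mirror_gene

FIXTURE_NAMES = ["ABCB7", "ENOSF1", "SEPT6", "HINT2", "TMEM14C", "DYNLL1"]


def _annotate(fixture, gene=None, genome=None):
    gene = gene or fixture.gene
    genome = genome or fixture.genome
    from crypticsplice.event_caller import enumerate_events

    event = enumerate_events([gene])[0]
    pair = classify_pair(event, genome)
    tx = gene.transcript(fixture.canonical_tx_id)
    return gene, pair, annotate_consequence(gene, tx, pair, genome)


class TestNmdRule:
    @pytest.mark.parametrize(
        "ptc,junctions,expected",
        [
            (100, [150, 200], True),  # 100 nt upstream of the last junction
            (300, [150, 200], False),  # stop within the last exon
            (150, [120, 200], True),  # exactly 50 nt: boundary inclusive
            (151, [120, 200], False),
            (0, [], False),
        ],
    )
    def test_rule(self, ptc, junctions, expected):
        assert nmd_rule(ptc, junctions) is expected


class TestWorkedExamples:
    @pytest.mark.parametrize("name", FIXTURE_NAMES)
    def test_expected_annotation(self, worked_fixtures, name):
        fixture = worked_fixtures[name]
        _, _, ann = _annotate(fixture)
        for key, expected in fixture.expected.items():
            assert getattr(ann, key) == expected, f"{name}.{key}"

    @pytest.mark.parametrize("name", FIXTURE_NAMES)
    def test_insertion_equals_transcript_length_difference(self, worked_fixtures, name):
        fixture = worked_fixtures[name]
        gene = fixture.gene
        s_can = spliced_sequence(gene, gene.transcript(fixture.canonical_tx_id), fixture.genome)
        s_ab = spliced_sequence(gene, gene.transcript(fixture.cryptic_tx_id), fixture.genome)
        assert len(s_ab) - len(s_can) == fixture.expected["inserted_nt"]

    @pytest.mark.parametrize("name", FIXTURE_NAMES)
    def test_frame_effect_invariant_under_strand_mirror(self, worked_fixtures, name):
        fixture = worked_fixtures[name]
        mirrored, mgenome = mirror_gene(fixture.gene, fixture.genome)
        _, _, plus = _annotate(fixture)
        _, _, minus = _annotate(fixture, gene=mirrored, genome=mgenome)
        assert minus.frame_effect == plus.frame_effect
        assert minus.region == plus.region
        assert minus.inserted_nt == plus.inserted_nt
        assert minus.ptc == plus.ptc
        assert minus.nmd_sensitive == plus.nmd_sensitive

    @pytest.mark.parametrize("name", FIXTURE_NAMES)
    def test_agrees_with_full_translation_oracle(self, worked_fixtures, name):
        """Oracle: translate both isoforms end-to-end and diff the peptides."""
        fixture = worked_fixtures[name]
        gene, pair, ann = _annotate(fixture)
        tx = gene.transcript(fixture.canonical_tx_id)
        ab = gene.transcript(fixture.cryptic_tx_id)
        s_can = spliced_sequence(gene, tx, fixture.genome)
        s_ab = spliced_sequence(gene, ab, fixture.genome)

        # locate CDS start on each isoform independently, via genomic walk
        def tpos(transcript, gpos):
            off = 0
            for s, e in transcript.exons:
                if s <= gpos < e:
                    return off + (gpos - s)
                off += e - s
            raise AssertionError

        start_can = tpos(tx, tx.cds_start)
        start_ab = tpos(ab, ab.cds_start)

        def translate(seq, start):
            coding = seq[start:]
            coding = coding[: len(coding) - len(coding) % 3]
            return str(Seq(coding).translate())

        pep_can = translate(s_can, start_can)
        pep_ab = translate(s_ab, start_ab)
        stop_can = pep_can.find("*")
        stop_ab = pep_ab.find("*")
        if ann.region == "5UTR":
            # CDS untouched: peptides identical
            assert pep_ab[: stop_ab + 1] == pep_can[: stop_can + 1]
            assert not ann.ptc
        elif ann.frame_effect == "in_frame":
            assert (stop_ab < stop_can + ann.inserted_nt // 3) == ann.ptc
            if ann.ptc:
                # oracle PTC position in nt, from the peptide index
                assert start_ab + 3 * stop_ab == ann.ptc_offset
        else:  # frameshift
            assert ann.ptc == (stop_ab != -1 and stop_ab < len(pep_can))
            if ann.ptc:
                assert start_ab + 3 * stop_ab == ann.ptc_offset


class TestAmplicons:
    def test_abcb7_primer_pair_gives_153_and_174(self, worked_fixtures):
        fixture = worked_fixtures["ABCB7"]
        gene = fixture.gene
        s_can = spliced_sequence(gene, gene.transcript(fixture.canonical_tx_id), fixture.genome)
        s_ab = spliced_sequence(gene, gene.transcript(fixture.cryptic_tx_id), fixture.genome)
        amp = amplicon_lengths(s_can, s_ab, *ABCB7_PRIMERS)
        assert (amp.canonical_len, amp.aberrant_len) == (153, 174)
        assert amp.aberrant_len - amp.canonical_len == 21

    def test_primers_flanking_no_event_give_equal_lengths(self, worked_fixtures):
        fixture = worked_fixtures["ABCB7"]
        gene = fixture.gene
        s_can = spliced_sequence(gene, gene.transcript(fixture.canonical_tx_id), fixture.genome)
        s_ab = spliced_sequence(gene, gene.transcript(fixture.cryptic_tx_id), fixture.genome)
        # both primers inside the first exon, upstream of the event
        fwd, rev = s_can[5:25], s_can[50:70]
        amp = amplicon_lengths(s_can, s_ab, fwd, rev)
        assert amp.canonical_len == amp.aberrant_len == 65

    def test_absent_primer_names_the_primer(self):
        with pytest.raises(ValueError, match="fwd"):
            amplicon_lengths("ACGTACGT", "ACGTACGT", "TTTT", "ACGT")

    def test_multiply_matching_primer_rejected(self):
        with pytest.raises(ValueError, match="more than once"):
            amplicon_lengths("ACGTACGT", "ACGTACGT", "ACGT", "CGT")
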