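"""Packaged worked-example fixtures: six cryptic 3' splice-site events.

Each fixture is a minimal four-exon gene carrying one validated-style
upstream cryptic acceptor event:

* ``ABCB7``  -- 21-nt in-frame CDS insertion whose final three bases (the
  canonical AG preceded by T) form a premature termination codon; seven
  added codons; RT-PCR primer pair giving 153 bp (canonical) and 174 bp
  (aberrant) amplicons.
* ``ENOSF1`` -- 15-nt in-frame CDS insertion encoding five residues, no stop.
* ``SEPT6``  -- 17-nt insertion causing a frameshift.
* ``HINT2``  -- 11-nt insertion whose shifted frame terminates within the
  first bases of the next exon.
* ``TMEM14C`` / ``DYNLL1`` -- 14-nt insertions in the 5'UTR.

The chromosome sequences are fixed literal strings committed with the
package (bit-stable, never regenerated). They are synthetic: the genomic
sequences of the real genes are not reproduced here; each fixture satisfies
the printed constraints of its namesake event (insertion length, frame,
stop placement, amplicon sizes) on an otherwise arbitrary background. The
ABCB7 21-mer in particular is an arbitrary sequence meeting all stated
constraints, because the real insertion sequence is not printed anywhere
the package could cite.
"""

from __future__ import annotations

from dataclasses import dataclass

from .event_caller import SplicingEvent, enumerate_events
from .genome_io import GeneModel, TranscriptModel

__all__ = ["WorkedExampleFixture", "build_worked_example_fixtures", "EXPECTED_ANNOTATIONS", "ABCB7_PRIMERS"]

# exon scaffolds (0-based half-open genomic intervals, plus strand)
_SCAFFOLD_A = ((50, 130), (250, 322), (450, 540), (660, 780))  # CDS events
_SCAFFOLD_B = ((50, 130), (250, 340), (450, 540), (660, 780))  # 5'UTR events
_CDS_A = (70, 690)
_CDS_B = (280, 690)

# (scaffold, insertion length, canonical acceptor position)
_GEOMETRY = {
    "ABCB7": ("A", 21, 450),
    "ENOSF1": ("A", 15, 450),
    "SEPT6": ("A", 17, 450),
    "HINT2": ("A", 11, 450),
    "TMEM14C": ("B", 14, 250),
    "DYNLL1": ("B", 14, 250),
}

ABCB7_PRIMERS = ("TCCATTAATTGGGTCGGAGG", "CATCATCCACATGGTAGAGC")

#: Expected consequence annotations, frozen from the constraints each
#: fixture was built to satisfy (verified against a full-translation oracle).
EXPECTED_ANNOTATIONS: dict[str, dict] = {
    "ABCB7": dict(inserted_nt=21, region="CDS", frame_effect="in_frame",
                  added_codons=7, last_codon_is_stop=True, ptc=True,
                  ptc_offset=170, nmd_sensitive=True),
    "ENOSF1": dict(inserted_nt=15, region="CDS", frame_effect="in_frame",
                   added_codons=5, last_codon_is_stop=False, ptc=False,
                   ptc_offset=None, nmd_sensitive=False),
    "SEPT6": dict(inserted_nt=17, region="CDS", frame_effect="frameshift",
                  added_codons=None, last_codon_is_stop=False, ptc=True,
                  ptc_offset=212, nmd_sensitive=False),
    "HINT2": dict(inserted_nt=11, region="CDS", frame_effect="frameshift",
                  added_codons=None, last_codon_is_stop=False, ptc=True,
                  ptc_offset=164, nmd_sensitive=True),
    "TMEM14C": dict(inserted_nt=14, region="5UTR", frame_effect="utr_only",
                    added_codons=None, last_codon_is_stop=False, ptc=False,
                    ptc_offset=None, nmd_sensitive=False),
    "DYNLL1": dict(inserted_nt=14, region="5UTR", frame_effect="utr_only",
                   added_codons=None, last_codon_is_stop=False, ptc=False,
                   ptc_offset=None, nmd_sensitive=False),
}

_SEQUENCES: dict[str, str] = {
"ABCB7": (
        "CTGCATCGGCCTTTACATGATTCGACGATTGGTCCCCGCCGGACCAACATTTCGGCCTCTCATGGTATAC"
        "ATGTTAACCAGGTCGAGGGTGTCCGAGAGGGTAGCCAAACGTATGGGCCTTAGCTATGAAGTAGTGACTG"
        "ACGTTCCGTCATATTTTACTCCGGTGGAGTCGCACGCACCCGACTATGGCCCGAGATTAGTGGTACAAGG"
        "TCTCAATCAAATACCGCGACGCGAAGGATTCCTTTCTCAGGCAGTTCCATTAATTGGGTCGGAGGACTCA"
        "TCGCCCACGCGGTACGCAACATTGCCCTACCGAATAAATGTAGTCAACGCGTACAACCCAAGGTCGAACT"
        "TCTACAGCATTACTGACTTGAATAACCATGCCAGTCGTCACGAGCTTTACGCCCTACTAACCCTGAATTC"
        "CTTTCTCAGGCTGTTCTCATTTCTTCCTAGTGTCCTCGCGGTAATCACGGGAGTCCAGTAGCAAACGGAC"
        "ACTTGGAAGATTGCGCTGCTTTCAGCCATCATCCACATGGTAGAGCTTGCGTTAGATAGGAGCCCTTTAT"
        "CTTGTACAGCTAGGTAAGACACTACGGTTCACTGAACGCCGGTGCCTCACGCCTGTACTAACCTCGCAAA"
        "ACATCCCGCGTATCACACTTCCTTTCTCAGCCATTCTGTTGCTTGCGCTTTGAAGGGTAAAGGCAAGCGT"
        "CATCGGGCGCAATTAATCTACCCTCTTATCAGCCGTAACATGGGTTCAAAGACTTCGCGCGACACTGAGG"
        "TGAATAAAGTCGTGTGGAAGCTTCCCATCGTACAACCTTTAATGTAAATGCACGGAGAAC"
    ),
    "ENOSF1": (
        "CAGGATCCAGGCCTTGGTAAAACCTTTGCTGTGTAAGGTGCTGACGTACGGGCATACGCCCGTTCTGCTA"
        "ATGAATCAACGTACCCTTATATTTAATTCACGAACCGCCTCATCCCCCTCCCCTCCAGTGGTTGACACCT"
        "CATAATTTCGAGATGGCATCGCATGGAAGGTTTATTCATGCCGGAACACCGTATCTCCCCCCGACCCGTC"
        "CAAAACAGTCCAACCTTGACACACAGTATTCCTTTCTCAGGATGGCGCTGAAAGCTGTGCGGTACGTAGA"
        "GAGGCCTGCGGACAAAAGACCGACCTCCGTAATGTGTTCTTCGTCTTCAGGAGATTGGCAGTATCCTGTT"
        "GGATGAGAGCCATTCAACCAAAATCGCCTTTGGGTTGGCAGCAGTCCGAGACTGACAGTATACTAACCAA"
        "TTATTCCTTTCTCAGGTTCTTCCATTCCAGTCAATTAGTTGTCTAACTTGTACAAACTTGGTCTGTCGCC"
        "AAAGAAGGTCTACGGGACCGCGACATATAATATGCTGCAGCGACGCCGATGTGTTGAGAAGGCCATAAAG"
        "CCATCTCCCTTGTAGACCGTCTGTTTTGGCGCGTTTGTTGGTACCCTCTAATGTATAAGGAAGATGGGAG"
        "TATCACTAGGACCGGTGCTTCCTTTCTCAGGCGGAGCATAACTTCTTGTTGCCTTATTAAGCGTTAAGAC"
        "TGTGGTGGACGCTCGAGTGACCCTCGATGAGGGCCTCTCGGTAGAAGGATCATGTATCTGACGTGCATCA"
        "GCCTGGGTCCAGAGACAGGGACAGAGGGAGGGTTTTTAAGCTGGCAATGTCCCCAATCGC"
    ),
    "SEPT6": (
        "GCAAGAGTGTCAACGGGGTCACGGACATTCCATCCATTAGGATACTCCCAGCAAGAAATAGGCCCCTCCG"
        "ATGGTCCTGCGAATGATCCGTCAAAATCACCTGGAGGAGGGTCTTCACCGATCCCCAGTCGTCAATGATG"
        "CGCTAGGCTACCTATGGAGTGTGAGGGTCATTCGGTACAGATATTGGAAGACGTTCGGAGCAAGCCGGAC"
        "AACACGGCTCCAAGGCTGCGATCGCGAGTTCCTTTCTCAGACGTACCGACTGCACGGTATGTATTTCCCT"
        "TGTACGAAGAGTATACTATTGTTCAAAGCGAGCAAGTTGCGTGTCTCCCGCAGCGCATAGACTTCTGTGT"
        "GAGCCAGGCTACTGAAGCTAAACGTTGTAGTCTAATGGTGCAACCCTCGGCGGCAGAATACTAACCCCCC"
        "TTTCCTTTCTCAGCTTCCTTCTTCTTCCAGTCGGGCATTTGTGAGCCACGGAGTCGGAACAACGCTCGCC"
        "GTTTAATGAATGCGACTTGGTTTTGGTGGCGCGGTGCAGCAACGCGTACAGTGCCAGTTGTATTCGCCTC"
        "TCCATGGGTTTCGTTGCATACCAGCATGCTCGCGTCTAGGGCCGATACCAAGTATACTTTCATCCTTGCT"
        "GTAATGTTCGTGTCGCAGTTCCTTTCTCAGCGCACCTTGTTCTTTGTTAGATTCGTGTAATCTCAATGCT"
        "GCTGTCAGCAATCAGCGAGAGGCTCCATATAGAATCTCCCTCCGAAAGGCCATAACGCATTTTGCGTGCC"
        "TACTGACACTCCCGCAATGCGCGAGATCAAGCTCTCACAGGATTGAACAGATAAATGATG"
    ),
    "HINT2": (
        "GTCGCAAAGCATCGCCTGATCACGTTTTTATCACCCGTGGAGTCCGCATTAGGAGCAGGTCTGTTCCCAG"
        "ATGCATCGTATGCTGTTAGTACTGATCGCCAATTCATCGACCTACAGGGTGTACTTTTTAGTGCCTCTCT"
        "TTCGCCTCGCGGTGTCACTGTGCGATTTGCGCCCAAGGTAATGCGACCGCTAAGCCACGCCCCTCCGCCC"
        "TTAGCTCCGACACTAAGTCCGGTTCTTCTTCCTTTCTCAGGTAACACTGGGTATTACCGTAACACACTGC"
        "ATGCCCATCGTGTGTCATACCTCGAGACGAGGACTGTGTCCCGTGTAGCCGTCTCATAGCTAGCATCATA"
        "CAGATAGGGTTAGTATAGGGACTGGAGCGTTTGAACAAAACGCTATAATTTCCTGTGGTACACCTACTAA"
        "CATACTCTTCCTTTCTCAGCTTCTTCTTAGATAAAGTCGCCCTGGAGTGGACCCAGAACGCGAGCAATTC"
        "AATTAGGCACGAATTCTCACTCGCCAAATTGCCGTACCATCCATAGGCCAGTGCGCCGGTCCCAATCATT"
        "GACATTCCCCACAAGTCCGCGCATGCTATGTGTTCCTGGGAAAACCGTTCTTAGCCGCGCCCGCTAGCGG"
        "TCCGACGGCAGTTGGGAGTTCCTTTCTCAGCGCCGCAGATGCTGTTGCATACGACTCTAAAACTTGGTAG"
        "AACTTACACAAGACAGGTTAAAACATATGGGGACATGGGGCCTACGGATAAATGAGACGTTAATCGGCTC"
        "TCTCGCCGATAAAAGGCTCTCTCACCCACGTAAGGATTGAGGTACCGACCAACAACCGTG"
    ),
    "TMEM14C": (
        "CGTTGAGGCCCAGTAGGGACCGTGAAACTCCGTCACCGTTGGCGATTCCCCATGACGCGGGCAGCGTGGG"
        "TGACAGCAGCCGTAGGGTGTGCTAACTGGGAGATGATTCCCCAGGCATAGGTTACATTGAGTCACCGCCT"
        "ACCATAGCGTCGGAGAACATGAGATTGTTGCACGGATGGACGCTCTCAGACTTCGGATTCTTTCGGATAG"
        "GTACTAACTATCTTTTCCTTTCTCAGTCCTTCTTCCTTAGACGTTTTAGCCGGACGTCGGCACTCATTTC"
        "ATGCGGAATGGTCGTTATAACAGACTTATTGCGAGGCCGGAGAGAATCCTAGTCAAACGAGTAACGCCTG"
        "ACCTTAAGGTTGTAGGCAATACAATCCGGGAGACCGTTTTCACTTCAAGTCTCATAATTTGTGGCCGGGG"
        "TGGTGGGCTACTGCTGCTTTCCTTTCTCAGCCAGACCAAGGATCATCTTTCATGAACTGGCACGGTGCCG"
        "CACAATGTCTTAAGTCGAGGGGTAATGGGCGGCGCTGTGCCATTCGGTCCGTTTGTGGGCATAGATGACT"
        "TGGCGTTACAGTGACCTATTGCGGCTATTAAAACTCAACTGTAGGGGGGACAGCGCCCAAGCCTCAGATA"
        "AAAGTCCTCACAATCGGGTTCCTTTCTCAGCTTACGCTGCGCGGCTCCGATTGTGGGTAATAGTTAGATC"
        "CCTAACCAATCTGCACGTCATCTTATCACAGTACAGCTAATTTTCAGTAGACGTTCTGAACCCGTCGCTC"
        "CGATGGATATACCCCCTATCGGAGCAGATACCTACCAGATGTATAATTATAAGTTTACAG"
    ),
    "DYNLL1": (
        "GTCAAATCATAAACCAGCGATGAAATAACCGATGCCAGGGAACCACGAGATAAGACTTAATCATCACCTT"
        "CTATTAGTCCGGCGTTCACTCAAGCTAATCTCTGTCATTTCAATGCTGACAGAAGTTCTGGTCACCCTTT"
        "ATTGGGCCACAGCCACACGTATGGGGATTGGAACTACCAGTTGCATCGAAAGAGTAGTGACCTTTGGTAC"
        "ATACTAACTGTACTTTCCTTTCTCAGCTTCCTCTTCCTAGCGAAATGGGTGGCATGAGCCCCTTAGAATG"
        "ATGGTAATCGCCGTGTGCCTGGTTAATTCCACACCCTCGCCTATAGGCCCATATCTGTCGGTCACAAACT"
        "GATTCTGGCTTTAAACGTATTGCCAAGTGTCGTGATGAGAGATTGCTTAGTACTCCGTGAAATGAGAAAA"
        "ATCTATCCTCCTCACCTATTCCTTTCTCAGACGTATTCCGGTGTATGCATCATCTGTCGAAGCTGTTTTA"
        "TATTCGGCTGCATTCAGGAACACGACAGTCCCGCCTTGTGTTCATACGATGTACGTGAAGCAATCCTTAT"
        "AACAAGCGTCATTCACCGGTACAGGGGTTGGACTTGTAACTCACTCCCGTTCTGCCTTTCCCTATGGGCC"
        "CGCAGGACGCTCAGGCCCTTCCTTTCTCAGCGAGGTCCACTAGTATGCAGTGTCCTGTAACCGAAAGATT"
        "GGACCTAATAGAGGAATGTATGTTAGGACTGTTCAAACCCCAGTGTTCTCACGGAACGTACGTGGCGGTG"
        "GGAAGGCAGGTGGCCCGATGGCAGACACTTTTTCCTATCAAAATGGCTCTGACTACTTAA"
    ),
}


@dataclass(frozen=True)
class WorkedExampleFixture:
    """One packaged worked-example gene with its genome and expectations."""

    name: str
    gene: GeneModel
    genome: dict[str, str]
    canonical_tx_id: str
    cryptic_tx_id: str
    cryptic_pos: int
    canonical_pos: int
    expected: dict

    @property
    def event(self) -> SplicingEvent:
        events = enumerate_events([self.gene])
        assert len(events) == 1
        return events[0]


def build_worked_example_fixtures() -> dict[str, WorkedExampleFixture]:
    """The six packaged fixtures, fully deterministic."""
    fixtures = {}
    for name, (scaffold, ins_len, canonical) in _GEOMETRY.items():
        exons = _SCAFFOLD_A if scaffold == "A" else _SCAFFOLD_B
        cds_start, cds_end = _CDS_A if scaffold == "A" else _CDS_B
        cryptic = canonical - ins_len
        ab_exons = tuple(
            (cryptic, e) if s == canonical else (s, e) for s, e in exons
        )
        tx_can = TranscriptModel(f"{name}.can", exons, cds_start, cds_end)
        tx_cry = TranscriptModel(f"{name}.cry", ab_exons, cds_start, cds_end)
        gene = GeneModel(f"{name}LIKE", f"fix_{name}", "+", (tx_can, tx_cry))
        gene.validate()
        fixtures[name] = WorkedExampleFixture(
            name=name,
            gene=gene,
            genome={f"fix_{name}": _SEQUENCES[name]},
            canonical_tx_id=tx_can.transcript_id,
            cryptic_tx_id=tx_cry.transcript_id,
            cryptic_pos=cryptic,
            canonical_pos=canonical,
            expected=EXPECTED_ANNOTATIONS[name],
        )
    return fixtures
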