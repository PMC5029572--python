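"""Transcript-level consequences of cryptic 3' splice-site usage.

An upstream cryptic acceptor inserts intron-derived sequence into the mature
transcript (a downstream cryptic acceptor deletes exonic sequence; the same
machinery annotates it as a negative insertion). The annotation locates the
change relative to the CDS, determines the frame effect, scans for a
premature termination codon (PTC), and applies the classical
nonsense-mediated decay (NMD) rule: a PTC at least 50 nt upstream of the
final exon-exon junction marks the transcript NMD-sensitive. "Added codons"
counts inserted codons *including* a terminating codon when the insertion
ends in one; ``last_codon_is_stop`` keeps both readings recoverable.

In-silico RT-PCR amplicon lengths for the canonical and aberrant isoforms
are computed from exact primer match sites on the spliced sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .acceptor_features import AcceptorPair
from .genome_io import GeneModel, TranscriptModel, spliced_sequence

__all__ = [
    "ConsequenceAnnotation",
    "AmpliconPair",
    "NMD_DISTANCE_NT",
    "annotate_consequence",
    "aberrant_transcript",
    "amplicon_lengths",
    "nmd_rule",
]

NMD_DISTANCE_NT = 50  # PTC >= 50 nt upstream of the last junction -> NMD


@dataclass(frozen=True)
class ConsequenceAnnotation:
    """Consequence of one cryptic-acceptor event on one transcript."""

    event_id: str
    inserted_nt: int  # negative = deletion (downstream cryptic)
    region: str  # 5UTR | CDS | 3UTR | noncoding
    frame_effect: str | None  # in_frame | frameshift | utr_only
    added_codons: int | None
    last_codon_is_stop: bool
    ptc: bool
    ptc_offset: int | None  # aberrant-transcript coordinate of the stop codon start
    nmd_sensitive: bool


@dataclass(frozen=True)
class AmpliconPair:
    primer_fwd: str
    primer_rev: str
    canonical_len: int
    aberrant_len: int


def nmd_rule(ptc_offset: int, exon_junction_offsets: Sequence[int]) -> bool:
    """Classical NMD 50-nt rule, boundary inclusive.

    ``ptc_offset`` is the transcript coordinate (0-based) of the stop
    codon's first base; ``exon_junction_offsets`` are the transcript
    coordinates of exon-exon junctions (number of bases 5' of each
    junction). True iff the last junction lies at least 50 nt downstream
    of the stop.
    """
    if not exon_junction_offsets:
        return False
    return max(exon_junction_offsets) - ptc_offset >= NMD_DISTANCE_NT


def _transcript_coord(
    gene: GeneModel, tx: TranscriptModel, genomic_pos: int
) -> int:
    """Transcript-orientation coordinate of a genomic base position."""
    offset = 0
    for s, e in tx.exons:  # transcript order
        if gene.strand == "+":
            if s <= genomic_pos < e:
                return offset + (genomic_pos - s)
        else:
            if s <= genomic_pos < e:
                return offset + (e - 1 - genomic_pos)
        offset += e - s
    raise ValueError(f"genomic position {genomic_pos} not exonic in {tx.transcript_id}")


def _junction_offsets(tx: TranscriptModel) -> list[int]:
    offsets, acc = [], 0
    for s, e in tx.exons[:-1]:
        acc += e - s
        offsets.append(acc)
    return offsets


def aberrant_transcript(
    gene: GeneModel, tx: TranscriptModel, pair: AcceptorPair
) -> TranscriptModel:
    """The transcript with the canonical acceptor replaced by the cryptic one."""
    new_exons = []
    hit = False
    for s, e in tx.exons:
        boundary = s if gene.strand == "+" else e
        if boundary == pair.canonical_pos and not hit:
            hit = True
            if gene.strand == "+":
                new_exons.append((pair.cryptic_pos, e))
            else:
                new_exons.append((s, pair.cryptic_pos))
        else:
            new_exons.append((s, e))
    if not hit:
        raise ValueError(
            f"canonical acceptor {pair.canonical_pos} is not an exon boundary of "
            f"transcript {tx.transcript_id}"
        )
    return TranscriptModel(
        transcript_id=f"{tx.transcript_id}|cryptic",
        exons=tuple(new_exons),
        cds_start=tx.cds_start,
        cds_end=tx.cds_end,
    )


def _cds_transcript_span(gene: GeneModel, tx: TranscriptModel) -> tuple[int, int]:
    """(start, end) of the CDS in transcript coordinates, end exclusive."""
    if gene.strand == "+":
        start = _transcript_coord(gene, tx, tx.cds_start)
        end = _transcript_coord(gene, tx, tx.cds_end - 1) + 1
    else:
        start = _transcript_coord(gene, tx, tx.cds_end - 1)
        end = _transcript_coord(gene, tx, tx.cds_start) + 1
    return start, end


def annotate_consequence(
    gene: GeneModel,
    tx: TranscriptModel,
    pair: AcceptorPair,
    genome: Mapping[str, str],
) -> ConsequenceAnnotation:
    """Annotate insertion length, region, frame, PTC and NMD sensitivity.

    The canonical acceptor of ``pair`` must match an annotated exon start of
    ``tx`` (in transcript orientation). For in-frame CDS insertions the
    inserted codons and everything downstream are scanned for a stop; for
    frameshifts translation proceeds in the shifted frame from the change
    point. A stop 5' of the annotated termination codon is a PTC, and the
    50-nt last-junction rule decides NMD sensitivity.
    """
    inserted_nt = (
        pair.spacing_nt if pair.orientation == "upstream" else -pair.spacing_nt
    )
    ab_tx = aberrant_transcript(gene, tx, pair)
    change_point = _transcript_coord(
        gene,
        tx,
        pair.canonical_pos if gene.strand == "+" else pair.canonical_pos - 1,
    )

    if not tx.is_coding:
        return ConsequenceAnnotation(
            event_id=pair.event_id,
            inserted_nt=inserted_nt,
            region="noncoding",
            frame_effect=None,
            added_codons=None,
            last_codon_is_stop=False,
            ptc=False,
            ptc_offset=None,
            nmd_sensitive=False,
        )

    cds_start, cds_end = _cds_transcript_span(gene, tx)
    if change_point <= cds_start:
        region = "5UTR"
    elif change_point >= cds_end:
        region = "3UTR"
    else:
        region = "CDS"

    if region in {"5UTR", "3UTR"}:
        frame_effect = "utr_only"
    elif inserted_nt % 3 == 0:
        frame_effect = "in_frame"
    else:
        frame_effect = "frameshift"

    added_codons = (
        inserted_nt // 3 if region == "CDS" and frame_effect == "in_frame" else None
    )

    # translate the aberrant transcript from its (possibly shifted) CDS start
    ab_seq = spliced_sequence(gene, ab_tx, genome)
    ab_cds_start = cds_start + (inserted_nt if change_point <= cds_start else 0)
    ab_annot_stop = (cds_end - 3) + (inserted_nt if change_point <= cds_end - 3 else 0)
    coding = ab_seq[ab_cds_start:]
    coding = coding[: len(coding) - len(coding) % 3]
    peptide = str(Seq(coding).translate())
    stop_idx = peptide.find("*")
    ptc = False
    ptc_offset = None
    last_codon_is_stop = False
    if stop_idx != -1:
        stop_pos = ab_cds_start + 3 * stop_idx
        if stop_pos < ab_annot_stop:
            ptc = True
            ptc_offset = stop_pos
            if (
                region == "CDS"
                and frame_effect == "in_frame"
                and inserted_nt > 0
                and stop_pos == change_point + inserted_nt - 3
            ):
                last_codon_is_stop = True
    nmd = ptc and nmd_rule(ptc_offset, _junction_offsets(ab_tx))
    return ConsequenceAnnotation(
        event_id=pair.event_id,
        inserted_nt=inserted_nt,
        region=region,
        frame_effect=frame_effect,
        added_codons=added_codons,
        last_codon_is_stop=last_codon_is_stop,
        ptc=ptc,
        ptc_offset=ptc_offset,
        nmd_sensitive=nmd,
    )


def amplicon_lengths(
    canonical_seq: str,
    aberrant_seq: str,
    primer_fwd: str,
    primer_rev: str,
) -> AmpliconPair:
    """In-silico RT-PCR amplicon lengths on both spliced isoforms.

    Each primer must occur exactly once per transcript; the reverse primer
    is given as its transcript-strand match site. Lengths are inclusive of
    both primer sites.
    """

    def locate(seq: str, primer: str, name: str) -> int:
        first = seq.find(primer)
        if first == -1:
            raise ValueError(f"primer {name} ({primer}) absent from transcript")
        if seq.find(primer, first + 1) != -1:
            raise ValueError(f"primer {name} ({primer}) matches more than once")
        return first

    lengths = []
    for seq in (canonical_seq, aberrant_seq):
        fwd = locate(seq, primer_fwd, "fwd")
        rev = locate(seq, primer_rev, "rev")
        if rev < fwd:
            raise ValueError("reverse primer site lies 5' of the forward primer site")
        lengths.append(rev + len(primer_rev) - fwd)
    return AmpliconPair(
        primer_fwd=primer_fwd,
        primer_rev=primer_rev,
        canonical_len=lengths[0],
        aberrant_len=lengths[1],
    )
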