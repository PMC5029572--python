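"""Domain types, coordinate conventions, and readers/writers for standard formats.

Coordinate conventions used throughout the package
--------------------------------------------------
* Internal coordinates are **0-based, half-open** genomic intervals. GTF I/O
  converts at the boundary (GTF is 1-based, closed).
* Exons of a transcript are stored 5'->3' in *transcript* orientation, i.e.
  genomically ascending on the plus strand and descending on the minus strand.
* Acceptor-relative positions are expressed in transcript orientation with
  position -1 the last intronic nucleotide (the G of the AG dinucleotide),
  -2 the A of AG, and exonic positions +1, +2, ...
* Sequences attached to a :class:`SequenceRegion` are always transcript
  oriented (reverse-complemented for minus-strand regions).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq, reverse_complement
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneModel",
    "TranscriptModel",
    "SequenceRegion",
    "SampleManifest",
    "GtfParseError",
    "ValidationError",
    "read_gtf",
    "write_gtf",
    "read_fasta",
    "write_fasta",
    "read_junction_counts",
    "write_junction_counts",
    "read_manifest",
    "write_manifest",
    "spliced_sequence",
    "PURINES",
    "PYRIMIDINES",
    "GROUPS",
]

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
GROUPS = ("mutant", "wildtype", "control")

MIN_INTRON_NT = 4


class GtfParseError(ValueError):
    """Malformed GTF input; message names the offending line number."""


class ValidationError(ValueError):
    """A domain object violates its structural invariants."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: ordered exons plus an optional genomic CDS span.

    ``exons`` are (start, end) 0-based half-open genomic intervals ordered
    5'->3' in transcript orientation. ``cds_start``/``cds_end`` delimit the
    genomic CDS span (start < end regardless of strand) or are ``None`` for
    non-coding transcripts.
    """

    transcript_id: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def exons_genomic_order(self) -> list[tuple[int, int]]:
        return sorted(self.exons)

    def validate(self, strand: str) -> None:
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id}: zero exons")
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValidationError(
                    f"transcript {self.transcript_id}: bad exon interval ({s}, {e})"
                )
        ordered = self.exons_genomic_order()
        expected = ordered if strand == "+" else ordered[::-1]
        if list(self.exons) != expected:
            raise ValidationError(
                f"transcript {self.transcript_id}: exons not in transcript orientation"
            )
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 < e1:
                raise ValidationError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
            if s2 - e1 < MIN_INTRON_NT:
                raise ValidationError(
                    f"transcript {self.transcript_id}: intron shorter than "
                    f"{MIN_INTRON_NT} nt ({s2 - e1})"
                )
        if self.is_coding:
            if self.cds_end is None or not (self.cds_start < self.cds_end):
                raise ValidationError(
                    f"transcript {self.transcript_id}: invalid CDS span"
                )
            if not self._span_in_exons(self.cds_start, self.cds_end):
                raise ValidationError(
                    f"transcript {self.transcript_id}: CDS outside exon union"
                )

    def _span_in_exons(self, start: int, end: int) -> bool:
        # both endpoints must fall in exons and no intron boundary may be skipped
        covered = 0
        for s, e in self.exons_genomic_order():
            lo, hi = max(s, start), min(e, end)
            if lo < hi:
                covered += hi - lo
        within = any(s <= start < e for s, e in self.exons)
        within_end = any(s < end <= e for s, e in self.exons)
        return within and within_end and covered > 0


@dataclass(frozen=True)
class GeneModel:
    """A gene: one or more transcripts sharing chromosome and strand."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[TranscriptModel, ...]

    def validate(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        if not self.transcripts:
            raise ValidationError(f"gene {self.gene_id}: no transcripts")
        for t in self.transcripts:
            t.validate(self.strand)

    def transcript(self, transcript_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)


@dataclass(frozen=True)
class SequenceRegion:
    """A genomic interval with its transcript-oriented sequence attached."""

    chrom: str
    start: int
    end: int
    strand: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) != self.end - self.start:
            raise ValidationError(
                f"SequenceRegion {self.chrom}:{self.start}-{self.end}: sequence "
                f"length {len(self.seq)} != interval length {self.end - self.start}"
            )
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValidationError(f"SequenceRegion: non-ACGTN characters {sorted(bad)}")

    @classmethod
    def from_genome(
        cls, genome: Mapping[str, str], chrom: str, start: int, end: int, strand: str
    ) -> "SequenceRegion":
        raw = genome[chrom][start:end]
        seq = reverse_complement(raw) if strand == "-" else raw
        return cls(chrom=chrom, start=start, end=end, strand=strand, seq=seq)


@dataclass(frozen=True)
class SampleManifest:
    """Sample-to-group assignment for the three-level study design."""

    samples: tuple[tuple[str, str], ...]  # (sample_id, group)

    def __post_init__(self) -> None:
        seen = set()
        for sample_id, group in self.samples:
            if group not in GROUPS:
                raise ValidationError(
                    f"sample {sample_id}: group {group!r} not in {GROUPS}"
                )
            if sample_id in seen:
                raise ValidationError(f"duplicate sample_id {sample_id}")
            seen.add(sample_id)

    def group_of(self, sample_id: str) -> str:
        for sid, group in self.samples:
            if sid == sample_id:
                return group
        raise KeyError(sample_id)

    def samples_in(self, group: str) -> list[str]:
        return [sid for sid, g in self.samples if g == group]

    def require_comparable(self, group_a: str, group_b: str) -> None:
        for g in (group_a, group_b):
            if len(self.samples_in(g)) < 2:
                raise ValidationError(f"group {g!r} has fewer than 2 samples")


# ---------------------------------------------------------------------------
# GTF

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(attr_field))
    if "gene_id" not in attrs or "transcript_id" not in attrs:
        raise GtfParseError(
            f"GTF line {lineno}: attributes must include gene_id and transcript_id"
        )
    return attrs


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read gene models from GTF (exon and optional CDS features).

    Coordinates are converted to internal 0-based half-open; exon order is
    normalized to transcript orientation. Raises :class:`GtfParseError` with
    the offending line number on malformed input.
    """
    exons: dict[tuple[str, str], list[tuple[int, int]]] = {}
    cds: dict[tuple[str, str], list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}  # gene_id -> (chrom, strand)
    gene_order: list[str] = []
    tx_order: dict[str, list[str]] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"GTF line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr = fields
            if feature not in {"exon", "CDS"}:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"GTF line {lineno}: non-integer coordinate") from exc
            if start < 1 or end < start:
                raise GtfParseError(f"GTF line {lineno}: invalid interval {start}-{end}")
            if strand not in {"+", "-"}:
                raise GtfParseError(f"GTF line {lineno}: strand must be + or -")
            attrs = _parse_attributes(attr, lineno)
            gene_id, tx_id = attrs["gene_id"], attrs["transcript_id"]
            if gene_id in meta and meta[gene_id] != (chrom, strand):
                raise GtfParseError(
                    f"GTF line {lineno}: gene {gene_id} changes chrom/strand"
                )
            if gene_id not in meta:
                meta[gene_id] = (chrom, strand)
                gene_order.append(gene_id)
                tx_order[gene_id] = []
            if tx_id not in tx_order[gene_id]:
                tx_order[gene_id].append(tx_id)
            interval = (start - 1, end)  # 1-based closed -> 0-based half-open
            target = exons if feature == "exon" else cds
            target.setdefault((gene_id, tx_id), []).append(interval)

    genes = []
    for gene_id in gene_order:
        chrom, strand = meta[gene_id]
        transcripts = []
        for tx_id in tx_order[gene_id]:
            tx_exons = exons.get((gene_id, tx_id))
            if not tx_exons:
                raise ValidationError(
                    f"transcript {tx_id} of gene {gene_id} has zero exons"
                )
            ordered = sorted(tx_exons)
            if strand == "-":
                ordered = ordered[::-1]
            tx_cds = cds.get((gene_id, tx_id))
            cds_start = min(s for s, _ in tx_cds) if tx_cds else None
            cds_end = max(e for _, e in tx_cds) if tx_cds else None
            transcripts.append(
                TranscriptModel(
                    transcript_id=tx_id,
                    exons=tuple(ordered),
                    cds_start=cds_start,
                    cds_end=cds_end,
                )
            )
        gene = GeneModel(
            gene_id=gene_id, chrom=chrom, strand=strand, transcripts=tuple(transcripts)
        )
        gene.validate()
        genes.append(gene)
    return genes


def write_gtf(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GTF. Inverse of :func:`read_gtf` on valid input."""
    with open(path, "w") as fh:
        for gene in models:
            for tx in gene.transcripts:
                attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}";'
                for s, e in tx.exons_genomic_order():
                    fh.write(
                        f"{gene.chrom}\tcrypticsplice\texon\t{s + 1}\t{e}\t.\t"
                        f"{gene.strand}\t.\t{attrs}\n"
                    )
                if tx.is_coding:
                    for s, e in tx.exons_genomic_order():
                        lo, hi = max(s, tx.cds_start), min(e, tx.cds_end)
                        if lo < hi:
                            fh.write(
                                f"{gene.chrom}\tcrypticsplice\tCDS\t{lo + 1}\t{hi}\t.\t"
                                f"{gene.strand}\t.\t{attrs}\n"
                            )


# ---------------------------------------------------------------------------
# FASTA

_IUPAC_AMBIGUOUS = set("RYSWKMBDHV")


def read_fasta(path: str | Path, ambiguous: str = "reject") -> dict[str, str]:
    """Read FASTA into a chrom -> sequence mapping (upper-cased).

    ``ambiguous`` controls IUPAC codes other than N: ``"reject"`` raises,
    ``"to_n"`` maps them to N.
    """
    if ambiguous not in {"reject", "to_n"}:
        raise ValueError("ambiguous must be 'reject' or 'to_n'")
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise ValidationError(f"duplicate FASTA header {record.id!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise ValidationError(f"empty FASTA record {record.id!r}")
        extra = set(seq) - set("ACGTN")
        if extra:
            if extra - _IUPAC_AMBIGUOUS:
                raise ValidationError(
                    f"FASTA record {record.id!r}: invalid characters "
                    f"{sorted(extra - _IUPAC_AMBIGUOUS)}"
                )
            if ambiguous == "reject":
                raise ValidationError(
                    f"FASTA record {record.id!r}: ambiguity codes {sorted(extra)}"
                )
            seq = re.sub(f"[{''.join(sorted(_IUPAC_AMBIGUOUS))}]", "N", seq)
        out[record.id] = seq
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Junction counts and sample manifest (TSV)

COUNT_COLUMNS = ["event_id", "sample_id", "inc", "exc"]


def read_junction_counts(path: str | Path) -> pd.DataFrame:
    """Read per-sample inclusion/exclusion junction counts.

    Returns a DataFrame indexed by (event_id, sample_id) with integer columns
    ``inc`` and ``exc``. Missing (event, sample) pairs are simply absent.
    """
    df = pd.read_csv(path, sep="\t", dtype={"event_id": str, "sample_id": str})
    if list(df.columns) != COUNT_COLUMNS:
        raise ValidationError(
            f"junction count table must have columns {COUNT_COLUMNS}, "
            f"got {list(df.columns)}"
        )
    for col in ("inc", "exc"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or (vals % 1 != 0).any() or (vals < 0).any():
            raise ValidationError(f"column {col!r}: counts must be non-negative integers")
        df[col] = vals.astype(int)
    dup = df.duplicated(subset=["event_id", "sample_id"])
    if dup.any():
        first = df.loc[dup, ["event_id", "sample_id"]].iloc[0]
        raise ValidationError(
            f"duplicate (event, sample) row: ({first.event_id}, {first.sample_id})"
        )
    return df.set_index(["event_id", "sample_id"]).sort_index()


def write_junction_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.reset_index()[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> SampleManifest:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns)[:2] != ["sample_id", "group"]:
        raise ValidationError(
            f"manifest must start with columns sample_id, group; got {list(df.columns)}"
        )
    return SampleManifest(samples=tuple(zip(df["sample_id"], df["group"])))


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    pd.DataFrame(manifest.samples, columns=["sample_id", "group"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Spliced sequence

def spliced_sequence(gene: GeneModel, tx: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Transcript-oriented mature (spliced) sequence of ``tx``."""
    chrom_seq = genome[gene.chrom]
    parts = [chrom_seq[s:e] for s, e in tx.exons_genomic_order()]
    seq = "".join(parts)
    if gene.strand == "-":
        seq = reverse_complement(seq)
    return seq.upper()
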