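"""Synthetic data with the sequence and count structure of SF3B1-mutant splicing.

The generator emulates a three-group bulk RNA-seq study design (8 mutant,
4 wild-type, 5 control samples) in which upstream cryptic 3' splice sites are
enriched in the mutant group. Planted structure:

* cryptic-canonical spacing for regulated upstream A3SS pairs has its mode at
  15 nt (probability 0.4) over support 12-60 nt; unregulated pairs carry a
  NAGNAG atom at 3 nt (probability 0.25) over broad support 3-300 nt;
* canonical acceptors carry 18-20 nt polypyrimidine tracts, cryptic acceptors
  ~8 nt tracts with a 4-5 nt adenosine run starting 13-17 nt upstream of the
  AG (the run sits at the tract's 5' edge, where its purines also terminate
  the PPT scan);
* one branch-point heptamer (consensus TACTAAC, branch A at position 6) per
  acceptor, at class-specific BP-AG distances with medians 18 (upstream
  cryptic), 27 (canonical) and 26 (unregulated), all >= 12 nt; competing
  consensus matches in the search window are masked so recovery is
  well-posed;
* junction counts are beta-binomial around group PSIs, with the regulated
  inclusion shift (default 0.4) signed so the mutant group favors the longer
  isoform of upstream-cryptic events.

Background sequence is i.i.d. uniform over ACGT outside planted elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .branchpoint import BP_CONSENSUS
from .event_caller import SplicingEvent, enumerate_events
from .genome_io import (
    GeneModel,
    SampleManifest,
    TranscriptModel,
    write_fasta,
    write_gtf,
    write_junction_counts,
    write_manifest,
)

__all__ = [
    "SyntheticConfig",
    "AcceptorWindow",
    "SyntheticDataset",
    "generate_acceptor_windows",
    "generate_a3ss_pairs",
    "generate_dataset",
    "mirror_gene",
    "ACCEPTOR_CLASSES",
]

ACCEPTOR_CLASSES = ("cryptic", "canonical", "unregulated")

INTRON_WINDOW_NT = 100  # intronic context generated upstream of each acceptor
EXON_WINDOW_NT = 20

_PYR_T_PROB = 0.65  # uridine enrichment inside planted tracts


def _normalize(profile: dict[int, float]) -> dict[int, float]:
    total = sum(profile.values())
    return {k: v / total for k, v in sorted(profile.items())}


def _geometric_tail(
    support: range, exclude: frozenset[int], decay: float, mass: float
) -> dict[int, float]:
    raw = {s: decay ** (s - support.start) for s in support if s not in exclude}
    z = sum(raw.values())
    return {s: mass * w / z for s, w in raw.items()}


def default_spacing_regulated() -> dict[int, float]:
    """Mode 15 nt (P=0.4), remaining mass geometric over 12-60 nt."""
    profile = {15: 0.4}
    profile.update(_geometric_tail(range(12, 61), frozenset({15}), 0.9, 0.6))
    return _normalize(profile)


def default_spacing_unregulated() -> dict[int, float]:
    """NAGNAG atom at 3 nt (P=0.25), broad geometric support 4-300 nt."""
    profile = {3: 0.25}
    profile.update(_geometric_tail(range(4, 301), frozenset(), 0.98, 0.75))
    return _normalize(profile)


def default_bp_profile(acceptor_class: str) -> dict[int, float]:
    """Class-specific BP-AG distance profiles (medians 18 / 27 / 26)."""
    if acceptor_class == "cryptic":
        profile = {
            12: 0.01, 13: 0.01, 14: 0.03, 15: 0.05, 16: 0.08, 17: 0.12,
            18: 0.24, 19: 0.08, 20: 0.09, 21: 0.07, 22: 0.05, 23: 0.04,
            24: 0.03, 25: 0.03, 26: 0.02, 27: 0.02, 28: 0.01, 29: 0.01,
            30: 0.01,
        }
    elif acceptor_class == "canonical":
        profile = {
            18: 0.01, 19: 0.01, 20: 0.02, 21: 0.02, 22: 0.03, 23: 0.04,
            24: 0.06, 25: 0.08, 26: 0.12, 27: 0.18, 28: 0.12, 29: 0.08,
            30: 0.06, 31: 0.04, 32: 0.03, 33: 0.03, 34: 0.02, 35: 0.02,
            36: 0.01, 37: 0.01, 38: 0.005, 39: 0.0025, 40: 0.0025,
        }
    elif acceptor_class == "unregulated":
        profile = {
            18: 0.02, 19: 0.02, 20: 0.02, 21: 0.03, 22: 0.04, 23: 0.06,
            24: 0.08, 25: 0.12, 26: 0.18, 27: 0.12, 28: 0.08, 29: 0.06,
            30: 0.04, 31: 0.03, 32: 0.03, 33: 0.02, 34: 0.02, 35: 0.01,
            36: 0.01, 37: 0.005, 38: 0.0025, 39: 0.0025,
        }
    else:
        raise ValueError(f"unknown acceptor class {acceptor_class!r}")
    return _normalize(profile)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design and sequence-structure parameters of the generator."""

    seed: int = 0
    n_mutant: int = 8
    n_wildtype: int = 4
    n_control: int = 5
    n_events_per_type: dict[str, int] = field(
        default_factory=lambda: {"A3SS": 60, "A5SS": 12, "SE": 24, "MXE": 12, "RI": 42}
    )
    n_regulated_per_type: dict[str, int] = field(
        default_factory=lambda: {"A3SS": 30, "A5SS": 1, "SE": 3, "MXE": 2, "RI": 12}
    )
    n_a3ss_regulated_downstream: int = 2
    depth_mean: float = 100.0
    dispersion: float = 0.01
    spacing_profile_regulated: dict[int, float] = field(
        default_factory=default_spacing_regulated
    )
    spacing_profile_unregulated: dict[int, float] = field(
        default_factory=default_spacing_unregulated
    )
    ppt_profile_canonical: dict[int, float] = field(
        default_factory=lambda: _normalize({18: 1.0, 19: 1.0, 20: 1.0})
    )
    ppt_profile_cryptic: dict[int, float] = field(
        default_factory=lambda: _normalize({7: 0.25, 8: 0.5, 9: 0.25})
    )
    a_run_profile: dict[int, float] = field(
        default_factory=lambda: _normalize({4: 0.5, 5: 0.5})
    )
    bp_distance_profiles: dict[str, dict[int, float]] = field(
        default_factory=lambda: {c: default_bp_profile(c) for c in ACCEPTOR_CLASSES}
    )
    delta_psi_regulated: float = 0.4

    def validate(self) -> None:
        for name, profile in (
            ("spacing_profile_regulated", self.spacing_profile_regulated),
            ("spacing_profile_unregulated", self.spacing_profile_unregulated),
            ("ppt_profile_canonical", self.ppt_profile_canonical),
            ("ppt_profile_cryptic", self.ppt_profile_cryptic),
            ("a_run_profile", self.a_run_profile),
        ):
            if abs(sum(profile.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} not normalized")
        for cls, profile in self.bp_distance_profiles.items():
            if abs(sum(profile.values()) - 1.0) > 1e-9:
                raise ValueError(f"bp profile {cls} not normalized")
            if min(profile) < 12:
                raise ValueError("BP-AG distances must be >= 12 nt")
        if min(self.spacing_profile_regulated) < 3 or min(self.spacing_profile_unregulated) < 3:
            raise ValueError("spacing must be >= 3 nt")
        if not (0.0 <= self.dispersion < 1.0):
            raise ValueError("dispersion must be in [0, 1)")


@dataclass(frozen=True)
class AcceptorWindow:
    """One standalone acceptor with its planted ground truth."""

    acceptor_class: str
    seq: str
    boundary: int  # index of the first exonic base
    ppt_length: int  # planted tract length after any geometric truncation
    bp_distance: int
    a_run: tuple[int, int] | None  # (length, offset of 5'-most A) or None


def _sample(rng: np.random.Generator, profile: Mapping[int, float]) -> int:
    keys = sorted(profile)
    probs = np.array([profile[k] for k in keys], dtype=float)
    return int(rng.choice(keys, p=probs / probs.sum()))


def _random_bases(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(list("ACGT"), size=n))


def _pyrimidine(rng: np.random.Generator) -> str:
    return "T" if rng.random() < _PYR_T_PROB else "C"


def _mask_consensus_competitors(
    seq: list[str], planted_start: int, mask: set[int], rng: np.random.Generator
) -> None:
    """Degrade any non-planted occurrence of the BP consensus heptamer."""
    text = "".join(seq)
    pos = text.find(BP_CONSENSUS)
    guard = 0
    while pos != -1 and guard < 100:
        if pos != planted_start:
            free = [i for i in range(pos, pos + 7) if i not in mask]
            if free:
                i = free[len(free) // 2]
                seq[i] = "G" if seq[i] != "G" else "C"
            text = "".join(seq)
            pos = text.find(BP_CONSENSUS)
        else:
            pos = text.find(BP_CONSENSUS, pos + 1)
        guard += 1


def _break_background_a_runs(
    seq: list[str], boundary: int, mask: set[int], rng: np.random.Generator
) -> None:
    """Cap background A-runs in -25..-5 at length 2 (planted runs untouched)."""
    lo, hi = boundary - 25, boundary - 5
    run: list[int] = []
    for idx in range(max(lo, 0), hi + 1):
        if seq[idx] == "A":
            run.append(idx)
        else:
            run = []
        if len(run) >= 3 and not any(i in mask for i in run):
            seq[run[len(run) // 2]] = _pyrimidine(rng)
            run = []


def _assemble_acceptor_region(
    rng: np.random.Generator,
    acceptor_class: str,
    config: SyntheticConfig,
    intron_nt: int = INTRON_WINDOW_NT,
    exon_nt: int = EXON_WINDOW_NT,
) -> AcceptorWindow:
    """Assemble one acceptor window with planted PPT, BP heptamer and A-run.

    Offsets follow the package convention (-1 = G of AG). The PPT occupies
    -(L+2)..-3 and is terminated on its 5' side either by the planted A-run
    (cryptic class, when geometry allows) or by a purine 'GG' guard, so the
    scan rule recovers the planted length exactly. The planted tract length
    is truncated to d-6 when the drawn BP-AG distance d leaves no room.
    """
    if acceptor_class not in ACCEPTOR_CLASSES:
        raise ValueError(f"unknown acceptor class {acceptor_class!r}")
    boundary = intron_nt
    seq = _random_bases(rng, intron_nt + exon_nt)
    mask: set[int] = set()

    def put(offset: int, base: str) -> None:
        idx = boundary + offset
        seq[idx] = base
        mask.add(idx)

    d = _sample(rng, config.bp_distance_profiles[acceptor_class])
    ppt_profile = (
        config.ppt_profile_cryptic
        if acceptor_class == "cryptic"
        else config.ppt_profile_canonical
    )
    L = min(_sample(rng, ppt_profile), d - 6)
    if L < 1:
        raise ValueError(
            f"{acceptor_class} acceptor: BP distance {d} leaves no room for a tract"
        )

    put(-2, "A")
    put(-1, "G")
    for k in range(-(L + 2), -2):
        put(k, _pyrimidine(rng))

    a_run: tuple[int, int] | None = None
    if acceptor_class == "cryptic":
        feasible = [a for a in sorted(config.a_run_profile) if d >= a + L + 4]
        if feasible:
            restricted = {a: config.a_run_profile[a] for a in feasible}
            a = _sample(rng, restricted)
            d_a = a + L + 2  # offset of the run's 5'-most A; lands in 13..17
            for k in range(-d_a, -(L + 2)):
                put(k, "A")
            a_run = (a, -d_a)
    if a_run is None:
        put(-(L + 4), "G")
        put(-(L + 3), "G")

    hept_start = boundary - d - 5
    for i, base in enumerate(BP_CONSENSUS):
        seq[hept_start + i] = base
        mask.add(hept_start + i)
    if a_run is not None:
        stop_idx = boundary + a_run[1] - 1  # base 5'-adjacent to the run
        if stop_idx not in mask and seq[stop_idx] == "A":
            seq[stop_idx] = _pyrimidine(rng)

    _mask_consensus_competitors(seq, hept_start, mask, rng)
    _break_background_a_runs(seq, boundary, mask, rng)
    return AcceptorWindow(
        acceptor_class=acceptor_class,
        seq="".join(seq),
        boundary=boundary,
        ppt_length=L,
        bp_distance=d,
        a_run=a_run,
    )


def generate_acceptor_windows(
    acceptor_class: str,
    n: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    config: SyntheticConfig | None = None,
) -> list[AcceptorWindow]:
    """Generate ``n`` standalone acceptor windows of one class."""
    if rng is None:
        rng = np.random.default_rng(seed)
    config = config or SyntheticConfig()
    config.validate()
    return [_assemble_acceptor_region(rng, acceptor_class, config) for _ in range(n)]


# ---------------------------------------------------------------------------
# Full dataset generation

@dataclass
class SyntheticDataset:
    """In-memory bundle of everything :func:`generate_dataset` produces."""

    config: SyntheticConfig
    genes: list[GeneModel]
    genome: dict[str, str]
    counts: pd.DataFrame  # indexed by (event_id, sample_id), columns inc/exc
    manifest: SampleManifest
    truth: pd.DataFrame
    events: list[SplicingEvent]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gtf": outdir / "genes.gtf",
            "fasta": outdir / "genome.fa",
            "counts": outdir / "junction_counts.tsv",
            "manifest": outdir / "manifest.tsv",
            "truth": outdir / "planted_truth.tsv",
        }
        write_gtf(self.genes, paths["gtf"])
        write_fasta(self.genome, paths["fasta"])
        write_junction_counts(self.counts, paths["counts"])
        write_manifest(self.manifest, paths["manifest"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def mirror_gene(gene: GeneModel, genome: dict[str, str]) -> tuple[GeneModel, dict[str, str]]:
    """Strand-mirror a gene: reverse-complement its chromosome, flip coordinates.

    Produces an equivalent gene on the opposite strand; useful for checking
    that annotations are strand-invariant.
    """
    from Bio.Seq import reverse_complement

    chrom_seq = genome[gene.chrom]
    length = len(chrom_seq)
    new_strand = "-" if gene.strand == "+" else "+"

    def flip_interval(iv: tuple[int, int]) -> tuple[int, int]:
        s, e = iv
        return length - e, length - s

    new_txs = []
    for tx in gene.transcripts:
        exons = sorted(flip_interval(iv) for iv in tx.exons)
        if new_strand == "-":
            exons = exons[::-1]
        cds_start = cds_end = None
        if tx.is_coding:
            cds_start, cds_end = flip_interval((tx.cds_start, tx.cds_end))
        new_txs.append(
            TranscriptModel(
                transcript_id=tx.transcript_id,
                exons=tuple(exons),
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    new_gene = GeneModel(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand=new_strand,
        transcripts=tuple(new_txs),
    )
    return new_gene, {gene.chrom: reverse_complement(chrom_seq)}


def _oriented_exons(exons: list[tuple[int, int]], strand: str) -> tuple[tuple[int, int], ...]:
    ordered = sorted(exons)
    return tuple(ordered[::-1] if strand == "-" else ordered)


@dataclass
class _A3ssSketch:
    gene: GeneModel
    chrom_seq: str
    event_class: str  # regulated-upstream | regulated-downstream | unregulated
    spacing: int
    orientation: str
    truth: dict


def _build_a3ss_gene(
    rng: np.random.Generator,
    config: SyntheticConfig,
    gene_id: str,
    chrom: str,
    event_class: str,
    strand: str,
) -> _A3ssSketch:
    """One two-transcript A3SS gene built plus-strand, then mirrored if needed."""
    if event_class in {"regulated-upstream", "regulated-downstream"}:
        spacing = _sample(rng, config.spacing_profile_regulated)
    else:
        spacing = _sample(rng, config.spacing_profile_unregulated)
    if event_class == "regulated-upstream":
        orientation = "upstream"
    elif event_class == "regulated-downstream":
        orientation = "downstream"
    else:
        orientation = "upstream" if spacing == 3 or rng.random() < 0.5 else "downstream"

    flank, e1_len, e2_len, pad = 50, 100, 320, 30
    intron_len = pad + max(INTRON_WINDOW_NT, spacing + 2) + (
        spacing if orientation == "upstream" and event_class == "regulated-upstream" else 0
    )
    e1 = (flank, flank + e1_len)
    intron = (e1[1], e1[1] + intron_len)
    e2 = (intron[1], intron[1] + e2_len)
    chrom_len = e2[1] + flank
    seq = _random_bases(rng, chrom_len)
    canonical = e2[0]

    truth: dict = {"ppt_len_canonical": np.nan, "ppt_len_cryptic": np.nan,
                   "bp_distance_canonical": np.nan, "bp_distance_cryptic": np.nan,
                   "a_run_len": np.nan, "a_run_offset": np.nan}

    if event_class == "regulated-upstream":
        cryptic = canonical - spacing
        region = _assemble_acceptor_region(rng, "cryptic", config)
        # intronic 100 nt end exactly at the cryptic boundary
        seq[cryptic - INTRON_WINDOW_NT : cryptic] = list(region.seq[:INTRON_WINDOW_NT])
        truth.update(
            ppt_len_cryptic=region.ppt_length,
            bp_distance_cryptic=region.bp_distance,
        )
        if region.a_run is not None:
            truth.update(a_run_len=region.a_run[0], a_run_offset=region.a_run[1])
        # inter-acceptor segment: purine guard + short pyrimidine stretch + AG
        inter = list("AG")
        budget = spacing - 2
        fill = [_pyrimidine(rng) for _ in range(max(budget - 2, 0))]
        guard = ["G"] * min(budget - len(fill), 2)
        seq[cryptic : cryptic + spacing] = (guard + fill + inter)[:spacing]
        truth["ppt_len_canonical"] = max(len(fill), 0)
    else:
        region = _assemble_acceptor_region(rng, "canonical", config)
        seq[canonical - INTRON_WINDOW_NT : canonical] = list(region.seq[:INTRON_WINDOW_NT])
        truth.update(
            ppt_len_canonical=region.ppt_length,
            bp_distance_canonical=region.bp_distance,
        )
        if orientation == "upstream":
            # the cryptic AG may land inside the canonical tract; that is the
            # shared BP/PPT-unit geometry tandem acceptors actually have
            cryptic = canonical - spacing
            seq[cryptic - 2] = "A"
            seq[cryptic - 1] = "G"
        else:
            cryptic = canonical + spacing
            seq[cryptic - 2] = "A"
            seq[cryptic - 1] = "G"

    # splice donor for realism
    seq[intron[0]] = "G"
    seq[intron[0] + 1] = "T"

    exons_can = [e1, (canonical, e2[1])]
    exons_cry = [e1, (cryptic, e2[1])]
    tx_can = TranscriptModel(f"{gene_id}.can", _oriented_exons(exons_can, "+"))
    tx_cry = TranscriptModel(f"{gene_id}.cry", _oriented_exons(exons_cry, "+"))
    gene = GeneModel(gene_id=gene_id, chrom=chrom, strand="+", transcripts=(tx_can, tx_cry))
    chrom_seq = "".join(seq)
    if strand == "-":
        gene, flipped = mirror_gene(gene, {chrom: chrom_seq})
        chrom_seq = flipped[chrom]
    return _A3ssSketch(
        gene=gene,
        chrom_seq=chrom_seq,
        event_class=event_class,
        spacing=spacing,
        orientation=orientation,
        truth=truth,
    )


def _build_simple_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    event_type: str,
    strand: str,
) -> tuple[GeneModel, str]:
    """A minimal two-transcript gene for A5SS / SE / MXE / RI events."""
    flank = 50
    if event_type == "SE":
        e1 = (flank, flank + 100)
        e2 = (e1[1] + 150, e1[1] + 150 + 90)
        e3 = (e2[1] + 150, e2[1] + 150 + 150)
        chrom_len = e3[1] + flank
        tx_a = [e1, e2, e3]
        tx_b = [e1, e3]
    elif event_type == "RI":
        e1 = (flank, flank + 100)
        e2 = (e1[1] + 120, e1[1] + 120 + 150)
        chrom_len = e2[1] + flank
        tx_a = [(e1[0], e2[1])]  # retained
        tx_b = [e1, e2]
    elif event_type == "MXE":
        e1 = (flank, flank + 100)
        e2a = (e1[1] + 120, e1[1] + 120 + 80)
        e2b = (e2a[1] + 120, e2a[1] + 120 + 85)
        e4 = (e2b[1] + 120, e2b[1] + 120 + 150)
        chrom_len = e4[1] + flank
        tx_a = [e1, e2a, e4]
        tx_b = [e1, e2b, e4]
    elif event_type == "A5SS":
        ext = int(rng.integers(10, 61))
        e1_short = (flank, flank + 150)
        e1_long = (flank, flank + 150 + ext)
        e2 = (e1_long[1] + 130, e1_long[1] + 130 + 150)
        chrom_len = e2[1] + flank
        tx_a = [e1_long, e2]
        tx_b = [e1_short, e2]
    else:
        raise ValueError(event_type)
    seq = "".join(_random_bases(rng, chrom_len))
    tx1 = TranscriptModel(f"{gene_id}.a", _oriented_exons(tx_a, "+"))
    tx2 = TranscriptModel(f"{gene_id}.b", _oriented_exons(tx_b, "+"))
    gene = GeneModel(gene_id=gene_id, chrom=chrom, strand="+", transcripts=(tx1, tx2))
    if strand == "-":
        gene, flipped = mirror_gene(gene, {chrom: seq})
        seq = flipped[chrom]
    return gene, seq


def _beta_binomial(
    rng: np.random.Generator, n: int, psi: float, dispersion: float
) -> int:
    if n == 0:
        return 0
    if psi <= 0.0:
        return 0
    if psi >= 1.0:
        return n
    if dispersion <= 0.0:
        return int(rng.binomial(n, psi))
    a = psi * (1.0 - dispersion) / dispersion
    b = (1.0 - psi) * (1.0 - dispersion) / dispersion
    return int(rng.binomial(n, rng.beta(a, b)))


def _default_manifest(config: SyntheticConfig) -> SampleManifest:
    samples = (
        [(f"M{i+1}", "mutant") for i in range(config.n_mutant)]
        + [(f"W{i+1}", "wildtype") for i in range(config.n_wildtype)]
        + [(f"C{i+1}", "control") for i in range(config.n_control)]
    )
    return SampleManifest(samples=tuple(samples))


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate gene models, genome, junction counts, manifest and truth.

    Deterministic given ``config.seed``: the same configuration always
    produces byte-identical outputs. Each event lives on its own
    chromosome; planted truth and emitted events are in bijection by
    event_id.
    """
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    manifest = _default_manifest(config)

    genes: list[GeneModel] = []
    genome: dict[str, str] = {}
    events: list[SplicingEvent] = []
    truth_rows: list[dict] = []
    count_rows: list[dict] = []

    specs: list[tuple[str, str]] = []  # (event_type, event_class)
    for etype in ("A3SS", "A5SS", "SE", "MXE", "RI"):
        n_total = config.n_events_per_type.get(etype, 0)
        n_reg = min(config.n_regulated_per_type.get(etype, 0), n_total)
        if etype == "A3SS":
            n_down = min(config.n_a3ss_regulated_downstream, n_reg)
            specs += [("A3SS", "regulated-upstream")] * (n_reg - n_down)
            specs += [("A3SS", "regulated-downstream")] * n_down
            specs += [("A3SS", "unregulated")] * (n_total - n_reg)
        else:
            specs += [(etype, "regulated")] * n_reg
            specs += [(etype, "unregulated")] * (n_total - n_reg)

    for idx, (etype, eclass) in enumerate(specs):
        gene_id = f"SYNT{idx:04d}"
        chrom = f"chr_{gene_id}"
        strand = "+" if rng.random() < 0.5 else "-"
        extra_truth: dict = {}
        if etype == "A3SS":
            sketch = _build_a3ss_gene(rng, config, gene_id, chrom, eclass, strand)
            gene, seq = sketch.gene, sketch.chrom_seq
            extra_truth = dict(
                sketch.truth,
                spacing_nt=sketch.spacing,
                orientation=sketch.orientation,
            )
            event_class = sketch.event_class
        else:
            gene, seq = _build_simple_gene(rng, gene_id, chrom, etype, strand)
            event_class = "other-type"
            extra_truth = {"spacing_nt": np.nan, "orientation": ""}
        regulated = eclass.startswith("regulated")
        genes.append(gene)
        genome[chrom] = seq
        found = enumerate_events([gene])
        if len(found) != 1 or found[0].event_type != etype:
            raise RuntimeError(
                f"gene {gene_id}: expected one {etype} event, got "
                f"{[e.event_type for e in found]}"
            )
        event = found[0]
        events.append(event)

        # group PSIs of the longer isoform
        if regulated:
            mutant_favors_long = not (etype == "A3SS" and eclass == "regulated-downstream")
            if mutant_favors_long:
                psi_ref = float(rng.uniform(0.10, 0.50))
                psi_mut = min(psi_ref + config.delta_psi_regulated, 0.99)
            else:
                psi_ref = float(rng.uniform(0.50, 0.90))
                psi_mut = max(psi_ref - config.delta_psi_regulated, 0.01)
        else:
            psi_ref = float(rng.uniform(0.35, 0.65))
            psi_mut = psi_ref
        group_psi = {"mutant": psi_mut, "wildtype": psi_ref, "control": psi_ref}

        for sample_id, group in manifest.samples:
            n = int(rng.poisson(config.depth_mean))
            inc = _beta_binomial(rng, n, group_psi[group], config.dispersion)
            count_rows.append(
                {
                    "event_id": event.event_id,
                    "sample_id": sample_id,
                    "inc": inc,
                    "exc": n - inc,
                }
            )
        truth_rows.append(
            {
                "event_id": event.event_id,
                "gene_id": gene_id,
                "event_type": etype,
                "event_class": event_class,
                "regulated": regulated,
                "psi_mutant": psi_mut,
                "psi_wildtype": psi_ref,
                "psi_control": psi_ref,
                **extra_truth,
            }
        )

    counts = (
        pd.DataFrame(count_rows).set_index(["event_id", "sample_id"]).sort_index()
    )
    truth = pd.DataFrame(truth_rows)
    return SyntheticDataset(
        config=config,
        genes=genes,
        genome=genome,
        counts=counts,
        manifest=manifest,
        truth=truth,
        events=events,
    )


def generate_a3ss_pairs(
    event_class: str,
    n: int,
    seed: int,
    config: SyntheticConfig | None = None,
) -> SyntheticDataset:
    """Dataset containing only A3SS events of one class (for class-level stats)."""
    base = config or SyntheticConfig()
    if event_class not in {"regulated-upstream", "regulated-downstream", "unregulated"}:
        raise ValueError(f"unknown A3SS event class {event_class!r}")
    n_reg = n if event_class.startswith("regulated") else 0
    cfg = replace(
        base,
        seed=seed,
        n_events_per_type={"A3SS": n},
        n_regulated_per_type={"A3SS": n_reg},
        n_a3ss_regulated_downstream=n if event_class == "regulated-downstream" else 0,
    )
    return generate_dataset(cfg)
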