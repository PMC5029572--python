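"""End-to-end orchestration: call -> classify -> features -> BP -> consequence.

One :func:`run_pipeline` call reads the four inputs (GTF, FASTA, junction
counts, manifest), runs every analysis stage, and writes a reproducible
report bundle: per-event results and the significant subset (GeneID / event
/ inclusion-level-difference / P / FDR layout), a per-type enrichment
summary (Yates chi-square), acceptor-pair features with spacing modes, PPT
calls and strength scores, branch-point calls with per-class medians,
transcript-consequence annotations, and a JSON run manifest recording seed,
thresholds, versions, and per-stage event counts so filter attrition is
auditable.

Cryptic-side assignment: for significant A3SS events the cryptic acceptor
is the isoform favored in mutant (negative inclusion-level difference means
the longer isoform, hence the upstream acceptor); non-significant events
are carried as the unregulated class.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .acceptor_features import (
    acceptor_window,
    build_frequency_matrix,
    call_ppt,
    classify_pair,
    spacing_mode_log2,
    train_acceptor_model,
)
from .branchpoint import bp_distance_summary, calls_to_frame, find_branchpoint
from .consequence import annotate_consequence
from .event_caller import (
    apply_filters,
    category_overrepresentation,
    enumerate_events,
    results_to_frame,
    test_differential,
)
from .genome_io import (
    GeneModel,
    SampleManifest,
    SequenceRegion,
    read_fasta,
    read_gtf,
    read_junction_counts,
    read_manifest,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

INTRON_CONTEXT_NT = 100
EXON_CONTEXT_NT = 20

_COMPARISONS = {
    "mutant_vs_wildtype": ("wildtype", "wt-mut"),
    "mutant_vs_control": ("control", "HC-mut"),
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and event context."""


@dataclass(frozen=True)
class RunConfig:
    gtf: str
    fasta: str
    counts: str
    manifest: str
    outdir: str
    comparison: str = "mutant_vs_wildtype"
    alpha: float = 0.05
    delta: float = 0.3
    min_count: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.comparison not in _COMPARISONS:
            raise ValueError(
                f"comparison must be one of {sorted(_COMPARISONS)}"
            )
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 <= self.delta <= 1):
            raise ValueError("delta must be in [0, 1]")


def _acceptor_region(
    genome: Mapping[str, str], chrom: str, strand: str, boundary_pos: int
) -> tuple[str, int] | None:
    """Transcript-oriented (sequence, boundary-index) context of an acceptor."""
    chrom_len = len(genome[chrom])
    if strand == "+":
        start = boundary_pos - INTRON_CONTEXT_NT
        end = boundary_pos + EXON_CONTEXT_NT
    else:
        start = boundary_pos - EXON_CONTEXT_NT
        end = boundary_pos + INTRON_CONTEXT_NT
    if start < 0 or end > chrom_len:
        return None
    region = SequenceRegion.from_genome(genome, chrom, start, end, strand)
    return region.seq, INTRON_CONTEXT_NT


def _stage(name: str, event_id: str | None = None):
    ctx = f"stage {name}" + (f", event {event_id}" if event_id else "")
    return ctx


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Run every stage and write the report bundle into ``config.outdir``.

    Returns a dict of the in-memory stage outputs (events, results,
    significant, enrichment, pairs, branchpoints, consequences, manifest).
    Deterministic: rerunning with the same inputs reproduces the bundle
    byte for byte.
    """
    config.validate()
    reference_group, sign_label = _COMPARISONS[config.comparison]
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict[str, object] = {}

    genes = read_gtf(config.gtf)
    genome = read_fasta(config.fasta)
    counts = read_junction_counts(config.counts)
    manifest = read_manifest(config.manifest)
    manifest.require_comparable("mutant", reference_group)
    genes_by_id = {g.gene_id: g for g in genes}

    # --- event calling and differential test
    events = enumerate_events(genes)
    events_by_id = {e.event_id: e for e in events}
    results = [
        test_differential(
            e.event_id,
            counts,
            manifest,
            reference_group=reference_group,
            min_count=config.min_count,
        )
        for e in events
    ]
    significant = apply_filters(results, alpha=config.alpha, delta=config.delta)
    sig_ids = {r.event_id for r in significant}
    log["events_total"] = len(events)
    log["events_testable"] = sum(r.testable for r in results)
    log["events_significant"] = len(significant)
    log["genes_significant"] = len({events_by_id[r.event_id].gene_id for r in significant})

    all_df = results_to_frame(results, events_by_id, sign_label)
    sig_df = results_to_frame(significant, events_by_id, sign_label)
    all_df.to_csv(outdir / "results_all.tsv", sep="\t", index=False)
    sig_df.to_csv(outdir / "significant.tsv", sep="\t", index=False)

    enrichment = category_overrepresentation(
        [events_by_id[r.event_id] for r in significant], events, alpha=config.alpha
    )
    enr_df = pd.DataFrame([asdict(e) for e in enrichment])
    enr_df.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    # --- acceptor pairs and sequence features
    results_by_id = {r.event_id: r for r in results}
    pair_rows = []
    windows: dict[str, dict[str, tuple[str, int] | None]] = {}
    for event in events:
        if event.event_type != "A3SS":
            continue
        r = results_by_id[event.event_id]
        if event.event_id in sig_ids and r.inc_level_difference is not None:
            cryptic_isoform = "long" if r.inc_level_difference < 0 else "short"
        else:
            cryptic_isoform = "long"
        try:
            pair = classify_pair(event, genome, cryptic_isoform=cryptic_isoform)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"{_stage('features', event.event_id)}: {exc}") from exc
        if event.event_id in sig_ids:
            cls = f"regulated-{pair.orientation}"
        else:
            cls = "unregulated"
        win = {
            "cryptic": _acceptor_region(genome, event.chrom, event.strand, pair.cryptic_pos),
            "canonical": _acceptor_region(genome, event.chrom, event.strand, pair.canonical_pos),
        }
        windows[event.event_id] = win
        row = {
            "event_id": event.event_id,
            "gene_id": event.gene_id,
            "chrom": event.chrom,
            "strand": event.strand,
            "class": cls,
            "orientation": pair.orientation,
            "spacing_nt": pair.spacing_nt,
            "is_nagnag": pair.is_nagnag,
            "cryptic_pos": pair.cryptic_pos,
            "canonical_pos": pair.canonical_pos,
        }
        for side in ("cryptic", "canonical"):
            ppt = call_ppt(*win[side]) if win[side] else None
            row[f"ppt_length_{side}"] = ppt.length_nt if ppt else np.nan
            row[f"ppt_interruptions_{side}"] = ppt.interruptions if ppt else np.nan
        pair_rows.append(row)
    pairs_df = pd.DataFrame(pair_rows)

    # strength model trained on canonical windows of unregulated + regulated events
    canonical_training = [
        acceptor_window(*w["canonical"])
        for w in windows.values()
        if w["canonical"] is not None
    ]
    canonical_training = [w for w in canonical_training if "N" not in w]
    model = None
    if len(canonical_training) >= 100:
        model = train_acceptor_model(canonical_training)
    if not pairs_df.empty:
        for side in ("cryptic", "canonical"):
            scores = []
            for eid in pairs_df["event_id"]:
                w = windows[eid][side]
                s = model.score(acceptor_window(*w)) if (model and w) else None
                scores.append(np.nan if s is None else s)
            pairs_df[f"strength_{side}"] = scores
    pairs_df.to_csv(outdir / "acceptor_pairs.tsv", sep="\t", index=False)
    log["a3ss_pairs"] = len(pairs_df)
    log["strength_model_trained"] = model is not None

    # spacing modes per class
    spacing_rows = []
    if not pairs_df.empty:
        for cls, sub in pairs_df.groupby("class"):
            sm = spacing_mode_log2(list(sub["spacing_nt"]))
            spacing_rows.append(
                {"class": cls, "n": len(sub), "log2_mode": sm.mode}
            )
        nag = pairs_df[pairs_df["is_nagnag"]]
        if len(nag):
            spacing_rows.append(
                {
                    "class": "nagnag",
                    "n": len(nag),
                    "log2_mode": spacing_mode_log2(list(nag["spacing_nt"])).mode,
                }
            )
    pd.DataFrame(spacing_rows).to_csv(outdir / "spacing_modes.tsv", sep="\t", index=False)

    # frequency matrices for logo rendering
    for side in ("cryptic", "canonical"):
        wins = [
            acceptor_window(*windows[eid][side])
            for eid in (pairs_df["event_id"] if not pairs_df.empty else [])
            if windows[eid][side] is not None
        ]
        wins = [w for w in wins if "N" not in w]
        if wins:
            build_frequency_matrix(wins).to_frame().to_csv(
                outdir / f"freq_matrix_{side}.tsv", sep="\t", index=False
            )

    # --- branch points
    bp_calls, bp_classes, bp_ids = [], [], []
    for row in pair_rows:
        for side in ("cryptic", "canonical"):
            w = windows[row["event_id"]][side]
            call = find_branchpoint(*w) if w else None
            bp_calls.append(call)
            label = row["class"] if side == "cryptic" else f"canonical-of-{row['class']}"
            bp_classes.append(label)
            bp_ids.append(row["event_id"])
    bp_df = calls_to_frame(bp_ids, bp_classes, bp_calls)
    bp_df.to_csv(outdir / "branchpoints.tsv", sep="\t", index=False)
    if bp_calls:
        bp_summary = bp_distance_summary(bp_calls, bp_classes)
    else:
        bp_summary = pd.DataFrame()
    bp_summary.to_csv(outdir / "bp_summary.tsv", sep="\t", index=False)

    # --- consequences
    cons_rows = []
    for row in pair_rows:
        event = events_by_id[row["event_id"]]
        gene = genes_by_id[event.gene_id]
        pair = classify_pair(
            event,
            genome,
            cryptic_isoform="long" if row["orientation"] == "upstream" else "short",
        )
        target_tx = None
        for tx in gene.transcripts:
            boundaries = [
                s if gene.strand == "+" else e for s, e in tx.exons
            ]
            if pair.canonical_pos in boundaries:
                target_tx = tx
                break
        if target_tx is None:
            raise PipelineError(
                f"{_stage('consequence', event.event_id)}: canonical acceptor "
                f"{pair.canonical_pos} not found on any transcript"
            )
        try:
            ann = annotate_consequence(gene, target_tx, pair, genome)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(
                f"{_stage('consequence', event.event_id)}: {exc}"
            ) from exc
        cons_rows.append(
            {
                "event_id": ann.event_id,
                "inserted_nt": ann.inserted_nt,
                "region": ann.region,
                "frame_effect": ann.frame_effect or "",
                "added_codons": ann.added_codons if ann.added_codons is not None else "",
                "ptc": ann.ptc,
                "nmd_sensitive": ann.nmd_sensitive,
            }
        )
    cons_df = pd.DataFrame(cons_rows)
    cons_df.to_csv(outdir / "consequence.tsv", sep="\t", index=False)

    run_manifest = {
        "package": "crypticsplice",
        "version": __version__,
        "seed": config.seed,
        "comparison": config.comparison,
        "sign_convention": sign_label,
        "thresholds": {
            "alpha": config.alpha,
            "delta": config.delta,
            "min_count": config.min_count,
        },
        "stages": log,
    }
    (outdir / "run_manifest.json").write_text(
        json.dumps(run_manifest, indent=2, sort_keys=True) + "\n"
    )
    return {
        "events": events,
        "results": results,
        "significant": significant,
        "enrichment": enrichment,
        "pairs": pairs_df,
        "branchpoints": bp_df,
        "bp_summary": bp_summary,
        "consequences": cons_df,
        "manifest": run_manifest,
    }
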