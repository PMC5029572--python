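"""Branch-point prediction upstream of 3' splice sites.

The branch point (BP) is the intronic adenosine attacked in the first
transesterification of splicing, typically 18-40 nt upstream of the acceptor
AG with a minimal workable separation of ~12 nt. Every adenosine in the
search window is scored with a 7-mer position-specific log-odds model
anchored on the extended branch-point consensus (reference motif TACTAAC,
branch adenosine at heptamer position 6); the top-scoring adenosine is
reported together with its BP-AG distance.

The scorer is a consensus log-odds model, not a trained SVM: absolute scores
are model-specific, and only relative comparisons between acceptor classes
and the called positions/distances are meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BranchPointCall",
    "BP_CONSENSUS",
    "BP_ADENOSINE_POS",
    "DEFAULT_SEARCH_WINDOW",
    "MIN_BP_AG_DISTANCE",
    "bp_heptamer_log_odds",
    "score_heptamer",
    "find_branchpoint",
    "bp_distance_summary",
]

BP_CONSENSUS = "TACTAAC"
BP_ADENOSINE_POS = 6  # 1-based position of the branch adenosine in the heptamer
MIN_BP_AG_DISTANCE = 12
DEFAULT_SEARCH_WINDOW = (-100, -MIN_BP_AG_DISTANCE)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
# Consensus-base probability per heptamer position; the branch adenosine
# itself is near-invariant.
_CONSENSUS_P = (0.70, 0.70, 0.70, 0.70, 0.70, 0.97, 0.70)
_BACKGROUND = 0.25


def bp_heptamer_log_odds() -> np.ndarray:
    """The fixed (7, 4) log-odds matrix of the heptamer scorer, in bits."""
    mat = np.empty((7, 4))
    for pos, (cons, p_cons) in enumerate(zip(BP_CONSENSUS, _CONSENSUS_P)):
        p_other = (1.0 - p_cons) / 3.0
        for base, j in _BASE_INDEX.items():
            p = p_cons if base == cons else p_other
            mat[pos, j] = math.log2(p / _BACKGROUND)
    return mat


_LOG_ODDS = bp_heptamer_log_odds()


def score_heptamer(heptamer: str) -> float | None:
    """Log-odds score (bits) of a 7-mer against the BP model; None on N."""
    if len(heptamer) != 7:
        raise ValueError("heptamer must be 7 nt")
    if "N" in heptamer:
        return None
    return float(sum(_LOG_ODDS[pos, _BASE_INDEX[b]] for pos, b in enumerate(heptamer)))


@dataclass(frozen=True)
class BranchPointCall:
    """Top-scoring branch-point adenosine for one acceptor."""

    bp_offset: int  # acceptor-relative offset of the BP adenosine (negative)
    score: float
    bp_ag_distance_nt: int
    in_window: bool

    def __post_init__(self) -> None:
        if self.bp_ag_distance_nt != abs(self.bp_offset):
            raise ValueError("bp_ag_distance_nt must equal |bp_offset|")


def find_branchpoint(
    window: str,
    boundary: int,
    search_window: tuple[int, int] = DEFAULT_SEARCH_WINDOW,
) -> BranchPointCall | None:
    """Locate the top-scoring BP adenosine upstream of an acceptor.

    ``window`` is a transcript-oriented sequence; ``boundary`` is the index
    of the first exonic base. Every A whose offset lies in ``search_window``
    (inclusive) is scored on its heptamer (positions offset-5..offset+1);
    the highest-scoring A wins, ties broken toward the smaller BP-AG
    distance. Returns ``None`` when no scoreable adenosine lies in range.
    """
    lo, hi = search_window
    if lo > hi:
        raise ValueError("search_window must be (more negative, less negative)")
    if hi > -MIN_BP_AG_DISTANCE:
        raise ValueError(f"search window may not come closer than -{MIN_BP_AG_DISTANCE}")
    best: tuple[float, int] | None = None  # (score, offset)
    # iterate 3' -> 5' so ties resolve to the smaller distance
    for offset in range(hi, lo - 1, -1):
        idx = boundary + offset
        if idx < 0 or idx >= len(window):
            continue
        if window[idx] != "A":
            continue
        start = idx - (BP_ADENOSINE_POS - 1)
        end = start + 7
        if start < 0 or end > len(window):
            continue
        s = score_heptamer(window[start:end])
        if s is None:
            continue
        if best is None or s > best[0]:
            best = (s, offset)
    if best is None:
        return None
    score, offset = best
    return BranchPointCall(
        bp_offset=offset,
        score=score,
        bp_ag_distance_nt=abs(offset),
        in_window=True,
    )


def bp_distance_summary(
    calls: Sequence[BranchPointCall | None],
    class_labels: Sequence[str],
    min_calls: int = 20,
) -> pd.DataFrame:
    """Per-class median BP-AG distance and median score.

    Medians are computed over called (non-absent) acceptors only; the
    fraction of absent calls is reported per class. Classes with zero calls
    get missing medians and ``flag = "no_calls"``; classes below
    ``min_calls`` are flagged ``"few_calls"``.
    """
    if len(calls) != len(class_labels):
        raise ValueError("calls and class_labels must align")
    rows = []
    for cls in sorted(set(class_labels)):
        members = [c for c, lab in zip(calls, class_labels) if lab == cls]
        called = [c for c in members if c is not None]
        if not called:
            rows.append(
                {
                    "class": cls,
                    "n": len(members),
                    "n_called": 0,
                    "fraction_absent": 1.0,
                    "median_bp_ag_distance_nt": float("nan"),
                    "median_score": float("nan"),
                    "flag": "no_calls",
                }
            )
            continue
        distances = [c.bp_ag_distance_nt for c in called]
        scores = [c.score for c in called]
        rows.append(
            {
                "class": cls,
                "n": len(members),
                "n_called": len(called),
                "fraction_absent": 1.0 - len(called) / len(members),
                "median_bp_ag_distance_nt": float(np.median(distances)),
                "median_score": float(np.median(scores)),
                "flag": "" if len(called) >= min_calls else "few_calls",
            }
        )
    return pd.DataFrame(rows)


def calls_to_frame(
    event_ids: Sequence[str],
    class_labels: Sequence[str],
    calls: Sequence[BranchPointCall | None],
) -> pd.DataFrame:
    """Tabular (TSV-ready) view of per-acceptor BP calls."""
    rows = []
    for eid, cls, call in zip(event_ids, class_labels, calls):
        rows.append(
            {
                "event_id": eid,
                "class": cls,
                "bp_offset": call.bp_offset if call else pd.NA,
                "bp_ag_distance_nt": call.bp_ag_distance_nt if call else pd.NA,
                "score": call.score if call else pd.NA,
            }
        )
    return pd.DataFrame(rows)
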