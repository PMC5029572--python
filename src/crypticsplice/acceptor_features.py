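"""Sequence properties of alternative 3' splice-site (acceptor) pairs.

This module classifies A3SS pairs as upstream/downstream cryptic, measures
AG-to-AG spacing distributions (reported as a log2 mode, the convention used
for tandem-acceptor spacing), calls polypyrimidine tracts (PPT) with an
explicit scan rule, trains a position-specific log-odds strength model on
canonical acceptors, and builds per-position frequency matrices for sequence
logos.

All acceptor-relative offsets follow the package convention: -1 is the last
intronic base (the G of AG), +1 the first exonic base. Window functions take
a transcript-oriented sequence plus ``boundary``, the index of the first
exonic base within that sequence.

The acceptor strength model is a position-specific log-odds scorer over the
23-nt window (-20..+3) standard for 3' splice-site strength estimation. It is
self-contained (trained on the supplied canonical windows); absolute scores
are model-specific and not comparable to published maximum-entropy values —
only relative comparisons between acceptor classes are meaningful.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import PURINES, PYRIMIDINES

if TYPE_CHECKING:  # pragma: no cover
    from .event_caller import SplicingEvent

__all__ = [
    "AcceptorPair",
    "PPTCall",
    "ARun",
    "FrequencyMatrix",
    "AcceptorStrengthModel",
    "GroupComparison",
    "SpacingMode",
    "classify_pair",
    "spacing_mode_log2",
    "call_ppt",
    "train_acceptor_model",
    "compare_groups",
    "build_frequency_matrix",
    "acceptor_window",
    "STRENGTH_WINDOW_INTRON",
    "STRENGTH_WINDOW_EXON",
]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

STRENGTH_WINDOW_INTRON = 20  # intronic nt in the strength-model window
STRENGTH_WINDOW_EXON = 3  # exonic nt
PPT_MIN_WINDOW = 40  # call_ppt needs at least -40..-1
A_RUN_WINDOW = (-25, -5)  # search range for the A-run, inclusive offsets


@dataclass(frozen=True)
class ARun:
    """Longest adenosine run in the A-run search window."""

    length: int
    offset: int  # acceptor-relative offset of the 5'-most A of the run


@dataclass(frozen=True)
class PPTCall:
    """Polypyrimidine tract geometry at one acceptor.

    ``start_offset`` is the 5'-most tract position (negative, inclusive);
    ``end_offset`` is exclusive, so ``length_nt == end_offset - start_offset``.
    """

    start_offset: int
    end_offset: int
    length_nt: int
    pyrimidine_fraction: float
    interruptions: int
    a_run: ARun | None


@dataclass(frozen=True)
class AcceptorPair:
    """A cryptic/canonical acceptor pair from one A3SS event."""

    event_id: str
    canonical_pos: int  # genomic coordinate of the intron/exon boundary
    cryptic_pos: int
    strand: str
    orientation: str  # "upstream" | "downstream": cryptic relative to canonical
    spacing_nt: int
    is_nagnag: bool


@dataclass(frozen=True)
class SpacingMode:
    """Histogram of log2 spacings (bin width 0.1) and its modal bin center."""

    curve: pd.DataFrame  # columns: log2_center, count, density
    mode: float | None


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    p_value: float
    testable: bool


def _is_purine(base: str) -> bool:
    return base in PURINES


def offset_base(window: str, boundary: int, offset: int) -> str:
    """Base at an acceptor-relative offset (-1 = last intronic, +1 = first exonic)."""
    if offset == 0:
        raise ValueError("offset 0 is undefined; use -1 or +1")
    idx = boundary + offset if offset < 0 else boundary + offset - 1
    return window[idx]


def acceptor_window(window: str, boundary: int) -> str:
    """The 23-nt strength-model window (-20..+3) around the boundary."""
    if boundary < STRENGTH_WINDOW_INTRON or len(window) - boundary < STRENGTH_WINDOW_EXON:
        raise ValueError("window does not cover -20..+3 around the boundary")
    return window[boundary - STRENGTH_WINDOW_INTRON : boundary + STRENGTH_WINDOW_EXON]


# ---------------------------------------------------------------------------
# Pair classification and spacing

def classify_pair(
    event: "SplicingEvent",
    genome: dict[str, str] | None = None,
    cryptic_isoform: str = "long",
) -> AcceptorPair:
    """Classify an A3SS event's acceptor pair as upstream or downstream cryptic.

    ``cryptic_isoform`` names which isoform uses the cryptic acceptor: the
    ``"long"`` isoform (intron-proximal acceptor, the dominant class in
    SF3B1-mutant data) or the ``"short"`` one. With a ``genome``, spacing-3
    pairs are additionally checked for the NAGNAG tandem-acceptor motif (the
    6-mer N AG N AG ending at the 3'-most acceptor); without sequence,
    spacing 3 alone marks the pair NAGNAG.
    """
    if event.event_type != "A3SS":
        raise TypeError(f"classify_pair requires an A3SS event, got {event.event_type}")
    if cryptic_isoform not in {"long", "short"}:
        raise ValueError("cryptic_isoform must be 'long' or 'short'")
    acc_long, acc_short = event.acceptor_long, event.acceptor_short
    cryptic = acc_long if cryptic_isoform == "long" else acc_short
    canonical = acc_short if cryptic_isoform == "long" else acc_long
    # The long isoform's acceptor is intron-proximal, i.e. upstream in
    # transcript orientation, on both strands.
    orientation = "upstream" if cryptic == acc_long else "downstream"
    spacing = abs(cryptic - canonical)
    is_nagnag = spacing == 3
    if is_nagnag and genome is not None:
        # 6-mer ending at the 3'-most (exon-proximal) acceptor, transcript
        # orientation: N AG N AG
        from .genome_io import SequenceRegion

        three_prime = max(cryptic, canonical) if event.strand == "+" else min(cryptic, canonical)
        if event.strand == "+":
            region = SequenceRegion.from_genome(
                genome, event.chrom, three_prime - 6, three_prime, "+"
            )
        else:
            region = SequenceRegion.from_genome(
                genome, event.chrom, three_prime, three_prime + 6, "-"
            )
        six = region.seq
        is_nagnag = six[1:3] == "AG" and six[4:6] == "AG"
    return AcceptorPair(
        event_id=event.event_id,
        canonical_pos=canonical,
        cryptic_pos=cryptic,
        strand=event.strand,
        orientation=orientation,
        spacing_nt=spacing,
        is_nagnag=is_nagnag,
    )


def spacing_mode_log2(spacings: Sequence[int]) -> SpacingMode:
    """Mode of the log2-transformed spacing distribution, to one decimal.

    Spacings are log2-transformed and binned at width 0.1 (bins centered on
    multiples of 0.1); the mode is the center of the fullest bin, ties broken
    toward the smaller value. Returns a missing mode for an empty class and
    the histogram curve for plotting. Modes from classes below ~20 pairs
    should be treated as unreliable.
    """
    spacings = [s for s in spacings if s >= 1]
    if not spacings:
        return SpacingMode(
            curve=pd.DataFrame(columns=["log2_center", "count", "density"]), mode=None
        )
    centers = np.round(np.log2(np.asarray(spacings, dtype=float)), 1)
    counts = Counter(centers)
    total = len(spacings)
    curve = (
        pd.DataFrame(
            {"log2_center": list(counts), "count": [counts[c] for c in counts]}
        )
        .sort_values("log2_center")
        .reset_index(drop=True)
    )
    curve["density"] = curve["count"] / (total * 0.1)
    best = max(counts.values())
    mode = min(c for c, n in counts.items() if n == best)
    return SpacingMode(curve=curve, mode=float(mode))


# ---------------------------------------------------------------------------
# Polypyrimidine tract

def call_ppt(
    window: str,
    boundary: int,
    min_pyrimidine_fraction: float = 0.7,
) -> PPTCall | None:
    """Call the polypyrimidine tract upstream of an acceptor.

    Scan rule: start at offset -3 and extend 5' while interruptions are
    single purines only (two consecutive purines terminate the scan) and the
    running pyrimidine fraction stays >= ``min_pyrimidine_fraction``; the
    tract is then trimmed to start and end on a pyrimidine. The longest
    adenosine run in -25..-5 is reported alongside.

    Returns ``None`` (missing call) when the scanned window contains N.
    The window must cover at least offsets -40..-1.
    """
    if boundary < PPT_MIN_WINDOW:
        raise ValueError(f"window must cover -{PPT_MIN_WINDOW}..-1 upstream of boundary")
    upstream = window[:boundary]
    if "N" in upstream[-PPT_MIN_WINDOW:]:
        return None

    included: list[tuple[int, str]] = []  # (offset, base), 3' -> 5'
    n_pyr = 0
    prev_purine = False
    for k in range(3, boundary + 1):
        base = upstream[-k]
        purine = _is_purine(base)
        if purine and prev_purine:
            break
        frac = (n_pyr + (0 if purine else 1)) / (len(included) + 1)
        if frac < min_pyrimidine_fraction:
            break
        included.append((-k, base))
        n_pyr += 0 if purine else 1
        prev_purine = purine

    # trim to pyrimidine at both ends
    while included and _is_purine(included[0][1]):
        removed = included.pop(0)
        n_pyr -= 0 if _is_purine(removed[1]) else 1
    while included and _is_purine(included[-1][1]):
        included.pop()

    a_run = _longest_a_run(window, boundary)
    if not included:
        return PPTCall(
            start_offset=0,
            end_offset=0,
            length_nt=0,
            pyrimidine_fraction=0.0,
            interruptions=0,
            a_run=a_run,
        )
    end_offset = included[0][0] + 1  # exclusive
    start_offset = included[-1][0]
    length = end_offset - start_offset
    n_pur_inside = sum(1 for _, b in included if _is_purine(b))
    return PPTCall(
        start_offset=start_offset,
        end_offset=end_offset,
        length_nt=length,
        pyrimidine_fraction=(length - n_pur_inside) / length,
        interruptions=n_pur_inside,
        a_run=a_run,
    )


def _longest_a_run(window: str, boundary: int) -> ARun | None:
    lo, hi = A_RUN_WINDOW  # inclusive offsets, lo more negative
    best_len, best_offset = 0, 0
    run_len = 0
    for offset in range(lo, hi + 1):
        idx = boundary + offset
        if idx < 0:
            continue
        if window[idx] == "A":
            run_len += 1
            if run_len > best_len:
                best_len = run_len
                best_offset = offset - run_len + 1
        else:
            run_len = 0
    if best_len == 0:
        return None
    return ARun(length=best_len, offset=best_offset)


# ---------------------------------------------------------------------------
# Acceptor strength model

class AcceptorStrengthModel:
    """Position-specific log-odds acceptor strength scorer.

    Trained on canonical acceptor windows of length 23 (-20..+3, AG at
    -2..-1). ``score(seq) = sum_pos log2(f_pos(base) / q(base))`` with
    add-one smoothing; the background ``q`` is the overall base composition
    of the training windows.
    """

    window_length = STRENGTH_WINDOW_INTRON + STRENGTH_WINDOW_EXON

    def __init__(self, log_odds: np.ndarray, model_id: str = "ppm-logodds-23nt"):
        if log_odds.shape != (self.window_length, 4):
            raise ValueError("log-odds matrix must be (23, 4)")
        self.log_odds = log_odds
        self.model_id = model_id

    @classmethod
    def train(cls, windows: Sequence[str], min_windows: int = 100) -> "AcceptorStrengthModel":
        if len(windows) < min_windows:
            raise ValueError(f"need >= {min_windows} training windows, got {len(windows)}")
        counts = np.zeros((cls.window_length, 4))
        for w in windows:
            if len(w) != cls.window_length:
                raise ValueError(
                    f"training window length {len(w)} != {cls.window_length}"
                )
            if w[STRENGTH_WINDOW_INTRON - 2 : STRENGTH_WINDOW_INTRON] != "AG":
                raise ValueError("training window lacks AG at -2..-1")
            for pos, base in enumerate(w):
                if base == "N":
                    raise ValueError("training windows must not contain N")
                counts[pos, BASE_INDEX[base]] += 1
        freqs = (counts + 1) / (counts.sum(axis=1, keepdims=True) + 4)
        bg_counts = counts.sum(axis=0)
        q = (bg_counts + 1) / (bg_counts.sum() + 4)
        return cls(log_odds=np.log2(freqs / q))

    def score(self, window: str) -> float | None:
        """Log-odds score in bits; ``None`` when the window contains N."""
        if len(window) != self.window_length:
            raise ValueError(f"window length {len(window)} != {self.window_length}")
        if "N" in window:
            return None
        return float(
            sum(self.log_odds[pos, BASE_INDEX[b]] for pos, b in enumerate(window))
        )

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.log_odds.argmax(axis=1))

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())


def train_acceptor_model(
    canonical_windows: Sequence[str], min_windows: int = 100
) -> AcceptorStrengthModel:
    """Train the acceptor strength model on canonical 23-nt windows."""
    return AcceptorStrengthModel.train(canonical_windows, min_windows=min_windows)


# ---------------------------------------------------------------------------
# Group comparison

def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float]
) -> GroupComparison:
    """Two-sided Mann-Whitney U (normal approximation, tie-corrected).

    Groups with fewer than 3 values are flagged untestable. When every
    observation is tied the p-value is 1 by convention.
    """
    a = [v for v in values_a if v is not None and not math.isnan(v)]
    b = [v for v in values_b if v is not None and not math.isnan(v)]
    if len(a) < 3 or len(b) < 3:
        return GroupComparison(statistic=float("nan"), p_value=float("nan"), testable=False)
    if len(set(a) | set(b)) == 1:
        return GroupComparison(statistic=len(a) * len(b) / 2.0, p_value=1.0, testable=True)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    p = float(res.pvalue)
    if math.isnan(p):  # fully tied data with zero tie-corrected variance
        p = 1.0
    return GroupComparison(statistic=float(res.statistic), p_value=min(p, 1.0), testable=True)


# ---------------------------------------------------------------------------
# Frequency matrix

@dataclass(frozen=True)
class FrequencyMatrix:
    """Per-position base counts/frequencies over aligned acceptor windows."""

    offsets: tuple[int, ...]
    counts: np.ndarray  # (length, 4), columns A C G T
    n_sequences: int

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_sequences

    def information_content(self) -> np.ndarray:
        """Per-position information content (bits): 2 - entropy."""
        f = self.frequencies
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(f > 0, f * np.log2(f), 0.0)
        return 2.0 + plogp.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.frequencies, columns=list(BASES))
        df.insert(0, "offset", self.offsets)
        df["information_bits"] = self.information_content()
        return df


def build_frequency_matrix(
    windows: Iterable[str], offsets: Sequence[int] | None = None
) -> FrequencyMatrix:
    """Build a position frequency matrix from equal-length windows.

    ``offsets`` labels positions in acceptor-relative coordinates; the
    default labels a 23-nt window as -20..-1, +1..+3.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("no windows")
    length = len(windows[0])
    if any(len(w) != length for w in windows):
        raise ValueError("windows must have equal length")
    counts = np.zeros((length, 4))
    for w in windows:
        for pos, base in enumerate(w):
            if base not in BASE_INDEX:
                raise ValueError(f"invalid base {base!r} in window")
            counts[pos, BASE_INDEX[base]] += 1
    if offsets is None:
        if length == STRENGTH_WINDOW_INTRON + STRENGTH_WINDOW_EXON:
            offsets = tuple(range(-STRENGTH_WINDOW_INTRON, 0)) + (1, 2, 3)
        else:
            offsets = tuple(range(-length, 0))
    if len(offsets) != length:
        raise ValueError("offsets length must match window length")
    return FrequencyMatrix(offsets=tuple(offsets), counts=counts, n_sequences=len(windows))
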