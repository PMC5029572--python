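# Methods

## Scope and data model

The package analyses cryptic 3′ splice-site (acceptor) usage from
splice-junction counts. It does not align reads or assemble transcripts: its
inputs are gene models (GTF), genomic sequence (FASTA), a per-sample table of
inclusion/exclusion junction counts per event, and a sample manifest over a
three-level design (mutant / wildtype / control). Internally all coordinates
are 0-based half-open, exons are kept in transcript orientation, and every
acceptor-relative position uses one convention on both strands: −1 is the
last intronic base (the G of the AG dinucleotide), +1 the first exonic base.
Windows containing N yield missing scores rather than numbers, so ambiguous
sequence cannot silently bias class statistics.

## Event calling and differential inclusion

Events are enumerated by diffing every transcript pair of a gene into local
"bubbles" between shared exons and classifying each bubble: a single exon
differing only at its acceptor-side boundary is an A3SS (donor-side: A5SS); a
cassette exon between shared anchors is exon skipping; two disjoint exons
between anchors are mutually exclusive; a single exon spanning two exons plus
their intron is a retained intron. Bubbles with no classifiable shape
(e.g. no shared internal anchor) are skipped. Events are deduplicated by
coordinates, so N transcripts yield each local difference once. The "longer
isoform" is the variant producing more mature transcript: inclusion, retained
intron, upstream acceptor, downstream donor.

PSI of the longer isoform is inc/(inc+exc), treated as missing below a
per-sample count floor (default 10; junction evidence below that is too noisy
to quantify a ratio). The group test is a binomial likelihood-ratio test of
one pooled PSI versus group-specific PSIs (df = 1). Patient replicates are
overdispersed relative to a binomial, so by default the statistic is
quasi-corrected: the Pearson dispersion φ̂ is estimated from the per-sample
residuals under group-specific PSIs, and G²/φ̂ is referred to F(1, N−2),
with φ̂ floored at 1. Under the generator's default beta-binomial noise
(dispersion 0.01, depth ≈ 100, variance inflation ≈ 2) this keeps the null
rejection rate at nominal level (0.047 measured at α = 0.05 over 1,000 null
events) where the uncorrected LRT rejects ≈ 0.18; power at the planted
inclusion shift of 0.4 (8 vs 4 samples, depth 100) is ≈ 1. The uncorrected
test remains available via `overdispersion="none"`.

The inclusion-level difference is signed reference − mutant: negative means
the longer isoform is up in mutant. Significance requires FDR < α
(Benjamini–Hochberg over testable events, each comparison corrected
separately) and |Δψ| > δ, defaults α = 0.05, δ = 0.3. Both thresholds are
configurable; note that a well-known *ABCB7* event (FDR 0.006, Δψ = −0.184)
would fail the default |Δψ| filter, so analyses targeting genes with modest
inclusion shifts may want a lower δ. Per-type overrepresentation among
significant events uses the Yates-continuity-corrected χ² on the 2×2 table of
significant/non-significant by type/other, skipped with a flag when an
expected cell falls below 1.

## Acceptor features

**Pair classification.** For an A3SS event the cryptic side must be named
(it is not derivable from geometry alone); the pipeline assigns it from the
sign of the inclusion-level difference for significant events — the isoform
favored in mutant is the cryptic one — and defaults to the long isoform
otherwise. Orientation is upstream when the cryptic acceptor is
intron-proximal. Spacing-3 pairs are checked for the NAGNAG tandem-acceptor
motif (N AG N AG ending at the 3′-most acceptor) when sequence is available.

**Spacing mode.** Spacings are log2-transformed and binned at width 0.1 with
bin centers on multiples of 0.1 (so 15 nt → 3.9, 3 nt → 1.6); the mode is
the fullest bin's center, ties broken toward the smaller value. A histogram
was chosen over a kernel density because it is deterministic and matches
one-decimal reporting.

**PPT scan.** From −3, extend 5′ while (a) no two consecutive purines occur
and (b) the running pyrimidine fraction stays ≥ 0.7, then trim both ends to
pyrimidines. Length, interruptions and pyrimidine fraction are reported,
along with the longest adenosine run in −25..−5 — the diagnostic feature of
SF3B1-class cryptic acceptors. The 0.7 threshold and single-purine tolerance
are exposed as parameters.

**Strength model.** A position-specific log-odds scorer over the 23-nt
window −20..+3 (the standard acceptor strength window), trained on canonical
windows with add-one smoothing against the training set's overall base
composition. Scores are in bits and model-specific: they support relative
comparisons (cryptic vs canonical) but are not comparable to published
maximum-entropy scores. The expectation of the score under the model's own
background is −Σ_pos KL(q‖f_pos), which is strongly negative for a
structured model; only a structureless model scores background near zero.

**Group comparisons** of feature distributions use the two-sided
Mann–Whitney U with normal approximation and tie correction; fully tied data
return p = 1, and groups under 3 values are flagged untestable.

## Branch points

Every adenosine with offset in −100..−12 is scored by a fixed 7-mer log-odds
matrix anchored on the TACTAAC consensus (branch adenosine at position 6,
consensus probability 0.7 per position, 0.97 at the branch A, uniform
background). The search floor of 12 nt encodes the minimal workable BP–AG
separation. The top-scoring adenosine wins; ties go to the smaller distance.
This consensus scorer deliberately replaces a trained SVM: absolute scores
are therefore model-specific, and downstream statistics use only called
positions, distances, and within-run score comparisons.

## Consequences and NMD

The aberrant transcript is built by substituting the cryptic acceptor for
the canonical one; an upstream cryptic acceptor inserts the terminal
intronic fragment (which necessarily ends in the canonical AG), a downstream
one deletes exonic sequence (annotated as a negative insertion by the same
machinery). The change point is located against the CDS to set the region
(5′UTR / CDS / 3′UTR / noncoding) and frame effect; translation of the
aberrant CDS (Biopython) finds the first stop, which is a PTC when it lies
5′ of the annotated termination codon. "Added codons" counts inserted codons
including a terminal stop — so a 21-nt insertion ending in a stop adds
seven codons — and `last_codon_is_stop` keeps the alternative reading
(six residues plus stop) recoverable. NMD sensitivity follows the classical
rule: PTC at least 50 nt upstream of the last exon–exon junction, boundary
inclusive. In-silico RT-PCR requires each primer to match its transcript
exactly once and reports lengths inclusive of both primer sites.

## Synthetic data generator

The generator emulates the study conditions the analysis targets: 8 mutant,
4 wild-type and 5 control samples; per-type event counts with regulated
(planted Δψ = 0.4) events concentrated in upstream A3SS and retained
introns; junction counts drawn beta-binomially (dispersion 0.01 — patient
replicates, not technical ones) around group PSIs at a mean depth of 100,
with the sign arranged so mutant favors the longer isoform of
upstream-cryptic events. Sequence structure per acceptor class:

- canonical: pure-pyrimidine PPT of 18–20 nt (U-enriched, P(T) = 0.65)
  ending at −3, branch-point heptamer at BP–AG distances with median 27
  (support 18–40);
- upstream cryptic: PPT of 7–9 nt (median 8), a 4–5 nt adenosine run planted
  immediately 5′ of the tract — its start lands 13–16 nt upstream of the AG
  and its purines double as the tract terminator the scan rule needs — and
  BP distances with median 18 (support 12–30);
- unregulated: canonical-like elements with BP median 26; spacings carry a
  0.25 atom at 3 nt (NAGNAG) over broad support 3–300 nt, while regulated
  spacings have a 0.4 atom at 15 nt over support 12–60 nt with a geometric
  tail.

Geometric feasibility forces two documented adjustments: the planted PPT is
truncated to d−6 when the drawn BP distance d leaves no room for tract plus
heptamer, and the A-run is omitted when no disjoint placement exists (only
short-d windows); the class medians of both profiles are preserved exactly.
A purine guard ("GG", or the A-run itself) always terminates the planted
tract so the scan recovers the planted length exactly. Exactly one consensus
heptamer is planted per window; any competing consensus match in the search
range is degraded, and background A-runs in the A-run window are capped at
2, making branch-point and A-run recovery well-posed. Background sequence is
i.i.d. uniform — the simplest null for log-odds scorers.

In full datasets the two acceptors of a pair share one intron, so at modal
15-nt spacing the cryptic AG necessarily sits inside the canonical tract
span (the shared BP/PPT-unit geometry of real tandem acceptors); dataset
introns therefore plant the cryptic-class elements for regulated events and
canonical-class elements for unregulated ones, while the standalone
per-class window generator plants each class at full fidelity for
class-level statistics. Dataset genes are non-coding; coding consequences
are exercised by the six packaged fixtures, whose sequences are fixed
literals (bit-stable) satisfying every stated constraint of their namesake
events — including a synthetic 21-mer for the ABCB7-style insertion, since
the real inserted sequence is available only as a trace image.

What the generator does **not** emulate: read-level artifacts (mapping bias,
PCR duplicates), expression-level variation between genes, correlated noise
across events within a sample, degenerate branch points, and PPTs with
internal purine interruptions beyond those the planted elements create.
Passing parameter-recovery tests therefore demonstrates the estimators'
correctness on clean signal at realistic depth and design, not robustness to
alignment-level artifacts in real data.

## Problem sizes and numerical choices

Class-level statistics use 500 windows or pairs per class and the
calibration checks 1,000 null / 200 powered events — sizes at which the
binomial sampling error of a rejection rate (±0.014 at 0.05) and of a median
over the planted profiles are well inside the stated tolerances, while a
full run of suite plus acceptance script stays in the tens of seconds.
Deterministic tie-breaks throughout (histogram mode → smaller value; branch
point → smaller distance); one seed drives each generated dataset, and
identical configurations produce byte-identical outputs. Missing inputs
(zero-depth samples, N-containing windows, classes with no calls) propagate
as missing values with flags rather than zeros.

## Known limitations

- The differential test models junction counts only; retained-intron PSI uses
  retention vs spliced junction counts without an intronic read-depth term.
- Acceptor and branch-point scores are package-internal log-odds values, not
  calibrated against published maximum-entropy or SVM scores.
- The cryptic side of a non-significant A3SS pair is assigned by convention
  (long isoform), which matters only for orientation summaries of the
  unregulated class.
- Paired-sample designs and more than three groups are out of scope.
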