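"""Event enumeration, PSI, differential testing, filters, enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from crypticsplice.event_caller import (
    apply_filters,
    category_overrepresentation,
    compute_psi,
    enumerate_events,
    test_differential as run_differential_test,
    yates_chi2,
    DiffSplicingResult,
)
from crypticsplice.genome_io import GeneModel, SampleManifest, TranscriptModel


def _gene(transcript_exons: dict[str, list[tuple[int, int]]], strand="+"):
    txs = tuple(
        TranscriptModel(tid, tuple(sorted(exons, reverse=strand == "-")))
        for tid, exons in transcript_exons.items()
    )
    return GeneModel("g", "chr1", strand, txs)


class TestEnumerateEvents:
    def test_acceptor_shift_yields_one_a3ss(self):
        gene = _gene({"t1": [(100, 200), (300, 400)], "t2": [(100, 200), (279, 400)]})
        events = enumerate_events([gene])
        assert [e.event_type for e in events] == ["A3SS"]
        ev = events[0]
        assert ev.acceptor_long == 279 and ev.acceptor_short == 300
        assert abs(ev.acceptor_long - ev.acceptor_short) == 21
        assert ev.longer_isoform_id == "t2"

    def test_single_transcript_gene_yields_nothing(self):
        gene = _gene({"t1": [(100, 200), (300, 400)]})
        assert enumerate_events([gene]) == []

    def test_three_transcripts_one_se_one_a3ss(self):
        # t1 full; t2 skips the middle exon; t3 shifts the last acceptor
        gene = _gene(
            {
                "t1": [(100, 200), (300, 350), (500, 600)],
                "t2": [(100, 200), (500, 600)],
                "t3": [(100, 200), (300, 350), (480, 600)],
            }
        )
        events = enumerate_events([gene])
        assert sorted(e.event_type for e in events) == ["A3SS", "SE"]

    def test_matches_hand_enumerated_oracle_on_four_transcripts(self):
        # all pairwise local diffs, deduplicated: SE, A3SS, RI around one gene
        gene = _gene(
            {
                "t1": [(100, 200), (300, 350), (500, 600)],
                "t2": [(100, 200), (500, 600)],
                "t3": [(100, 200), (300, 350), (480, 600)],
                "t4": [(100, 200), (300, 600)],  # retains the last intron
            }
        )
        got = {(e.event_type, e.long_exons, e.short_exons) for e in enumerate_events([gene])}
        # oracle: exhaustive hand enumeration of all C(4,2) transcript pairs
        # (t2-t3 is a complex bubble with no shared internal anchor: no event)
        expected = {
            ("SE", ((300, 350),), ()),  # t1-t2
            ("A3SS", ((480, 600),), ((500, 600),)),  # t1-t3
            ("RI", ((300, 600),), ((300, 350), (500, 600))),  # t1-t4
            ("A3SS", ((300, 600),), ((500, 600),)),  # t2-t4
            ("RI", ((300, 600),), ((300, 350), (480, 600))),  # t3-t4
        }
        assert got == expected

    def test_event_types_on_minus_strand(self):
        # mirror of the acceptor-shift case: acceptor is the exon end on '-'
        gene = _gene(
            {"t1": [(300, 400), (100, 200)], "t2": [(300, 400), (100, 221)]},
            strand="-",
        )
        events = enumerate_events([gene])
        assert [e.event_type for e in events] == ["A3SS"]
        assert events[0].acceptor_long == 221 and events[0].acceptor_short == 200

    def test_ri_and_mxe_detected(self):
        ri = _gene({"t1": [(100, 200), (300, 400)], "t2": [(100, 400)]})
        assert [e.event_type for e in enumerate_events([ri])] == ["RI"]
        mxe = _gene(
            {
                "t1": [(100, 200), (300, 350), (600, 700)],
                "t2": [(100, 200), (420, 480), (600, 700)],
            }
        )
        assert [e.event_type for e in enumerate_events([mxe])] == ["MXE"]


class TestComputePsi:
    @pytest.mark.parametrize(
        "inc,exc,expected",
        [(30, 10, 0.75), (0, 0, None), (10, 0, 1.0), (5, 4, None)],
    )
    def test_examples(self, inc, exc, expected):
        assert compute_psi(inc, exc) == expected

    @given(st.integers(0, 10_000), st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_psi_bounds(self, inc, exc):
        psi = compute_psi(inc, exc, min_count=1)
        assert psi is None or 0.0 <= psi <= 1.0


def _counts(rows):
    return (
        pd.DataFrame(rows, columns=["event_id", "sample_id", "inc", "exc"])
        .set_index(["event_id", "sample_id"])
        .sort_index()
    )


MANIFEST = SampleManifest(
    samples=tuple(
        [(f"M{i}", "mutant") for i in range(4)] + [(f"W{i}", "wildtype") for i in range(4)]
    )
)


class TestDifferential:
    def test_identical_groups_null_identity(self):
        counts = _counts(
            [("E", s, 30, 30) for s, _ in MANIFEST.samples]
        )
        r = run_differential_test("E", counts, MANIFEST)
        assert r.inc_level_difference == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_sign_convention_longer_up_in_mutant_is_negative(self):
        rows = [("E", f"M{i}", 80, 20) for i in range(4)]
        rows += [("E", f"W{i}", 20, 80) for i in range(4)]
        r = run_differential_test("E", _counts(rows), MANIFEST)
        assert r.inc_level_difference == pytest.approx(-0.6)
        assert r.p_value < 0.01

    def test_untestable_when_group_missing(self):
        rows = [("E", f"M{i}", 80, 20) for i in range(4)]
        rows += [("E", f"W{i}", 2, 3) for i in range(4)]  # below min_count
        r = run_differential_test("E", _counts(rows), MANIFEST)
        assert not r.testable and r.p_value is None

    def test_ild_bounds(self, default_dataset):
        ds = default_dataset
        for event in ds.events[:40]:
            r = run_differential_test(event.event_id, ds.counts, ds.manifest)
            if r.inc_level_difference is not None:
                assert -1.0 <= r.inc_level_difference <= 1.0


def _result(event_id, p, ild):
    return DiffSplicingResult(
        event_id=event_id,
        comparison="mutant_vs_wildtype",
        psi_per_sample={},
        mean_psi_mutant=0.5,
        mean_psi_reference=0.5 + ild,
        inc_level_difference=ild,
        p_value=p,
        testable=True,
    )


class TestFilters:
    def test_low_fdr_but_small_ild_excluded(self):
        # significant FDR with |ILD| below the 0.3 threshold must not pass
        results = [_result("abcb7_like", 1e-4, -0.184)] + [
            _result(f"bg{i}", 0.5, 0.0) for i in range(20)
        ]
        sig = apply_filters(results)
        assert sig == []
        assert results[0].fdr < 0.05  # it fails on the ILD filter, not FDR

    def test_boundary_retained(self):
        results = [_result("a", 0.001, 0.31)] + [
            _result(f"bg{i}", 0.9, 0.0) for i in range(10)
        ]
        sig = apply_filters(results)
        assert [r.event_id for r in sig] == ["a"]
        assert sig[0].fdr < 0.05

    def test_empty_input(self):
        assert apply_filters([]) == []

    def test_bh_fdr_monotone_in_p_rank(self):
        rng = np.random.default_rng(0)
        results = [_result(f"e{i}", p, 0.5) for i, p in enumerate(rng.uniform(size=50))]
        apply_filters(results)
        ordered = sorted(results, key=lambda r: r.p_value)
        fdrs = [r.fdr for r in ordered]
        assert all(a <= b + 1e-12 for a, b in zip(fdrs, fdrs[1:]))


class TestYatesChi2:
    def test_hand_evaluated_example(self):
        stat, _ = yates_chi2([[10, 90], [30, 70]])
        assert stat == pytest.approx(11.28125, abs=1e-9)

    def test_agrees_with_scipy_continuity_correction(self):
        for table in ([[10, 90], [30, 70]], [[5, 15], [25, 55]], [[40, 2], [3, 55]]):
            stat, p = yates_chi2(table)
            ref = chi2_contingency(np.array(table), correction=True)
            assert stat == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_equal_proportions_not_significant(self):
        sig = ["A3SS"] * 10 + ["RI"] * 10
        total = ["A3SS"] * 50 + ["RI"] * 50
        enr = category_overrepresentation(sig, total)
        by_type = {e.event_type: e for e in enr}
        assert by_type["A3SS"].direction == "not significant"
        assert by_type["A3SS"].p_value > 0.9

    def test_extreme_enrichment_overrepresented(self):
        sig = ["A3SS"] * 30
        total = ["A3SS"] * 40 + ["RI"] * 100 + ["SE"] * 60
        enr = {e.event_type: e for e in category_overrepresentation(sig, total)}
        assert enr["A3SS"].direction == "overrepresented"
        assert enr["RI"].direction == "underrepresented"

    def test_small_expected_cell_skipped(self):
        sig = ["A3SS"]
        total = ["A3SS"] * 2 + ["RI"] * 2
        enr = {e.event_type: e for e in category_overrepresentation(sig, total)}
        assert enr["A5SS"].skipped
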