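"""Acceptor-pair classification, spacing modes, PPT calling, strength model."""

import math

import numpy as np
import pytest

from crypticsplice.acceptor_features import (
    acceptor_window,
    build_frequency_matrix,
    call_ppt,
    classify_pair,
    compare_groups,
    spacing_mode_log2,
    train_acceptor_model,
)
from crypticsplice.event_caller import enumerate_events
from crypticsplice.genome_io import GeneModel, TranscriptModel
from crypticsplice.synthetic_data import (
    SyntheticConfig,
    generate_acceptor_windows,
    mirror_gene,
)


def _a3ss_gene(canonical=300, shift=-21, strand="+"):
    """Two-transcript gene whose second exon acceptor moves by ``shift``."""
    exons_can = [(100, 200), (canonical, 400)]
    exons_cry = [(100, 200), (canonical + shift, 400)]
    order = strand == "-"
    txs = (
        TranscriptModel("can", tuple(sorted(exons_can, reverse=order))),
        TranscriptModel("cry", tuple(sorted(exons_cry, reverse=order))),
    )
    return GeneModel("g", "chr1", strand, txs)


class TestClassifyPair:
    def test_upstream_21nt(self):
        event = enumerate_events([_a3ss_gene(shift=-21)])[0]
        pair = classify_pair(event)
        assert pair.orientation == "upstream"
        assert pair.spacing_nt == 21
        assert not pair.is_nagnag

    def test_downstream_40nt(self):
        event = enumerate_events([_a3ss_gene(shift=-40)])[0]
        pair = classify_pair(event, cryptic_isoform="short")
        assert pair.orientation == "downstream"
        assert pair.spacing_nt == 40

    def test_nagnag_requires_motif(self):
        gene = _a3ss_gene(shift=-3)
        event = enumerate_events([gene])[0]
        # sequence ...CAGCAG| upstream of the 3'-most acceptor
        genome = {"chr1": "T" * 294 + "CAGCAG" + "A" * 200}
        assert classify_pair(event, genome).is_nagnag
        genome_no = {"chr1": "T" * 294 + "CATCAG" + "A" * 200}
        assert not classify_pair(event, genome_no).is_nagnag

    def test_non_a3ss_rejected(self):
        gene = GeneModel(
            "g",
            "chr1",
            "+",
            (
                TranscriptModel("t1", ((100, 200), (300, 400))),
                TranscriptModel("t2", ((100, 400),)),
            ),
        )
        event = enumerate_events([gene])[0]
        with pytest.raises(TypeError):
            classify_pair(event)

    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize("shift", [-21, -3, -15])
    def test_orientation_agrees_with_coordinate_oracle_on_both_strands(
        self, strand, shift
    ):
        gene = _a3ss_gene(shift=shift, strand="+")
        genome = {"chr1": "ACGT" * 125}
        if strand == "-":
            gene, genome = mirror_gene(gene, genome)
        event = enumerate_events([gene])[0]
        pair = classify_pair(event)
        # oracle: upstream iff the cryptic boundary is 5' of the canonical in
        # transcript orientation
        if strand == "+":
            upstream = pair.cryptic_pos < pair.canonical_pos
        else:
            upstream = pair.cryptic_pos > pair.canonical_pos
        assert pair.orientation == ("upstream" if upstream else "downstream")
        assert pair.spacing_nt == abs(shift)


class TestSpacingMode:
    @pytest.mark.parametrize(
        "spacings,mode",
        [([15] * 30, 3.9), ([3] * 30, 1.6), ([4, 4, 8], 2.0)],
    )
    def test_log2_modes(self, spacings, mode):
        assert spacing_mode_log2(spacings).mode == pytest.approx(mode)

    def test_empty_class_missing_mode(self):
        sm = spacing_mode_log2([])
        assert sm.mode is None and sm.curve.empty

    def test_tie_breaks_to_smaller_value(self):
        sm = spacing_mode_log2([4] * 5 + [8] * 5)
        assert sm.mode == pytest.approx(2.0)

    def test_density_integrates_to_one(self):
        sm = spacing_mode_log2([15] * 20 + [12] * 10 + [30] * 10)
        assert (sm.curve["density"] * 0.1).sum() == pytest.approx(1.0)


def _window(upstream: str, exon: str = "ATGGCCGGTTAACCGGTTAA") -> tuple[str, int]:
    """Build a window string from the intronic part (3' end = offset -1)."""
    pad = "G" * (60 - len(upstream))
    intron = pad + upstream
    return intron + exon, len(intron)


class TestCallPpt:
    def test_uninterrupted_19nt_tract(self):
        # 19 pyrimidines at -21..-3, purines 5' of that
        seq, boundary = _window("AA" + "TCTTCCTTTCTTCCTTTCT" + "AG")
        ppt = call_ppt(seq, boundary)
        assert ppt.length_nt == 19
        assert ppt.interruptions == 0
        assert ppt.start_offset == -21 and ppt.end_offset == -2

    def test_a_run_terminates_scan(self):
        # 8 pyrimidines at -10..-3 preceded by AAAAA at -15..-11
        seq, boundary = _window("AAAAA" + "TTCCTTTC" + "AG")
        ppt = call_ppt(seq, boundary)
        assert ppt.length_nt == 8
        assert ppt.a_run is not None
        assert (ppt.a_run.length, ppt.a_run.offset) == (5, -15)

    def test_double_purine_breaks_after_five(self):
        seq, boundary = _window("TTTTTTGG" + "TTCTC" + "AG")
        assert call_ppt(seq, boundary).length_nt == 5

    def test_single_purine_interruption_tolerated(self):
        seq, boundary = _window("GG" + "TTTTT" + "A" + "TTTTT" + "AG")
        ppt = call_ppt(seq, boundary)
        assert ppt.length_nt == 11
        assert ppt.interruptions == 1
        assert ppt.pyrimidine_fraction == pytest.approx(10 / 11)

    def test_window_too_short_is_error(self):
        with pytest.raises(ValueError, match="-40"):
            call_ppt("T" * 30, 10)

    def test_n_in_window_gives_missing_call(self):
        seq, boundary = _window("GG" + "TTNTT" + "TTTTT" + "AG")
        assert call_ppt(seq, boundary) is None


@pytest.fixture(scope="module")
def model():
    windows = [
        acceptor_window(w.seq, w.boundary)
        for w in generate_acceptor_windows("canonical", 300, seed=42)
    ]
    return train_acceptor_model(windows)


class TestStrengthModel:

    def test_consensus_scores_maximum(self, model):
        assert model.score(model.consensus()) == pytest.approx(model.max_score())

    def test_background_matched_scores_match_closed_form_expectation(self, model):
        # i.i.d. draws from the model's background composition q score, in
        # expectation, exactly -sum_pos KL(q || f_pos) bits: the closed-form
        # oracle for the log-odds null (zero only for a structureless model)
        rng = np.random.default_rng(7)
        train = [
            acceptor_window(w.seq, w.boundary)
            for w in generate_acceptor_windows("canonical", 300, seed=42)
        ]
        counts = np.zeros(4)
        for w in train:
            for b in w:
                counts["ACGT".index(b)] += 1
        q_emp = (counts + 1) / (counts.sum() + 4)  # model's smoothed background
        expected = float((q_emp * model.log_odds).sum())
        scores = [
            model.score(
                "".join(rng.choice(list("ACGT"), p=q_emp / q_emp.sum(), size=model.window_length))
            )
            for _ in range(1000)
        ]
        assert expected < 0  # structured model: background scores negative
        assert float(np.mean(scores)) == pytest.approx(expected, abs=0.5)

    def test_window_with_n_gives_missing_score(self, model):
        w = "N" + model.consensus()[1:]
        assert model.score(w) is None

    def test_wrong_length_rejected(self, model):
        with pytest.raises(ValueError):
            model.score("ACGT")

    def test_too_few_training_windows_rejected(self):
        with pytest.raises(ValueError, match="100"):
            train_acceptor_model(["A" * 23] * 10)

    def test_cryptic_windows_score_lower_than_canonical(self, model):
        cryptic = [
            acceptor_window(w.seq, w.boundary)
            for w in generate_acceptor_windows("cryptic", 200, seed=43)
        ]
        canonical = [
            acceptor_window(w.seq, w.boundary)
            for w in generate_acceptor_windows("canonical", 200, seed=44)
        ]
        mean_cry = np.mean([model.score(w) for w in cryptic])
        mean_can = np.mean([model.score(w) for w in canonical])
        assert mean_cry < mean_can


class TestCompareGroups:
    def test_identical_multisets_p_one(self):
        r = compare_groups([1, 2, 3, 4], [4, 3, 2, 1])
        assert r.p_value == pytest.approx(1.0)

    def test_fully_separated_groups_minimal_p(self):
        r = compare_groups([1, 2, 3], [11, 12, 13])
        assert r.statistic == 0.0
        # minimal achievable p for the asymptotic method at n=3,3
        r_less = compare_groups([1, 2, 11], [3, 12, 13])
        assert r.p_value < 0.1
        assert r.p_value <= r_less.p_value

    def test_all_equal_constant_p_one(self):
        r = compare_groups([5, 5, 5], [5, 5, 5])
        assert r.p_value == pytest.approx(1.0)

    def test_small_groups_untestable(self):
        r = compare_groups([1, 2], [3, 4, 5])
        assert not r.testable


class TestFrequencyMatrix:
    def test_identical_windows(self):
        fm = build_frequency_matrix(["AC", "AC"], offsets=(-2, -1))
        assert fm.frequencies[0, 0] == 1.0  # A at position 1
        assert fm.counts.sum(axis=1).tolist() == [2, 2]

    def test_half_split_information_content(self):
        fm = build_frequency_matrix(["AC", "GT"], offsets=(-2, -1))
        assert np.allclose(fm.information_content(), [1.0, 1.0])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            build_frequency_matrix(["AC", "ACG"])

    def test_canonical_windows_are_pyrimidine_rich_upstream(self):
        windows = [
            acceptor_window(w.seq, w.boundary)
            for w in generate_acceptor_windows("canonical", 200, seed=5)
        ]
        fm = build_frequency_matrix(windows)
        offs = np.array(fm.offsets)
        sel = (offs >= -20) & (offs <= -5)
        pyr = fm.frequencies[:, 1] + fm.frequencies[:, 3]  # C + T
        assert pyr[sel].mean() > 0.7
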