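"""Degradome mapping, duplex scoring, cleavage candidates, categories 0-4."""

import itertools

import numpy as np
import pytest

from soymir.degradome import (TPlot, align_duplex, category_distribution,
                              classify_category, find_cleavage_candidates,
                              find_target_sites, map_degradome, score_duplex)
from soymir.io import revcomp

MIRNA = "TGACAGAAGAGAGTGAGCAC"  # 20 nt


def tplot_from(counts: dict[int, int], length=500, tid="t1") -> TPlot:
    tp = TPlot(tid, length)
    for p, c in counts.items():
        tp.add(p, c)
    return tp


class TestMapping:
    def test_single_read_maps_to_its_position(self):
        transcript = "A" * 99 + "GATTACAGATTACAGATTACA" + "C" * 80
        tplots, multi = map_degradome(["GATTACAGATTACAGATTACA"], {"t1": transcript})
        assert tplots["t1"].counts == {100: 1}
        assert multi == 0

    def test_multimapper_counted_everywhere_and_flagged(self):
        read = "GATTACAGATTACAGATTACA"
        t1 = "A" * 10 + read + "C" * 10
        t2 = "G" * 30 + read + "T" * 5
        tplots, multi = map_degradome([read], {"t1": t1, "t2": t2})
        assert tplots["t1"].counts == {11: 1}
        assert tplots["t2"].counts == {31: 1}
        assert multi == 1

    def test_empty_transcriptome_rejected(self):
        with pytest.raises(ValueError):
            map_degradome(["ACGT"], {})


class TestDuplexScore:
    def test_perfect_complement_scores_zero(self):
        aln = score_duplex(MIRNA, revcomp(MIRNA))
        assert aln.score == 0.0
        assert set(aln.states) == {"match"}

    def test_gu_wobble_in_core_scores_one(self):
        # miRNA position 5 is A; a G:U wobble needs G:T or T:G, so use a
        # miRNA with G at position 5 opposite T
        mir = "TGACGGAAGAGAGTGAGCAC"
        site = list(revcomp(mir))
        site[len(site) - 5] = "T"  # opposite miRNA position 5 (G) -> G:T wobble
        aln = score_duplex(mir, "".join(site))
        assert aln.score == pytest.approx(1.0)
        assert aln.states[4] == "wobble"

    def test_mismatch_outside_core_undoubled(self):
        site = list(revcomp(MIRNA))
        site[0] = {"A": "C", "C": "A", "G": "A", "T": "G"}[site[0]]  # miRNA pos 20
        aln = score_duplex(MIRNA, "".join(site))
        assert aln.score == pytest.approx(1.0)
        assert aln.states[19] == "mismatch"

    def test_mismatch_in_core_doubled(self):
        site = list(revcomp(MIRNA))
        p = 10
        idx = len(site) - p
        site[idx] = {"A": "C", "C": "A", "G": "A", "T": "G"}[site[idx]]
        aln = score_duplex(MIRNA, "".join(site))
        assert aln.score == pytest.approx(2.0)

    def test_gapped_alignment_penalised(self):
        window = revcomp(MIRNA)[1:]  # one target base missing
        aln = align_duplex(MIRNA, window, max_gaps=1)
        assert aln.states.count("gap") == 1
        assert 0 < aln.score <= 4.0

    def test_window_length_bound(self):
        with pytest.raises(ValueError):
            align_duplex(MIRNA, revcomp(MIRNA)[:-3], max_gaps=1)


class TestCleavageCandidates:
    def _site_alignment(self, start=101):
        return score_duplex(MIRNA, revcomp(MIRNA), target_start=start)

    def test_peak_opposite_position_ten(self):
        aln = self._site_alignment(101)
        c = aln.cleavage_position
        assert c == 101 + 20 - 10
        tp = tplot_from({c: 8})
        out = find_cleavage_candidates(tp, [aln])
        assert out == [(aln, c, 8)]

    def test_signal_five_nt_away_not_candidate(self):
        aln = self._site_alignment(101)
        tp = tplot_from({aln.cleavage_position + 5: 30})
        assert find_cleavage_candidates(tp, [aln]) == []

    def test_window_edge_included(self):
        aln = self._site_alignment(101)
        tp = tplot_from({aln.cleavage_position - 1: 2})
        out = find_cleavage_candidates(tp, [aln], window=1)
        assert out[0][1] == aln.cleavage_position - 1


class TestCategories:
    @pytest.mark.parametrize(
        "counts, position, expected",
        [
            ({100: 10, 200: 3, 300: 2}, 100, 0),
            ({100: 10, 200: 10}, 100, 1),
            ({100: 1, 200: 50}, 100, 4),
            ({100: 5, 200: 50, 300: 2, 400: 2}, 100, 2),  # 5 < 50, 5 > median 3.5
            ({100: 2, 200: 50, 300: 2, 400: 2}, 100, 3),  # 2 == median
        ],
    )
    def test_rule_examples(self, counts, position, expected):
        assert classify_category(tplot_from(counts), position) == expected

    def test_no_reads_at_position_is_no_call(self):
        with pytest.raises(ValueError):
            classify_category(tplot_from({100: 3}), 200)

    def test_median_over_all_positions_flag(self):
        tp = tplot_from({100: 3, 200: 50}, length=100_0)
        # occupied median is 26.5 -> category 3; over all positions median 0 -> 2
        assert classify_category(tp, 100) == 3
        assert classify_category(tp, 100, median_over_occupied=False) == 2

    @staticmethod
    def oracle(values, position_count, n_max, maximum, median):
        """Independent rule-by-rule restatement of the category definitions."""
        if position_count == 1:
            return 4
        if position_count == maximum and n_max == 1:
            return 0
        if position_count == maximum:
            return 1
        if position_count > median:
            return 2
        return 3

    def test_exhaustive_small_vectors_match_oracle(self):
        """All count vectors length ≤ 4, counts ≤ 4: one category each,
        mutually exclusive and exhaustive, equal to the rule oracle."""
        for length in range(1, 5):
            for vector in itertools.product(range(5), repeat=length):
                occupied = [v for v in vector if v >= 1]
                if not occupied:
                    continue
                tp = tplot_from({10 * (i + 1): v for i, v in enumerate(vector) if v},
                                length=100)
                maximum = max(occupied)
                median = float(np.median(occupied))
                for i, v in enumerate(vector):
                    if v < 1:
                        continue
                    got = classify_category(tp, 10 * (i + 1))
                    want = self.oracle(occupied, v, occupied.count(maximum),
                                       maximum, median)
                    assert got == want, (vector, i)
                    assert got in {0, 1, 2, 3, 4}

    def test_count_scaling_preserves_top_categories(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            vec = rng.integers(0, 6, size=5)
            if vec.max() == 0:
                continue
            for factor in (2, 3, 7):
                for i, v in enumerate(vec):
                    if v < 1:
                        continue
                    tp1 = tplot_from({10 * (j + 1): int(c) for j, c in enumerate(vec) if c})
                    tp2 = tplot_from({10 * (j + 1): int(c) * factor
                                      for j, c in enumerate(vec) if c})
                    c1 = classify_category(tp1, 10 * (i + 1))
                    c2 = classify_category(tp2, 10 * (i + 1))
                    if c1 in (0, 1):
                        assert c2 == c1
                    if c1 == 2:
                        assert c2 != 3
                    if c1 == 3:
                        assert c2 != 2


def test_site_scan_and_distribution():
    transcript = "T" * 50 + revcomp(MIRNA) + "G" * 50
    sites = find_target_sites(MIRNA, transcript)
    assert any(s.score == 0.0 and s.target_start == 51 for s in sites)
    from soymir.degradome import TargetCall
    calls = [TargetCall("m", "t", sites[0], 5, c) for c in (0, 0, 2, 4)]
    assert category_distribution(calls) == {0: 2, 1: 0, 2: 1, 3: 0, 4: 1}
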