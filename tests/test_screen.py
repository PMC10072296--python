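import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cck3r.screen import (
    hamming_similarity,
    screen_candidates,
    screen_report,
    similarity_score,
)
from cck3r.synth import FamilySpec, make_receptor_family
from cck3r.topology import ScreenConfig

from conftest import make_reference, make_segment_set


def brute_hamming(a: str, b: str) -> int:
    """Oracle: enumerate every ungapped offset of the shorter along the longer."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    best = 0
    for off in range(len(long_) - len(short) + 1):
        count = sum(
            1
            for i, ch in enumerate(short)
            if ch == long_[off + i] and ch != "X"
        )
        best = max(best, count)
    return best


class TestHammingSimilarity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("PEPTIDE", "PEPTIDE", 7),
            ("AAAA", "CCCC", 0),
            ("ACDEFG", "CDEF", 4),  # offsets give 0, 4, 0
            ("MKT", "MQT", 2),
            ("WWAA", "WW", 2),
            ("XX", "XX", 0),  # X never matches, even X vs X
            ("AXA", "AAA", 2),
        ],
    )
    def test_known_values(self, a, b, expected):
        assert hamming_similarity(a, b) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hamming_similarity("", "A")

    strings = st.text(alphabet="ACGT", min_size=1, max_size=8)

    @settings(max_examples=300, derandomize=True)
    @given(strings, strings)
    def test_matches_bruteforce_and_symmetric(self, a, b):
        value = hamming_similarity(a, b)
        assert value == brute_hamming(a, b)
        assert value == hamming_similarity(b, a)
        assert 0 <= value <= min(len(a), len(b))

    @settings(max_examples=200, derandomize=True)
    @given(strings, strings)
    def test_full_match_iff_substring(self, a, b):
        short, long_ = (a, b) if len(a) <= len(b) else (b, a)
        assert (hamming_similarity(a, b) == len(short)) == (short in long_)


class TestSimilarityScore:
    def test_identical_segments_score_total_length(self):
        ref = make_reference("CCK1R", NTERM="MKTAY", ECL1="WDE", ECL2="QQRS")
        cand = make_segment_set("c1", NTERM="MKTAY", ECL1="WDE", ECL2="QQRS")
        per, total = similarity_score(cand, ref)
        assert total == 12 == ref.total_length

    def test_disjoint_residues_score_zero(self):
        ref = make_reference("CCK1R", NTERM="AAAA", ECL1="CCC")
        cand = make_segment_set("c1", NTERM="WWWW", ECL1="YYY")
        _, total = similarity_score(cand, ref)
        assert total == 0

    def test_two_segment_toy(self):
        # NTERM MKT vs MQT -> 2; ECL1 WWAA vs WW -> 2
        ref = make_reference("CCK1R", NTERM="MQT", ECL1="WW")
        cand = make_segment_set("c1", NTERM="MKT", ECL1="WWAA")
        per, total = similarity_score(cand, ref)
        assert dict(per) == {"NTERM": 2, "ECL1": 2, "ECL2": 0, "ECL3": 0}
        assert total == 4

    def test_unmatched_roles_contribute_zero(self):
        ref = make_reference("CCK1R", NTERM="MKT")
        cand = make_segment_set("c1", ECL1="MKT")
        _, total = similarity_score(cand, ref)
        assert total == 0

    def test_per_segment_bounded_by_segment_lengths(self):
        ref = make_reference("CCK1R", NTERM="MKTWAY", ECL1="DD")
        cand = make_segment_set("c1", NTERM="MKT", ECL1="DDDDD")
        per, _ = similarity_score(cand, ref)
        counts = dict(per)
        assert counts["NTERM"] <= 3
        assert counts["ECL1"] <= 2


class TestScreenCandidates:
    def setup_method(self):
        self.ref1 = make_reference("CCK1R", NTERM="MKTAYW", ECL1="DERS")
        self.ref2 = make_reference("CCK2R", NTERM="MKWAYW", ECL1="DEQS")

    def test_self_copy_ranks_first_with_maximal_score(self):
        own = make_segment_set("self", NTERM="MKTAYW", ECL1="DERS")
        other = make_segment_set("other", NTERM="GGGGGG", ECL1="HHHH")
        results = screen_candidates([own, other], self.ref1, self.ref2)
        assert results[0].candidate_id == "self"
        assert results[0].score_vs_cck1r == self.ref1.total_length

    def test_empty_candidate_list(self):
        assert screen_candidates([], self.ref1, self.ref2) == []

    def test_duplicate_ids_rejected(self):
        c = make_segment_set("dup", NTERM="MKTAYW")
        with pytest.raises(ValueError):
            screen_candidates([c, c], self.ref1, self.ref2)

    def test_threshold_modes(self):
        cand = make_segment_set("c1", NTERM="MKTAYW", ECL1="DEQS")  # 10 vs ref1...
        cfg_each = ScreenConfig(similarity_threshold=9, threshold_mode="each")
        cfg_sum = ScreenConfig(similarity_threshold=19, threshold_mode="sum")
        r_each = screen_candidates([cand], self.ref1, self.ref2, cfg_each)[0]
        r_sum = screen_candidates([cand], self.ref1, self.ref2, cfg_sum)[0]
        assert r_each.passes_threshold == (
            r_each.score_vs_cck1r >= 9 and r_each.score_vs_cck2r >= 9
        )
        assert r_sum.passes_threshold == (r_sum.total >= 19)

    def test_scores_invariant_under_candidate_permutation(self, rng):
        cands = [
            make_segment_set(f"c{i}", NTERM="MKTAYW"[: 3 + i % 3], ECL1="DERS")
            for i in range(5)
        ]
        base = {
            r.candidate_id: (r.score_vs_cck1r, r.score_vs_cck2r)
            for r in screen_candidates(cands, self.ref1, self.ref2)
        }
        perm = [cands[i] for i in rng.permutation(5)]
        again = {
            r.candidate_id: (r.score_vs_cck1r, r.score_vs_cck2r)
            for r in screen_candidates(perm, self.ref1, self.ref2)
        }
        assert base == again
        # adding a candidate never changes others' scores
        extra = make_segment_set("extra", NTERM="MKTAYW")
        more = {
            r.candidate_id: (r.score_vs_cck1r, r.score_vs_cck2r)
            for r in screen_candidates(cands + [extra], self.ref1, self.ref2)
        }
        for cid, scores in base.items():
            assert more[cid] == scores

    def test_tie_break_is_lexicographic(self):
        a = make_segment_set("b_cand", NTERM="MKTAYW")
        b = make_segment_set("a_cand", NTERM="MKTAYW")
        results = screen_candidates([a, b], self.ref1, self.ref2)
        assert [r.candidate_id for r in results] == ["a_cand", "b_cand"]

    def test_report_columns(self):
        cand = make_segment_set("c1", NTERM="MKTAYW")
        report = screen_report(screen_candidates([cand], self.ref1, self.ref2))
        assert list(report.columns) == [
            "candidate_id",
            "score_cck1r",
            "score_cck2r",
            "total",
            "passes",
        ]


def test_mean_score_nonincreasing_in_divergence():
    """Screen scores fall as generated extracellular divergence rises."""
    from cck3r.screen import extract_extracellular_segments
    from cck3r.topology import predict_topology

    mean_scores = []
    for div in (0.05, 0.5):
        totals = []
        for seed in range(20):
            fam = make_receptor_family(
                FamilySpec(n_candidates=5, loop_divergence=div, seed=seed)
            )
            segs = [
                extract_extracellular_segments(predict_topology(c), c)
                for c in fam.candidates
            ]
            results = screen_candidates(segs, fam.reference_cck1r, fam.reference_cck2r)
            totals.extend(r.total for r in results)
        mean_scores.append(np.mean(totals))
    assert mean_scores[0] > mean_scores[1]
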