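"""Tandem-repeat masking, hit merging, density statistic, quadrant calls."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crmscan.density import (
    CRMCandidate,
    ClassifierConfig,
    DensityProfile,
    RepeatInterval,
    RepeatMask,
    classify,
    detect_tandem_repeats,
    merge_hits,
    tfbs_density,
)
from crmscan.motifs import DnaSequence, MotifHit
from crmscan.simulate import make_profile, plant_sequence, random_background


def _hit(start, end=None, raw=15.0):
    return MotifHit(
        motif_id="M",
        tf_name="T",
        seq_id="s",
        start=start,
        end=end if end is not None else start + 8,
        strand="+",
        raw_score=raw,
        relative_score=0.9,
    )


def brute_repeat_positions(s, max_unit=6, min_copies=3, min_total_len=12):
    """Independent oracle: union of all intervals [a, b) where some unit
    u <= max_unit satisfies s[k] == s[k-u] throughout, with >= min_copies
    full copies and span >= min_total_len."""
    n = len(s)
    masked = set()
    for u in range(1, max_unit + 1):
        for a in range(n):
            b = a + u
            while b < n and s[b] == s[b - u]:
                b += 1
            span = b - a
            if span // u >= min_copies and span >= min_total_len:
                masked.update(range(a, b))
    return masked


class TestTandemRepeats:
    def test_ac_microsatellite_embedded(self):
        # flanks chosen so the period-2 run cannot extend into them
        s = "GTTCGATCGG" + "ACACACACACACAC" + "GTCTGGATTCGATGACCTGTTGCCTT"
        mask = detect_tandem_repeats(DnaSequence("x", s))
        assert [(iv.start, iv.end, iv.unit_length) for iv in mask.intervals] == [
            (10, 24, 2)
        ]
        assert mask.intervals[0].copies == 7

    def test_hexamer_repeat(self):
        mask = detect_tandem_repeats(DnaSequence("x", "CTCCCT" * 3))
        assert len(mask.intervals) == 1
        iv = mask.intervals[0]
        assert (iv.start, iv.end) == (0, 18)
        assert iv.unit_length <= 6

    def test_complex_sequence_has_empty_mask(self):
        rng = np.random.default_rng(123)
        s = random_background(50, 0.5, rng)
        # verify against the independent oracle rather than trusting the draw
        assert brute_repeat_positions(s) == set()
        assert detect_tandem_repeats(DnaSequence("x", s)).intervals == ()

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=12, max_size=60))
    def test_masked_positions_match_oracle(self, s):
        mask = detect_tandem_repeats(DnaSequence("h", s))
        got = set()
        for iv in mask.intervals:
            got.update(range(iv.start, iv.end))
        assert got == brute_repeat_positions(s)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            detect_tandem_repeats(DnaSequence("x", "ACGT"), max_unit=11)


class TestMergeHits:
    def test_within_window_is_one_count(self):
        assert merge_hits([_hit(0), _hit(5)], 5) == 1

    def test_anchor_based_chaining(self):
        # 103 joins anchor 100; 110 is 10 bp from the anchor -> new cluster
        assert merge_hits([_hit(100), _hit(103), _hit(110)], 5) == 2

    def test_neighbor_chaining_differs(self):
        # neighbor-based: 105 joins 100, 109 joins 105 -> a single chain
        hits = [_hit(100), _hit(105), _hit(109)]
        assert merge_hits(hits, 5, chaining="anchor") == 2
        assert merge_hits(hits, 5, chaining="neighbor") == 1

    def test_empty(self):
        assert merge_hits([], 5) == 0

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            merge_hits([_hit(0)], -1)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 200), min_size=0, max_size=20))
    def test_greedy_oracle_and_order_invariance(self, starts):
        hits = [_hit(s) for s in starts]
        # independent left-to-right re-simulation on sorted starts
        expected = 0
        anchor = None
        for s in sorted(starts):
            if anchor is None or s - anchor > 5:
                expected += 1
                anchor = s
        assert merge_hits(hits, 5) == expected
        rng = np.random.default_rng(0)
        shuffled = list(hits)
        rng.shuffle(shuffled)
        assert merge_hits(shuffled, 5) == expected


class TestTfbsDensity:
    def test_stated_formula_arithmetic(self):
        # merged counts 6 and 4 on a 300-bp CRM -> 2.0 and 1.333 per 100 bp
        assert 6 / 300 * 100 == pytest.approx(2.0)
        dp = DensityProfile("c", 300, 6, 4, 6 / 300 * 100, 4 / 300 * 100, "A2", True)
        assert dp.density_high == pytest.approx(1.3333, abs=1e-4)

    def test_planted_sites_give_exact_density(self):
        profile = make_profile("TGACGTCATT", sharpness=1.0)
        sites = [(profile, 30 + 50 * k, "+") for k in range(9)]
        seq, _ = plant_sequence(500, sites, seed=42, seq_id="crm")
        crm = CRMCandidate("crm", seq)
        dp = tfbs_density(crm, [profile])
        assert dp.count_high == 9
        assert dp.density_high == pytest.approx(1.8)
        assert dp.count_low >= dp.count_high

    def test_repeat_masked_hits_are_skipped(self):
        profile = make_profile("ACACACAC", sharpness=1.0)
        # an (AC)9 repeat carries every consensus window; all lie inside the mask
        s = "GTTCGATCGG" + "AC" * 9 + "GTCTGGATTCGATGACCTGTTGCCTTAGGATCGT"
        seq = DnaSequence("rep", s)
        crm = CRMCandidate("rep", seq)
        mask = detect_tandem_repeats(seq)
        assert mask.intervals  # the repeat is detected
        with_mask = tfbs_density(crm, [profile], mask=mask)
        without = tfbs_density(crm, [profile], mask=None)
        assert without.count_low > 0
        assert with_mask.count_low == 0 and with_mask.count_high == 0
        assert with_mask.density_low == 0.0
        # full length stays in the denominator
        assert with_mask.length_bp == len(s)

    def test_count_subset_monotonicity_random(self):
        profile = make_profile("TGACGTCA", sharpness=0.8)
        rng = np.random.default_rng(9)
        for k in range(10):
            seq = DnaSequence(f"r{k}", random_background(400, 0.5, rng))
            dp = tfbs_density(CRMCandidate(seq.id, seq), [profile])
            assert dp.count_high <= dp.count_low

    def test_duplication_leaves_density_nearly_unchanged(self):
        profile = make_profile("TGACGTCATT", sharpness=1.0)
        sites = [(profile, 30 + 50 * k, "+") for k in range(9)]
        seq, _ = plant_sequence(500, sites, seed=42, seq_id="crm")
        doubled = DnaSequence("crm2", seq.bases * 2)
        d1 = tfbs_density(CRMCandidate("crm", seq), [profile])
        d2 = tfbs_density(CRMCandidate("crm2", doubled), [profile])
        # at most one extra junction-spanning count: 1 count boundary effect
        assert abs(d2.density_high - d1.density_high) <= 100.0 / len(doubled)

    def test_zero_length_rejected(self):
        empty = CRMCandidate("z", DnaSequence("z", ""))
        with pytest.raises(ValueError):
            tfbs_density(empty, [make_profile("ACGT")])


class TestClassify:
    CFG = ClassifierConfig()

    def _dp(self, dlow, dhigh):
        return DensityProfile("c", 100, 0, 0, dlow, dhigh, "A4", False)

    def test_above_both_cuts_is_a2_active(self):
        out = classify(self._dp(2.0, 1.2), self.CFG)
        assert out.quadrant == "A2" and out.predicted_active

    def test_below_both_cuts_inactive(self):
        out = classify(self._dp(1.0, 0.5), self.CFG)
        assert out.quadrant != "A2" and not out.predicted_active

    def test_on_cut_line_is_not_above(self):
        out = classify(self._dp(1.8, 1.0), self.CFG)  # y exactly at the cut
        assert out.quadrant != "A2" and not out.predicted_active

    def test_or_rule(self):
        cfg = ClassifierConfig(combine_rule="OR")
        out = classify(self._dp(1.8, 0.2), cfg)
        assert out.predicted_active and out.quadrant == "A3"

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ClassifierConfig(thr_low=12, thr_high=11)
        with pytest.raises(ValueError):
            ClassifierConfig(combine_rule="XOR")


class TestClassifierSeparation:
    def test_planted_vs_decoy_candidates(self):
        """Candidates planted well above both cuts are all called active;
        motif-free decoys of the same length and GC are all inactive, and
        their background hit density is measured, not assumed zero."""
        cfg = ClassifierConfig()
        panel = [
            make_profile(c, sharpness=1.0, motif_id=f"P{i}")
            for i, c in enumerate(("TAATTAGCGC", "CCATTGTTCT", "TTGGCAAGGA"))
        ]
        active_calls, decoy_calls, decoy_density = [], [], []
        for k in range(10):
            sites = [
                (panel[j % 3], 20 + 20 * j, "+" if j % 2 else "-") for j in range(12)
            ]
            seq, _ = plant_sequence(300, sites, seed=100 + k, seq_id=f"hot{k}")
            dp = tfbs_density(CRMCandidate(seq.id, seq), panel, cfg)
            assert dp.density_low >= 2 * cfg.density_x_cut
            assert dp.density_high >= 2 * cfg.density_y_cut
            active_calls.append(dp.predicted_active)
            decoy = DnaSequence(
                f"cold{k}", random_background(300, 0.5, np.random.default_rng(200 + k))
            )
            ddp = tfbs_density(CRMCandidate(decoy.id, decoy), panel, cfg)
            decoy_calls.append(ddp.predicted_active)
            decoy_density.append(ddp.density_low)
        assert all(active_calls)
        assert not any(decoy_calls)
        assert max(decoy_density) < cfg.density_x_cut
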