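"""Unit, oracle and property tests for the evaluation statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from placloop.errors import UndefinedScoreError
from placloop.evaluation import (
    MotifAnnotation,
    SpriteMatrix,
    classify_motif_orientation,
    coarsen_pair,
    cre_enrichment,
    motif_orientation_proportions,
    pair_overlap,
    reproducibility,
    sensitivity,
    sprite_rank,
)
from placloop.grid import BinGrid


def loops(rows):
    return pd.DataFrame(rows, columns=["chrom", "start1", "start2"])


class TestOverlap:
    def test_identical_pair_overlaps(self):
        assert pair_overlap(("c", 50_000, 150_000),
                            loops([("c", 50_000, 150_000)]))

    def test_gap_boundary_inclusive(self):
        ref = loops([("c", 50_000, 150_000)])
        assert pair_overlap(("c", 65_000, 165_000), ref)        # both at 15 kb
        assert not pair_overlap(("c", 65_000, 170_000), ref)    # right at 20 kb
        assert not pair_overlap(("c", 70_000, 150_000), ref)    # left at 20 kb

    def test_chromosome_must_match(self):
        assert not pair_overlap(("d", 50_000, 150_000),
                                loops([("c", 50_000, 150_000)]))

    def test_anchors_not_crossed(self):
        # query left anchor near reference right anchor only
        assert not pair_overlap(("c", 150_000, 250_000),
                                loops([("c", 50_000, 150_000)]))

    @settings(max_examples=40, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        ref = loops([
            ("c", int(a) * 1_000, int(a + g) * 1_000)
            for a, g in zip(rng.integers(0, 300, 25), rng.integers(5, 80, 25))
        ])
        for _ in range(20):
            s1 = int(rng.integers(0, 300)) * 1_000
            s2 = s1 + int(rng.integers(5, 80)) * 1_000
            brute = any(
                abs(s1 - r.start1) <= 15_000 and abs(s2 - r.start2) <= 15_000
                for r in ref.itertuples()
            )
            assert pair_overlap(("c", s1, s2), ref) == brute


class TestReproducibilityAndSensitivity:
    def test_identical_sets(self):
        a = loops([("c", 10_000, 60_000), ("c", 100_000, 200_000)])
        assert reproducibility(a, a) == (1.0, 1.0)

    def test_disjoint_sets(self):
        a = loops([("c", 10_000, 500_000)])
        b = loops([("c", 200_000, 900_000)])
        assert reproducibility(a, b) == (0.0, 0.0)

    def test_directional_fractions(self):
        a = loops([("c", k * 100_000, k * 100_000 + 50_000) for k in range(10)])
        b = pd.concat([a.iloc[:7], loops([("c", 5_000_000, 6_000_000)] * 3)],
                      ignore_index=True)
        fa, fb = reproducibility(a, b)
        assert fa == pytest.approx(0.7)
        assert fb == pytest.approx(0.7)

    def test_empty_query_is_nan(self):
        a = loops([("c", 10_000, 60_000)])
        fa, fb = reproducibility(a.iloc[:0], a)
        assert np.isnan(fa) and fb == 0.0

    def test_sensitivity_values(self):
        ref = loops([("c", k * 100_000, k * 100_000 + 50_000) for k in range(10)])
        shifted = ref.copy()
        shifted.loc[5:, ["start1", "start2"]] += 30_000  # beyond the 15 kb slack
        assert sensitivity(ref, ref) == 1.0
        assert sensitivity(shifted, ref) == pytest.approx(0.5)
        assert sensitivity(ref.iloc[:0], ref) == 0.0
        with pytest.raises(UndefinedScoreError):
            sensitivity(ref, ref.iloc[:0])


class TestMotifOrientation:
    @pytest.fixture()
    def annot(self):
        grid = BinGrid({"c": 100_000}, 5_000)
        motifs = pd.DataFrame(
            {
                "chrom": ["c", "c", "c", "c", "c"],
                "start": [1_000, 11_000, 21_000, 31_000, 32_000],
                "end": [1_019, 11_019, 21_019, 31_019, 32_019],
                "strand": ["+", "-", "+", "+", "-"],
            }
        )
        # bins: 0 '+', 2 '-', 4 '+', 6 mixed
        return MotifAnnotation.from_motifs(motifs, grid)

    def test_bin_orientations(self, annot):
        assert annot.bin_orientation("c", 0) == "+"
        assert annot.bin_orientation("c", 2) == "-"
        assert annot.bin_orientation("c", 6) == "mixed"
        assert annot.bin_orientation("c", 3) == "none"

    def test_four_orientation_classes(self, annot):
        assert classify_motif_orientation(("c", 0, 2), annot) == "convergent"
        assert classify_motif_orientation(("c", 2, 4), annot) == "divergent"
        assert classify_motif_orientation(("c", 0, 4), annot) == "tandem"
        assert classify_motif_orientation(("c", 0, 6), annot) == "untestable"
        assert classify_motif_orientation(("c", 0, 3), annot) == "untestable"

    def test_proportions(self, annot):
        pairs = pd.DataFrame(
            {"chrom": "c", "bin1": [0, 2, 0, 0], "bin2": [2, 4, 4, 6]}
        )
        props = motif_orientation_proportions(pairs, annot)
        assert props == {"convergent": pytest.approx(1 / 3),
                         "tandem": pytest.approx(1 / 3),
                         "divergent": pytest.approx(1 / 3)}

    def test_no_testable_pairs_raises(self, annot):
        pairs = pd.DataFrame({"chrom": "c", "bin1": [0], "bin2": [6]})
        with pytest.raises(UndefinedScoreError):
            motif_orientation_proportions(pairs, annot)

    def test_null_orientation_enumeration_is_one_quarter_convergent(self):
        # over all equally likely single-motif orientation pairs the
        # convergent fraction is exactly 25%
        grid = BinGrid({"c": 20_000}, 5_000)
        counts = {"convergent": 0, "tandem": 0, "divergent": 0}
        for left in "+-":
            for right in "+-":
                motifs = pd.DataFrame(
                    {"chrom": ["c", "c"], "start": [1_000, 11_000],
                     "end": [1_019, 11_019], "strand": [left, right]}
                )
                annot = MotifAnnotation.from_motifs(motifs, grid)
                counts[classify_motif_orientation(("c", 0, 2), annot)] += 1
        assert counts == {"convergent": 1, "divergent": 1, "tandem": 2}


class TestCreEnrichment:
    def make_inputs(self, target_bins, control_feature_bins=(), n=None):
        grid = BinGrid({"c": 500_000}, 5_000)
        protein = pd.DataFrame(
            {"chrom": "c", "start": [50_000 + 1_000], "end": [50_000 + 2_000]}
        )  # protein peak in bin 10
        rows = []
        for t in target_bins:
            lo, hi = sorted((10, t))
            rows.append(("c", lo, hi))
        xor_calls = pd.DataFrame(rows, columns=["chrom", "bin1", "bin2"])
        feature_bins = set(control_feature_bins)
        feats = pd.DataFrame(
            [("c", b * 5_000 + 100, b * 5_000 + 200) for b in feature_bins]
            or [("c", 490_001, 490_002)],
            columns=["chrom", "start", "end"],
        )
        return xor_calls, protein, feats, grid

    def test_score_is_target_over_control_ratio(self):
        # targets at bins 20 and 30 (controls 0 and -10: only 0 usable)
        xor_calls, protein, _, grid = self.make_inputs([20, 30])
        feats = pd.DataFrame(
            [("c", 20 * 5_000 + 10, 20 * 5_000 + 20)],
            columns=["chrom", "start", "end"],
        )
        pct_t, pct_c, score = cre_enrichment(xor_calls, xor_calls, protein,
                                             feats, grid)
        assert pct_t == pytest.approx(0.5)   # 1 of 2 targets on a feature
        assert pct_c == 0.0
        assert score == np.inf

    def test_controls_mirror_targets(self):
        # target bin 14 -> control 6; feature on 6 only
        xor_calls, protein, _, grid = self.make_inputs([14])
        feats = pd.DataFrame([("c", 6 * 5_000 + 10, 6 * 5_000 + 20)],
                             columns=["chrom", "start", "end"])
        pct_t, pct_c, score = cre_enrichment(xor_calls, xor_calls, protein,
                                             feats, grid)
        assert (pct_t, pct_c) == (0.0, 1.0)
        assert score == 0.0

    def test_off_chromosome_and_protein_bound_controls_dropped(self):
        grid = BinGrid({"c": 500_000}, 5_000)
        protein = pd.DataFrame(
            {"chrom": ["c", "c"], "start": [51_000, 1_000], "end": [52_000, 2_000]}
        )  # protein peaks in bins 10 and 0
        # target 30 -> control -10 (off); target 20 -> control 0 (protein-bound)
        # target 14 -> control 6 (usable)
        xor_calls = pd.DataFrame(
            [("c", 10, 30), ("c", 10, 20), ("c", 10, 14)],
            columns=["chrom", "bin1", "bin2"],
        )
        feats = pd.DataFrame([("c", 490_001, 490_002)],
                             columns=["chrom", "start", "end"])
        _, pct_c, _ = cre_enrichment(xor_calls, xor_calls, protein, feats, grid)
        assert pct_c == 0.0  # exactly the one usable control, without a feature

    def test_no_usable_controls_raises(self):
        xor_calls, protein, feats, grid = self.make_inputs([30])  # control -10
        with pytest.raises(UndefinedScoreError):
            cre_enrichment(xor_calls, xor_calls, protein, feats, grid)

    def test_no_xor_calls_raises(self):
        xor_calls, protein, feats, grid = self.make_inputs([14])
        with pytest.raises(UndefinedScoreError):
            cre_enrichment(xor_calls.iloc[:0], xor_calls, protein, feats, grid)

    def test_non_xor_pair_rejected(self):
        xor_calls, protein, feats, grid = self.make_inputs([14])
        bad = pd.DataFrame([("c", 30, 40)], columns=["chrom", "bin1", "bin2"])
        with pytest.raises(ValueError):
            cre_enrichment(bad, bad, protein, feats, grid)

    def test_exclude_interacting_controls(self):
        # the (anchor, control) pair coincides with an identified interaction
        xor_calls, protein, _, grid = self.make_inputs([14])
        feats = pd.DataFrame([("c", 6 * 5_000 + 10, 6 * 5_000 + 20)],
                             columns=["chrom", "start", "end"])
        all_calls = pd.DataFrame([("c", 6, 10), ("c", 10, 14)],
                                 columns=["chrom", "bin1", "bin2"])
        with pytest.raises(UndefinedScoreError):
            cre_enrichment(xor_calls, all_calls, protein, feats, grid,
                           exclude_interacting_controls=True)

    def test_random_features_score_near_one(self):
        # with features scattered uniformly, target and control rates agree
        rng = np.random.default_rng(0)
        grid = BinGrid({"c": 5_000_000}, 5_000)
        protein = pd.DataFrame({"chrom": "c", "start": [2_500_100],
                                "end": [2_500_200]})  # anchor bin 500
        offsets = rng.choice(np.r_[np.arange(-80, -1), np.arange(2, 81)], 300)
        xor_calls = pd.DataFrame(
            [("c", *sorted((500, 500 + int(o)))) for o in offsets],
            columns=["chrom", "bin1", "bin2"],
        )
        feature_bins = rng.choice(1_000, 500, replace=False)
        feats = pd.DataFrame(
            [("c", int(b) * 5_000 + 1, int(b) * 5_000 + 2) for b in feature_bins],
            columns=["chrom", "start", "end"],
        )
        _, _, score = cre_enrichment(xor_calls, xor_calls, protein, feats, grid)
        assert 0.8 <= score <= 1.25


class TestSprite:
    def make_sprite(self, values, flags):
        n = len(values)
        mat = np.zeros((n, n))
        d = 2
        for m, v in enumerate(values[: n - d]):
            mat[m, m + d] = v
        return SpriteMatrix({"c": mat}, {"c": np.asarray(flags, dtype=bool)},
                            resolution=25_000), d

    def test_rank_counts_strictly_larger_flagged_pairs(self):
        sprite, d = self.make_sprite([5.0, 3.0, 1.0, 4.0, 0.0, 0.0],
                                     [True] * 6)
        assert sprite_rank(("c", 1, 1 + d), sprite) == 2   # 5 and 4 beat 3
        assert sprite_rank(("c", 0, 0 + d), sprite) == 0   # top of its distance

    def test_ties_do_not_count(self):
        sprite, d = self.make_sprite([3.0, 3.0, 3.0, 0, 0, 0], [True] * 6)
        assert sprite_rank(("c", 0, d), sprite) == 0

    def test_unflagged_pairs_ignored(self):
        flags = [False, False, True, True, False, False]
        # pair (0, 2): flags[0] | flags[2] -> anchored; (1, 3), (2, 4) anchored
        sprite, d = self.make_sprite([9.0, 7.0, 1.0, 0, 0, 0], flags)
        # query (2, 4) value 1: larger values 9 (pair 0: anchored via bin 2)
        # and 7 (pair 1: anchored via bin 3)
        assert sprite_rank(("c", 2, 2 + d), sprite) == 2
        sprite2, _ = self.make_sprite([9.0, 7.0, 1.0, 0, 0, 0],
                                      [False, False, False, False, True, False])
        # only pair (2, 4) is anchored now
        assert sprite_rank(("c", 2, 2 + d), sprite2) == 0

    def test_out_of_range_query_rejected(self):
        sprite, d = self.make_sprite([1.0, 0, 0, 0, 0, 0], [True] * 6)
        with pytest.raises(ValueError):
            sprite_rank(("c", 4, 9), sprite)

    @settings(max_examples=40, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        mat = np.triu(rng.random((n, n)), 1)
        flags = rng.random(n) < 0.4
        sprite = SpriteMatrix({"c": mat}, {"c": flags}, resolution=25_000)
        i = int(rng.integers(0, n - 2))
        j = int(rng.integers(i + 1, n))
        d = j - i
        oracle = sum(
            1
            for m in range(n - d)
            if (flags[m] or flags[m + d]) and mat[m, m + d] > mat[i, j]
        )
        assert sprite_rank(("c", i, j), sprite) == oracle

    def test_from_triplets(self):
        trip = pd.DataFrame(
            {"chrom": ["c", "c"], "bin1": [3, 0], "bin2": [1, 2],
             "value": [2.5, 7.0]}
        )
        sprite = SpriteMatrix.from_triplets(trip, {"c": 5}, {"c": {1}}, 25_000)
        assert sprite.value("c", 1, 3) == 2.5
        assert sprite.value("c", 3, 1) == 2.5
        assert sprite.peak_flags["c"].tolist() == [False, True, False, False, False]


class TestCoarsen:
    def test_center_mapping(self):
        # fine bin 10 at 5 kb: center 52,500 -> coarse bin 2 at 25 kb
        assert coarsen_pair(("c", 10, 20), 5_000, 25_000) == ("c", 2, 4)

    def test_boundary_uses_half_open_floor(self):
        # fine bin 9: center 47,500 -> coarse bin 1; fine bin 5: center 27,500
        assert coarsen_pair(("c", 5, 9), 5_000, 25_000) == ("c", 1, 1)

    def test_identity_when_resolutions_match(self):
        assert coarsen_pair(("c", 7, 11), 5_000, 5_000) == ("c", 7, 11)
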