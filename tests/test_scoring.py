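"""Scoring engine: shift-tolerant matching, confusion counts, aggregation,
coordinate recovery, ANOVA."""

import itertools

import numpy as np
import pytest
from scipy import stats

from rnamotifbench.benchmark import BenchmarkRecord
from rnamotifbench.core import BasePair, RnaSequence, SecondaryStructure, parse_dbn
from rnamotifbench.scoring import (
    CoordinateResolutionError,
    MotifPrediction,
    aggregate,
    anova_oneway,
    is_shift_match,
    metrics_from_counts,
    read_predictions,
    resolve_coordinates,
    score_pairs,
    score_record,
    select_best,
    write_predictions,
)

from conftest import random_pair_set


class TestShiftMatch:
    @pytest.mark.parametrize(
        "p, r, expected",
        [
            ((2, 10), (1, 10), True),   # i shifted by one
            ((1, 10), (1, 10), True),   # identical
            ((1, 9), (1, 10), True),    # j shifted by one
            ((2, 9), (1, 10), False),   # both sides shifted
            ((3, 10), (1, 10), False),  # shift of two
        ],
    )
    def test_rule(self, p, r, expected):
        assert is_shift_match(BasePair(*p), BasePair(*r)) is expected

    def test_symmetric(self, rng):
        for _ in range(100):
            i, j = sorted(rng.integers(1, 30, size=2))
            k, l = sorted(rng.integers(1, 30, size=2))
            if i == j or k == l:
                continue
            p, r = BasePair(int(i), int(j)), BasePair(int(k), int(l))
            assert is_shift_match(p, r) == is_shift_match(r, p)


def brute_force_matching(pred, ref):
    """Exhaustive maximum one-to-one matching size (oracle)."""
    best = 0
    pred = list(pred)
    ref = list(ref)

    def grow(idx, used, size):
        nonlocal best
        best = max(best, size)
        if idx == len(pred):
            return
        grow(idx + 1, used, size)
        for rj in range(len(ref)):
            if rj not in used and is_shift_match(pred[idx], ref[rj]):
                grow(idx + 1, used | {rj}, size + 1)

    grow(0, frozenset(), 0)
    return best


class TestScorePairs:
    def test_identical_sets(self):
        pairs = {BasePair(1, 10), BasePair(2, 9)}
        c = score_pairs(pairs, pairs, 10)
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 0, 0, 43)

    def test_single_shift_is_tp(self):
        c = score_pairs({BasePair(2, 10)}, {BasePair(1, 10)}, 10)
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)

    def test_empty_prediction_all_fn(self):
        ref = {BasePair(1, 10), BasePair(2, 9), BasePair(3, 8)}
        c = score_pairs(set(), ref, 10)
        assert (c.tp, c.fp, c.fn) == (0, 0, 3)
        m = metrics_from_counts("x", "f", c)
        assert m.sn == 0.0 and m.ppv is None

    def test_pair_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            score_pairs({BasePair(1, 11)}, set(), 10)

    def test_one_to_one_equals_bruteforce_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(6, 20))
            pred = random_pair_set(rng, n, int(rng.integers(0, 9)))
            ref = random_pair_set(rng, n, int(rng.integers(0, 9)))
            c = score_pairs(pred, ref, n, mode="one-to-one")
            expected_tp = brute_force_matching(pred, ref)
            assert c.tp == expected_tp
            assert c.fp == len(pred) - expected_tp
            assert c.fn == len(ref) - expected_tp

    def test_per_pair_tp_at_least_one_to_one_tp(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 20))
            pred = random_pair_set(rng, n, int(rng.integers(0, 8)))
            ref = random_pair_set(rng, n, int(rng.integers(0, 8)))
            per_pair = score_pairs(pred, ref, n).tp
            one_one = score_pairs(pred, ref, n, mode="one-to-one").tp
            assert per_pair >= one_one

    def test_translation_invariance(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 25))
            pred = random_pair_set(rng, n, 4)
            ref = random_pair_set(rng, n, 4)
            off = int(rng.integers(1, 10))
            shift = lambda ps: {p.shifted(off, off) for p in ps}
            a = score_pairs(pred, ref, n + off)
            b = score_pairs(shift(pred), shift(ref), n + off)
            assert (a.tp, a.fp, a.fn) == (b.tp, b.fp, b.fn)


def _record(full="AAGGCAUU", start=3, end=6, dbn="(..)"):
    return BenchmarkRecord(
        identifier="rec1",
        sequence=RnaSequence("rec1", full),
        motif_start=start,
        motif_end=end,
        structure=parse_dbn(dbn),
        source_row="row1",
        family="fam",
    )


class TestResolveCoordinates:
    def test_substring_located(self):
        rec = _record()
        pred = MotifPrediction(
            "rec1", 1, 5.0, motif_text="GGCA",
            pairs=frozenset({BasePair(1, 4)}),
        )
        got = resolve_coordinates(pred, rec)
        assert (got.start, got.end) == (3, 6)
        assert got.pairs == frozenset({BasePair(3, 6)})

    def test_coordinates_present_is_identity(self):
        pred = MotifPrediction("rec1", 1, 5.0, start=3, end=6)
        assert resolve_coordinates(pred, _record()) is pred

    def test_ambiguous_occurrences_listed(self):
        rec = _record(full="GGAGG", start=1, end=2, dbn="..")
        pred = MotifPrediction("rec1", 1, 1.0, motif_text="GG")
        with pytest.raises(CoordinateResolutionError) as exc:
            resolve_coordinates(pred, rec)
        assert exc.value.positions == (1, 4)
        first = resolve_coordinates(pred, rec, take_first=True)
        assert first.start == 1

    def test_absent_everywhere_is_error(self):
        pred = MotifPrediction("rec1", 1, 1.0, motif_text="CCCCCC")
        with pytest.raises(CoordinateResolutionError, match="not found"):
            resolve_coordinates(pred, _record())


class TestSelectBest:
    def _preds(self, scores):
        return [
            MotifPrediction("r", rank, s, start=1, end=4)
            for rank, s in enumerate(scores, start=1)
        ]

    def test_max_score_wins(self):
        assert select_best(self._preds([3, 7, 5])).score == 7

    def test_single_is_itself(self):
        assert select_best(self._preds([2])).score == 2

    def test_tie_goes_to_lowest_rank(self):
        assert select_best(self._preds([7, 7])).rank == 1

    def test_lower_is_better_direction(self):
        assert select_best(self._preds([3, 7, 5]), higher_is_better=False).score == 3

    def test_limit_caps_candidate_pool(self):
        preds = self._preds([0] * 10 + [99])  # rank 11 ignored
        assert select_best(preds, limit=10).score == 0

    def test_empty_returns_none(self):
        assert select_best([]) is None


class TestScoreRecord:
    def test_truth_fed_back_scores_perfectly(self):
        rec = _record()
        pred = MotifPrediction(
            "rec1", 1, 1.0, start=3, end=6,
            pairs=rec.absolute_truth_pairs(),
        )
        m = score_record(rec, [pred])
        assert m.sn == m.ppv == m.sp == 1.0

    def test_no_predictions_counts_all_fn(self):
        m = score_record(_record(), [])
        assert m.sn == 0.0
        assert m.counts.fn == 1


class TestAggregate:
    def _metric(self, rid, fam, sn):
        from rnamotifbench.scoring import ConfusionCounts, RecordMetrics

        return RecordMetrics(
            rid, fam, ConfusionCounts(1, 0, 0, 1), sn, sn, sn
        )

    def test_identical_values_average_to_themselves(self):
        rep = aggregate([self._metric("a", "f", 0.8), self._metric("b", "f", 0.8)])
        assert rep.overall["sn"] == pytest.approx(0.8)

    def test_within_family_mean(self):
        rep = aggregate([self._metric("a", "f", 0.0), self._metric("b", "f", 1.0)])
        assert rep.family_means["f"]["sn"] == pytest.approx(0.5)

    def test_overall_is_family_weighted(self):
        rep = aggregate(
            [
                self._metric("a", "f1", 0.2),
                self._metric("b", "f1", 0.2),
                self._metric("c", "f1", 0.2),
                self._metric("d", "f2", 0.4),
            ]
        )
        # f1 mean 0.2 (3 records), f2 mean 0.4 (1 record): families weigh equally
        assert rep.overall["sn"] == pytest.approx(0.3)

    def test_undefined_values_excluded_and_counted(self):
        rep = aggregate([self._metric("a", "f", None), self._metric("b", "f", 1.0)])
        assert rep.overall["sn"] == pytest.approx(1.0)
        assert rep.undefined_counts["sn"] == 1


class TestAnova:
    def test_equal_group_means_give_zero(self):
        res = anova_oneway([[1, 2, 3], [1, 2, 3]])
        assert res.f_statistic == pytest.approx(0.0)

    def test_matches_reference_implementation(self):
        groups = [
            [6.9, 5.4, 5.8, 4.6, 4.0],
            [8.3, 6.8, 7.8, 9.2, 6.5],
            [8.0, 10.5, 8.1, 6.9, 9.3],
        ]
        res = anova_oneway(groups)
        f_ref, p_ref = stats.f_oneway(*groups)
        assert res.f_statistic == pytest.approx(float(f_ref), abs=1e-9)
        assert res.p_value == pytest.approx(float(p_ref), abs=1e-9)
        assert res.df_between == 2 and res.df_within == 12
        assert res.f_critical == pytest.approx(
            float(stats.f.ppf(0.95, 2, 12)), abs=1e-12
        )

    def test_location_invariance(self, rng):
        groups = [list(rng.normal(size=6)) for _ in range(3)]
        shifted = [[x + 17.5 for x in g] for g in groups]
        assert anova_oneway(groups).f_statistic == pytest.approx(
            anova_oneway(shifted).f_statistic
        )

    def test_degenerate_all_constant_equal_is_undefined(self):
        res = anova_oneway([[2.0, 2.0], [2.0, 2.0]])
        assert np.isnan(res.f_statistic)

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([[1, 2, 3]])


class TestInterchangeFormat:
    def test_round_trip(self, tmp_path):
        preds = [
            MotifPrediction(
                "rec1", 1, 3.5, start=5, end=10,
                pairs=frozenset({BasePair(5, 10), BasePair(6, 9)}),
            ),
            MotifPrediction("rec2", 1, 1.0, motif_text="GGAAUU"),
        ]
        p = tmp_path / "preds.tsv"
        write_predictions(preds, p)
        back = read_predictions(p)
        assert back["rec1"][0].pairs == preds[0].pairs
        assert back["rec1"][0].start == 5
        assert back["rec2"][0].motif_text == "GGAAUU"
        assert not back["rec2"][0].resolved

    def test_malformed_line_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("rec1\t1\t2.0\n")
        with pytest.raises(ValueError, match="6 tab-separated"):
            read_predictions(p)
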