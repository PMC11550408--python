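"""Matching and metric computations against hand arithmetic and oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msanet import (
    MatchResult,
    ValidationError,
    categorize_detections,
    counting_metrics,
    localization_metrics,
    match_points,
)

from oracles import brute_greedy_match

points_strategy = st.lists(
    st.tuples(
        st.floats(0, 100, allow_nan=False, width=32),
        st.floats(0, 100, allow_nan=False, width=32),
    ),
    min_size=0,
    max_size=8,
)


class TestMatchPoints:
    def test_pair_just_inside_threshold_is_accepted(self):
        m = match_points([(0.0, 0.0)], [(24.0, 0.0)])
        assert m.tp == 1 and m.fp == 0 and m.fn == 0
        assert m.pairs[0][2] == pytest.approx(24.0)

    def test_pair_beyond_threshold_is_rejected(self):
        m = match_points([(0.0, 0.0)], [(26.0, 0.0)])
        assert m.tp == 0 and m.fp == 1 and m.fn == 1

    def test_greedy_assignment_on_the_three_point_example(self):
        m = match_points([(0.0, 0.0), (10.0, 0.0)], [(9.0, 0.0), (30.0, 0.0)], threshold=25.0)
        assert m.pairs == [(1, 0, 1.0)]
        assert m.unmatched_gt == [0]
        assert m.unmatched_pred == [1]

    def test_one_to_one_and_conservation_invariants(self, rng):
        gt = [tuple(p) for p in rng.uniform(0, 50, size=(7, 2))]
        pred = [tuple(p) for p in rng.uniform(0, 50, size=(5, 2))]
        m = match_points(gt, pred, threshold=20.0)
        gis = [gi for gi, _, _ in m.pairs]
        pis = [pi for _, pi, _ in m.pairs]
        assert len(set(gis)) == len(gis) and len(set(pis)) == len(pis)
        assert m.tp + m.fn == len(gt)
        assert m.tp + m.fp == len(pred)
        assert all(d <= 20.0 for _, _, d in m.pairs)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(points_strategy, points_strategy, st.floats(5, 40))
    def test_agrees_with_brute_force_greedy(self, gt, pred, threshold):
        ours = match_points(gt, pred, threshold)
        oracle = brute_greedy_match(gt, pred, threshold)
        assert len(ours.pairs) == len(oracle)
        assert {(gi, pi) for gi, pi, _ in ours.pairs} == {(gi, pi) for gi, pi, _ in oracle}

    def test_maximality_no_free_pair_within_threshold(self, rng):
        gt = [tuple(p) for p in rng.uniform(0, 30, size=(8, 2))]
        pred = [tuple(p) for p in rng.uniform(0, 30, size=(8, 2))]
        m = match_points(gt, pred, threshold=10.0)
        for gi in m.unmatched_gt:
            for pi in m.unmatched_pred:
                d = np.hypot(gt[gi][0] - pred[pi][0], gt[gi][1] - pred[pi][1])
                assert d > 10.0

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValidationError):
            match_points([], [], threshold=0.0)


class TestLocalizationMetrics:
    def test_pooled_counts_give_reported_precision_recall_f1(self):
        # dataset-level error-typology counts: TP 35,565 / FP 9,270 / FN 6,539
        m = MatchResult(
            pairs=[(i, i, 1.0) for i in range(35_565)],
            unmatched_gt=list(range(35_565, 35_565 + 6_539)),
            unmatched_pred=list(range(35_565, 35_565 + 9_270)),
            threshold=25.0,
        )
        report = localization_metrics([m])
        assert report.precision == pytest.approx(0.7932, abs=5e-5)
        assert report.recall == pytest.approx(0.8447, abs=5e-5)
        assert report.f1 == pytest.approx(0.8182, abs=5e-5)

    def test_identical_point_sets_give_perfect_scores(self):
        pts = [(1.0, 2.0), (5.0, 5.0)]
        report = localization_metrics([match_points(pts, pts) for _ in range(3)])
        assert report.med == 0.0
        assert report.precision == report.recall == report.f1 == 1.0

    def test_med_is_mean_of_pair_distances(self):
        m = MatchResult(
            pairs=[(0, 0, 3.0), (1, 1, 5.0)], unmatched_gt=[], unmatched_pred=[], threshold=25.0
        )
        assert localization_metrics([m]).med == pytest.approx(4.0)

    def test_match_free_images_excluded_from_med_and_counted(self):
        with_pairs = MatchResult([(0, 0, 2.0)], [], [], 25.0)
        match_free = MatchResult([], [0], [0], 25.0)
        report = localization_metrics([with_pairs, match_free])
        assert report.med == pytest.approx(2.0)
        assert report.n_images_without_matches == 1

    def test_swapping_gt_and_pred_swaps_precision_and_recall(self, rng):
        gt = [tuple(p) for p in rng.uniform(0, 40, size=(6, 2))]
        pred = [tuple(p) for p in rng.uniform(0, 40, size=(9, 2))]
        fwd = localization_metrics([match_points(gt, pred, 15.0)])
        rev = localization_metrics([match_points(pred, gt, 15.0)])
        assert fwd.precision == pytest.approx(rev.recall)
        assert fwd.recall == pytest.approx(rev.precision)
        assert fwd.f1 == pytest.approx(rev.f1)
        if fwd.med is not None:
            assert fwd.med == pytest.approx(rev.med)

    def test_f1_is_exactly_the_harmonic_mean(self):
        m = MatchResult([(0, 0, 1.0)], [1, 2], [1], 25.0)  # TP=1 FP=1 FN=2
        report = localization_metrics([m])
        p, r = report.precision, report.recall
        assert report.f1 == pytest.approx(2 * p * r / (p + r))

    def test_zero_images_rejected(self):
        with pytest.raises(ValidationError):
            localization_metrics([])


class TestCountingMetrics:
    def test_perfect_prediction(self):
        cm = counting_metrics([10, 20, 30], [10, 20, 30])
        assert cm.r2 == 1.0 and cm.mae == 0.0 and cm.rmse == 0.0

    def test_hand_example(self):
        cm = counting_metrics([10, 20, 30], [12, 18, 33])
        assert cm.mae == pytest.approx(7 / 3, abs=1e-4)
        assert cm.rmse == pytest.approx(np.sqrt(17 / 3), abs=1e-4)
        assert cm.r2 == pytest.approx(1 - 17 / 200)

    def test_agrees_with_sklearn(self, rng):
        gt = rng.integers(5, 60, size=12).astype(float)
        pred = gt + rng.normal(0, 3, size=12)
        from sklearn.metrics import mean_absolute_error, r2_score

        cm = counting_metrics(gt, pred)
        assert cm.r2 == pytest.approx(r2_score(gt, pred))
        assert cm.mae == pytest.approx(mean_absolute_error(gt, pred))

    def test_zero_variance_reports_r2_undefined(self):
        cm = counting_metrics([5, 5, 5], [4, 6, 5])
        assert cm.r2 is None
        assert not cm.r2_defined
        assert cm.mae > 0

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValidationError):
            counting_metrics([1, 2], [1])


class TestCategorize:
    def test_empty_predictions_label_all_gt_fn(self):
        gt = [(0.0, 0.0), (5.0, 5.0)]
        m = match_points(gt, [])
        labels = categorize_detections(m, gt, [])
        assert labels["gt"] == ["FN", "FN"]
        assert labels["pred"] == []

    def test_three_point_example_labels(self):
        gt = [(0.0, 0.0), (10.0, 0.0)]
        pred = [(9.0, 0.0), (30.0, 0.0)]
        m = match_points(gt, pred)
        labels = categorize_detections(m, gt, pred)
        assert labels["gt"] == ["FN", "TP"]
        assert labels["pred"] == ["TP", "FP"]

    def test_label_counts_reconcile_with_match_counts(self, rng):
        gt = [tuple(p) for p in rng.uniform(0, 40, size=(6, 2))]
        pred = [tuple(p) for p in rng.uniform(0, 40, size=(7, 2))]
        m = match_points(gt, pred, threshold=12.0)
        labels = categorize_detections(m, gt, pred)
        assert labels["gt"].count("TP") == m.tp == labels["pred"].count("TP")
        assert labels["gt"].count("FN") == m.fn
        assert labels["pred"].count("FP") == m.fp
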