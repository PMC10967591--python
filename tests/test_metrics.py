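"""Tracking and segmentation metrics: formulas, protocol, oracle equivalence."""

import numpy as np
import pytest

from flockmotion import (
    MetricError,
    MotCounts,
    ObservationModel,
    SimConfig,
    degrade,
    encode_rle,
    evaluate,
    fps_throughput,
    identification_metrics,
    iou,
    iou_bbox,
    match_tracks,
    miou,
    mota,
    rmse,
    simulate_flock,
)
from reference_mot import ref_clearmot, ref_id_metrics, trackset_to_frames


class TestMota:
    def test_perfect_score(self):
        c = MotCounts(true_positives=10, total_ground_truth_objects=10)
        assert mota(c) == 1.0

    def test_formula_arithmetic(self):
        c = MotCounts(true_positives=9, false_positives=1, misses=1,
                      identity_switches=1, total_ground_truth_objects=10)
        assert mota(c) == pytest.approx(0.7)

    def test_can_be_negative(self):
        c = MotCounts(true_positives=1, false_positives=30, misses=1,
                      identity_switches=0, total_ground_truth_objects=2)
        assert mota(c) < 0

    def test_zero_gt_undefined(self):
        with pytest.raises(MetricError, match="undefined"):
            mota(MotCounts())

    def test_matches_brute_force_on_random_counts(self, rng):
        for _ in range(200):
            total = int(rng.integers(1, 500))
            tp = int(rng.integers(0, total + 1))
            c = MotCounts(
                true_positives=tp,
                misses=total - tp,
                false_positives=int(rng.integers(0, 200)),
                identity_switches=int(rng.integers(0, tp + 1)),
                total_ground_truth_objects=total,
            )
            expected = 1 - (c.false_positives + c.misses + c.identity_switches) / total
            assert mota(c) == expected


class TestMatchTracks:
    def test_perfect_tracking(self, make_trackset):
        rows = [(f, tid, 100 * tid, 10 * f) for f in range(20) for tid in (1, 2, 3)]
        gt = make_trackset(rows)
        _, c = match_tracks(gt, make_trackset(rows))
        assert (c.false_positives, c.misses, c.identity_switches) == (0, 0, 0)
        assert c.true_positives == c.total_ground_truth_objects == 60
        assert mota(c) == 1.0

    def test_single_missing_detection(self, make_trackset):
        rows = [(f, 1, 100, 10 * f) for f in range(10)]
        gt = make_trackset(rows)
        pred = make_trackset(rows[:-1])
        _, c = match_tracks(gt, pred)
        assert c.misses == 1
        assert c.false_positives == 0

    def test_extra_prediction_is_false_positive(self, make_trackset):
        rows = [(f, 1, 100, 10 * f) for f in range(10)]
        pred = make_trackset(rows + [(3, 9, 900, 900)])
        _, c = match_tracks(make_trackset(rows), pred)
        assert c.false_positives == 1

    def test_identity_switch_charged_once(self, make_trackset):
        gt = make_trackset([(f, 1, 100, 100) for f in range(10)])
        pred = make_trackset([(f, 1, 100, 100) for f in range(5)]
                             + [(f, 2, 100, 100) for f in range(5, 10)])
        _, c = match_tracks(gt, pred)
        assert c.identity_switches == 1
        assert mota(c) == pytest.approx(1 - 1 / 10)

    def test_switch_counted_across_gap(self, make_trackset):
        gt = make_trackset([(f, 1, 100, 100) for f in range(10)])
        pred = make_trackset([(f, 1, 100, 100) for f in range(4)]
                             + [(f, 2, 100, 100) for f in range(6, 10)])
        _, c = match_tracks(gt, pred)
        assert c.identity_switches == 1
        assert c.misses == 2

    def test_persistence_keeps_existing_pairing(self, make_trackset):
        # Two preds near one gt: the previously matched identity must be kept
        # even when the other pred drifts slightly closer.
        gt = make_trackset([(0, 1, 100, 100), (1, 1, 100, 100)])
        pred = make_trackset([(0, 5, 100, 100), (0, 6, 180, 100),
                              (1, 6, 101, 100), (1, 5, 103, 100)])
        _, c = match_tracks(gt, pred, threshold=120.0)
        assert c.identity_switches == 0

    def test_fps_mismatch_rejected(self, make_trackset):
        gt = make_trackset([(0, 1, 0, 0)])
        pred = make_trackset([(0, 1, 0, 0)], fps=30.0)
        with pytest.raises(MetricError, match="fps"):
            match_tracks(gt, pred)

    def test_gate_excludes_distant_prediction(self, make_trackset):
        gt = make_trackset([(0, 1, 100, 100)])
        pred = make_trackset([(0, 1, 100, 500)])
        _, c = match_tracks(gt, pred, threshold=108.0)
        assert c.misses == 1 and c.false_positives == 1


class TestIdentificationMetrics:
    def test_perfect_tracking(self, make_trackset):
        rows = [(f, tid, 100 * tid, 5 * f) for f in range(10) for tid in (1, 2)]
        gt = make_trackset(rows)
        assert identification_metrics(gt, make_trackset(rows)) == (1.0, 1.0, 1.0)

    def test_harmonic_mean_arithmetic(self, make_trackset):
        # Overlap 4 frames, 8 gt detections, 5 predicted: IDP=0.8, IDR=0.5,
        # IDF1 = 2*0.8*0.5/1.3 = 8/13 = 0.6154 (4 d.p.).
        gt = make_trackset([(f, 1, 100, 100) for f in range(8)])
        pred = make_trackset([(f, 1, 100, 100) for f in range(4)]
                             + [(f, 1, 100, 900) for f in range(4, 5)])
        idp, idr, idf1 = identification_metrics(gt, pred, threshold=108.0)
        assert (idp, idr) == (0.8, 0.5)
        assert round(idf1, 4) == 0.6154

    def test_empty_both_sides_is_one_with_warning(self):
        from flockmotion import TrackSet

        with pytest.warns(UserWarning, match="empty"):
            out = identification_metrics(TrackSet(), TrackSet(), threshold=10)
        assert out == (1.0, 1.0, 1.0)

    def test_idf1_between_idp_and_idr(self, rng, make_trackset):
        for seed in range(10):
            gt, pred = _random_scenario(seed, n_birds=4, frames=30)
            idp, idr, idf1 = identification_metrics(gt, pred, threshold=108.0)
            assert min(idp, idr) - 1e-12 <= idf1 <= max(idp, idr) + 1e-12


def _random_scenario(seed, n_birds=5, frames=50, preset="undyed"):
    cfg = SimConfig(n_birds=n_birds, duration_frames=frames, seed=seed,
                    noise=ObservationModel.preset(preset))
    gt = simulate_flock(cfg)
    pred = degrade(gt.pixel_tracks, cfg.noise, seed=seed + 1000,
                   frame_size=cfg.frame_size)
    return gt.pixel_tracks, pred


class TestOracleEquivalence:
    """Package CLEAR-MOT vs the independent brute-force reference."""

    @pytest.mark.parametrize("seed", range(12))
    def test_counts_and_identity_metrics_match(self, seed):
        n_birds = 3 + seed % 5
        gt, pred = _random_scenario(seed, n_birds=n_birds, frames=40)
        threshold = 108.0
        _, c = match_tracks(gt, pred, threshold=threshold)
        ref = ref_clearmot(trackset_to_frames(gt), trackset_to_frames(pred), threshold)
        assert (c.true_positives, c.false_positives, c.misses,
                c.identity_switches, c.total_ground_truth_objects) == (
            ref["tp"], ref["fp"], ref["miss"], ref["ids"], ref["total_gt"])
        idp, idr, idf1 = identification_metrics(gt, pred, threshold=threshold)
        ridp, ridr, ridf1 = ref_id_metrics(
            trackset_to_frames(gt), trackset_to_frames(pred), threshold)
        assert (idp, idr, idf1) == (ridp, ridr, ridf1)

    def test_more_swaps_never_increase_mota_or_idf1(self):
        cfg = SimConfig(n_birds=6, duration_frames=150, seed=21)
        gt = simulate_flock(cfg)
        scores = []
        for swap in (0.0, 0.01, 0.05):
            model = ObservationModel(id_swap_prob=swap)
            pred = degrade(gt.pixel_tracks, model, seed=77, frame_size=cfg.frame_size)
            _, c = match_tracks(gt.pixel_tracks, pred)
            _, _, idf1 = identification_metrics(gt.pixel_tracks, pred)
            scores.append((mota(c), idf1))
        assert scores[0] >= scores[1] >= scores[2]


class TestIou:
    def _square(self, left, top, side, shape=(40, 40)):
        r = np.zeros(shape, dtype=np.uint8)
        r[top:top + side, left:left + side] = 1
        return encode_rle(r)

    def test_identical_masks(self):
        a = self._square(5, 5, 10)
        assert iou(a, a) == 1.0

    def test_disjoint_masks(self):
        assert iou(self._square(0, 0, 10), self._square(20, 20, 10)) == 0.0

    def test_half_overlap_is_one_third(self):
        a = self._square(0, 0, 10)
        b = self._square(5, 0, 10)  # overlap = half of each square's area
        assert iou(a, b) == pytest.approx(1 / 3)

    def test_symmetry(self, rng):
        for _ in range(20):
            a = encode_rle(rng.integers(0, 2, (15, 15)))
            b = encode_rle(rng.integers(0, 2, (15, 15)))
            assert iou(a, b) == iou(b, a)

    def test_both_empty_is_zero_with_warning(self):
        e = encode_rle(np.zeros((5, 5), dtype=np.uint8))
        with pytest.warns(UserWarning, match="empty"):
            assert iou(e, e) == 0.0

    def test_size_mismatch_rejected(self):
        a = self._square(0, 0, 5, shape=(20, 20))
        b = self._square(0, 0, 5, shape=(30, 30))
        with pytest.raises(MetricError, match="size"):
            iou(a, b)

    def test_bbox_iou_half_overlap(self):
        assert iou_bbox((0, 0, 10, 10), (5, 0, 10, 10)) == pytest.approx(1 / 3)


class TestMiou:
    def _class_masks(self, rng, n_classes=3, shape=(20, 25)):
        return {c: [encode_rle((rng.random(shape) < 0.4).astype(np.uint8), track_id=c)]
                for c in range(1, n_classes + 1)}

    def test_perfect_segmentation(self, rng):
        gt = self._class_masks(rng)
        assert miou(gt, gt) == 1.0

    def test_mean_of_one_and_zero_is_half(self):
        full = encode_rle(np.ones((10, 10), dtype=np.uint8))
        left = np.zeros((10, 10), dtype=np.uint8)
        left[:, :5] = 1
        right = 1 - left
        pred = {1: [full], 2: [encode_rle(left)]}
        gt = {1: [full], 2: [encode_rle(right)]}
        assert miou(pred, gt) == pytest.approx(0.5)

    def test_matches_brute_force_pixel_sets(self, rng):
        for _ in range(30):
            pred = self._class_masks(rng)
            gt = self._class_masks(rng)
            from flockmotion import decode_rle

            expected = np.mean([
                (decode_rle(pred[c][0]).astype(bool) & decode_rle(gt[c][0]).astype(bool)).sum()
                / (decode_rle(pred[c][0]).astype(bool) | decode_rle(gt[c][0]).astype(bool)).sum()
                for c in pred
            ])
            assert miou(pred, gt) == pytest.approx(expected, abs=1e-12)

    def test_class_absent_from_both_excluded(self, rng):
        gt = self._class_masks(rng, n_classes=2)
        pred = {k: list(v) for k, v in gt.items()}
        empty = encode_rle(np.zeros((20, 25), dtype=np.uint8))
        gt[3] = [empty]
        pred[3] = [empty]
        with pytest.warns(UserWarning, match="excluded"):
            assert miou(pred, gt) == 1.0


class TestRmse:
    def test_identical_vectors(self):
        assert rmse([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]) == 0.0

    def test_printed_arithmetic(self):
        assert rmse([0.0, 0.0], [0.03, 0.04]) == pytest.approx(0.03536, abs=5e-6)

    def test_constant_offset(self, rng):
        y = rng.uniform(0, 0.2, 50)
        assert rmse(y, y + 0.017) == pytest.approx(0.017)

    def test_zero_iff_equal(self, rng):
        y = rng.uniform(0, 1, 20)
        yhat = y.copy()
        yhat[3] += 1e-6
        assert rmse(y, y) == 0.0
        assert rmse(y, yhat) > 0.0

    def test_matches_brute_force(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 40))
            y, yhat = rng.normal(size=n), rng.normal(size=n)
            expected = np.sqrt(sum((a - b) ** 2 for a, b in zip(y, yhat)) / n)
            assert rmse(y, yhat) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("y, yhat", [([], []), ([1.0], [1.0, 2.0])])
    def test_invalid_input_rejected(self, y, yhat):
        with pytest.raises(MetricError):
            rmse(y, yhat)


class TestThroughputAndReport:
    def test_fps_ratio(self):
        assert fps_throughput(180, 10.0) == 18.0
        assert fps_throughput(0, 10.0) == 0.0

    def test_zero_time_rejected(self):
        with pytest.raises(MetricError):
            fps_throughput(10, 0.0)

    def test_report_bounds(self, make_trackset):
        gt, pred = _random_scenario(3, n_birds=5, frames=60)
        report = evaluate(gt, pred)
        assert report.mota <= 1.0
        assert 0.0 <= report.idf1 <= 1.0
        assert min(report.idp, report.idr) - 1e-12 <= report.idf1 \
            <= max(report.idp, report.idr) + 1e-12
        assert "MOTA" in report.summary()
        d = report.to_dict()
        assert d["true_positives"] + d["misses"] == d["total_gt_objects"]
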