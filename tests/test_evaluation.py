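"""Matching, precision/recall, AP vs a brute-force PR-envelope oracle,
error taxonomy, and confusion-matrix consistency."""

import numpy as np
import pytest

from germinet import evaluation as E


def brute_force_ap(records, n_gt):
    """Independent PR-envelope oracle: for each of the 101 recall points,
    scan every confidence cutoff and take the best achievable precision."""
    records = sorted(records, key=lambda r: -r[0])
    prefixes = []
    tp = fp = 0
    for _, is_tp in records:
        tp, fp = tp + is_tp, fp + (1 - is_tp)
        prefixes.append((tp / n_gt, tp / (tp + fp)))
    total = 0.0
    for r in np.linspace(0, 1, 101):
        feasible = [p for rec, p in prefixes if rec >= r - 1e-12]
        total += max(feasible) if feasible else 0.0
    return total / 101


def _box(cx, cy, s=0.1):
    return (cx, cy, s, s)


def random_case(rng, max_dets=20):
    """Random per-image detections/gts with controlled overlap structure."""
    n_img = int(rng.integers(1, 4))
    dets, gts = [], []
    for _ in range(n_img):
        n_gt = int(rng.integers(0, 6))
        g = [(_box(rng.uniform(0.1, 0.9), rng.uniform(0.1, 0.9)),
              int(rng.integers(0, 2))) for _ in range(n_gt)]
        d = []
        for box, cls in g:
            for _ in range(int(rng.integers(0, 3))):
                jit = rng.normal(0, 0.03, 2)
                d.append(((box[0] + jit[0], box[1] + jit[1], 0.1, 0.1),
                          int(rng.integers(0, 2)) if rng.uniform() < 0.3 else cls,
                          float(rng.uniform(0.1, 1.0))))
        for _ in range(int(rng.integers(0, 3))):  # pure false alarms
            d.append((_box(rng.uniform(), rng.uniform()), int(rng.integers(0, 2)),
                      float(rng.uniform(0.1, 1.0))))
        dets.append(d[:max_dets])
        gts.append(g)
    return dets, gts


class TestMatchDetections:
    def test_perfect(self):
        gts = [(_box(0.3, 0.3), 0), (_box(0.7, 0.7), 1)]
        dets = [(g[0], g[1], 0.9) for g in gts]
        res = E.match_detections(dets, gts, 0.5)
        assert (res.tp, res.fp, res.fn) == (2, 0, 0)

    def test_no_detections(self):
        res = E.match_detections([], [(_box(0.3, 0.3), 0)] * 1, 0.5)
        assert (res.tp, res.fp, res.fn) == (0, 0, 1)

    def test_two_dets_one_gt_repeated(self):
        gts = [(_box(0.5, 0.5), 0)]
        dets = [(_box(0.5, 0.5), 0, 0.9), (_box(0.505, 0.5), 0, 0.8)]
        res = E.match_detections(dets, gts, 0.5)
        assert (res.tp, res.fp, res.fn) == (1, 1, 0)
        assert res.det_flags == ["tp", "repeated"]

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            E.match_detections([], [], 1.5)


class TestPrecisionRecall:
    @pytest.mark.parametrize("tp,fp,fn,p,r", [
        (49, 1, 0, 0.98, 1.0),
        (0, 0, 5, 1.0, 0.0),     # no predictions: P convention = 1
        (9, 1, 1, 0.9, 0.9),
    ])
    def test_substitution(self, tp, fp, fn, p, r):
        assert E.precision_recall(tp, fp, fn) == (pytest.approx(p), pytest.approx(r))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            E.precision_recall(-1, 0, 0)


class TestAveragePrecision:
    def test_single_correct_detection(self):
        gts = [[(_box(0.5, 0.5), 0)]]
        dets = [[(_box(0.5, 0.5), 0, 0.9)]]
        assert E.average_precision(dets, gts) == pytest.approx(1.0)

    def test_wrong_class_detection(self):
        gts = [[(_box(0.5, 0.5), 0)]]
        dets = [[(_box(0.5, 0.5), 1, 0.9)]]
        assert E.average_precision(dets, gts) == pytest.approx(0.0)

    def test_three_det_hand_case(self):
        """conf .9 TP, .8 FP, .7 TP on 2 GTs."""
        gts = [[(_box(0.2, 0.2), 0), (_box(0.8, 0.8), 0)]]
        dets = [[(_box(0.2, 0.2), 0, 0.9), (_box(0.5, 0.5), 0, 0.8),
                 (_box(0.8, 0.8), 0, 0.7)]]
        ap = E.average_precision(dets, gts)
        oracle = brute_force_ap([(0.9, 1), (0.8, 0), (0.7, 1)], 2)
        assert ap == pytest.approx(oracle, abs=1e-9)
        # envelope: P=1 up to R=0.5, then P=2/3 up to R=1
        assert ap == pytest.approx((51 * 1.0 + 50 * 2 / 3) / 101, abs=1e-9)

    def test_oracle_equivalence_randomized(self, rng):
        for _ in range(200):
            dets, gts = random_case(rng)
            n_gt = sum(len(g) for g in gts)
            if n_gt == 0:
                continue
            for cls in (0, 1):
                d_c = [[d for d in ds if d[1] == cls] for ds in dets]
                g_c = [[g for g in gs if g[1] == cls] for gs in gts]
                n = sum(len(g) for g in g_c)
                if n == 0:
                    continue
                records = []
                for ds, gs in zip(d_c, g_c):
                    res = E.match_detections(ds, gs, 0.5)
                    confs = sorted((x[2] for x in ds), reverse=True)
                    records += [(c, 1 if f == "tp" else 0)
                                for c, f in zip(confs, res.det_flags)]
                assert E.average_precision(dets, gts, 0.5, cls) == pytest.approx(
                    brute_force_ap(records, n), abs=1e-9)

    def test_adding_correct_detection_never_lowers_ap(self, rng):
        for _ in range(50):
            dets, gts = random_case(rng)
            if sum(len(g) for g in gts) == 0 or not gts[0]:
                continue
            before = E.average_precision(dets, gts, 0.5)
            box, cls = gts[0][0]
            dets2 = [list(d) for d in dets]
            dets2[0] = dets2[0] + [(box, cls, 1.0)]
            after = E.average_precision(dets2, gts, 0.5)
            assert after >= before - 1e-12

    def test_raising_iou_threshold_never_raises_ap(self, rng):
        for _ in range(50):
            dets, gts = random_case(rng)
            if sum(len(g) for g in gts) == 0:
                continue
            aps = [E.average_precision(dets, gts, t) for t in (0.5, 0.65, 0.8)]
            assert aps[0] >= aps[1] - 1e-12 >= aps[2] - 2e-12

    def test_no_ground_truth_warns_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(E.average_precision([[]], [[]]))


class TestMeanAP:
    def test_perfect(self):
        gts = [[(_box(0.3, 0.3), 0), (_box(0.7, 0.7), 1)]]
        dets = [[(g[0], g[1], 0.9) for g in gts[0]]]
        m50, m5095 = E.mean_ap(dets, gts)
        assert m50 == pytest.approx(1.0) and m5095 == pytest.approx(1.0)

    def test_all_wrong_class(self):
        gts = [[(_box(0.3, 0.3), 0)]]
        dets = [[(_box(0.3, 0.3), 1, 0.9)]]
        assert E.mean_ap(dets, gts)[0] == pytest.approx(0.0)

    def test_map5095_bounded_by_map50(self, rng):
        for _ in range(10):
            dets, gts = random_case(rng)
            if sum(len(g) for g in gts) == 0:
                continue
            m50, m5095 = E.mean_ap(dets, gts)
            assert m5095 <= m50 + 1e-12


class TestErrorTaxonomy:
    def test_clean_run(self):
        gts = [[(_box(0.5, 0.5), 0)]]
        dets = [[(_box(0.5, 0.5), 0, 0.9)]]
        tally = E.error_taxonomy(dets, gts, 1, 49)
        assert (tally.missed, tally.false_alarm, tally.repeated) == (0, 0, 0)
        assert tally.error_rate == 0.0

    def test_printed_counts_arithmetic(self):
        """1 missed + 7 false alarms + 3 repeated over 30 x 49 seeds."""
        tally = E.ErrorTally(1, 7, 3, 30, 49)
        assert tally.error_rate == pytest.approx(11 / 1470)
        assert tally.error_rate == pytest.approx(0.00748, abs=5e-5)

    def test_components_constructed(self):
        gts = [[(_box(0.2, 0.2), 0), (_box(0.8, 0.8), 0)]]
        dets = [[(_box(0.2, 0.2), 0, 0.9),      # tp
                 (_box(0.205, 0.2), 0, 0.8),    # repeated
                 (_box(0.5, 0.5), 0, 0.7)]]     # false alarm
        tally = E.error_taxonomy(dets, gts, 1, 49)
        assert (tally.missed, tally.false_alarm, tally.repeated) == (1, 1, 1)

    def test_components_sum_to_fp_plus_fn(self, rng):
        for _ in range(30):
            dets, gts = random_case(rng)
            tally = E.error_taxonomy(dets, gts, len(gts), 49)
            fp = fn = 0
            for ds, gs in zip(dets, gts):
                res = E.match_detections(ds, gs, 0.5)
                fp, fn = fp + res.fp, fn + res.fn
            assert tally.false_alarm + tally.repeated == fp
            assert tally.missed == fn

    def test_invalid_seed_count(self):
        with pytest.raises(ValueError):
            E.ErrorTally(0, 0, 0, 1, 0)


class TestConfusionMatrix:
    def test_perfect_diagonal(self):
        gts = [[(_box(0.3, 0.3), 0), (_box(0.7, 0.7), 1)]]
        dets = [[(g[0], g[1], 0.9) for g in gts[0]]]
        cm = E.confusion_matrix(dets, gts)
        assert cm[0, 0] == 1 and cm[1, 1] == 1 and cm.sum() == 2

    def test_spurious_prediction_hits_background_column(self):
        cm = E.confusion_matrix([[(_box(0.5, 0.5), 0, 0.9)]], [[]])
        assert cm[0, 2] == 1 and cm.sum() == 1

    def test_missed_gt_hits_background_row(self):
        cm = E.confusion_matrix([[]], [[(_box(0.5, 0.5), 1)]])
        assert cm[2, 1] == 1 and cm.sum() == 1

    def test_totals_consistent_with_matcher(self, rng):
        for _ in range(30):
            dets, gts = random_case(rng)
            cm = E.confusion_matrix(dets, gts)
            for cls in (0, 1):
                tp = fp = fn = 0
                for ds, gs in zip(dets, gts):
                    res = E.match_detections(
                        [d for d in ds if d[1] == cls],
                        [g for g in gs if g[1] == cls], 0.5)
                    tp, fp, fn = tp + res.tp, fp + res.fp, fn + res.fn
                assert cm[cls, cls] == tp
                assert cm[cls].sum() - cm[cls, cls] == fp
                assert cm[:, cls].sum() - cm[cls, cls] == fn
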