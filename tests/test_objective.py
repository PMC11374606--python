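"""NWD/GIoU closed forms, Hungarian matching vs brute force, loss contract."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from germinet import objective as O
from germinet.nn.tensor import Tensor

boxes_st = st.tuples(
    st.floats(-5, 5), st.floats(-5, 5),
    st.floats(0.05, 8), st.floats(0.05, 8),
)


class TestWasserstein:
    def test_identity_is_zero(self):
        assert O.wasserstein2_sq((1, 2, 3, 4), (1, 2, 3, 4)) == 0.0

    def test_hand_case(self):
        # centers 3,4 apart, equal sizes: 3^2 + 4^2 = 25
        assert O.wasserstein2_sq((0, 0, 2, 2), (3, 4, 2, 2)) == pytest.approx(25.0)

    @settings(deadline=None, derandomize=True)
    @given(boxes_st, boxes_st)
    def test_symmetry_and_nonnegativity(self, a, b):
        assert O.wasserstein2_sq(a, b) == pytest.approx(O.wasserstein2_sq(b, a))
        assert O.wasserstein2_sq(a, b) >= 0.0

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValueError):
            O.wasserstein2_sq((0, 0, 0, 2), (0, 0, 2, 2))


class TestNWD:
    def test_identity_is_one(self):
        for C in (1.0, 12.8, 100.0):
            assert O.nwd((0, 0, 2, 2), (0, 0, 2, 2), O.NWDParams(C=C)) == 1.0

    def test_hand_cases(self):
        p = O.NWDParams(C=1.0)
        assert O.nwd((0, 0, 2, 2), (3, 4, 2, 2), p) == pytest.approx(math.exp(-5), rel=1e-9)
        assert O.nwd((0, 0, 2, 2), (0, 0, 4, 4), p) == pytest.approx(
            math.exp(-math.sqrt(2)), rel=1e-9)

    def test_squared_exponent_option(self):
        p = O.NWDParams(C=1.0, squared_exponent=True)
        assert O.nwd((0, 0, 2, 2), (3, 4, 2, 2), p) == pytest.approx(math.exp(-25), rel=1e-9)

    def test_monotone_decay_with_center_distance(self):
        vals = [O.nwd((0, 0, 1, 1), (d, 0, 1, 1)) for d in np.linspace(0, 3, 10)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_monotone_decay_with_size_mismatch(self):
        vals = [O.nwd((0, 0, 1, 1), (0, 0, 1 + s, 1 + s)) for s in np.linspace(0, 3, 10)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    @settings(deadline=None, derandomize=True)
    @given(boxes_st, boxes_st)
    def test_bounds(self, a, b):
        v = O.nwd(a, b)
        assert 0.0 < v <= 1.0

    def test_tiny_box_scale_insensitivity_vs_iou(self):
        """At a fixed relative offset, NWD responds far less to absolute
        scale than IoU — the small-target property motivating the loss."""
        from germinet.evaluation import box_iou

        def pair(scale):
            return (0, 0, scale, scale), (0.6 * scale, 0, scale, scale)

        iou_big = box_iou(*pair(1.0))
        iou_small = box_iou(*pair(0.01))
        assert iou_big == pytest.approx(iou_small, abs=1e-9)  # IoU is scale-free
        p = O.NWDParams(C=0.05)
        nwd_big, nwd_small = O.nwd(*pair(1.0), p), O.nwd(*pair(0.01), p)
        # tiny boxes stay close to 1 while big boxes decay: smooth ranking
        assert nwd_small > 0.85 > nwd_big

    def test_invalid_C_rejected(self):
        with pytest.raises(ValueError):
            O.NWDParams(C=0.0)


class TestGIoU:
    def test_identity(self):
        assert O.giou((0, 0, 2, 2), (0, 0, 2, 2)) == pytest.approx(1.0)

    def test_far_separation_approaches_minus_one(self):
        assert O.giou((0, 0, 0.01, 0.01), (1000, 1000, 0.01, 0.01)) < -0.99

    def test_half_overlapping_unit_squares(self):
        # IoU = 1/3, hull = 1.5 covers union exactly -> GIoU = 1/3
        assert O.giou((0, 0, 1, 1), (0.5, 0, 1, 1)) == pytest.approx(1 / 3)

    def test_matrix_matches_scalar(self, rng):
        pred = np.column_stack([rng.uniform(-2, 2, (6, 2)), rng.uniform(0.1, 3, (6, 2))])
        gt = np.column_stack([rng.uniform(-2, 2, (4, 2)), rng.uniform(0.1, 3, (4, 2))])
        mat = O._giou_matrix(pred, gt)
        for i in range(6):
            for j in range(4):
                assert mat[i, j] == pytest.approx(O.giou(pred[i], gt[j]), rel=1e-5)


class TestHungarian:
    def test_two_by_two_diagonal(self):
        rows, cols = O.hungarian_match(
            np.array([[5.0, -5.0], [-5.0, 5.0]]),
            np.array([[0.2, 0.2, 0.1, 0.1], [0.8, 0.8, 0.1, 0.1]]),
            np.array([[0.2, 0.2, 0.1, 0.1], [0.8, 0.8, 0.1, 0.1]]),
            np.array([0, 1]),
        )
        assert list(rows[np.argsort(cols)]) == [0, 1]

    def test_empty_targets_all_background(self):
        rows, cols = O.hungarian_match(np.zeros((5, 2)), np.full((5, 4), 0.5),
                                       np.empty((0, 4)), np.empty(0, dtype=int))
        assert len(rows) == 0 and len(cols) == 0

    def test_capacity_error(self):
        with pytest.raises(ValueError):
            O.hungarian_match(np.zeros((1, 2)), np.full((1, 4), 0.5),
                              np.full((2, 4), 0.5), np.array([0, 1]))

    def test_matches_brute_force_for_small_problems(self, rng):
        params = O.NWDParams()
        for _ in range(30):
            m = int(rng.integers(1, 6))
            q = m + int(rng.integers(0, 3))
            logits = rng.normal(size=(q, 2))
            pred = np.column_stack([rng.uniform(0.2, 0.8, (q, 2)),
                                    rng.uniform(0.05, 0.3, (q, 2))])
            gt = np.column_stack([rng.uniform(0.2, 0.8, (m, 2)),
                                  rng.uniform(0.05, 0.3, (m, 2))])
            labels = rng.integers(0, 2, m)
            rows, cols = O.hungarian_match(logits, pred, gt, labels, params)

            prob = 1 / (1 + np.exp(-logits))
            def cost(i, j):
                c = params.lambda_cls * (1 - prob[i, labels[j]])
                c += params.lambda_l1 * np.abs(pred[i] - gt[j]).sum()
                c += params.lambda_box * (
                    params.mix_ratio * (1 - O.nwd(pred[i], gt[j], params))
                    + (1 - params.mix_ratio) * (1 - O.giou(pred[i], gt[j])))
                return c

            best = min(
                (sum(cost(r, j) for j, r in enumerate(perm))
                 for perm in itertools.permutations(range(q), m)),
            )
            got = sum(cost(r, c) for r, c in zip(rows, cols))
            assert got == pytest.approx(best, rel=1e-6)


class TestTotalLoss:
    def _outputs(self, boxes, logits):
        return {"logits": Tensor(logits), "boxes": Tensor(boxes),
                "aux": [(Tensor(logits), Tensor(boxes))]}

    def test_perfect_boxes_zero_box_terms(self):
        gt = {"boxes": np.array([[0.3, 0.3, 0.1, 0.1]]), "labels": np.array([0])}
        boxes = np.full((1, 4, 4), 0.7, np.float32)
        boxes[0, 2] = [0.3, 0.3, 0.1, 0.1]
        logits = np.full((1, 4, 2), -6.0, np.float32)
        logits[0, 2, 0] = 6.0
        _, parts = O.total_loss(self._outputs(boxes, logits), [gt])
        assert parts["l1"] == pytest.approx(0.0, abs=1e-6)
        assert parts["box"] == pytest.approx(0.0, abs=1e-5)

    def test_r_zero_reduces_to_giou_objective(self, rng):
        gt = {"boxes": np.array([[0.4, 0.4, 0.2, 0.2]]), "labels": np.array([1])}
        boxes = rng.uniform(0.2, 0.8, (1, 3, 4)).astype(np.float32)
        logits = rng.normal(size=(1, 3, 2)).astype(np.float32)
        p0 = O.NWDParams(mix_ratio=0.0)
        _, parts = O.total_loss(self._outputs(boxes, logits), [gt], p0)
        rows, cols = O.hungarian_match(logits[0], boxes[0], gt["boxes"], gt["labels"], p0)
        expected = p0.lambda_box * (1 - O.giou(boxes[0, rows[0]], gt["boxes"][0]))
        assert parts["box"] == pytest.approx(expected, rel=1e-4)

    def test_box_term_decreases_with_center_offset(self):
        gt = {"boxes": np.array([[0.5, 0.5, 0.2, 0.2]]), "labels": np.array([0])}
        vals = []
        for off in (0.2, 0.1, 0.05, 0.0):
            boxes = np.array([[[0.5 + off, 0.5, 0.2, 0.2]]], np.float32)
            logits = np.full((1, 1, 2), 2.0, np.float32)
            _, parts = O.total_loss(self._outputs(boxes, logits), [gt])
            vals.append(parts["box"])
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_empty_batch_zero_loss_with_warning(self):
        with pytest.warns(UserWarning):
            total, parts = O.total_loss(
                {"logits": Tensor(np.zeros((0, 1, 2))), "boxes": Tensor(np.zeros((0, 1, 4))),
                 "aux": []}, [])
        assert parts["total"] == 0.0
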