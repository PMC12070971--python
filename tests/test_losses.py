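import math

import numpy as np
import pytest

from sdd.autograd import Tensor
from sdd.geometry import Box
from sdd.losses import (AssignmentTable, LossWeights, boxes_iog, boxes_iou,
                        ciou_loss, classification_loss, occlusion_loss,
                        repbox_loss, repgt_loss, smooth_ln)


class TestCIoU:
    def test_perfect(self):
        assert ciou_loss(Box(0, 0, 2, 3), Box(0, 0, 2, 3)).item() == pytest.approx(0.0, abs=1e-9)

    def test_concentric_equal_aspect(self):
        # IoU=0.25, centers coincide, aspect terms cancel -> 1 - 0.25
        assert ciou_loss(Box(-1, -1, 1, 1), Box(-2, -2, 2, 2)).item() == pytest.approx(0.75, abs=1e-7)

    def test_disjoint_same_shape(self):
        # IoU=0, rho^2=4, enclosing diag^2=13, v=0 -> 1 + 4/13
        val = ciou_loss(Box(0, 0, 1, 2), Box(2, 0, 3, 2)).item()
        assert val == pytest.approx(1 + 4 / 13, abs=1e-7)

    def test_zero_extent_errors(self):
        with pytest.raises(ValueError):
            ciou_loss(Box(0, 0, 0, 1), Box(0, 0, 1, 1))


class TestSmoothLn:
    def test_zero(self):
        assert smooth_ln(0.0, 0.5).item() == 0.0

    def test_at_sigma(self):
        assert smooth_ln(0.5, 0.5).item() == pytest.approx(-math.log(0.5), abs=1e-12)

    def test_linear_branch(self):
        assert smooth_ln(0.9, 0.5).item() == pytest.approx(0.8 - math.log(0.5), abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            smooth_ln(1.0, 0.5)
        with pytest.raises(ValueError):
            smooth_ln(0.5, 1.0)

    @pytest.mark.parametrize("sigma", [0.2, 0.5, 0.8])
    def test_c1_continuity_at_sigma(self, sigma):
        eps = 1e-7
        left = smooth_ln(sigma - eps, sigma).item()
        right = smooth_ln(sigma + eps, sigma).item()
        assert right - left == pytest.approx(0.0, abs=1e-5)
        dleft = (smooth_ln(sigma, sigma).item() - smooth_ln(sigma - eps, sigma).item()) / eps
        dright = (smooth_ln(sigma + eps, sigma).item() - smooth_ln(sigma, sigma).item()) / eps
        assert dleft == pytest.approx(1.0 / (1.0 - sigma), rel=1e-4)
        assert dright == pytest.approx(1.0 / (1.0 - sigma), rel=1e-4)


class TestRepGT:
    def test_single_gt_no_repulsion(self):
        table = AssignmentTable([0], [-1])
        assert repgt_loss([Box(0, 0, 2, 2)], [Box(0, 0, 2, 2)], table).item() == 0.0

    def test_quarter_iog(self):
        # IoG(P, G_rep) = area(P cap G1)/area(G1) = 1/4 -> -ln(3/4)
        preds = [Box(0, 0, 2, 2)]
        gts = [Box(0, 0, 2, 2), Box(1, 1, 3, 3)]
        table = AssignmentTable([0], [1])
        val = repgt_loss(preds, gts, table, LossWeights(sigma_repgt=0.5)).item()
        assert val == pytest.approx(-math.log(0.75), abs=1e-7)

    def test_disjoint_positives_zero(self):
        preds = [Box(0, 0, 1, 1), Box(10, 10, 11, 11)]
        gts = [Box(0, 0, 1, 1), Box(10, 10, 11, 11), Box(20, 20, 21, 21)]
        table = AssignmentTable([0, 1], [2, 2])
        assert repgt_loss(preds, gts, table).item() == 0.0

    def test_empty_positives_warns(self):
        with pytest.warns(UserWarning):
            assert repgt_loss([], [Box(0, 0, 1, 1)], AssignmentTable([], [])).item() == 0.0

    def test_divides_by_all_positives(self):
        # second positive has no repulsion candidate yet still counts in |P+|
        preds = [Box(0, 0, 2, 2), Box(50, 50, 52, 52)]
        gts = [Box(0, 0, 2, 2), Box(1, 1, 3, 3), Box(50, 50, 52, 52)]
        table = AssignmentTable([0, 2], [1, -1])
        val = repgt_loss(preds, gts, table).item()
        assert val == pytest.approx(-math.log(0.75) / 2, abs=1e-7)


class TestRepBox:
    def test_single_group(self):
        table = AssignmentTable([0, 0], [-1, -1])
        assert repbox_loss([Box(0, 0, 2, 2), Box(1, 1, 3, 3)], table).item() == 0.0

    def test_disjoint_groups(self):
        table = AssignmentTable([0, 1], [-1, -1])
        assert repbox_loss([Box(0, 0, 1, 1), Box(5, 5, 6, 6)], table).item() == 0.0

    def test_one_seventh_pair(self):
        table = AssignmentTable([0, 1], [-1, -1])
        val = repbox_loss([Box(0, 0, 2, 2), Box(1, 1, 3, 3)], table,
                          LossWeights(sigma_repbox=0.5)).item()
        assert val == pytest.approx(-math.log(6 / 7), rel=1e-6)

    def test_monotone_in_overlap(self):
        table = AssignmentTable([0, 1], [-1, -1])
        prev = -1.0
        for shift in (1.9, 1.5, 1.0, 0.5):
            val = repbox_loss([Box(0, 0, 2, 2), Box(shift, shift, shift + 2, shift + 2)],
                              table).item()
            assert val >= prev
            prev = val


class TestOcclusionLoss:
    def test_perfect_no_overlap(self):
        preds = [Box(0, 0, 2, 2), Box(5, 5, 7, 7)]
        gts = [Box(0, 0, 2, 2), Box(5, 5, 7, 7)]
        table = AssignmentTable([0, 1], [-1, -1])
        total, comps = occlusion_loss(preds, gts, table)
        assert total.item() == pytest.approx(0.0, abs=1e-9)

    def test_repulsion_free_equals_mean_ciou(self):
        preds = [Box(0, 0, 2, 2), Box(10, 10, 13, 12)]
        gts = [Box(0.5, 0, 2.5, 2), Box(10, 11, 13, 13)]
        table = AssignmentTable([0, 1], [-1, -1])
        total, comps = occlusion_loss(preds, gts, table)
        expected = (ciou_loss(preds[0], gts[0]).item() + ciou_loss(preds[1], gts[1]).item()) / 2
        assert total.item() == pytest.approx(expected, abs=1e-9)

    def test_weighted_composition(self):
        # frozen arithmetic of the worked component values
        composed = 0.75 + 0.4 * (-math.log(0.75)) + 0.6 * (-math.log(6 / 7))
        assert composed == pytest.approx(0.9576, abs=5e-4)
        # and the implementation composes its own components the same way
        preds = [Box(0, 0, 2, 2), Box(1, 1, 3, 3)]
        gts = [Box(0.2, 0, 2.2, 2), Box(1, 1.3, 3, 3.3), Box(0.5, 0.5, 1.5, 1.5)]
        table = AssignmentTable([0, 1], [2, 2])
        w = LossWeights()
        total, comps = occlusion_loss(preds, gts, table, w)
        assert total.item() == pytest.approx(
            comps["ciou"].item() + w.alpha * comps["repgt"].item()
            + w.beta * comps["repbox"].item(), abs=1e-9)

    def test_alpha_beta_zero_is_pure_ciou(self, rng):
        xy = rng.uniform(0, 10, size=(4, 2))
        wh = rng.uniform(1, 6, size=(4, 2))
        preds = [Box(x, y, x + w, y + h) for (x, y), (w, h) in zip(xy, wh)]
        gts = [Box(b.x1 + 0.5, b.y1 + 0.5, b.x2 + 1.0, b.y2 + 1.2) for b in preds]
        table = AssignmentTable(np.arange(4), np.full(4, -1))
        w = LossWeights(alpha=0.0, beta=0.0)
        total, _ = occlusion_loss(preds, gts, table, w)
        mean_ciou = np.mean([ciou_loss(p, g).item() for p, g in zip(preds, gts)])
        assert total.item() == pytest.approx(mean_ciou, abs=1e-9)


class TestClassificationLoss:
    def test_saturated_match(self):
        logits = np.array([20.0, -20.0])
        targets = np.array([1.0, 0.0])
        assert classification_loss(logits, targets).item() == pytest.approx(0.0, abs=1e-6)

    def test_ln2_at_zero_logit(self):
        assert classification_loss(np.array([0.0]), np.array([1.0])).item() == \
            pytest.approx(math.log(2), abs=1e-12)

    def test_swap_symmetry(self, rng):
        logits = rng.normal(size=10)
        targets = rng.random(10)
        a = classification_loss(logits, targets).item()
        b = classification_loss(-logits, 1.0 - targets).item()
        assert a == pytest.approx(b, rel=1e-9)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            classification_loss(np.zeros(3), np.zeros(4))


def _random_scene(rng, n_pred=4, n_gt=3):
    preds = rng.uniform(0, 10, size=(n_pred, 2))
    preds = np.concatenate([preds, preds + rng.uniform(1, 6, size=(n_pred, 2))], axis=1)
    gts = rng.uniform(0, 10, size=(n_gt, 2))
    gts = np.concatenate([gts, gts + rng.uniform(1, 6, size=(n_gt, 2))], axis=1)
    attr = rng.integers(0, n_gt, size=n_pred)
    rep = np.array([(a + 1) % n_gt if n_gt > 1 else -1 for a in attr])
    return preds, gts, AssignmentTable(attr, rep)


class TestGradients:
    """Autodiff gradients of every loss match central finite differences."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_occlusion_loss_gradcheck(self, seed):
        rng = np.random.default_rng(seed)
        preds, gts, table = _random_scene(rng)
        w = LossWeights()

        def value(flat):
            p = Tensor(flat.reshape(-1, 4))
            return occlusion_loss(p, Tensor(gts), table, w)[0].item()

        p = Tensor(preds.astype(np.float64), requires_grad=True)
        total, _ = occlusion_loss(p, Tensor(gts), table, w)
        total.backward()
        eps = 1e-6
        flat = preds.astype(np.float64).ravel()
        for i in range(len(flat)):
            up, dn = flat.copy(), flat.copy()
            up[i] += eps
            dn[i] -= eps
            num = (value(up) - value(dn)) / (2 * eps)
            got = p.grad.ravel()[i]
            assert got == pytest.approx(num, rel=1e-4, abs=1e-6)

    def test_classification_gradcheck(self, rng):
        logits = rng.normal(size=6)
        targets = rng.random(6)
        x = Tensor(logits.astype(np.float64), requires_grad=True)
        classification_loss(x, targets).backward()
        eps = 1e-6
        for i in range(6):
            up, dn = logits.copy(), logits.copy()
            up[i] += eps
            dn[i] -= eps
            num = (classification_loss(up, targets).item()
                   - classification_loss(dn, targets).item()) / (2 * eps)
            assert x.grad[i] == pytest.approx(num, rel=1e-4, abs=1e-8)


def test_loss_weight_validation():
    with pytest.raises(ValueError):
        LossWeights(alpha=-1)
    with pytest.raises(ValueError):
        LossWeights(sigma_repgt=1.0)
    with pytest.raises(ValueError):
        LossWeights(epsilon=0.0)
    assert LossWeights().alpha == 0.4
    assert LossWeights().beta == 0.6
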