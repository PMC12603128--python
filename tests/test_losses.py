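"""Loss functions against closed forms and independent scalar-loop oracles."""

import math

import numpy as np
import pytest

from spineseg.losses import (LossConfig, bce_dice_loss, bce_loss,
                             bce_loss_grad, cce_dice_loss, cce_loss,
                             dice_loss, dice_loss_grad, focal_loss,
                             focal_loss_grad, get_loss)

CFG = LossConfig()


# -- independent scalar-loop oracles ----------------------------------------

def bce_oracle(y, p, eps=1e-7):
    total, n = 0.0, 0
    for yi, pi in zip(np.ravel(y), np.ravel(p)):
        pi = min(max(pi, eps), 1 - eps)
        total += -(yi * math.log(pi) + (1 - yi) * math.log(1 - pi))
        n += 1
    return total / n


def focal_oracle(y, p, alpha, gamma, eps=1e-7):
    total, n = 0.0, 0
    for yi, pi in zip(np.ravel(y), np.ravel(p)):
        pi = min(max(pi, eps), 1 - eps)
        pt = pi if yi == 1 else 1 - pi
        total += alpha * (1 - pt) ** gamma * (-math.log(pt))
        n += 1
    return total / n


def dice_oracle(y, p, smooth):
    c = y.shape[-1]
    losses = []
    for ch in range(c):
        inter = num = den = 0.0
        for yi, pi in zip(np.ravel(y[..., ch]), np.ravel(p[..., ch])):
            inter += yi * pi
            num += yi
            den += pi
        losses.append(1 - (2 * inter + smooth) / (num + den + smooth))
    return sum(losses) / c


def cce_oracle(y, p, eps=1e-7):
    flat_y = y.reshape(-1, y.shape[-1])
    flat_p = p.reshape(-1, p.shape[-1])
    total = 0.0
    for yrow, prow in zip(flat_y, flat_p):
        for yc, pc in zip(yrow, prow):
            pc = min(max(pc, eps), 1 - eps)
            total += -yc * math.log(pc)
    return total / len(flat_y)


def random_pair(rng, shape=(8, 8, 2)):
    logits = rng.normal(size=shape)
    p = np.exp(logits) / np.exp(logits).sum(axis=-1, keepdims=True)
    y = np.eye(shape[-1])[rng.integers(0, shape[-1], shape[:-1])]
    return y, p


# -- closed-form examples ----------------------------------------------------

class TestClosedForms:
    def test_bce_half_probability_is_ln2(self):
        assert bce_loss(np.array([1.0]), np.array([0.5])) == \
            pytest.approx(math.log(2), abs=1e-9)

    def test_bce_crisp_correct_is_near_zero(self):
        y = np.eye(2)[np.array([[0, 1], [1, 0]])]
        assert bce_loss(y, y) == pytest.approx(0.0, abs=1e-6)

    def test_dice_toy_one_third(self):
        cfg = LossConfig(smooth=0.0)
        # single channel y=[1,0], p=[1,1]: 1 - 2*1/(1+2) = 1/3
        v = dice_loss(np.array([[1.0], [0.0]]), np.array([[1.0], [1.0]]), cfg)
        assert v == pytest.approx(1 / 3, abs=1e-12)

    def test_dice_perfect_overlap_is_zero(self):
        y = np.eye(2)[np.array([[0, 1], [1, 0]])]
        assert dice_loss(y, y) == pytest.approx(0.0, abs=1e-12)

    def test_dice_empty_channel_with_smoothing(self):
        # both empty: (0 + s)/(0 + s) = 1 -> channel loss 0
        y = np.zeros((4, 1))
        assert dice_loss(y, y, LossConfig(smooth=1.0)) == pytest.approx(0.0)

    def test_focal_toy_value(self):
        # y=1, p=0.5, alpha=.5, gamma=2: 0.5 * 0.25 * ln 2
        v = focal_loss(np.array([1.0]), np.array([0.5]),
                       LossConfig(alpha=0.5, gamma=2.0))
        assert v == pytest.approx(0.5 * 0.25 * math.log(2), abs=1e-9)

    def test_focal_reduces_to_bce(self, rng):
        y, p = random_pair(rng)
        cfg = LossConfig(alpha=1.0, gamma=0.0)
        assert focal_loss(y, p, cfg) == pytest.approx(bce_loss(y, p, cfg), abs=1e-9)

    def test_cce_uniform_four_class(self):
        y = np.zeros((1, 4))
        y[0, 2] = 1.0
        p = np.full((1, 4), 0.25)
        assert cce_loss(y, p) == pytest.approx(math.log(4), abs=1e-9)

    def test_cce_crisp_correct_near_zero(self):
        y = np.eye(4)[np.array([[0, 1], [2, 3]])]
        assert cce_loss(y, y.astype(float)) == pytest.approx(0.0, abs=1e-5)


class TestCompoundStructure:
    def test_unit_weights_sum(self, rng):
        y, p = random_pair(rng)
        assert bce_dice_loss(y, p) == \
            pytest.approx(bce_loss(y, p) + dice_loss(y, p), abs=1e-12)

    def test_lambda_weighting(self, rng):
        y, p = random_pair(rng)
        only_dice = LossConfig(lambda1=0.0, lambda2=1.0)
        assert bce_dice_loss(y, p, only_dice) == pytest.approx(dice_loss(y, p))
        double_bce = LossConfig(lambda1=2.0, lambda2=0.0)
        assert bce_dice_loss(y, p, double_bce) == \
            pytest.approx(2 * bce_loss(y, p))

    def test_cce_dice_composition(self, rng):
        y, p = random_pair(rng, (6, 6, 4))
        assert cce_dice_loss(y, p) == \
            pytest.approx(cce_loss(y, p) + dice_loss(y, p), abs=1e-12)

    def test_linearity_in_lambdas(self, rng):
        y, p = random_pair(rng)
        v1 = bce_dice_loss(y, p, LossConfig(lambda1=0.3, lambda2=1.7))
        assert v1 == pytest.approx(0.3 * bce_loss(y, p) + 1.7 * dice_loss(y, p))


class TestLoopOracles:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_bce_matches_loop(self, seed):
        y, p = random_pair(np.random.default_rng(seed))
        assert bce_loss(y, p) == pytest.approx(bce_oracle(y, p), abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_focal_matches_loop(self, seed):
        y, p = random_pair(np.random.default_rng(seed))
        assert focal_loss(y, p) == \
            pytest.approx(focal_oracle(y, p, CFG.alpha, CFG.gamma), abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_dice_matches_loop(self, seed):
        y, p = random_pair(np.random.default_rng(seed))
        assert dice_loss(y, p) == \
            pytest.approx(dice_oracle(y, p, CFG.smooth), abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_cce_matches_loop(self, seed):
        y, p = random_pair(np.random.default_rng(seed), (5, 5, 4))
        assert cce_loss(y, p) == pytest.approx(cce_oracle(y, p), abs=1e-6)


class TestProperties:
    def test_all_losses_non_negative_finite(self, rng):
        y, p = random_pair(rng)
        for name in ("bce", "dice", "focal", "bce_dice", "cce", "cce_dice"):
            v = get_loss(name)(y, p)
            assert np.isfinite(v) and v >= 0.0

    def test_focal_bounded_by_bce_at_alpha_one(self, rng):
        y, p = random_pair(rng)
        for gamma in (0.0, 0.5, 2.0, 5.0):
            cfg = LossConfig(alpha=1.0, gamma=gamma)
            assert focal_loss(y, p, cfg) <= bce_loss(y, p, cfg) + 1e-12

    def test_pixel_permutation_invariance(self, rng):
        y, p = random_pair(rng, (16, 2))
        perm = rng.permutation(16)
        assert bce_loss(y, p) == pytest.approx(bce_loss(y[perm], p[perm]))
        assert dice_loss(y, p) == pytest.approx(dice_loss(y[perm], p[perm]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            bce_loss(np.zeros((2, 2)), np.zeros((2, 3)))

    def test_non_one_hot_rejected_by_cce(self):
        y = np.full((2, 4), 0.25)
        with pytest.raises(ValueError, match="one-hot"):
            cce_loss(y, y)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(alpha=0.0)
        with pytest.raises(ValueError):
            LossConfig(gamma=-1.0)
        with pytest.raises(ValueError):
            LossConfig(clip_eps=0.7)


class TestGradients:
    """Analytic loss gradients against central differences."""

    @pytest.mark.parametrize("grad_fn", [bce_loss_grad, dice_loss_grad,
                                         focal_loss_grad])
    def test_gradient_matches_numeric(self, grad_fn, rng):
        y, p = random_pair(rng, (4, 4, 2))
        p = 0.02 + 0.96 * p  # keep away from the clipping boundary
        _, g = grad_fn(y, p)
        flat = p.reshape(-1)
        for i in rng.integers(0, flat.size, size=8):
            eps = 1e-6
            orig = flat[i]
            flat[i] = orig + eps
            vp = grad_fn(y, p)[0]
            flat[i] = orig - eps
            vm = grad_fn(y, p)[0]
            flat[i] = orig
            assert g.reshape(-1)[i] == pytest.approx(
                (vp - vm) / (2 * eps), rel=1e-4, abs=1e-8)
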