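"""Loss components against independent scalar oracles."""

import numpy as np
import pytest

from mpdc import losses as L
from mpdc.autodiff import Tensor, softmax_channels
from mpdc.decoupling import DecoupleMasks, decouple, split_confidence
from mpdc.network import MPDCNet, NetworkConfig, PerspectiveOutputs


def softmax_np(x):
    e = np.exp(x - np.max(x))
    return e / e.sum()


def outputs_from_scores(o_pos, o_rev=None, o_fus=None):
    """PerspectiveOutputs built directly from raw score arrays."""
    o_pos = Tensor(np.asarray(o_pos, dtype=np.float32))
    out = PerspectiveOutputs(
        O_pos=o_pos, O_rev=None, O_fus=None,
        P_pos=softmax_channels(o_pos), P_rev=None, P_fus=None)
    if o_rev is not None:
        out.O_rev = Tensor(np.asarray(o_rev, dtype=np.float32))
        out.P_rev = softmax_channels(-out.O_rev)
    if o_fus is not None:
        out.O_fus = Tensor(np.asarray(o_fus, dtype=np.float32))
        out.P_fus = softmax_channels(out.O_fus)
    return out


class TestDiceLoss:
    def test_perfect_onehot_prediction(self):
        gt = L.one_hot(np.array([[[0, 1], [1, 0]]]), 2)
        assert L.dice_loss(Tensor(gt), gt).item() == pytest.approx(0.0, abs=1e-4)

    def test_uniform_prediction_scalar_oracle(self):
        # single pixel, gt class 1: fg Dice 2*0.5/1.5, bg Dice ~0 -> loss ~2/3
        p = Tensor(np.full((1, 2, 1, 1), 0.5, dtype=np.float32))
        gt = L.one_hot(np.ones((1, 1, 1), dtype=np.int64), 2)
        assert L.dice_loss(p, gt).item() == pytest.approx(2 / 3, abs=1e-3)

    def test_permutation_invariant_to_pixel_order(self, rng):
        p = rng.dirichlet(np.ones(2), size=(1, 4, 4)).transpose(0, 3, 1, 2).astype(np.float32)
        gt = rng.integers(0, 2, size=(1, 4, 4))
        perm = rng.permutation(16)
        p2 = p.reshape(1, 2, 16)[:, :, perm].reshape(1, 2, 4, 4)
        gt2 = gt.reshape(1, 16)[:, perm].reshape(1, 4, 4)
        a = L.dice_loss(Tensor(p), L.one_hot(gt, 2)).item()
        b = L.dice_loss(Tensor(p2), L.one_hot(gt2, 2)).item()
        assert a == pytest.approx(b, abs=1e-6)


class TestSupervisedLosses:
    def test_unlabeled_items_contribute_nothing(self, rng):
        scores = rng.normal(size=(4, 2, 4, 4)).astype(np.float32)
        labels = rng.integers(0, 2, size=(4, 4, 4))
        a = L.supervised_losses(outputs_from_scores(scores, -scores, scores), labels, 2)
        # mutate the unlabeled half arbitrarily: losses unchanged
        scores2 = scores.copy()
        scores2[2:] += 100.0
        b = L.supervised_losses(outputs_from_scores(scores2, -scores2, scores2), labels, 2)
        for x, y in zip(a, b):
            assert x.item() == pytest.approx(y.item(), abs=1e-6)

    def test_matched_positive_and_reverse_scores_give_equal_losses(self, rng):
        # O_rev = -O_pos makes P_rev identical to P_pos
        scores = rng.normal(size=(2, 2, 4, 4)).astype(np.float32)
        labels = rng.integers(0, 2, size=(2, 4, 4))
        sup_p, sup_r, _ = L.supervised_losses(outputs_from_scores(scores, -scores), labels, 2)
        assert sup_p.item() == pytest.approx(sup_r.item(), abs=1e-6)

    def test_ground_truth_inversion_arm(self):
        # with gt inversion, softmax(O_rev) is scored against the flipped truth;
        # a reverse branch that nails the background scores near zero
        labels = np.array([[[1, 0], [0, 1]]])
        o_rev = 50.0 * (2.0 * L.one_hot(1 - labels, 2) - 1.0)
        out = outputs_from_scores(np.zeros_like(o_rev), o_rev)
        _, sup_r, _ = L.supervised_losses(out, labels, 1, gt_inversion=True)
        assert sup_r.item() == pytest.approx(0.0, abs=1e-4)

    def test_no_labeled_items_returns_zeros(self, rng):
        scores = rng.normal(size=(2, 2, 4, 4)).astype(np.float32)
        res = L.supervised_losses(outputs_from_scores(scores, scores, scores),
                                  np.zeros((0, 4, 4), dtype=np.int64), 0)
        assert all(t.item() == 0.0 for t in res)


class TestDirectionConsistency:
    def _single_pixel_setup(self):
        # one pixel, pos wins: hP_pos=(0.8,0.2) vs lP_rev=(0.55,0.45)
        p = Tensor(np.array([0.8, 0.2], dtype=np.float32).reshape(1, 2, 1, 1))
        r = Tensor(np.array([0.55, 0.45], dtype=np.float32).reshape(1, 2, 1, 1))
        masks = DecoupleMasks(
            consistent=np.zeros((1, 1, 1), bool),
            inconsistent=np.ones((1, 1, 1), bool),
            high_pos=np.ones((1, 1, 1), bool),
            high_rev=np.zeros((1, 1, 1), bool))
        return p, r, masks

    def test_single_pixel_scalar_oracle(self):
        p, r, masks = self._single_pixel_setup()
        h_pos, l_pos, h_rev, l_rev = split_confidence(p, r, masks)
        loss = L.direction_consistency_loss(h_pos, l_pos, h_rev, l_rev, masks)
        # mean((0.25^2 + 0.25^2)/2 classes) = 0.0625
        assert loss.item() == pytest.approx(0.0625, abs=1e-6)

    def test_zero_when_low_side_matches_high_side(self, rng):
        p = Tensor(rng.dirichlet(np.ones(2), size=(1, 3, 3)).transpose(0, 3, 1, 2).astype(np.float32))
        masks = decouple(p, p + Tensor(np.full(p.shape, 1e-4, dtype=np.float32)), 0.99)
        h_pos, l_pos, h_rev, l_rev = split_confidence(p, p, masks)
        assert L.direction_consistency_loss(h_pos, l_pos, h_rev, l_rev, masks).item() == pytest.approx(0.0, abs=1e-9)

    def test_empty_masks_give_zero(self):
        z = Tensor(np.zeros((1, 2, 2, 2), dtype=np.float32))
        masks = DecoupleMasks(np.ones((1, 2, 2), bool), np.zeros((1, 2, 2), bool),
                              np.zeros((1, 2, 2), bool), np.zeros((1, 2, 2), bool))
        assert L.direction_consistency_loss(z, z, z, z, masks).item() == 0.0

    def test_high_confidence_side_receives_no_gradient(self):
        p_scores = Tensor(np.array([1.0, -1.0], dtype=np.float32).reshape(1, 2, 1, 1),
                          requires_grad=True)
        r_scores = Tensor(np.array([0.2, -0.2], dtype=np.float32).reshape(1, 2, 1, 1),
                          requires_grad=True)
        p, r = softmax_channels(p_scores), softmax_channels(r_scores)
        masks = DecoupleMasks(np.zeros((1, 1, 1), bool), np.ones((1, 1, 1), bool),
                              np.ones((1, 1, 1), bool), np.zeros((1, 1, 1), bool))
        h_pos, l_pos, h_rev, l_rev = split_confidence(p, r, masks)
        L.direction_consistency_loss(h_pos, l_pos, h_rev, l_rev, masks).backward()
        assert p_scores.grad is None or not np.abs(p_scores.grad).any()
        assert np.abs(r_scores.grad).max() > 0


class TestCpsLoss:
    def _consistent_outputs(self, rng, b=1, size=4):
        o = rng.normal(size=(b, 2, size, size)).astype(np.float32) * 3
        out = outputs_from_scores(o, -o, o)
        masks = decouple(out.P_pos.data, out.P_rev.data, 0.0)
        assert masks.consistent.all()
        return out, masks

    def test_gate_term_counts(self, rng):
        out, masks = self._consistent_outputs(rng)
        _, n_low = L.cps_loss(out, masks, m_confidence=0.94)
        _, n_high = L.cps_loss(out, masks, m_confidence=0.96)
        assert n_low == 2
        assert n_high == 6

    def test_single_pixel_scalar_ce_oracle(self):
        # consistent pixel, O_pos=(2,0), pseudo-label from rev = 0:
        # CE = -log softmax(2,0)[0] = 0.1269
        o_pos = np.array([2.0, 0.0], dtype=np.float32).reshape(1, 2, 1, 1)
        o_rev = np.array([-3.0, 3.0], dtype=np.float32).reshape(1, 2, 1, 1)  # P_rev favors class 0
        out = outputs_from_scores(o_pos, o_rev, o_pos)
        masks = decouple(out.P_pos.data, out.P_rev.data, 0.0)
        loss, n = L.cps_loss(out, masks, m_confidence=0.96, pairs=("P-R",))
        expected_term1 = -np.log(softmax_np(np.array([2.0, 0.0]))[0])
        # second term: CE(-O_rev=(3,-3), PL_pos=0) = -log softmax(3,-3)[0]
        expected_term2 = -np.log(softmax_np(np.array([3.0, -3.0]))[0])
        assert n == 2
        assert loss.item() == pytest.approx(expected_term1 + expected_term2, abs=1e-4)
        assert expected_term1 == pytest.approx(0.1269, abs=1e-4)

    def test_agreeing_confident_branches_give_vanishing_loss(self, rng):
        lab = rng.integers(0, 2, size=(1, 4, 4))
        o = 60.0 * (2.0 * L.one_hot(lab, 2) - 1.0)
        out = outputs_from_scores(o, -o, o)
        masks = decouple(out.P_pos.data, out.P_rev.data, 0.0)
        loss, _ = L.cps_loss(out, masks, m_confidence=0.96)
        assert loss.item() == pytest.approx(0.0, abs=1e-6)

    def test_empty_consistent_part_returns_zero(self, rng):
        out, _ = self._consistent_outputs(rng)
        masks = decouple(out.P_pos.data, out.P_rev.data, 1.0)
        loss, n = L.cps_loss(out, masks, m_confidence=0.96)
        assert loss.item() == 0.0 and n == 0

    def test_pseudo_labels_carry_no_gradient(self, rng):
        o_pos = Tensor(rng.normal(size=(1, 2, 3, 3)).astype(np.float32), requires_grad=True)
        o_rev = Tensor(rng.normal(size=(1, 2, 3, 3)).astype(np.float32), requires_grad=True)
        out = PerspectiveOutputs(O_pos=o_pos, O_rev=o_rev, O_fus=None,
                                 P_pos=softmax_channels(o_pos),
                                 P_rev=softmax_channels(-o_rev), P_fus=None)
        masks = decouple(out.P_pos.data, out.P_rev.data, 0.0)
        loss, _ = L.cps_loss(out, masks, m_confidence=0.5)
        loss.backward()
        # both score tensors receive gradient only through their CE operand
        # (pseudo-labels are integer arrays, structurally gradient-free);
        # the loss must nonetheless be differentiable end to end
        assert o_pos.grad is not None or o_rev.grad is not None


class TestChannelCompressAndFeatureLoss:
    def test_two_channel_scalar_oracle(self):
        f = Tensor(np.array([3.0, -4.0], dtype=np.float32).reshape(1, 2, 1, 1))
        assert L.channel_compress(f, p=2).item() == pytest.approx(12.5)

    def test_zero_input_and_sign_invariance(self, rng):
        z = Tensor(np.zeros((1, 3, 2, 2), dtype=np.float32))
        assert not L.channel_compress(z).data.any()
        f = rng.normal(size=(1, 3, 2, 2)).astype(np.float32)
        a = L.channel_compress(Tensor(f)).data
        b = L.channel_compress(Tensor(-f)).data
        np.testing.assert_allclose(a, b, atol=1e-7)

    def test_identical_pyramids_give_zero(self, rng):
        pyr = [Tensor(rng.normal(size=(1, 4, s, s)).astype(np.float32)) for s in (8, 4)]
        assert L.feature_consistency_loss(pyr, pyr).item() == 0.0

    def test_one_pixel_oracle(self):
        e = [Tensor(np.array([[[[1.0]]]], dtype=np.float32))]
        d = [Tensor(np.array([[[[np.sqrt(3.0)]]]], dtype=np.float32))]
        # compressed values 1 and 3 -> (3-1)^2 = 4
        assert L.feature_consistency_loss(e, d).item() == pytest.approx(4.0, abs=1e-4)

    def test_noise_strictly_increases_loss(self, rng):
        e = [Tensor(rng.normal(size=(1, 4, 4, 4)).astype(np.float32))]
        base = L.feature_consistency_loss(e, e).item()
        for _ in range(10):
            noisy = [Tensor(e[0].data + rng.normal(0, 0.5, e[0].shape).astype(np.float32))]
            assert L.feature_consistency_loss(e, noisy).item() > base

    def test_level_count_mismatch_rejected(self, rng):
        pyr = [Tensor(rng.normal(size=(1, 4, 4, 4)).astype(np.float32))]
        with pytest.raises(ValueError):
            L.feature_consistency_loss([], pyr)


class TestTotalLoss:
    def test_additivity(self):
        vals = (0.1, 0.2, 0.3, 0.05, 0.02, 0.03)
        ts = [Tensor(np.float32(v)) for v in vals]
        total, bundle = L.total_loss(*ts)
        assert total.item() == pytest.approx(0.70, abs=1e-6)
        assert bundle.total == pytest.approx(sum(vals), abs=1e-6)

    def test_all_zero(self):
        total, bundle = L.total_loss(*[Tensor(np.float32(0.0))] * 6)
        assert total.item() == 0.0 and bundle.total == 0.0

    def test_nan_component_raises_named_error(self):
        ts = [Tensor(np.float32(0.0))] * 5 + [Tensor(np.float32(np.nan))]
        with pytest.raises(FloatingPointError, match="feat"):
            L.total_loss(*ts)


class TestFuzz:
    def test_all_components_nonnegative_and_finite(self, rng):
        for _ in range(200):
            b, c, s = 1, 2, 4
            scores = rng.normal(size=(b, c, s, s)).astype(np.float32) * 5
            out = outputs_from_scores(scores, rng.normal(size=scores.shape).astype(np.float32),
                                      rng.normal(size=scores.shape).astype(np.float32))
            labels = rng.integers(0, c, size=(b, s, s))
            sup = L.supervised_losses(out, labels, b)
            gamma = rng.uniform(0.5, 1.0)
            masks = decouple(out.P_pos.data, out.P_rev.data, gamma)
            hp, lp, hr, lr = split_confidence(out.P_pos, out.P_rev, masks)
            dc = L.direction_consistency_loss(hp, lp, hr, lr, masks)
            m = L.mean_confidence(out.P_pos, out.P_rev)
            cps, _ = L.cps_loss(out, masks, m)
            for t in (*sup, dc, cps):
                assert np.isfinite(t.item()) and t.item() >= -1e-7

    def test_equal_prediction_fixpoint(self, rng):
        # identical confident branches, consistent everywhere: cps + dc = 0
        lab = rng.integers(0, 2, size=(1, 4, 4))
        o = 60.0 * (2.0 * L.one_hot(lab, 2) - 1.0)
        out = outputs_from_scores(o, -o, o)
        masks = decouple(out.P_pos.data, out.P_rev.data, 0.5)
        assert masks.consistent.all()
        hp, lp, hr, lr = split_confidence(out.P_pos, out.P_rev, masks)
        dc = L.direction_consistency_loss(hp, lp, hr, lr, masks)
        cps, _ = L.cps_loss(out, masks, L.mean_confidence(out.P_pos, out.P_rev))
        assert dc.item() + cps.item() == pytest.approx(0.0, abs=1e-6)
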