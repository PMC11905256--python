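"""Losses, warm-up, EMA and training-loop contracts of the mean-teacher engine."""

import numpy as np
import pytest

from ssdaseg._tensor import Tensor
from ssdaseg.mean_teacher import (LossWeights, TrainConfig, consistency_loss,
                                  consistency_weight, cross_entropy_loss,
                                  effective_lambda, ema_update, soft_dice_loss,
                                  supervised_loss, total_loss, train)
from ssdaseg.nn import BatchNorm3d, Linear, Module, Sequential
from ssdaseg.optim import stepwise_exponential_lr


def _perfect_pred(target, n_classes=5):
    oh = np.zeros((target.shape[0], n_classes) + target.shape[1:], dtype=np.float64)
    for c in range(n_classes):
        oh[:, c][target == c] = 1.0
    return oh


class TestSupervisedLoss:
    def test_perfect_prediction_gives_zero(self, rng):
        t = rng.integers(0, 5, size=(2, 4, 4, 4))
        loss = supervised_loss(Tensor(_perfect_pred(t)), t, LossWeights())
        assert loss.item() == pytest.approx(0.0, abs=1e-5)

    def test_uniform_prediction_ce_is_log5(self, rng):
        t = rng.integers(0, 5, size=(1, 3, 3, 3))
        pred = np.full((1, 5, 3, 3, 3), 0.2)
        ce = cross_entropy_loss(Tensor(pred), t)
        assert ce.item() == pytest.approx(np.log(5.0), abs=1e-6)

    def test_dice_hand_example_two_voxels(self):
        """pred class-1 probabilities (1, 0) against target (1, 1):
        soft dice for class 1 = 2/3, per-class dice loss contribution 1/3."""
        pred = np.zeros((1, 2, 1, 1, 2))
        pred[0, 1, 0, 0, 0] = 1.0      # voxel 0 -> class 1
        pred[0, 0, 0, 0, 1] = 1.0      # voxel 1 -> class 0
        target = np.ones((1, 1, 1, 2), dtype=np.int64)
        loss = soft_dice_loss(Tensor(pred), target)
        # class 1: 2*1/(1+2) = 2/3; class 0: 2*0/(1+0) -> 0; mean dice = 1/3
        assert loss.item() == pytest.approx(1.0 - (2.0 / 3.0 + 0.0) / 2.0, abs=1e-5)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="must equal 1"):
            LossWeights(lam_dice=0.5, lam_ce=0.3).validate()

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            supervised_loss(Tensor(np.zeros((0, 5, 2, 2, 2))),
                            np.zeros((0, 2, 2, 2), dtype=int), LossWeights())


class TestConsistencyLoss:
    def test_identical_predictions_give_zero(self, rng):
        p = rng.random((2, 5, 3, 3, 3))
        assert consistency_loss(Tensor(p), p).item() == pytest.approx(0.0)

    def test_constant_offset_closed_form(self, rng):
        p = rng.random((1, 5, 2, 2, 2))
        assert consistency_loss(Tensor(p), p + 0.1).item() == pytest.approx(0.01, abs=1e-9)

    def test_symmetric(self, rng):
        a, b = rng.random((2, 1, 5, 2, 2, 2))
        assert consistency_loss(Tensor(a), b).item() == \
            pytest.approx(consistency_loss(Tensor(b), a).item())

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            consistency_loss(Tensor(np.zeros((1, 5, 2, 2, 2))),
                             np.zeros((1, 5, 2, 2, 4)))


class TestConsistencyWeight:
    def test_final_iteration_reaches_amplitude(self):
        assert consistency_weight(1000, 1000) == pytest.approx(0.1, abs=0)

    def test_initial_value_closed_form(self):
        assert consistency_weight(0, 1000) == \
            pytest.approx(0.1 * np.exp(-5.0), abs=1e-12)

    def test_monotone_on_dense_grid(self):
        k_max = 997
        vals = [consistency_weight(k, k_max) for k in range(k_max + 1)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_zero_kmax_rejected(self):
        with pytest.raises(ValueError, match="k_max"):
            consistency_weight(0, 0)


class TestTotalLoss:
    def test_lambda_zero_reduces_to_supervised(self):
        w = LossWeights(lam=0.0)
        loss, lam_eff = total_loss(1.3, 0.7, w, 10, 100)
        assert loss == pytest.approx(1.3)
        assert lam_eff == 0.0

    def test_final_step_arithmetic(self):
        w = LossWeights(lam=2.0)
        loss, lam_eff = total_loss(1.0, 0.5, w, 100, 100)
        assert lam_eff == pytest.approx(2.0)
        assert loss == pytest.approx(2.0)

    def test_zero_unsupervised_term(self):
        loss, _ = total_loss(0.42, 0.0, LossWeights(lam=3.0), 50, 100)
        assert loss == pytest.approx(0.42)


class _ToyModule(Module):
    def __init__(self, value):
        super().__init__()
        self.lin = Linear(2, 2)
        self.lin.weight.data = np.full((2, 2), value, dtype=np.float64)
        self.bn = BatchNorm3d(2)


class TestEMA:
    def test_eta_zero_copies_student(self):
        s, t = _ToyModule(3.0), _ToyModule(7.0)
        ema_update(s, t, 0.0)
        np.testing.assert_array_equal(t.lin.weight.data, s.lin.weight.data)

    def test_eta_one_freezes_teacher(self):
        s, t = _ToyModule(3.0), _ToyModule(7.0)
        ema_update(s, t, 1.0)
        np.testing.assert_array_equal(t.lin.weight.data, np.full((2, 2), 7.0))

    @pytest.mark.parametrize("eta", [0.0, 0.5, 0.99, 1.0])
    def test_constant_student_closed_form(self, eta):
        """m iterated updates against η^m t0 + (1-η^m) s, to 1e-10."""
        m = 25
        t0, sval = 7.0, 3.0
        s, t = _ToyModule(sval), _ToyModule(t0)
        for _ in range(m):
            ema_update(s, t, eta)
        want = eta ** m * t0 + (1 - eta ** m) * sval
        np.testing.assert_allclose(t.lin.weight.data, want, atol=1e-10)

    def test_running_stats_follow_same_rule(self):
        s, t = _ToyModule(1.0), _ToyModule(1.0)
        s.bn.set_buffer("running_mean", np.full(2, 4.0, dtype=np.float32))
        t.bn.set_buffer("running_mean", np.zeros(2, dtype=np.float32))
        ema_update(s, t, 0.5)
        np.testing.assert_allclose(t.bn.running_mean, 2.0)

    def test_topology_mismatch_rejected(self):
        class Other(Module):
            def __init__(self):
                super().__init__()
                self.other = Linear(2, 2)

        with pytest.raises(ValueError, match="topology"):
            ema_update(_ToyModule(1.0), Other(), 0.5)


class TestLrSchedule:
    def test_stepwise_exponential_values(self):
        assert stepwise_exponential_lr(9e-4, 0) == pytest.approx(9e-4)
        assert stepwise_exponential_lr(9e-4, 249) == pytest.approx(9e-4)
        assert stepwise_exponential_lr(9e-4, 250) == pytest.approx(9e-4 * 0.95)
        assert stepwise_exponential_lr(9e-4, 500) == pytest.approx(9e-4 * 0.95 ** 2)


class TestTrainingLoop:
    def test_smoke_run_history_contract(self, tiny_dataset, tiny_net_cfg):
        res = train(tiny_dataset, tiny_net_cfg, LossWeights(),
                    TrainConfig(steps=4, augment=False), seed=7)
        h = res.history
        assert len(h) == 4
        assert np.isfinite(h[["loss_sup", "loss_un", "loss_total"]].values).all()
        # loss decomposition identity at every step
        np.testing.assert_allclose(h["loss_total"],
                                   h["loss_sup"] + h["lambda_eff"] * h["loss_un"],
                                   rtol=1e-5, atol=1e-7)

    def test_teacher_receives_no_gradients(self, tiny_dataset, tiny_net_cfg):
        res = train(tiny_dataset, tiny_net_cfg, LossWeights(),
                    TrainConfig(steps=2, augment=False), seed=1)
        assert all(p.grad is None for p in res.teacher.parameters())

    def test_lambda_zero_matches_plain_supervised_trajectory(self, tiny_dataset,
                                                             tiny_net_cfg):
        """With λ=0 the student's weight trajectory equals a run without the
        whole teacher/consistency machinery, given identical seeds."""
        a = train(tiny_dataset, tiny_net_cfg, LossWeights(lam=0.0),
                  TrainConfig(steps=3, augment=False), seed=5)
        b = train(tiny_dataset, tiny_net_cfg, LossWeights(lam=0.0),
                  TrainConfig(steps=3, augment=False, use_semt=False), seed=5)
        sa, sb = a.student.state_dict(), b.student.state_dict()
        assert sa.keys() == sb.keys()
        for key in sa:
            np.testing.assert_array_equal(sa[key], sb[key])

    def test_same_seed_reproduces_history(self, tiny_dataset, tiny_net_cfg):
        cfg = TrainConfig(steps=3, augment=True)
        h1 = train(tiny_dataset, tiny_net_cfg, LossWeights(), cfg, seed=9).history
        h2 = train(tiny_dataset, tiny_net_cfg, LossWeights(), cfg, seed=9).history
        assert h1.equals(h2)

    def test_empty_tu_disables_consistency_with_warning(self, phantom_spec,
                                                        tiny_net_cfg):
        from ssdaseg.synthetic import generate_dataset
        spec = type(phantom_spec)(grid_size=(16, 16, 8))
        ds = generate_dataset(spec, 2, 2, 1.0, seed=0, n_test=1)
        assert not ds.TU
        with pytest.warns(UserWarning, match="TU is empty"):
            res = train(ds, tiny_net_cfg, LossWeights(),
                        TrainConfig(steps=2, augment=False), seed=0)
        assert (res.history["loss_un"] == 0).all()
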