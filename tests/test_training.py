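"""Loss terms against hand-computed oracles; gradient checks; training loops."""

import numpy as np
import pytest

from limitedct import (LossWeights, NetPlan, TrainConfig, build_autoencoder,
                       build_discriminator, loss_adv, loss_ae, loss_disc,
                       loss_mse, loss_reg, train_autoencoder, train_stage)
from limitedct._autodiff import Tensor


class FixedScoreDisc:
    """A stand-in discriminator returning a fixed score (for boundary cases)."""

    def __init__(self, score):
        self.score = score

    def forward(self, x):
        n = x.data.shape[0] if isinstance(x, Tensor) else x.shape[0]
        return Tensor(np.full(n, self.score))


class TestLossMSE:
    def test_identical_arrays_give_zero(self, rng):
        x = rng.random((2, 1, 8, 8))
        assert loss_mse(x, x).item() == 0.0

    def test_hand_computed_2x2_case(self):
        gt = np.ones((1, 1, 2, 2))
        pred = np.array([[[[0.0, 1.0], [1.0, 1.0]]]])
        assert loss_mse(pred, gt).item() == pytest.approx(0.25)

    def test_quadratic_homogeneity(self, rng):
        gt = rng.random((1, 1, 4, 4))
        resid = rng.random((1, 1, 4, 4))
        l1 = loss_mse(gt + resid, gt).item()
        l3 = loss_mse(gt + 3.0 * resid, gt).item()
        assert l3 == pytest.approx(9.0 * l1)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            loss_mse(np.zeros((1, 1, 4, 4)), np.zeros((1, 1, 4, 5)))


class TestLossReg:
    def test_constant_image_gives_zero_gradient_energy(self):
        # the smoothing constant 1e-8 leaves a floor of sqrt(eps) = 1e-4
        assert loss_reg(np.full((1, 1, 8, 8), 0.7)).item() <= 1e-4 + 1e-12

    def test_hand_computed_1x2_case(self):
        """[0, 1]: one unit forward difference over two pixels -> 0.5."""
        img = np.array([[[[0.0, 1.0]]]])
        assert loss_reg(img).item() == pytest.approx(0.5, abs=1e-3)

    def test_invariant_to_constant_shift(self, rng):
        img = rng.random((1, 1, 8, 8))
        a = loss_reg(img).item()
        b = loss_reg(img + 3.21).item()
        assert a == pytest.approx(b, rel=1e-12)


class TestLossAdvAndDisc:
    def test_adv_boundary_cases(self, rng):
        pred = rng.random((2, 1, 8, 8))
        assert loss_adv(pred, FixedScoreDisc(1.0)).item() == pytest.approx(0.0)
        assert loss_adv(pred, FixedScoreDisc(0.0)).item() == pytest.approx(1.0)

    def test_adv_monotone_decreasing_in_score(self, rng):
        pred = rng.random((1, 1, 8, 8))
        vals = [loss_adv(pred, FixedScoreDisc(s)).item()
                for s in (0.1, 0.5, 0.9)]
        assert vals[0] > vals[1] > vals[2]

    def test_disc_boundary_cases(self, rng):
        gt = rng.random((1, 1, 8, 8))
        pred = rng.random((1, 1, 8, 8))

        class TwoScoreDisc:
            def __init__(self, s_gt, s_pred):
                self.scores = iter([s_gt, s_pred])

            def forward(self, x):
                return Tensor(np.array([next(self.scores)]))

        assert loss_disc(gt, pred, TwoScoreDisc(1.0, 0.0)).item() == 0.0
        assert loss_disc(gt, pred, TwoScoreDisc(0.0, 1.0)).item() == 2.0

    def test_disc_loss_bounded_with_real_network(self, rng):
        d = build_discriminator(NetPlan(1, 4, 2), seed=0)
        gt = rng.random((2, 1, 16, 16))
        pred = rng.random((2, 1, 16, 16))
        val = loss_disc(gt, pred, d).item()
        assert 0.0 <= val <= 2.0


class TestLossAE:
    def test_zero_when_perfect_and_fooling(self):
        gt = np.full((1, 1, 8, 8), 0.5)  # constant -> zero TV term
        total = loss_ae(gt, gt, FixedScoreDisc(1.0)).item()
        assert total == pytest.approx(0.0, abs=1e-6)

    def test_weights_1_0_0_reduce_to_mse(self, rng):
        gt = rng.random((1, 1, 8, 8))
        pred = rng.random((1, 1, 8, 8))
        w = LossWeights(1.0, 0.0, 0.0)
        assert loss_ae(pred, gt, FixedScoreDisc(0.3), w).item() == \
            pytest.approx(loss_mse(pred, gt).item())

    def test_default_weights_compose_the_three_terms(self, rng):
        gt = rng.random((1, 1, 8, 8))
        pred = rng.random((1, 1, 8, 8))
        d = FixedScoreDisc(0.4)
        w = LossWeights()
        expected = (1.0 * loss_mse(pred, gt).item()
                    + 1e-3 * loss_adv(pred, d).item()
                    + 2e-8 * loss_reg(pred).item())
        assert loss_ae(pred, gt, d, w).item() == pytest.approx(expected)

    def test_mse_term_dominates_at_default_weights(self, rng):
        gt = rng.random((1, 1, 8, 8))
        pred = gt + rng.normal(0, 0.2, size=gt.shape)
        d = FixedScoreDisc(0.5)
        w = LossWeights()
        terms = {"mse": w.alpha1 * loss_mse(pred, gt).item(),
                 "adv": w.alpha2 * loss_adv(pred, d).item(),
                 "reg": w.alpha3 * loss_reg(pred).item()}
        assert all(np.isfinite(v) for v in terms.values())
        assert terms["mse"] > terms["adv"] > terms["reg"]


class TestGradients:
    @staticmethod
    def _finite_diff(f, x, eps=1e-6):
        g = np.zeros_like(x)
        it = np.nditer(x, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            g[idx] = (f(xp) - f(xm)) / (2 * eps)
        return g

    def test_mse_gradient_matches_finite_differences(self, rng):
        gt = rng.random((1, 1, 8, 8))
        x = rng.random((1, 1, 8, 8))
        t = Tensor(x, requires_grad=True)
        loss_mse(t, gt).backward()
        fd = self._finite_diff(lambda z: loss_mse(z, gt).item(), x)
        np.testing.assert_allclose(t.grad, fd, rtol=1e-4, atol=1e-8)

    def test_reg_gradient_matches_finite_differences(self, rng):
        x = rng.random((1, 1, 8, 8))
        t = Tensor(x, requires_grad=True)
        loss_reg(t).backward()
        fd = self._finite_diff(lambda z: loss_reg(z).item(), x)
        np.testing.assert_allclose(t.grad, fd, rtol=1e-4, atol=1e-8)

    def test_network_loss_gradient_matches_finite_differences(self, rng):
        """End-to-end gradcheck through a tiny autoencoder's first conv."""
        ae = build_autoencoder(NetPlan(1, 2, 1), seed=0).train()
        x = rng.random((1, 1, 4, 4))
        gt = rng.random((1, 1, 4, 4))
        w = ae.enc[0].c1.w

        def f(wdata):
            old = w.data.copy()
            w.data = wdata
            val = loss_mse(ae.forward(x), gt).item()
            w.data = old
            return val

        for p in ae.parameters():
            p.grad = None
        loss_mse(ae.forward(x), gt).backward()
        fd = self._finite_diff(f, w.data.copy(), eps=1e-6)
        np.testing.assert_allclose(w.grad, fd, rtol=1e-4, atol=1e-7)


class TestTrainingLoop:
    def test_zero_learning_rate_leaves_parameters_unchanged(self, rng):
        x = rng.random((2, 1, 16, 16))
        y = rng.random((2, 1, 16, 16))
        plan = NetPlan(1, 4, 2)
        cfg = TrainConfig(learning_rate=0.0, max_steps=5, seed=3,
                          batch_size=2)
        res = train_autoencoder(x, y, plan, cfg, adversarial=False)
        ref = build_autoencoder(plan,
                                seed=int(np.random.default_rng(3)
                                         .integers(2 ** 31)))
        for p, q in zip(res.model.parameters(), ref.parameters()):
            np.testing.assert_array_equal(p.data, q.data)
        mses = [h["l_mse"] for h in res.history]
        assert len(set(np.round(mses, 15))) <= 2  # flat up to batch choice

    def test_same_seed_reproduces_identical_history(self, rng):
        x = rng.random((4, 1, 16, 16))
        y = rng.random((4, 1, 16, 16))
        cfg = TrainConfig(learning_rate=1e-3, max_steps=8, seed=7,
                          batch_size=2)
        a = train_autoencoder(x, y, NetPlan(1, 4, 2), cfg)
        b = train_autoencoder(x, y, NetPlan(1, 4, 2), cfg)
        assert a.history == b.history

    def test_non_finite_loss_aborts_with_step_index(self, rng):
        x = rng.random((2, 1, 16, 16))
        y = rng.random((2, 1, 16, 16)) * 1e200  # squared error overflows
        cfg = TrainConfig(learning_rate=10.0, max_steps=30, seed=0,
                          batch_size=2)
        with pytest.raises(RuntimeError, match="step"):
            train_autoencoder(x, y, NetPlan(1, 4, 2), cfg,
                              adversarial=False)

    def test_loss_history_csv(self, rng, tmp_path):
        x = rng.random((2, 1, 16, 16))
        y = rng.random((2, 1, 16, 16))
        res = train_autoencoder(x, y, NetPlan(1, 4, 2),
                                TrainConfig(max_steps=3, seed=0))
        path = tmp_path / "log.csv"
        res.history_csv(path)
        import csv

        with open(path) as fh:
            rows = list(csv.DictReader(fh))
        assert len(rows) == 3
        assert set(rows[0]) == {"step", "l_mse", "l_adv", "l_reg", "l_dis"}

    def test_spatial_stage_trains_two_blocks(self, rng):
        stacks = rng.random((3, 5, 16, 16))
        targets = rng.random((3, 16, 16))
        cfg = TrainConfig(learning_rate=1e-3, max_steps=3, seed=1,
                          batch_size=2)
        res1, res2 = train_stage("spatial", {"stacks": stacks,
                                             "targets": targets},
                                 cfg, plan=NetPlan(3, 4, 2),
                                 adversarial=False)
        assert res1.model.plan.in_channels == 3
        assert res2.model.plan.in_channels == 3
        assert len(res1.history) == 3 and len(res2.history) == 3

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError):
            train_stage("bogus", {}, TrainConfig())
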