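"""Architecture contracts, loss identities, training behaviour."""

import numpy as np
import pytest

import iaprec.autodiff as ad
import iaprec.network as net
from iaprec.apmodel import APParams, simulate_ap
from iaprec.network import (
    ArchConfig,
    LossBreakdown,
    QPIAUNet,
    TrainConfig,
    hybrid_loss,
    load_checkpoint,
    physics_loss,
    quantile_loss,
    reconstruct,
    save_checkpoint,
    total_quantile_loss,
)

TINY = ArchConfig(
    input_len=250, base_channels=4, levels=2, resblock_count=3, kernel_size=7,
)
rng = np.random.default_rng(0)


class TestBuild:
    def test_forward_shapes_and_finiteness(self):
        m = QPIAUNet(TINY, seed=0)
        x = np.zeros((3, 250), dtype=np.float32)
        v, p = m.forward(x, training=False)
        for q in TINY.quantiles:
            assert v[q].shape == (3, 250)
            assert np.all(np.isfinite(v[q].data))
            a, k, xx = p[q]
            assert a.shape == (3, 1) and k.shape == (3, 1) and xx.shape == (3, 1)
            assert np.all((a.data > 0) & (a.data < 1))
            assert np.all(k.data > 0)
            assert np.all((xx.data >= 0) & (xx.data <= 1))

    def test_parameter_count_is_pure_function_of_config(self):
        m1 = QPIAUNet(TINY, seed=0)
        m2 = QPIAUNet(TINY, seed=99)
        assert m1.n_parameters() == m2.n_parameters()

    def test_identical_seed_identical_weights(self):
        m1 = QPIAUNet(TINY, seed=5)
        m2 = QPIAUNet(TINY, seed=5)
        for a, b in zip(m1.params(), m2.params()):
            np.testing.assert_array_equal(a.data, b.data)

    def test_output_length_equals_input_length_over_config_grid(self):
        for L in (125, 200, 250):
            for levels in (1, 2):
                arch = ArchConfig(
                    input_len=L, base_channels=4, levels=levels,
                    resblock_count=levels + 1, kernel_size=5,
                )
                m = QPIAUNet(arch, seed=0)
                v, _ = m.forward(np.zeros((2, L), dtype=np.float32))
                assert all(v[q].shape == (2, L) for q in arch.quantiles)

    def test_se_block_with_zeroed_dense_layers_gates_at_half(self):
        m = QPIAUNet(TINY, seed=0)
        se = m.enc_res[0].se
        for p in (se.w1, se.b1, se.w2, se.b2):
            p.data[:] = 0.0
        x = ad.Tensor(rng.standard_normal((2, 10, 4)).astype(np.float32))
        gate = se(x)
        np.testing.assert_allclose(gate.data, 0.5, atol=1e-7)

    def test_checkpoint_roundtrip(self, tmp_path):
        m = QPIAUNet(TINY, seed=3)
        x = rng.standard_normal((2, 250)).astype(np.float32)
        v1, _ = m.forward(x)
        path = str(tmp_path / "model")
        save_checkpoint(path, m)
        m2 = load_checkpoint(path)
        v2, _ = m2.forward(x)
        for q in TINY.quantiles:
            np.testing.assert_array_equal(v1[q].data, v2[q].data)


def _params(batch, a=0.15, k=8.0, x=0.5):
    return (
        ad.Tensor(np.full((batch, 1), a, np.float32)),
        ad.Tensor(np.full((batch, 1), k, np.float32)),
        ad.Tensor(np.full((batch, 1), x, np.float32)),
    )


class TestLosses:
    def test_beta_zero_hybrid_equals_alpha_times_mae(self):
        cfg = TrainConfig(alpha=10.0, beta=0.0)
        actual = rng.random((4, 100)).astype(np.float32)
        lb = hybrid_loss(ad.Tensor(actual), actual, _params(4), cfg)
        assert lb.total == 0.0
        lb2 = hybrid_loss(ad.Tensor(actual + 0.01), actual, _params(4), cfg)
        assert lb2.total == pytest.approx(0.1, rel=1e-5)

    def test_pinball_half_mae_identity(self):
        actual = rng.random((3, 50)).astype(np.float32)
        pred = ad.Tensor(actual + rng.standard_normal((3, 50)).astype(np.float32) * 0.1)
        mae = float(np.mean(np.abs(pred.data - actual)))
        assert float(quantile_loss(pred, actual, 0.5).data) == pytest.approx(0.5 * mae, rel=1e-5)

    def test_pinball_asymmetry(self):
        actual = np.full((2, 10), 0.5, np.float32)
        below = ad.Tensor(actual - 0.1)
        above = ad.Tensor(actual + 0.1)
        assert float(quantile_loss(below, actual, 0.95).data) == pytest.approx(0.095, rel=1e-5)
        assert float(quantile_loss(above, actual, 0.95).data) == pytest.approx(0.005, rel=1e-5)

    def test_log_term_vanishes_when_physics_sum_is_one(self):
        cfg = TrainConfig(alpha=1.0, beta=5.0)
        actual = rng.random((2, 30)).astype(np.float32)
        preds = {q: ad.Tensor(actual) for q in (0.05, 0.5, 0.95)}
        lp = ad.Tensor(np.float32(1.0 / 3.0))

        # monkeypatch-free: identical heads, physics term forced to sum 1
        lb = total_quantile_loss(preds, actual, {q: _params(2) for q in preds}, cfg)
        # data terms are 0 (pred == actual); total = beta * log(sum L_p)
        lp_sum = sum(lb.physics_terms.values())
        assert lb.total == pytest.approx(cfg.beta * np.log(lp_sum), rel=1e-4)

    def test_joint_loss_sums_per_quantile_pinball(self):
        cfg = TrainConfig(alpha=2.0, beta=0.0)
        actual = rng.random((2, 40)).astype(np.float32)
        pred = ad.Tensor(actual + 0.1)
        preds = {q: pred for q in (0.05, 0.5, 0.95)}
        lb = total_quantile_loss(preds, actual, {q: _params(2) for q in preds}, cfg)
        # one-sided error e: pinball weights (1-q) sum to 1.5 - (0.05+0.5+0.95)=1.05... computed directly
        expected = sum(
            float(quantile_loss(pred, actual, q).data) for q in (0.05, 0.5, 0.95)
        )
        assert lb.total == pytest.approx(cfg.alpha * expected, rel=1e-5)
        # hand arithmetic: one-sided overshoot by e weights (1-q); sum = 1.5*e*... checked via identity
        e = 0.1
        assert expected == pytest.approx((0.95 + 0.5 + 0.05) * e, rel=1e-3)

    def test_physics_loss_lower_on_true_trajectory_than_shuffled(self):
        p = APParams(a=0.15, k=8.0, x=0.5)
        tr = simulate_ap(p, v0=0.3, dt=1e-3, T=4.0)
        v = tr.v[None, :].astype(np.float32)
        cfg = TrainConfig(phys_dt=1e-3)
        a, k, x = _params(1)
        good = float(physics_loss(ad.Tensor(v), a, k, x, cfg).data)
        sh = v.copy()
        rng.shuffle(sh[0])
        bad = float(physics_loss(ad.Tensor(sh), a, k, x, cfg).data)
        assert good < bad


class TestTraining:
    def _data(self, n=24, L=250):
        r = np.random.default_rng(1)
        eap = r.standard_normal((n, L)).astype(np.float32)
        t = np.linspace(0, 1, L, dtype=np.float32)
        iap = 0.1 + 0.8 * np.exp(-((t[None] - 0.3) ** 2) / 0.02) * r.random((n, 1)).astype(np.float32)
        return eap, iap

    def test_loss_decreases_on_smoke_run(self):
        eap, iap = self._data(64)
        m = QPIAUNet(TINY, seed=0)
        h = net.train(m, eap, iap, TrainConfig(epochs=2, seed=0, batch_size=16))
        assert h["loss"].iloc[1] < h["loss"].iloc[0]

    def test_zero_weights_leave_model_unchanged(self):
        eap, iap = self._data(16)
        m = QPIAUNet(TINY, seed=0)
        before = [p.data.copy() for p in m.params()]
        h = net.train(m, eap, iap, TrainConfig(epochs=1, seed=0, alpha=0.0, beta=0.0))
        assert h["loss"].iloc[0] == 0.0
        for p, b in zip(m.params(), before):
            np.testing.assert_array_equal(p.data, b)

    def test_same_seed_reproduces_final_loss(self):
        eap, iap = self._data(32)
        losses = []
        for _ in range(2):
            m = QPIAUNet(TINY, seed=0)
            h = net.train(m, eap, iap, TrainConfig(epochs=2, seed=0, batch_size=16))
            losses.append(h["loss"].iloc[-1])
        assert losses[0] == pytest.approx(losses[1], abs=1e-6)

    def test_group_split_never_mixes_groups(self):
        groups = np.array(["a", "a", "b", "b", "b", "c"])
        tr, va = net.group_split(groups, "b")
        assert set(groups[va]) == {"b"}
        assert "b" not in set(groups[tr])
        assert len(tr) + len(va) == groups.size


class TestReconstruct:
    def test_untrained_outputs_finite_with_crossing_count(self):
        m = QPIAUNet(TINY, seed=0)
        res = reconstruct(m, rng.standard_normal((3, 250)).astype(np.float32))
        assert len(res) == 3
        for r in res:
            assert np.all(np.isfinite(r.v_q50))
            assert 0 <= r.crossing_count <= 250

    def test_wrong_length_rejected(self):
        m = QPIAUNet(TINY, seed=0)
        with pytest.raises(ValueError):
            reconstruct(m, np.zeros((2, 300), dtype=np.float32))

    def test_training_improves_reconstruction_of_training_pair(self):
        r = np.random.default_rng(2)
        eap = r.standard_normal((8, 250)).astype(np.float32)
        t = np.linspace(0, 1, 250, dtype=np.float32)
        iap = (0.1 + 0.9 * np.exp(-((t[None] - 0.3) ** 2) / 0.01)).repeat(8, 0)
        m = QPIAUNet(TINY, seed=0)
        before = reconstruct(m, eap)
        mae0 = np.mean([np.abs(b.v_q50 - iap[i]).mean() for i, b in enumerate(before)])
        net.train(m, eap, iap, TrainConfig(epochs=30, seed=0, batch_size=8, beta=0.0))
        after = reconstruct(m, eap)
        mae1 = np.mean([np.abs(a.v_q50 - iap[i]).mean() for i, a in enumerate(after)])
        assert mae1 < mae0
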