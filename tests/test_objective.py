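"""Losses (soft, multilevel, joint) and the training loop."""

import numpy as np
import pytest

from tcmgen import ModelConfig, PrescriptionModel, SynthConfig, generate_corpus, make_world
from tcmgen.autodiff import Tensor
from tcmgen.objective import (loss_ckgm, loss_final, soft_cross_entropy,
                              step_cross_entropy, train)

ONE = Tensor(np.array(1.0))


def uniform_dist(v):
    return Tensor(np.full(v, 1.0 / v))


class TestLossCkgm:
    def test_uniform_single_label_hand_value(self):
        """Uniform prediction over 4 tokens, one label step, phi1=phi2=1:
        soft term = (1/2)(1/1 + 1) log 4 = log 4; ordered term = log 4."""
        loss = loss_ckgm([uniform_dist(4)], [2], 4, ONE, ONE)
        assert float(loss.data) == pytest.approx(2.0 * np.log(4.0), rel=1e-12)

    def test_perfect_prediction_limit(self):
        p = np.full(4, 1e-12)
        p[1] = 1.0 - 3e-12
        loss = loss_ckgm([Tensor(p)], [1], 4, ONE, ONE)
        assert float(loss.data) == pytest.approx(0.0, abs=1e-9)

    def test_phi1_scales_soft_term_linearly(self):
        dists = [uniform_dist(5), uniform_dist(5)]
        labels = [1, 3]
        l1 = float(loss_ckgm(dists, labels, 5, ONE, ONE).data)
        l2 = float(loss_ckgm(dists, labels, 5, Tensor(np.array(2.0)), ONE).data)
        soft = float(soft_cross_entropy(dists, labels, 5).data)
        assert l2 - l1 == pytest.approx(soft, rel=1e-9)

    def test_underflow_clamped_with_warning(self, caplog):
        p = np.array([1.0, 0.0, 0.0])
        p[0] = 1.0
        with caplog.at_level("WARNING"):
            loss = loss_ckgm([Tensor(p)], [1], 3, ONE, ONE)
        assert np.isfinite(float(loss.data))
        assert any("underflow" in r.message for r in caplog.records)


class TestSoftLoss:
    def test_two_herb_toy_matches_scalar_oracle(self):
        """Explicit summation oracle for the weak-order soft loss."""
        rng = np.random.default_rng(0)
        v = 6
        dists_np = [rng.dirichlet(np.ones(v)) for _ in range(3)]
        labels = [2, 4, 5]
        got = float(soft_cross_entropy([Tensor(d) for d in dists_np],
                                       labels, v).data)
        q = np.zeros(v)
        q[labels] = 1.0
        m = len(labels)
        want = 0.0
        for d, y in zip(dists_np, labels):
            onehot = np.zeros(v)
            onehot[y] = 1.0
            want -= (0.5 * (q / m + onehot) * np.log(d)).sum()
        assert got == pytest.approx(want, rel=1e-12)

    def test_bag_term_invariant_to_label_order(self):
        v = 5
        d1, d2 = uniform_dist(v), uniform_dist(v)
        a = float(soft_cross_entropy([d1, d2], [1, 3], v).data)
        b = float(soft_cross_entropy([d1, d2], [3, 1], v).data)
        # uniform predictions: only the bag term matters, order cannot
        assert a == pytest.approx(b, rel=1e-12)

    def test_nonnegative(self, rng):
        for _ in range(10):
            v = 7
            dists = [Tensor(rng.dirichlet(np.ones(v))) for _ in range(4)]
            labels = list(rng.integers(0, v, size=4))
            assert float(soft_cross_entropy(dists, labels, v).data) >= 0.0
            assert float(step_cross_entropy(dists, labels).data) >= 0.0


class TestLossFinal:
    def _forward(self, use_ckgm=True, fixed=None):
        cfg = SynthConfig(seed=3, n_pairs_sp=10, n_pairs_pe=4)
        sp, pe = generate_corpus(make_world(cfg), cfg)
        mcfg = ModelConfig(d_embed=8, d_hidden=8, d_att=8, n_layers=1,
                           n_heads=1, seed=1, use_ckgm=use_ckgm)
        if fixed:
            mcfg.uncertainty_weighting = False
            mcfg.fixed_psi = fixed
        m = PrescriptionModel(sp, pe, mcfg, chl_min_count=0)
        fwd = m.network.forward_pair(sp[0], None)
        return fwd, m.network

    def test_psi2_zero_reduces_to_herb_branch(self):
        fwd, net = self._forward(fixed=(1.0, 0.0))
        total, bd = loss_final(fwd, net)
        assert float(total.data) == pytest.approx(bd.loss_herb_soft, rel=1e-9)
        assert bd.psi2 == 0.0

    def test_breakdown_components_recompose(self):
        fwd, net = self._forward(fixed=(0.7, 0.3))
        total, bd = loss_final(fwd, net)
        assert float(total.data) == pytest.approx(
            0.7 * bd.loss_herb_soft + 0.3 * bd.loss_ckgm, rel=1e-9)

    def test_uncertainty_weights_stay_positive(self):
        fwd, net = self._forward()
        _, bd = loss_final(fwd, net)
        assert bd.psi1 > 0 and bd.psi2 > 0 and bd.phi1 > 0 and bd.phi2 > 0

    def test_gradient_check_on_small_toy(self, rng):
        """Finite-difference vs analytic gradients of the joint loss on a
        4-dimensional model, 1e-4 relative tolerance."""
        fwd, net = self._forward()
        cfg = SynthConfig(seed=5, n_pairs_sp=6, n_pairs_pe=2, symptoms_per_pair=(3, 4))
        sp, pe = generate_corpus(make_world(cfg), cfg)
        mcfg = ModelConfig(d_embed=4, d_hidden=4, d_att=4, n_layers=1,
                           n_heads=1, seed=2)
        m = PrescriptionModel(sp, pe, mcfg, chl_min_count=0)
        net = m.network
        kb = m.build_kb()
        pool = net.retrieve(sp[0].symptoms, kb, exclude_source_id=sp[0].source_id)

        def value():
            f = net.forward_pair(sp[0], pool.herbs)
            t, _ = loss_final(f, net)
            return t

        t = value()
        net.zero_grad()
        t.backward()
        params = net.named_parameters()
        eps = 1e-6
        names = sorted(params)
        picks = rng.choice(len(names), size=20, replace=False)
        for pi in picks:
            p = params[names[pi]]
            g_an = p.grad if p.grad is not None else np.zeros_like(p.data)
            flat = p.data.reshape(-1)
            i = int(rng.integers(flat.size))
            orig = flat[i]
            flat[i] = orig + eps
            lp = float(value().data)
            flat[i] = orig - eps
            lm = float(value().data)
            flat[i] = orig
            fd = (lp - lm) / (2 * eps)
            an = g_an.reshape(-1)[i]
            # 1e-4 relative with an absolute floor at the central-difference
            # noise level (machine eps * |loss| / step)
            assert abs(fd - an) <= 1e-4 * max(abs(fd), abs(an)) + 2e-6, \
                f"{names[pi]}[{i}]: fd={fd} analytic={an}"


class TestTraining:
    def _corpus(self, n=10, seed=3):
        cfg = SynthConfig(seed=seed, n_pairs_sp=n, n_pairs_pe=4)
        return generate_corpus(make_world(cfg), cfg)

    def test_two_epoch_determinism(self):
        logs = []
        for _ in range(2):
            sp, pe = self._corpus()
            mcfg = ModelConfig(d_embed=8, d_hidden=8, d_att=8, n_layers=1,
                               n_heads=1, epochs=2, seed=9, k=3)
            m = PrescriptionModel(sp, pe, mcfg, chl_min_count=0)
            res = m.fit()
            logs.append([row["total"] for row in res.loss_log])
        assert logs[0] == logs[1]

    def test_loss_decreases_on_small_corpus(self):
        sp, pe = self._corpus(n=30, seed=6)
        mcfg = ModelConfig(d_embed=12, d_hidden=12, d_att=12, n_layers=1,
                           n_heads=1, epochs=6, seed=1, k=5)
        m = PrescriptionModel(sp, pe, mcfg, chl_min_count=0)
        res = m.fit()
        assert res.loss_log[5]["total"] < res.loss_log[0]["total"]
        assert res.log.best_state is not None

    def test_full_ablation_reduces_to_plain_encoder_decoder(self):
        sp, pe = self._corpus()
        mcfg = ModelConfig(d_embed=8, d_hidden=8, d_att=8, n_layers=1,
                           n_heads=1, epochs=1, seed=2, use_ckgm=False,
                           use_hcp=False, use_chl=False)
        m = PrescriptionModel(sp, pe, mcfg)
        res = m.fit()
        assert res.loss_log[0]["loss_ckgm"] == 0.0
        herbs = res.generate(sp[0].symptoms)
        assert isinstance(herbs, list)

    def test_ckgm_pretraining_runs(self):
        sp, pe = self._corpus()
        mcfg = ModelConfig(d_embed=8, d_hidden=8, d_att=8, n_layers=1,
                           n_heads=1, epochs=1, seed=2, ckgm_pretrain_epochs=2)
        m = PrescriptionModel(sp, pe, mcfg, chl_min_count=0)
        res = m.fit()
        assert len(res.loss_log) == 1
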