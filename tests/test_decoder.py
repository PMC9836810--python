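"""Dual-source attention, coverage, copy mixture, greedy generation."""

import numpy as np
import pytest

from tcmgen import autodiff as ad
from tcmgen.autodiff import Tensor
from tcmgen.decoder import PrescriptionDecoder, scatter_add
from tcmgen.layers import Embedding


def make_decoder(seed=0, d=6, vocab=12, **kw):
    rng = np.random.default_rng(seed)
    emb = Embedding(rng, vocab, d)
    dec = PrescriptionDecoder(rng, emb, d, d, vocab, n_layers=1, n_heads=1, **kw)
    return dec, emb


class TestCandidateAttention:
    def test_equal_embeddings_give_uniform(self):
        dec, _ = make_decoder()
        embeds = Tensor(np.tile(np.arange(6.0), (4, 1)))
        a1, _ = dec.candidate_attentions(embeds, None, Tensor(np.zeros(6)))
        assert np.allclose(a1.data, 0.25)

    def test_single_candidate(self):
        dec, emb = make_decoder()
        a1, a2 = dec.candidate_attentions(None, ad.getitem(emb.table, np.array([3])),
                                          Tensor(np.zeros(6)))
        assert a1 is None and np.allclose(a2.data, [1.0])

    def test_matches_scalar_softmax_oracle(self, rng):
        dec, emb = make_decoder(seed=2)
        ids = np.array([1, 3, 5, 7, 9])
        embeds = ad.getitem(emb.table, ids)
        s = Tensor(rng.normal(size=6))
        a1, _ = dec.candidate_attentions(embeds, None, s)
        att = dec.att_chl
        scores = []
        for row in embeds.data:
            z = np.tanh(att.w_e.w.data.T @ row + att.w_s.w.data.T @ s.data
                        + att.b.data)
            scores.append(att.v.data @ z)
        e = np.exp(scores - np.max(scores))
        assert np.allclose(a1.data, e / e.sum(), atol=1e-12)


class TestHybridGate:
    def test_zero_weights_give_half(self):
        dec, _ = make_decoder()
        dec.w_hyb.data[...] = 0.0
        g = dec.hybrid_gate(Tensor(np.ones(6)), Tensor(np.ones(6)), Tensor(np.ones(6)))
        assert float(g.data) == pytest.approx(0.5)

    def test_saturation(self):
        dec, _ = make_decoder()
        dec.w_hyb.data[...] = 10.0
        g = dec.hybrid_gate(Tensor(np.ones(6)), Tensor(np.ones(6)), Tensor(np.ones(6)))
        assert float(g.data) > 0.999

    def test_matches_scalar_sigmoid(self, rng):
        dec, _ = make_decoder(seed=5)
        s, h, p = (Tensor(rng.normal(size=6)) for _ in range(3))
        g = dec.hybrid_gate(s, h, p)
        z = dec.w_hyb.data @ np.concatenate([s.data, h.data, p.data])
        assert float(g.data) == pytest.approx(1 / (1 + np.exp(-z)), rel=1e-12)


class TestComplementaryAttention:
    def _setup(self):
        hcp = Tensor(np.array([[1.0, 0.0], [0.0, 1.0]]))
        chl = Tensor(np.array([[2.0, 0.0], [0.0, 2.0]]))
        a2 = Tensor(np.array([0.7, 0.3]))
        a1 = Tensor(np.array([0.4, 0.6]))
        return a1, a2, chl, hcp

    def test_gate_one_concentrates_on_hcp(self):
        dec, _ = make_decoder(d=2, vocab=6)
        a1, a2, chl, hcp = self._setup()
        a_hyb, o = dec.complementary_attention(a1, a2, Tensor(np.array(1.0)), chl, hcp)
        assert np.allclose(a_hyb.data, [0.7, 0.3, 0.0, 0.0])
        assert np.allclose(o.data, 0.7 * hcp.data[0] + 0.3 * hcp.data[1])

    def test_gate_zero_concentrates_on_chl(self):
        dec, _ = make_decoder(d=2, vocab=6)
        a1, a2, chl, hcp = self._setup()
        a_hyb, _ = dec.complementary_attention(a1, a2, Tensor(np.array(0.0)), chl, hcp)
        assert np.allclose(a_hyb.data, [0.0, 0.0, 0.4, 0.6])

    def test_hand_arithmetic_mid_gate(self):
        dec, _ = make_decoder(d=2, vocab=6)
        a1, a2, chl, hcp = self._setup()
        a_hyb, o = dec.complementary_attention(a1, a2, Tensor(np.array(0.3)), chl, hcp)
        want = [0.3 * 0.7, 0.3 * 0.3, 0.7 * 0.4, 0.7 * 0.6]
        assert np.allclose(a_hyb.data, want)
        assert a_hyb.data.sum() == pytest.approx(1.0)
        manual = sum(w * e for w, e in zip(want, [*hcp.data, *chl.data]))
        assert np.allclose(o.data, manual)

    def test_no_candidates_gives_zero_context(self):
        dec, _ = make_decoder()
        a_hyb, o = dec.complementary_attention(None, None, None, None, None)
        assert a_hyb is None and np.allclose(o.data, 0.0)


class TestCoverage:
    def test_identical_encoder_states_give_uniform(self):
        dec, _ = make_decoder()
        enc = Tensor(np.tile(np.arange(6.0), (5, 1)))
        a3, c3 = dec.coverage_attention(enc, Tensor(np.zeros(6)), [])
        assert np.allclose(a3.data, 0.2)
        assert np.allclose(c3.data, enc.data[0])

    def test_empty_prefix_only_bias_shift(self):
        """With no generated herbs the coverage term vanishes: scores reduce
        to v.tanh(Wh h + Ws s + b)."""
        dec, _ = make_decoder(seed=3)
        enc = Tensor(np.random.default_rng(0).normal(size=(4, 6)))
        s = Tensor(np.zeros(6))
        a3, _ = dec.coverage_attention(enc, s, [])
        manual = []
        for row in enc.data:
            z = np.tanh(dec.cov_wh.w.data.T @ row + dec.cov_ws.w.data.T @ s.data
                        + dec.cov_b.data)
            manual.append(dec.cov_v.data @ z)
        e = np.exp(manual - np.max(manual))
        assert np.allclose(a3.data, e / e.sum(), atol=1e-12)

    def test_prefix_changes_distribution(self, rng):
        dec, emb = make_decoder(seed=4)
        enc = Tensor(rng.normal(size=(4, 6)))
        s = Tensor(rng.normal(size=6))
        a_empty, _ = dec.coverage_attention(enc, s, [])
        a_full, _ = dec.coverage_attention(enc, s, [emb(2), emb(3)])
        assert not np.allclose(a_empty.data, a_full.data)


class TestOutputDistribution:
    def test_copy_mixture_hand_example(self):
        """Vocabulary {A,B,C}; candidates {B,C} with copy masses {0.4, 0.6};
        P_vocab = (0.2, 0.3, 0.5); p_gen = 0.5 -> (0.10, 0.35, 0.55)."""
        dec, _ = make_decoder(d=4, vocab=3)
        dec.out.w.data[...] = 0.0
        dec.out.b.data[...] = np.log([0.2, 0.3, 0.5])
        for p in (dec.pg_ws, dec.pg_wp, dec.pg_wcs, dec.pg_b):
            p.data[...] = 0.0      # p_gen = sigmoid(0) = 0.5
        zero = Tensor(np.zeros(4))
        a_hyb = Tensor(np.array([0.4, 0.6]))
        p_vocab, p_cand, p_gen, p_final = dec.output_distribution(
            zero, zero, zero, zero, a_hyb, np.array([1, 2]))
        assert np.allclose(p_vocab.data, [0.2, 0.3, 0.5])
        assert float(p_gen.data) == pytest.approx(0.5)
        assert np.allclose(p_final.data, [0.10, 0.35, 0.55])

    def test_generation_only_path(self):
        dec, _ = make_decoder(d=4, vocab=3)
        zero = Tensor(np.zeros(4))
        p_vocab, p_cand, _, p_final = dec.output_distribution(
            zero, zero, zero, zero, None, None)
        assert p_cand is None
        assert np.allclose(p_final.data, p_vocab.data)

    def test_pgen_extremes(self):
        dec, _ = make_decoder(d=4, vocab=5)
        zero = Tensor(np.zeros(4))
        a_hyb = Tensor(np.array([0.25, 0.75]))
        dec.pg_b.data[...] = 50.0
        *_, p_final = dec.output_distribution(zero, zero, zero, zero, a_hyb,
                                              np.array([1, 2]))
        assert np.allclose(p_final.data, np.exp(dec.out.b.data * 0) / 5, atol=1e-9)
        dec.pg_b.data[...] = -50.0
        *_, p_final = dec.output_distribution(zero, zero, zero, zero, a_hyb,
                                              np.array([1, 2]))
        assert p_final.data[0] == pytest.approx(0.0, abs=1e-9)
        assert p_final.data[1] == pytest.approx(0.25, abs=1e-9)
        assert p_final.data[2] == pytest.approx(0.75, abs=1e-9)

    def test_convexity_of_mixture(self, rng):
        dec, _ = make_decoder(d=4, vocab=6)
        zero = Tensor(rng.normal(size=4))
        a_hyb = ad.softmax(Tensor(rng.normal(size=3)))
        ids = np.array([1, 2, 4])
        p_vocab, p_cand, p_gen, p_final = dec.output_distribution(
            zero, zero, zero, zero, a_hyb, ids)
        lo = np.minimum(p_vocab.data, p_cand.data)
        hi = np.maximum(p_vocab.data, p_cand.data)
        assert np.all(p_final.data >= lo - 1e-12)
        assert np.all(p_final.data <= hi + 1e-12)


class TestGeneration:
    def test_mask_mode_never_duplicates(self, tiny_model):
        net = tiny_model.network
        kb = tiny_model.build_kb()
        for p in tiny_model.sp_pairs[:10]:
            herbs = net.generate(p.symptoms, kb=kb, mode="mask")
            assert len(herbs) == len(set(herbs))

    def test_max_len_one(self, tiny_model):
        herbs = tiny_model.network.generate(
            tiny_model.sp_pairs[0].symptoms, max_len=1)
        assert len(herbs) <= 1

    def test_trace_has_one_row_per_step(self, tiny_model):
        net = tiny_model.network
        herbs, trace = net.generate(tiny_model.sp_pairs[0].symptoms,
                                    kb=tiny_model.build_kb(),
                                    mode="mask", emit_trace=True)
        assert len(trace) >= len(herbs)
        n1 = len(tiny_model.sp_pairs[0].symptoms)
        for row in trace:
            assert len(row["coverage_attention"]) == n1
            assert sum(row["coverage_attention"]) == pytest.approx(1.0, abs=1e-9)

    def test_only_chl_ablation_still_normalised(self, small_corpus):
        from tcmgen import ModelConfig, PrescriptionModel
        sp, pe = small_corpus
        cfg = ModelConfig(d_embed=8, d_hidden=8, d_att=8, n_layers=1,
                          n_heads=1, use_hcp=False, seed=3)
        m = PrescriptionModel(sp, pe, cfg, chl_min_count=0)
        fwd = m.network.forward_pair(sp[0], None)
        for st in fwd.step_states:
            assert st.a_hcp is None and st.g_hyb is None
            assert st.p_final.data.sum() == pytest.approx(1.0, abs=1e-9)
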