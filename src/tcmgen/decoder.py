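"""Candidates coverage decoder: dual-source attention, coverage, copy mixture.

Per generation step t, with previous decoder state s_{t-1}:

1. additive attention a1 over the conventional herb library (CHL) and a2
   over the retrieved herbal candidate pool (HCP);
2. an adaptive gate g_hyb = sigmoid(w . [s_{t-1}, HCP context, e(h_{t-1})])
   splits probability mass between the two sets: HCP slots carry
   g_hyb * a2, CHL slots (1 - g_hyb) * a1, giving the complementary
   distribution a_hyb and its context O_t over candidate herb embeddings;
3. coverage attention a3 over the encoder states, conditioned on a pooled
   embedding of the herbs generated so far, discourages re-attending to
   already-served symptoms and yields the context c3_t;
4. the autoregressive core updates the state from the context-conditioned
   token stream;
5. the output mixes a generation softmax over the full herb vocabulary
   with the candidate copy mass, weighted by p_gen.

A herb appearing in both candidate sets keeps separate attention slots;
their masses merge by token when the copy distribution is scattered into
the vocabulary.  Mask-mode generation additionally zeroes already-emitted
herbs before the argmax, making duplicates impossible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .layers import Embedding, GRUCore, Linear, Module, TransformerCore

__all__ = ["DecoderStepState", "PrescriptionDecoder", "scatter_add"]


def scatter_add(values: Tensor, index: np.ndarray, size: int) -> Tensor:
    """Scatter a slot-indexed mass vector into a token-indexed one,
    summing slots that map to the same token (differentiable)."""
    data = np.zeros(size)
    np.add.at(data, index, values.data)
    out = Tensor(data, prev=(values,))
    if out.requires_grad:
        def _bw(g):
            values._accumulate(g[index])
        out._backward = _bw
    return out


@dataclass
class DecoderStepState:
    """Everything one decode step produced (distributions kept as tensors
    during training; ``.trace_row()`` detaches for inspection)."""

    s_dec: Tensor
    content_attention: Tensor            # a_t over symptom positions (Eq-4 style)
    cs: Tensor
    a_chl: Optional[Tensor]
    a_hcp: Optional[Tensor]
    g_hyb: Optional[Tensor]
    a_hyb: Optional[Tensor]
    context_o: Tensor
    a_cov: Tensor                        # coverage distribution over positions
    c_cov: Tensor
    p_gen: Tensor
    p_vocab: Tensor
    p_candidate: Optional[Tensor]        # copy mass scattered into the vocab
    p_final: Tensor
    token_id: Optional[int] = None

    def trace_row(self) -> dict:
        return {
            "token_id": self.token_id,
            "content_attention": self.content_attention.data.tolist(),
            "coverage_attention": self.a_cov.data.tolist(),
            "g_hyb": None if self.g_hyb is None else float(self.g_hyb.data),
            "p_gen": float(self.p_gen.data),
            "a_hyb": None if self.a_hyb is None else self.a_hyb.data.tolist(),
        }


class _CandidateAttention(Module):
    """a_i = softmax_i v . tanh(W_e emb_i + W_s s + b)."""

    def __init__(self, rng, d_embed: int, d_state: int, d_att: int):
        super().__init__()
        self.w_e = self.add_child("w_e", Linear(rng, d_embed, d_att, bias=False))
        self.w_s = self.add_child("w_s", Linear(rng, d_state, d_att, bias=False))
        self.b = self.add_param("b", np.zeros(d_att))
        self.v = self.add_param("v", rng.normal(0.0, 0.1, size=d_att))

    def __call__(self, embeds: Tensor, s: Tensor,
                 we_cache: Tensor | None = None) -> Tensor:
        we = we_cache if we_cache is not None else self.w_e(embeds)
        scores = ad.matmul(ad.tanh(ad.add(ad.add(we, self.w_s(s)), self.b)), self.v)
        return ad.softmax(scores)


class PrescriptionDecoder(Module):
    def __init__(self, rng, herb_embedding: Embedding, d_hidden: int, d_att: int,
                 herb_vocab_size: int, core: str = "transformer",
                 n_layers: int = 2, n_heads: int = 2, coverage_pool: str = "sum"):
        super().__init__()
        self.herb_embedding = herb_embedding  # shared with the parent model
        d_embed = herb_embedding.d
        self.att_chl = self.add_child("att_chl",
                                      _CandidateAttention(rng, d_embed, d_embed, d_att))
        self.att_hcp = self.add_child("att_hcp",
                                      _CandidateAttention(rng, d_embed, d_embed, d_att))
        self.w_hyb = self.add_param("w_hyb",
                                    rng.normal(0.0, 0.1, size=d_embed + d_embed + d_embed))
        # coverage attention (distinct bias from the HCP attention's)
        self.cov_wh = self.add_child("cov_wh", Linear(rng, d_hidden, d_att, bias=False))
        self.cov_ws = self.add_child("cov_ws", Linear(rng, d_embed, d_att, bias=False))
        self.cov_wc = self.add_child("cov_wc", Linear(rng, d_embed, d_att, bias=False))
        self.cov_b = self.add_param("cov_b", np.zeros(d_att))
        self.cov_v = self.add_param("cov_v", rng.normal(0.0, 0.1, size=d_att))
        # autoregressive core + context injection
        core_cls = TransformerCore if core == "transformer" else GRUCore
        self.core = self.add_child("core", core_cls(rng, d_embed, n_layers=n_layers,
                                                    n_heads=n_heads))
        self.proj_o = self.add_child("proj_o", Linear(rng, d_embed, d_embed))
        self.proj_cs = self.add_child("proj_cs", Linear(rng, d_hidden, d_embed))
        self.proj_c3 = self.add_child("proj_c3", Linear(rng, d_hidden, d_embed))
        # output mixture
        self.out = self.add_child("out", Linear(rng, d_embed + d_hidden, herb_vocab_size))
        self.pg_ws = self.add_param("pg_ws", rng.normal(0.0, 0.1, size=d_embed))
        self.pg_wp = self.add_param("pg_wp", rng.normal(0.0, 0.1, size=d_embed))
        self.pg_wcs = self.add_param("pg_wcs", rng.normal(0.0, 0.1, size=d_hidden))
        self.pg_b = self.add_param("pg_b", np.zeros(()))
        self.d_embed, self.d_hidden = d_embed, d_hidden
        self.vocab_size = herb_vocab_size
        self.coverage_pool = coverage_pool

    # -- per-pair cache -------------------------------------------------
    def precompute(self, enc_states: Tensor, chl_embeds: Optional[Tensor],
                   hcp_embeds: Optional[Tensor]) -> dict:
        """Step-invariant projections, computed once per sequence."""
        return {
            "cov_wh": self.cov_wh(enc_states),
            "chl_we": None if chl_embeds is None else self.att_chl.w_e(chl_embeds),
            "hcp_we": None if hcp_embeds is None else self.att_hcp.w_e(hcp_embeds),
        }

    # -- individual operations ----------------------------------------
    def candidate_attentions(self, chl_embeds: Optional[Tensor],
                             hcp_embeds: Optional[Tensor],
                             s_prev: Tensor,
                             cache: Optional[dict] = None
                             ) -> tuple[Optional[Tensor], Optional[Tensor]]:
        cache = cache or {}
        a1 = (self.att_chl(chl_embeds, s_prev, cache.get("chl_we"))
              if chl_embeds is not None else None)
        a2 = (self.att_hcp(hcp_embeds, s_prev, cache.get("hcp_we"))
              if hcp_embeds is not None else None)
        return a1, a2

    def hybrid_gate(self, s_prev: Tensor, hcp_context: Tensor,
                    h_prev_embed: Tensor) -> Tensor:
        return ad.sigmoid(ad.dot(self.w_hyb,
                                 ad.concat([s_prev, hcp_context, h_prev_embed])))

    def complementary_attention(self, a1: Optional[Tensor], a2: Optional[Tensor],
                                g_hyb: Optional[Tensor],
                                chl_embeds: Optional[Tensor],
                                hcp_embeds: Optional[Tensor]
                                ) -> tuple[Optional[Tensor], Tensor]:
        """HCP slots first, then CHL slots; degenerate set memberships fall
        back to the surviving distribution with the gate pinned."""
        if a1 is None and a2 is None:
            return None, Tensor(np.zeros(self.d_embed))
        if a2 is None:      # only CHL: gate forced to 0
            return a1, ad.matmul(a1, chl_embeds)
        if a1 is None:      # only HCP: gate forced to 1
            return a2, ad.matmul(a2, hcp_embeds)
        a_hyb = ad.concat([ad.mul(g_hyb, a2), ad.mul(ad.sub(1.0, g_hyb), a1)])
        combined = ad.concat([hcp_embeds, chl_embeds], axis=0)
        return a_hyb, ad.matmul(a_hyb, combined)

    def coverage_attention(self, enc_states: Tensor, s_prev: Tensor,
                           generated_embeds: list[Tensor],
                           cache: Optional[dict] = None) -> tuple[Tensor, Tensor]:
        if generated_embeds:
            pool = generated_embeds[0]
            for e in generated_embeds[1:]:
                pool = ad.add(pool, e)
            if self.coverage_pool == "mean":
                pool = ad.scale(pool, 1.0 / len(generated_embeds))
            cov = self.cov_wc(pool)
        else:
            cov = Tensor(np.zeros(self.cov_b.data.shape))
        wh = (cache or {}).get("cov_wh")
        if wh is None:
            wh = self.cov_wh(enc_states)
        scores = ad.matmul(ad.tanh(ad.add(ad.add(wh, ad.add(self.cov_ws(s_prev), cov)),
                                          self.cov_b)), self.cov_v)
        a3 = ad.softmax(scores)
        return a3, ad.matmul(a3, enc_states)

    def decoder_step(self, stream: list[Tensor], s_prev: Tensor) -> Tensor:
        """Advance the autoregressive core over the conditioned token stream."""
        return self.core(stream, s_prev)

    def make_stream_element(self, h_prev_embed: Tensor, o: Tensor, cs: Tensor,
                            c3: Tensor) -> Tensor:
        """Context injection: token embedding plus projected step contexts."""
        return ad.add(ad.add(h_prev_embed, self.proj_o(o)),
                      ad.add(self.proj_cs(cs), self.proj_c3(c3)))

    def output_distribution(self, s_prev: Tensor, cs: Tensor, h_prev_embed: Tensor,
                            s_t: Tensor, a_hyb: Optional[Tensor],
                            candidate_ids: Optional[np.ndarray]
                            ) -> tuple[Tensor, Optional[Tensor], Tensor, Tensor]:
        p_vocab = ad.softmax(self.out(ad.concat([s_prev, cs])))
        p_gen = ad.sigmoid(ad.add(ad.add(ad.dot(self.pg_ws, s_t),
                                         ad.dot(self.pg_wp, h_prev_embed)),
                                  ad.add(ad.dot(self.pg_wcs, cs), self.pg_b)))
        if a_hyb is None:
            # generation-only ablation: all mass from the vocabulary head
            return p_vocab, None, p_gen, p_vocab
        p_cand = scatter_add(a_hyb, candidate_ids, self.vocab_size)
        p_final = ad.add(ad.mul(p_gen, p_vocab),
                         ad.mul(ad.sub(1.0, p_gen), p_cand))
        return p_vocab, p_cand, p_gen, p_final

    # -- one full step --------------------------------------------------
    def step(self, enc_states: Tensor, content_attention, cs: Tensor,
             s_prev: Tensor, h_prev_embed: Tensor, stream: list[Tensor],
             generated_embeds: list[Tensor],
             chl_embeds: Optional[Tensor], chl_ids: Optional[np.ndarray],
             hcp_embeds: Optional[Tensor], hcp_ids: Optional[np.ndarray],
             cache: Optional[dict] = None) -> DecoderStepState:
        """Run MCAM + coverage + core + output mixture for one step.

        ``stream`` is mutated: the context-conditioned embedding of the
        current input token is appended before the core advances.
        ``cache`` holds the step-invariant projections from ``precompute``.
        """
        a1, a2 = self.candidate_attentions(chl_embeds, hcp_embeds, s_prev, cache)
        g_hyb = None
        if a1 is not None and a2 is not None:
            hcp_ctx = ad.matmul(a2, hcp_embeds)
            g_hyb = self.hybrid_gate(s_prev, hcp_ctx, h_prev_embed)
        a_hyb, o_t = self.complementary_attention(a1, a2, g_hyb, chl_embeds, hcp_embeds)
        a3, c3 = self.coverage_attention(enc_states, s_prev, generated_embeds, cache)
        stream.append(self.make_stream_element(h_prev_embed, o_t, cs, c3))
        s_t = self.decoder_step(stream, s_prev)
        if a_hyb is not None:
            if hcp_ids is not None and chl_ids is not None:
                cand_ids = np.concatenate([hcp_ids, chl_ids])
            else:
                cand_ids = hcp_ids if hcp_ids is not None else chl_ids
        else:
            cand_ids = None
        p_vocab, p_cand, p_gen, p_final = self.output_distribution(
            s_prev, cs, h_prev_embed, s_t, a_hyb, cand_ids)
        return DecoderStepState(
            s_dec=s_t, content_attention=content_attention, cs=cs,
            a_chl=a1, a_hcp=a2, g_hyb=g_hyb, a_hyb=a_hyb, context_o=o_t,
            a_cov=a3, c_cov=c3, p_gen=p_gen, p_vocab=p_vocab,
            p_candidate=p_cand, p_final=p_final)


def generate(network, symptoms: list[str], kb=None, mode: str = "mask",
             max_len: int = 23, emit_trace: bool = False):
    """Greedy prescription generation; delegates to the fitted network.

    ``mode="mask"`` zeroes already-emitted herbs before the argmax (hard
    no-duplicate guarantee); ``mode="free"`` leaves the distribution alone.
    """
    return network.generate(symptoms, kb=kb, mode=mode, max_len=max_len,
                            emit_trace=emit_trace)
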