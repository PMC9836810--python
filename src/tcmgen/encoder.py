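"""Bidirectional hybrid encoder (EnGRU).

A bidirectional GRU reads the symptom token sequence; a *hybrid module*
then mixes the forward and backward states position by position with a
learned scalar gate

    h_i = w_i * h_i^f + (1 - w_i) * h_i^b,
    w_i = sigmoid( w_z . [h_i^f, h_{i-1}, e(s_{i-1}), u_i] + b_z ),

where h_{i-1} is the previous *mixed* state and u_i is the current token
embedding scaled by the accumulated gate mass of the strict prefix,
u_i = (sum_{j<i} w_j) * e(s_i) — the gate literature writes this
accumulation self-referentially; the strict-prefix form is the causal
reading and is computed left to right.  Boundary terms (h_0, e(s_0), the
empty prefix sum) are zero.

Content representation: at decoder step t, additive attention over the
mixed states scored against the previous decoder state gives a
distribution a_t and the context Cs_t = sum_i a_ti h_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .layers import Embedding, GRUCell, Linear, Module

__all__ = ["EncoderStates", "HybridEncoder", "ContentAttention"]


@dataclass
class EncoderStates:
    """Per-position state bundle; all four sequences share length n1."""

    forward_states: list[Tensor]
    backward_states: list[Tensor]
    hybrid_weights: list[Tensor]   # scalars in (0, 1)
    final_states: list[Tensor]

    def __len__(self) -> int:
        return len(self.final_states)

    def stacked(self) -> Tensor:
        return ad.stack(self.final_states)


class ContentAttention(Module):
    """Additive attention: a_i = softmax_i V.tanh(Ws s + Wh h_i); C = sum a_i h_i."""

    def __init__(self, rng, d_query: int, d_state: int, d_att: int):
        super().__init__()
        self.w_s = self.add_child("w_s", Linear(rng, d_query, d_att, bias=False))
        self.w_h = self.add_child("w_h", Linear(rng, d_state, d_att, bias=False))
        self.v = self.add_param("v", rng.normal(0.0, 0.1, size=d_att))

    def __call__(self, states: Tensor, query: Tensor,
                 wh_states: Tensor | None = None) -> tuple[Tensor, Tensor]:
        # wh_states: optional cached W_h @ states (states are fixed across
        # decoder steps, so callers precompute the projection once)
        if wh_states is None:
            wh_states = self.w_h(states)
        scores = ad.matmul(ad.tanh(ad.add(wh_states, self.w_s(query))), self.v)
        a = ad.softmax(scores)
        return a, ad.matmul(a, states)


class HybridEncoder(Module):
    """EnGRU over an arbitrary token stream (symptoms here, herbs in the
    guidance branch, which reuses this structure with its own parameters)."""

    def __init__(self, rng, embedding: Embedding, d_hidden: int, d_att: int,
                 d_query: int | None = None):
        super().__init__()
        self.embedding = embedding  # owned by the parent model, not a child here
        d_embed = embedding.d
        self.gru_f = self.add_child("gru_f", GRUCell(rng, d_embed, d_hidden))
        self.gru_b = self.add_child("gru_b", GRUCell(rng, d_embed, d_hidden))
        gate_dim = 2 * d_hidden + 2 * d_embed
        self.w_z = self.add_param("w_z", rng.normal(0.0, 0.1, size=gate_dim))
        self.b_z = self.add_param("b_z", np.zeros(()))
        self.d_query = d_query or d_hidden
        self.attention = self.add_child(
            "attention", ContentAttention(rng, self.d_query, d_hidden, d_att))
        self.d_hidden = d_hidden

    # -- operations ----------------------------------------------------
    def bigru_encode(self, token_ids: list[int]) -> tuple[list[Tensor], list[Tensor]]:
        """Forward and backward GRU passes over the embedded tokens."""
        if not token_ids:
            raise ValueError("cannot encode an empty sequence")
        embeds = [self.embedding(i) for i in token_ids]
        zero = Tensor(np.zeros(self.d_hidden))
        fwd, h = [], zero
        for e in embeds:
            h = self.gru_f(e, h)
            fwd.append(h)
        bwd, h = [], zero
        for e in reversed(embeds):
            h = self.gru_b(e, h)
            bwd.append(h)
        bwd.reverse()
        return fwd, bwd

    def hybrid_combine(self, forward_states: list[Tensor],
                       backward_states: list[Tensor],
                       embeds: list[Tensor]) -> tuple[list[Tensor], list[Tensor]]:
        """Left-to-right gated mix of the two directional state sequences."""
        if len(forward_states) != len(backward_states):
            raise ValueError("directional state sequences differ in length")
        d_embed = self.embedding.d
        zero_h = Tensor(np.zeros(self.d_hidden))
        zero_e = Tensor(np.zeros(d_embed))
        weights, finals = [], []
        prev_h, prev_e = zero_h, zero_e
        prefix = Tensor(np.zeros(()))
        for i, (hf, hb) in enumerate(zip(forward_states, backward_states)):
            u = ad.mul(prefix, embeds[i])
            gate_in = ad.concat([hf, prev_h, prev_e, u])
            w = ad.sigmoid(ad.add(ad.dot(self.w_z, gate_in), self.b_z))
            h = ad.add(ad.mul(w, hf), ad.mul(ad.sub(1.0, w), hb))
            weights.append(w)
            finals.append(h)
            prefix = ad.add(prefix, w)
            prev_h, prev_e = h, embeds[i]
        return weights, finals

    def encode(self, token_ids: list[int]) -> EncoderStates:
        fwd, bwd = self.bigru_encode(token_ids)
        embeds = [self.embedding(i) for i in token_ids]
        weights, finals = self.hybrid_combine(fwd, bwd, embeds)
        return EncoderStates(fwd, bwd, weights, finals)

    def content_representation(self, states: EncoderStates | Tensor,
                               dec_state_prev: Tensor,
                               wh_cache: Tensor | None = None) -> tuple[Tensor, Tensor]:
        """Attention a_t over positions and context Cs_t, queried by the
        previous decoder state (zero vector at the first step)."""
        stacked = states.stacked() if isinstance(states, EncoderStates) else states
        return self.attention(stacked, dec_state_prev, wh_states=wh_cache)

    def represent(self, token_ids: list[int]) -> np.ndarray:
        """Detached content representation with a zero query — the form
        stored in the knowledge base."""
        states = self.encode(token_ids)
        _, cs = self.content_representation(states, Tensor(np.zeros(self.d_query)))
        return cs.data.copy()
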