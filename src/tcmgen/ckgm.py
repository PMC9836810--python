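"""Prescription→efficacy guidance branch and its similarity gate.

The branch gives the symptom encoder a second supervision signal: encode
the gold prescription with an encoder of the same hybrid structure (its
own parameters, herb embeddings shared with the main decoder), decode the
prescription's efficacy phrase autoregressively, and compare the
prescription representation Ch with the symptom representation Cs by
cosine similarity.  When the two representations already agree (cosine at
or above the threshold ``delta``) the guidance is switched off; below the
threshold the auxiliary loss is scaled up by the hinge
``max(0, delta - SC)``, so supervision strengthens exactly when the
symptom encoder has not yet absorbed what the prescription implies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .encoder import HybridEncoder
from .layers import Embedding, GRUCore, Linear, Module, TransformerCore

__all__ = ["SimilarityGate", "GuidanceBranch", "similarity_gate", "cosine"]


@dataclass
class SimilarityGate:
    """Cosine score SC in [-1, 1] and the hinge guidance scale."""

    sc: Tensor
    guidance_scale: Tensor
    delta: float

    @property
    def sc_value(self) -> float:
        return float(self.sc.data)

    @property
    def scale_value(self) -> float:
        return float(self.guidance_scale.data)


def _norm(x: Tensor) -> Tensor:
    # sqrt via exp(log/2); arguments are strictly positive by the guard below
    return ad.exp(ad.scale(ad.log(ad.tsum(ad.mul(x, x))), 0.5))


def cosine(a: Tensor, b: Tensor) -> Tensor:
    na, nb = float(np.linalg.norm(a.data)), float(np.linalg.norm(b.data))
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    inv = ad.exp(ad.neg(ad.add(ad.log(_norm(a)), ad.log(_norm(b)))))
    return ad.mul(ad.dot(a, b), inv)


def similarity_gate(cs: Tensor, ch: Tensor, delta: float = 0.6) -> SimilarityGate:
    """SC = cos(Cs, Ch); guidance_scale = max(0, delta - SC)."""
    sc = cosine(cs, ch)
    return SimilarityGate(sc=sc, guidance_scale=ad.relu(ad.sub(delta, sc)), delta=delta)


class GuidanceBranch(Module):
    """CKGM: hybrid prescription encoder + autoregressive efficacy decoder."""

    def __init__(self, rng, herb_embedding: Embedding, eff_embedding: Embedding,
                 d_hidden: int, d_att: int, eff_vocab_size: int,
                 core: str = "transformer", n_layers: int = 2, n_heads: int = 2,
                 max_len: int = 8, bos_id: int = 1, eos_id: int = 2):
        super().__init__()
        self.encoder = self.add_child("encoder",
                                      HybridEncoder(rng, herb_embedding, d_hidden, d_att))
        self.eff_embedding = self.add_child("eff_embedding", eff_embedding)
        d = eff_embedding.d
        self.ch_proj = self.add_child("ch_proj", Linear(rng, d_hidden, d))
        core_cls = TransformerCore if core == "transformer" else GRUCore
        self.core = self.add_child("core", core_cls(rng, d, n_layers=n_layers,
                                                    n_heads=n_heads))
        self.out = self.add_child("out", Linear(rng, d, eff_vocab_size))
        self.max_len = max_len
        self.bos_id, self.eos_id = bos_id, eos_id
        self.d_hidden = d_hidden

    # -- operations ----------------------------------------------------
    def encode_prescription(self, herb_ids: list[int]) -> Tensor:
        """Content representation Ch of the prescription (zero query)."""
        states = self.encoder.encode(herb_ids)
        _, ch = self.encoder.content_representation(
            states, Tensor(np.zeros(self.encoder.d_query)))
        return ch

    def _stream(self, ch: Tensor, prefix_ids: list[int]) -> list[Tensor]:
        # Ch enters as a prepended context embedding before BOS
        return ([self.ch_proj(ch), self.eff_embedding(self.bos_id)]
                + [self.eff_embedding(i) for i in prefix_ids])

    def decode_step(self, ch: Tensor, prefix_ids: list[int],
                    s_prev: Tensor | None = None) -> tuple[Tensor, Tensor]:
        """Next-token distribution over the efficacy vocabulary and the
        decoder state that produced it."""
        if len(prefix_ids) >= self.max_len:
            raise ValueError("prefix already at maximum efficacy length")
        stream = self._stream(ch, prefix_ids)
        if isinstance(self.core, GRUCore):
            g = Tensor(np.zeros(self.eff_embedding.d)) if s_prev is None else s_prev
            for x in stream[-1:] if s_prev is not None else stream:
                g = self.core([x], g)
        else:
            g = self.core(stream)
        return ad.softmax(self.out(g)), g

    def teacher_forced(self, herb_ids: list[int], label_ids: list[int]
                       ) -> tuple[list[Tensor], Tensor]:
        """Distributions for every label step (labels include EOS); returns
        (per-step distributions, Ch)."""
        ch = self.encode_prescription(herb_ids)
        dists, s_prev = [], None
        for t in range(len(label_ids)):
            dist, s_prev = self.decode_step(ch, label_ids[:t], s_prev)
            dists.append(dist)
        return dists, ch

    def greedy_decode(self, herb_ids: list[int]) -> list[int]:
        """Argmax decoding until EOS or the length cap; deterministic."""
        ch = self.encode_prescription(herb_ids)
        out, s_prev = [], None
        while len(out) < self.max_len:
            dist, s_prev = self.decode_step(ch, out, s_prev)
            nxt = int(np.argmax(dist.data))
            if nxt == self.eos_id:
                break
            out.append(nxt)
        return out
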