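"""The full dual-branch generator network.

Wires together the shared token embeddings, the hybrid symptom encoder,
the prescription→efficacy guidance branch, and the candidates coverage
decoder, and exposes the two entry points the training loop and the user
need: a teacher-forced forward pass over one training pair, and greedy
generation with optional duplicate masking and a step trace.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .ckgm import GuidanceBranch, SimilarityGate, similarity_gate
from .config import ModelConfig
from .corpus import BOS, EOS, PAD, UNK, DataPair, TokenVocab
from .decoder import DecoderStepState, PrescriptionDecoder
from .encoder import HybridEncoder
from .layers import Embedding, Module
from .tkmm import KnowledgeBase, select_candidates

__all__ = ["TCMGenerator", "ForwardResult"]


@dataclass
class ForwardResult:
    """Teacher-forced forward pass of one SP pair."""

    step_states: list[DecoderStepState]
    herb_targets: list[int]              # label herb ids + EOS
    eff_dists: Optional[list[Tensor]]    # guidance-branch step distributions
    eff_targets: Optional[list[int]]     # label efficacy ids + EOS
    gate: Optional[SimilarityGate]
    cs0: Tensor
    ch: Optional[Tensor]


class TCMGenerator(Module):
    def __init__(self, vocab: TokenVocab, config: ModelConfig,
                 chl_herbs: list[str] | None = None):
        super().__init__()
        self.vocab, self.config = vocab, config
        rng = np.random.default_rng(config.seed)
        self.sym_embed = self.add_child(
            "sym_embed", Embedding(rng, len(vocab.symptom), config.d_embed))
        self.herb_embed = self.add_child(
            "herb_embed", Embedding(rng, len(vocab.herb), config.d_embed))
        eff_embed = Embedding(rng, len(vocab.efficacy), config.d_embed)
        self.encoder = self.add_child(
            "encoder", HybridEncoder(rng, self.sym_embed, config.d_hidden,
                                     config.d_att, d_query=config.d_embed))
        self.guidance: Optional[GuidanceBranch] = None
        if config.use_ckgm:
            self.guidance = self.add_child("guidance", GuidanceBranch(
                rng, self.herb_embed, eff_embed, config.d_hidden, config.d_att,
                len(vocab.efficacy), core=config.core, n_layers=config.n_layers,
                n_heads=config.n_heads, max_len=config.max_efficacy_len,
                bos_id=vocab.efficacy.index(BOS), eos_id=vocab.efficacy.index(EOS)))
        self.decoder = self.add_child("decoder", PrescriptionDecoder(
            rng, self.herb_embed, config.d_hidden, config.d_att, len(vocab.herb),
            core=config.core, n_layers=config.n_layers, n_heads=config.n_heads,
            coverage_pool=config.coverage_pool))
        # homoscedastic-uncertainty task weights: [psi1, psi2, phi1, phi2]
        self.rho = self.add_param("rho", np.zeros(4))
        self.set_chl(chl_herbs or [])
        self._special_herb_ids = np.array(
            [vocab.herb.index(t) for t in (PAD, BOS, UNK)])
        self.eos_herb = vocab.herb.index(EOS)

    def set_chl(self, herbs: list[str]) -> None:
        self.chl_herbs = list(herbs)
        self.chl_ids = np.array(self.vocab.herb.encode(herbs), dtype=int)

    # -- helpers --------------------------------------------------------
    def _candidate_tensors(self, hcp_herbs: Optional[list[str]]):
        cfg = self.config
        chl_embeds = chl_ids = hcp_embeds = hcp_ids = None
        if cfg.use_chl and len(self.chl_ids):
            chl_ids = self.chl_ids
            chl_embeds = ad.getitem(self.herb_embed.table, chl_ids)
        if cfg.use_hcp and hcp_herbs:
            hcp_ids = np.array(self.vocab.herb.encode(hcp_herbs), dtype=int)
            hcp_embeds = ad.getitem(self.herb_embed.table, hcp_ids)
        return chl_embeds, chl_ids, hcp_embeds, hcp_ids

    def represent(self, symptoms: list[str]) -> np.ndarray:
        """Frozen-encoder content representation of a symptom sequence."""
        return self.encoder.represent(self.vocab.symptom.encode(symptoms))

    def retrieve(self, symptoms: list[str], kb: KnowledgeBase,
                 exclude_source_id: str | None = None):
        """Candidate pool for a symptom sequence; k is clamped to the KB size."""
        avail = len(kb) - (1 if exclude_source_id is not None else 0)
        k = min(self.config.k, max(avail, 1))
        return select_candidates(kb, self.represent(symptoms), k=k,
                                 lambda1=self.config.lambda1,
                                 ed_norm=self.config.ed_norm,
                                 exclude_source_id=exclude_source_id)

    # -- training forward ----------------------------------------------
    def forward_pair(self, pair: DataPair, hcp_herbs: Optional[list[str]] = None
                     ) -> ForwardResult:
        vocab, cfg = self.vocab, self.config
        sym_ids = vocab.symptom.encode(pair.symptoms)
        enc = self.encoder.encode(sym_ids)
        enc_stacked = enc.stacked()
        herb_targets = vocab.herb.encode(pair.prescription) + [self.eos_herb]
        chl_embeds, chl_ids, hcp_embeds, hcp_ids = self._candidate_tensors(hcp_herbs)
        cache = self.decoder.precompute(enc_stacked, chl_embeds, hcp_embeds)
        wh_cache = self.encoder.attention.w_h(enc_stacked)

        zero = Tensor(np.zeros(cfg.d_embed))
        s_prev, h_prev = zero, zero
        stream: list[Tensor] = []
        generated: list[Tensor] = []
        states: list[DecoderStepState] = []
        cs0 = None
        for t, target in enumerate(herb_targets):
            a_t, cs = self.encoder.content_representation(enc_stacked, s_prev,
                                                          wh_cache=wh_cache)
            if t == 0:
                cs0 = cs
            st = self.decoder.step(enc_stacked, a_t, cs, s_prev, h_prev, stream,
                                   generated, chl_embeds, chl_ids,
                                   hcp_embeds, hcp_ids, cache)
            st.token_id = target
            states.append(st)
            s_prev = st.s_dec
            if target != self.eos_herb:
                h_prev = self.herb_embed(target)
                generated.append(h_prev)

        eff_dists = eff_targets = ch = gate = None
        if self.guidance is not None and pair.efficacy:
            eff_targets = (vocab.efficacy.encode(pair.efficacy)
                           + [vocab.efficacy.index(EOS)])
            eff_dists, ch = self.guidance.teacher_forced(
                vocab.herb.encode(pair.prescription), eff_targets)
            if cfg.use_scm:
                gate = similarity_gate(cs0, ch, cfg.delta)
        return ForwardResult(step_states=states, herb_targets=herb_targets,
                             eff_dists=eff_dists, eff_targets=eff_targets,
                             gate=gate, cs0=cs0, ch=ch)

    # -- generation ------------------------------------------------------
    def generate(self, symptoms: list[str], kb: Optional[KnowledgeBase] = None,
                 mode: str = "mask", max_len: int = 23, emit_trace: bool = False):
        """Greedy decoding; returns the herb token list, or (herbs, trace)
        when ``emit_trace`` is set."""
        if mode not in ("mask", "free"):
            raise ValueError("mode must be 'mask' or 'free'")
        vocab, cfg = self.vocab, self.config
        sym_ids = vocab.symptom.encode(symptoms)
        enc_stacked = self.encoder.encode(sym_ids).stacked()
        hcp_herbs = None
        if kb is not None and cfg.use_hcp and len(kb):
            hcp_herbs = self.retrieve(symptoms, kb).herbs
        chl_embeds, chl_ids, hcp_embeds, hcp_ids = self._candidate_tensors(hcp_herbs)
        cache = self.decoder.precompute(enc_stacked, chl_embeds, hcp_embeds)
        wh_cache = self.encoder.attention.w_h(enc_stacked)

        zero = Tensor(np.zeros(cfg.d_embed))
        s_prev, h_prev = zero, zero
        stream: list[Tensor] = []
        generated: list[Tensor] = []
        out_ids: list[int] = []
        trace: list[dict] = []
        while len(out_ids) < max_len:
            a_t, cs = self.encoder.content_representation(enc_stacked, s_prev,
                                                          wh_cache=wh_cache)
            st = self.decoder.step(enc_stacked, a_t, cs, s_prev, h_prev, stream,
                                   generated, chl_embeds, chl_ids,
                                   hcp_embeds, hcp_ids, cache)
            p = st.p_final.data.copy()
            p[self._special_herb_ids] = 0.0
            if mode == "mask" and out_ids:
                p[np.array(out_ids)] = 0.0
            total = p.sum()
            if total <= 0.0:      # everything masked away: stop cleanly
                break
            p /= total
            tok = int(np.argmax(p))
            st.token_id = tok
            if emit_trace:
                trace.append(st.trace_row())
            if tok == self.eos_herb:
                break
            out_ids.append(tok)
            s_prev = st.s_dec
            h_prev = self.herb_embed(tok)
            generated.append(h_prev)
        herbs = [vocab.herb.token(i) for i in out_ids]
        return (herbs, trace) if emit_trace else herbs
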