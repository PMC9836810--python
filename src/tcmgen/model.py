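"""Model/Results facade over the generator.

`PrescriptionModel` is constructed from corpora (it filters the pairs,
builds the vocabularies and the conventional herb library, and
initialises the network); `fit()` runs teacher-forced training and
returns a `PrescriptionResults` carrying the fitted network, the
knowledge base, the per-epoch loss log, and generation/evaluation
helpers plus a `summary()` table.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np

from .config import ModelConfig
from .corpus import (DataPair, TokenVocab, SubVocab, ConventionalHerbLibrary,
                     build_chl, build_vocab, filter_pairs, herb_counts, load_pairs)
from .evaluation import corpus_metrics
from .network import TCMGenerator
from .objective import TrainLog, train
from .tkmm import KnowledgeBase, build_kb

__all__ = ["PrescriptionModel", "PrescriptionResults"]


class PrescriptionModel:
    """Symptom→prescription generator specified by corpora and a config.

    Parameters
    ----------
    sp_pairs : list of DataPair
        Symptom–prescription training records (filtered to the length caps
        on construction).
    pe_pairs : list of DataPair, optional
        Prescription–efficacy records for the guidance branch.
    config : ModelConfig, optional
        Architecture, knowledge and optimisation settings.
    chl_min_count : int, optional
        Overrides ``config.chl_min_count`` — convenient for small corpora
        where the published high-frequency cutoff would empty the library.
    """

    def __init__(self, sp_pairs: list[DataPair],
                 pe_pairs: Optional[list[DataPair]] = None,
                 config: Optional[ModelConfig] = None,
                 chl_min_count: Optional[int] = None):
        self.config = config or ModelConfig()
        self.sp_pairs = filter_pairs(sp_pairs, self.config.max_symptoms,
                                     self.config.max_herbs)
        if not self.sp_pairs:
            raise ValueError("no SP pairs survive the length filters")
        self.pe_pairs = filter_pairs(pe_pairs, self.config.max_symptoms,
                                     self.config.max_herbs) if pe_pairs else []
        self.vocab = build_vocab(self.sp_pairs, self.pe_pairs)
        min_count = (chl_min_count if chl_min_count is not None
                     else self.config.chl_min_count)
        if self.config.use_chl:
            try:
                self.chl = build_chl(self.sp_pairs, min_count)
            except ValueError:
                # small corpora: fall back to the median herb count so the
                # library keeps the genuinely common herbs
                counts = herb_counts(self.sp_pairs)
                med = int(np.median(list(counts.values())))
                self.chl = build_chl(self.sp_pairs, med)
        else:
            self.chl = ConventionalHerbLibrary(herbs=[], counts={})
        self.network = TCMGenerator(self.vocab, self.config, self.chl.herbs)

    @classmethod
    def from_files(cls, sp_path, pe_path=None, config=None, **kw) -> "PrescriptionModel":
        sp = load_pairs(sp_path, "sp")
        pe = load_pairs(pe_path, "pe") if pe_path else None
        return cls(sp, pe, config, **kw)

    def fit(self, epochs: Optional[int] = None, early_stop=None,
            eval_every: int = 10) -> "PrescriptionResults":
        """Train and return the results wrapper (lowest-loss state kept)."""
        if epochs is not None:
            self.config.epochs = epochs
        log = train(self.network, self.sp_pairs, self.pe_pairs, self.config,
                    early_stop=early_stop, eval_every=eval_every)
        return PrescriptionResults(self, log)

    def build_kb(self, pairs: Optional[list[DataPair]] = None) -> KnowledgeBase:
        return build_kb(pairs or self.sp_pairs, self.network.represent)


class PrescriptionResults:
    """Fitted-model wrapper: estimates, diagnostics, generation."""

    def __init__(self, model: PrescriptionModel, log: TrainLog):
        self.model = model
        self.network = model.network
        self.log = log
        self.kb = log.kb

    # -- diagnostics ----------------------------------------------------
    @property
    def loss_log(self) -> list[dict]:
        return self.log.epochs

    @property
    def task_weights(self) -> dict:
        rho = self.network.rho.data
        return {name: float(np.exp(-rho[i]))
                for i, name in enumerate(("psi1", "psi2", "phi1", "phi2"))}

    def summary(self) -> str:
        cfg = self.model.config
        last = self.log.epochs[-1] if self.log.epochs else {}
        w = self.task_weights
        lines = [
            "Prescription Generation Model Results",
            "=" * 54,
            f"SP pairs (train):        {len(self.model.sp_pairs)}",
            f"PE pairs:                {len(self.model.pe_pairs)}",
            f"herb vocabulary:         {len(self.model.vocab.herb)}",
            f"symptom vocabulary:      {len(self.model.vocab.symptom)}",
            f"conventional library:    {len(self.model.chl)} herbs",
            f"knowledge base:          {len(self.kb) if self.kb else 0} records",
            f"hidden / embed size:     {cfg.d_hidden} / {cfg.d_embed}",
            f"decoder core:            {cfg.core} ({cfg.n_layers} layers)",
            f"retrieval k / lambda1:   {cfg.k} / {cfg.lambda1}",
            f"cosine gate delta:       {cfg.delta}",
            f"epochs run:              {len(self.log.epochs)}"
            + ("  [aborted on non-finite loss]" if self.log.aborted else ""),
            f"best epoch (total loss): {self.log.best_epoch}"
            f"  ({self.log.best_total:.4f})",
            f"final herb soft loss:    {last.get('loss_herb_soft', float('nan')):.4f}",
            f"final guidance loss:     {last.get('loss_ckgm', float('nan')):.4f}",
            "task weights:            "
            f"psi1={w['psi1']:.3f} psi2={w['psi2']:.3f} "
            f"phi1={w['phi1']:.3f} phi2={w['phi2']:.3f}",
            "=" * 54,
        ]
        return "\n".join(lines)

    # -- use ------------------------------------------------------------
    def generate(self, symptoms: list[str], mode: str = "mask",
                 max_len: Optional[int] = None, emit_trace: bool = False):
        return self.network.generate(
            symptoms, kb=self.kb, mode=mode,
            max_len=max_len or self.model.config.max_herbs,
            emit_trace=emit_trace)

    def evaluate(self, pairs: list[DataPair], mode: str = "mask",
                 average: str = "macro") -> dict:
        preds = [(self.generate(p.symptoms, mode=mode), p.prescription)
                 for p in pairs]
        return corpus_metrics(preds, average=average)

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint: parameters (npz) + config and vocab (json sidecar)."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.network.state_dict())
        meta = {
            "config": self.model.config.to_dict(),
            "vocab": {"symptom": self.model.vocab.symptom.itos,
                      "herb": self.model.vocab.herb.itos,
                      "efficacy": self.model.vocab.efficacy.itos},
            "vocab_hash": self.model.vocab.content_hash(),
            "chl": self.model.chl.herbs,
        }
        path.with_suffix(".json").write_text(json.dumps(meta))

    @staticmethod
    def load_network(path) -> TCMGenerator:
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        vocab = TokenVocab(symptom=SubVocab.from_itos(meta["vocab"]["symptom"]),
                           herb=SubVocab.from_itos(meta["vocab"]["herb"]),
                           efficacy=SubVocab.from_itos(meta["vocab"]["efficacy"]))
        net = TCMGenerator(vocab, ModelConfig.from_dict(meta["config"]), meta["chl"])
        with np.load(path.with_suffix(".npz")) as data:
            net.load_state_dict({k: data[k] for k in data.files})
        return net
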