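"""Shared fixtures: tiny synthetic worlds, corpora and models.

Everything is generated at test time from fixed seeds; dimensions are
kept small (8–32) so the full suite runs on one CPU.  The expensive
memorisation fixture is session-scoped and shared by every test that
needs a trained model.
"""

from __future__ import annotations

import numpy as np
import pytest

from tcmgen import (ModelConfig, PrescriptionModel, SynthConfig,
                    generate_corpus, make_world)
from tcmgen.evaluation import corpus_metrics


@pytest.fixture(scope="session")
def small_world():
    cfg = SynthConfig(seed=11, n_pairs_sp=40, n_pairs_pe=16,
                      symptoms_per_pair=(3, 7))
    return cfg, make_world(cfg)


@pytest.fixture(scope="session")
def small_corpus(small_world):
    cfg, world = small_world
    sp, pe = generate_corpus(world, cfg)
    return sp, pe


@pytest.fixture()
def tiny_model(small_corpus):
    """Untrained model with 8-dim layers — cheap enough per-test."""
    sp, pe = small_corpus
    cfg = ModelConfig(d_embed=8, d_hidden=8, d_att=8, n_layers=1, n_heads=1,
                      k=5, epochs=1, seed=5)
    return PrescriptionModel(sp, pe, cfg, chl_min_count=0)


@pytest.fixture(scope="session")
def memorize_setup():
    """The 50-pair memorisation corpus and its model config."""
    cfg = SynthConfig(seed=7, n_pairs_sp=50, n_pairs_pe=20)
    world = make_world(cfg)
    sp, pe = generate_corpus(world, cfg)
    mc = ModelConfig(d_embed=32, d_hidden=32, d_att=32, epochs=300, k=10, seed=7)
    return sp, pe, mc


@pytest.fixture(scope="session")
def overfit_results(memorize_setup):
    """Model trained to memorise 50 synthetic pairs (stops once the
    training-set F1 clears 0.95, within the 300-epoch cap)."""
    sp, pe, mc = memorize_setup
    model = PrescriptionModel(sp, pe, mc, chl_min_count=0)

    def reached_f1(epoch, net, kb):
        preds = [(net.generate(p.symptoms, kb=kb), p.prescription) for p in sp]
        return corpus_metrics(preds)["f1"] >= 0.95

    return model.fit(early_stop=reached_f1, eval_every=10)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
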