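"""Model and training configuration."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class ModelConfig:
    """Hyperparameters of the generator and its training loop.

    The published settings (embedding/hidden size 512, 500 epochs, batch 64)
    target GPU-scale corpora; desk-scale defaults here are small, and tests
    use 8–64 dimensions.  Field groups:

    * architecture — ``d_embed``/``d_hidden`` (token embedding and recurrent
      state sizes), ``d_att`` (attention score space), ``core`` (autoregressive
      decoder core: ``"transformer"`` or ``"gru"``) with depth/width knobs;
    * knowledge — ``k`` retrieved neighbours, blend weight ``lambda1``
      (``lambda2 = 1 - lambda1``), cosine gate threshold ``delta``,
      conventional-library cutoff ``chl_min_count``;
    * ablation switches — ``use_ckgm`` (prescription→efficacy guidance
      branch), ``use_scm`` (similarity gate), ``use_hcp``/``use_chl``
      (candidate sets; with both off the decoder is generation-only);
    * optimisation — Adam with the published defaults (lr 1e-3,
      betas 0.9/0.999, eps 1e-6); ``uncertainty_weighting`` learns the task
      weights psi/phi as exp(-rho) with a +rho regulariser, else they are
      fixed at the ``fixed_*`` values.
    """

    d_embed: int = 32
    d_hidden: int = 32
    d_att: int = 32
    core: str = "transformer"
    n_layers: int = 2
    n_heads: int = 2

    k: int = 20
    lambda1: float = 0.4
    delta: float = 0.6
    chl_min_count: int = 480
    ed_norm: str = "max"          # "max" or "minmax" per-query ED normalisation
    kb_refresh_epochs: int = 1
    kb_exclude_self: bool = True

    max_symptoms: int = 21
    max_herbs: int = 23
    max_efficacy_len: int = 8
    coverage_pool: str = "sum"    # "sum" or "mean" over generated-herb embeddings

    use_ckgm: bool = True
    use_scm: bool = True
    use_hcp: bool = True
    use_chl: bool = True

    lr: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-6
    epochs: int = 50
    batch_size: int = 8
    ckgm_pretrain_epochs: int = 0
    uncertainty_weighting: bool = True
    fixed_psi: tuple[float, float] = (1.0, 1.0)
    fixed_phi: tuple[float, float] = (1.0, 1.0)
    seed: int = 0

    @property
    def lambda2(self) -> float:
        return 1.0 - self.lambda1

    def __post_init__(self):
        if not 0.0 <= self.lambda1 <= 1.0:
            raise ValueError("lambda1 must lie in [0, 1]")
        if self.core not in ("transformer", "gru"):
            raise ValueError("core must be 'transformer' or 'gru'")
        if self.ed_norm not in ("max", "minmax"):
            raise ValueError("ed_norm must be 'max' or 'minmax'")
        if self.coverage_pool not in ("sum", "mean"):
            raise ValueError("coverage_pool must be 'sum' or 'mean'")
        if not self.use_chl and not self.use_hcp:
            # legal: generation-only ablation; copy branch disabled downstream
            pass

    def to_dict(self) -> dict:
        d = asdict(self)
        d["betas"] = list(self.betas)
        d["fixed_psi"] = list(self.fixed_psi)
        d["fixed_phi"] = list(self.fixed_phi)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("betas", "fixed_psi", "fixed_phi"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)
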